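"""Unit tests for the contribution/migration optimizer."""

import numpy as np
import pytest

from metadiv._kernels import score_kernel
from metadiv.divstats import het_partition
from metadiv.optimizer import (
    AnnealSchedule,
    Objective,
    allele_loss_prob,
    allele_loss_probs,
    anneal,
    expected_progeny_freqs,
    initial_plan,
    objective_value,
    propose_move,
    random_plan,
    _dosage_arrays,
)

from conftest import enumerate_tiny_plans, make_gm, mendelian_loss_oracle, random_gm

A, B = 0, 1


def one_deme_gm(sire_geno, dam_geno):
    """One deme with one male (index 1) and one female (index 0)."""
    return make_gm([[dam_geno], [sire_geno]], [0, 0], sex=[0, 1])


def plan_single_mating(gm, n_offspring):
    import numpy as np
    from metadiv.optimizer import ContributionPlan

    T = n_offspring
    return ContributionPlan(
        np.zeros(T, np.int64),
        np.ones(T, np.int64),
        np.zeros(T, np.int64),
        np.zeros(T, np.int64),
        gm.deme.astype(np.int64),
        gm.sex.astype(np.int64),
        np.array([T], dtype=np.int64),
    )


class TestObjectiveTypes:
    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError):
            Objective("maxFoo")

    @pytest.mark.parametrize("kwargs", [{"lam": -1.0}, {"lam": float("inf")},
                                        {"migrant_budget": -0.5}])
    def test_invalid_weights_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Objective("maxHT", **kwargs)

    def test_budget_rounds_to_population_total(self):
        assert Objective("maxHT", migrant_budget=0.4).total_migrants(5) == 2
        assert Objective("maxHT", migrant_budget=1.0).total_migrants(5) == 5
        assert Objective("maxHT", migrant_budget=2.0).total_migrants(5) == 10

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(cooling=1.5)


class TestExpectedProgenyFreqs:
    def test_sole_homozygous_contributors(self):
        gm = one_deme_gm([A, A], [A, A])
        ft = expected_progeny_freqs(plan_single_mating(gm, 4), gm)
        assert ft.freqs[0, 0, A] == 1.0

    def test_sole_heterozygous_contributors(self):
        gm = one_deme_gm([A, B], [A, B])
        ft = expected_progeny_freqs(plan_single_mating(gm, 4), gm)
        assert ft.freqs[0, 0, A] == pytest.approx(0.5)

    def test_dosage_weighting(self):
        # sire A/B and dam A/A each give 40 gametes into a deme of 40:
        # p'_A = (40 * 0.5 + 40 * 1.0) / 80 = 0.75
        gm = one_deme_gm([A, B], [A, A])
        ft = expected_progeny_freqs(plan_single_mating(gm, 40), gm)
        assert ft.freqs[0, 0, A] == pytest.approx(0.75)
        assert ft.freqs[0, 0, B] == pytest.approx(0.25)

    def test_frequencies_sum_to_one(self, rng):
        gm = random_gm(rng, n_demes=2, per_deme=6, n_loci=4, n_alleles=5)
        plan = initial_plan(gm, 2, rng)
        ft = expected_progeny_freqs(plan, gm)
        assert np.allclose(ft.freqs.sum(axis=2), 1.0)


class TestAlleleLoss:
    def test_homozygous_carrier_never_loses(self):
        gm = one_deme_gm([A, A], [B, B])
        assert allele_loss_prob(plan_single_mating(gm, 2), gm, 0, A, 0) == 0.0

    def test_single_het_two_gametes(self):
        # dam is the only A carrier (het); two independent halvings
        gm = one_deme_gm([B, B], [A, B])
        assert allele_loss_prob(plan_single_mating(gm, 2), gm, 0, A, 0) == 0.25

    def test_two_het_carriers_unequal_gametes(self):
        # het sire with 1 gamete + het dam with 3 gametes: (1/2)^4 = 0.0625
        import numpy as np
        from metadiv.optimizer import ContributionPlan

        gm = make_gm([[[B, B]], [[A, B]], [[A, B]]], [0, 0, 0], sex=[0, 1, 1])
        plan = ContributionPlan(
            np.zeros(4, np.int64),
            np.array([1, 2, 2, 2], np.int64),
            np.zeros(4, np.int64),
            np.zeros(4, np.int64),
            gm.deme.astype(np.int64),
            gm.sex.astype(np.int64),
            np.array([4], np.int64),
        )
        # A carriers entering the deme: het sire 1 (g=1) and het sire 2 (g=3)
        got = allele_loss_prob(plan, gm, 0, A, 0)
        assert got == pytest.approx(0.0625)
        assert got == pytest.approx(mendelian_loss_oracle(plan, gm, 0, A, 0))

    def test_absent_allele_loss_is_one(self):
        gm = one_deme_gm([A, A], [A, A])
        assert allele_loss_prob(plan_single_mating(gm, 2), gm, 0, B, 0) == 1.0

    def test_loss_non_increasing_in_gamete_count(self):
        gm = one_deme_gm([B, B], [A, B])
        losses = [
            allele_loss_prob(plan_single_mating(gm, n), gm, 0, A, 0)
            for n in (1, 2, 4, 8)
        ]
        assert all(x > y for x, y in zip(losses, losses[1:]))

    def test_matches_mendelian_enumeration_on_random_plans(self, rng):
        gm = random_gm(rng, n_demes=2, per_deme=4, n_loci=2, n_alleles=3)
        plan = initial_plan(gm, 1, rng, dest_sizes=[2, 2])
        loss = allele_loss_probs(plan, gm)
        for dest in range(2):
            for locus in range(2):
                for allele in range(3):
                    assert loss[dest, locus, allele] == pytest.approx(
                        mendelian_loss_oracle(plan, gm, locus, allele, dest), abs=1e-12
                    )


class TestObjectiveValue:
    def test_lambda_scales_the_within_component_linearly(self, rng):
        gm = random_gm(rng, n_demes=2, per_deme=6, n_loci=3, n_alleles=4)
        plan = initial_plan(gm, 2, rng)
        for method in ("maxHT", "maxAT"):
            s0 = objective_value(plan, gm, Objective(method, 0.0))
            s1 = objective_value(plan, gm, Objective(method, 1.0))
            s2 = objective_value(plan, gm, Objective(method, 2.0))
            assert s2 - s1 == pytest.approx(s1 - s0, abs=1e-10)

    def test_single_deme_maxht_is_expected_progeny_heterozygosity(self, rng):
        gm = random_gm(rng, n_demes=1, per_deme=8, n_loci=3, n_alleles=4)
        plan = random_plan(gm, rng)
        score = objective_value(plan, gm, Objective("maxHT", 1.0))
        h_s, d_g, _ = het_partition(expected_progeny_freqs(plan, gm))
        assert d_g == pytest.approx(0.0)
        assert score == pytest.approx(h_s)

    def test_rnd_has_no_objective(self, rng):
        gm = random_gm(rng)
        plan = random_plan(gm, rng)
        with pytest.raises(ValueError):
            objective_value(plan, gm, Objective("RND"))

    def test_kernel_agrees_with_reference_implementation(self, rng):
        gm = random_gm(rng, n_demes=3, per_deme=6, n_loci=4, n_alleles=6)
        xhalf, het, hom = _dosage_arrays(gm, np.arange(gm.n_loci))
        sizes = gm.deme_sizes().astype(np.float64)
        for _ in range(5):
            plan = initial_plan(gm, 3, rng)
            for method, lam in (("maxHT", 0.7), ("maxAT", 1.3), ("maxK", 1.0)):
                ref = objective_value(plan, gm, Objective(method, lam))
                got = score_kernel(
                    plan.sire, plan.dam, plan.dest, xhalf, het, hom,
                    {"maxHT": 0, "maxAT": 1, "maxK": 2}[method], lam, sizes,
                )
                assert got == pytest.approx(ref, abs=1e-10)


class TestMoves:
    def test_moves_preserve_all_plan_constraints(self, rng):
        gm = random_gm(rng, n_demes=3, per_deme=6, n_loci=3, n_alleles=4)
        plan = initial_plan(gm, 3, rng)
        for _ in range(300):
            plan = propose_move(plan, rng)
            plan.validate(migrant_total=3)

    def test_random_walk_reaches_every_feasible_plan(self, rng):
        # tiny instance: 2 demes x (1F + 2M), one offspring pair per deme,
        # exactly one migrant; the move graph must cover the whole plan space
        codes = rng.integers(0, 3, size=(6, 1, 2)).astype(np.uint8)
        gm = make_gm(codes, [0, 0, 0, 1, 1, 1], sex=[0, 1, 1, 0, 1, 1])
        all_plans = {p.canonical() for p in enumerate_tiny_plans(gm, [2, 2], 1)}
        plan = initial_plan(gm, 1, rng, dest_sizes=[2, 2])
        seen = {plan.canonical()}
        for _ in range(6000):
            plan = propose_move(plan, rng)
            seen.add(plan.canonical())
        assert seen == all_plans


class TestRandomPlan:
    def test_quota_and_no_migration(self, rng):
        gm = random_gm(rng, n_demes=3, per_deme=8, n_loci=2)
        plan = random_plan(gm, rng)
        plan.validate(migrant_total=0)
        assert plan.migrant_count == 0
        assert np.bincount(plan.dest).tolist() == [8, 8, 8]

    def test_contributions_are_multinomial(self, rng):
        # expected contribution 2 offspring per parent of each sex; the
        # realized female variance is almost surely positive
        gm = random_gm(rng, n_demes=1, per_deme=40, n_loci=2)
        plan = random_plan(gm, rng)
        counts = np.bincount(plan.dam, minlength=40)[:20]
        assert counts.sum() == 40
        assert counts.astype(float).var() > 0


class TestAnneal:
    def test_same_seed_is_bitwise_reproducible(self, rng):
        gm = random_gm(rng, n_demes=2, per_deme=6, n_loci=3, n_alleles=4)
        sched = AnnealSchedule(iters=500, per_temp=50)
        p1, s1 = anneal(gm, Objective("maxAT"), np.arange(3), sched, seed=42)
        p2, s2 = anneal(gm, Objective("maxAT"), np.arange(3), sched, seed=42)
        assert s1 == s2
        assert p1.canonical() == p2.canonical()

    def test_anneal_beats_random_plans_on_average(self, rng):
        gm = random_gm(rng, n_demes=2, per_deme=6, n_loci=3, n_alleles=5)
        sched = AnnealSchedule(iters=800, per_temp=80)
        for method in ("maxHT", "maxAT", "maxK"):
            obj = Objective(method, 1.0, 1.0)
            ann, rnd = [], []
            for seed in range(20):
                _, s = anneal(gm, obj, np.arange(3), sched, seed=seed)
                ann.append(s)
                r = np.random.default_rng(seed)
                rnd.append(objective_value(random_plan(gm, r), gm, obj))
            assert np.mean(ann) >= np.mean(rnd)

    def test_single_feasible_plan_is_returned(self):
        # one parent pair per deme, no migration: only one canonical plan
        codes = np.zeros((4, 2, 2), dtype=np.uint8)
        gm = make_gm(codes, [0, 0, 1, 1], sex=[0, 1, 0, 1])
        sched = AnnealSchedule(iters=100, per_temp=10)
        plan, _ = anneal(gm, Objective("maxHT", migrant_budget=0.0), np.arange(2), sched, 0)
        assert plan.migrant_count == 0
        assert set(plan.sire.tolist()) <= {1, 3}
        assert set(plan.dam.tolist()) <= {0, 2}
        plan.validate(migrant_total=0)
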