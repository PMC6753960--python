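"""Optimal contributions, matings and migrations by simulated annealing.

A contribution plan assigns every offspring of the next generation a natal
deme, a sire and dam from that deme, and a destination deme (a *migrant* is
an offspring whose destination differs from its natal deme).  The annealer
searches plans maximizing one of three objectives computed on the expected
progeny:

* ``maxHT`` - total gene diversity, D_G + lambda * H_S, on expected progeny
  allele frequencies;
* ``maxAT`` - total allelic diversity, D_A + lambda * A_S, where expected
  allele counts use per-allele retention probabilities under independent
  Mendelian transmission (demes and alleles treated as independent);
* ``maxK`` - expected number of alleles retained anywhere in the population
  (equivalently, the summed global allele-loss probability is minimized).

``RND`` is the unmanaged control: parents drawn uniformly with replacement,
no migration.

The migration budget is a population-wide total of round(m * n_demes)
migrants per generation; the initial plan realizes it exactly and every
search move preserves it, so managed runs at level m = 1 place on average
exactly one migrant per deme per generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import _kernels
from .divstats import FreqTable, het_partition
from .markers import MAX_ALLELES, GenotypeMatrix

__all__ = [
    "Objective",
    "AnnealSchedule",
    "ContributionPlan",
    "METHODS",
    "expected_progeny_freqs",
    "allele_loss_prob",
    "allele_loss_probs",
    "objective_value",
    "propose_move",
    "random_plan",
    "initial_plan",
    "anneal",
]

METHODS = ("maxHT", "maxAT", "maxK", "RND")
_METHOD_CODE = {"maxHT": 0, "maxAT": 1, "maxK": 2}


@dataclass(frozen=True)
class Objective:
    """Management objective: method, within-deme weight, migration level."""

    method: str
    lam: float = 1.0
    migrant_budget: float = 1.0  # mean migrants per deme per generation

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError("lambda must be finite and >= 0")
        if self.migrant_budget < 0:
            raise ValueError("migrant budget must be >= 0")

    def total_migrants(self, n_demes: int) -> int:
        return int(round(self.migrant_budget * n_demes))


@dataclass(frozen=True)
class AnnealSchedule:
    """Annealing schedule; ``t0 <= 0`` auto-calibrates the temperature from
    ``n_probe`` probe moves so early worsening moves are accepted ~50% of
    the time."""

    t0: float = 0.0
    cooling: float = 0.95
    per_temp: int = 200
    iters: int = 30_000
    n_probe: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise ValueError("cooling must be in (0, 1)")
        if self.iters <= 0 or self.per_temp <= 0:
            raise ValueError("iters and per_temp must be positive")


@dataclass
class ContributionPlan:
    """Per-offspring contribution/migration assignment.

    Arrays are indexed by offspring slot; ``sire``/``dam`` hold global
    parent indices into the genotype matrix the plan was built from.
    """

    natal: np.ndarray  # (T,) int64 natal deme of each offspring
    sire: np.ndarray  # (T,) int64
    dam: np.ndarray  # (T,) int64
    dest: np.ndarray  # (T,) int64 destination deme
    parent_deme: np.ndarray  # (P,) deme of every candidate parent
    parent_sex: np.ndarray  # (P,) 0 = female, 1 = male
    dest_sizes: np.ndarray  # (D,) configured offspring count per deme

    @property
    def n_offspring(self) -> int:
        return self.natal.size

    @property
    def n_parents(self) -> int:
        return self.parent_deme.size

    @property
    def n_demes(self) -> int:
        return self.dest_sizes.size

    @property
    def migrant_count(self) -> int:
        return int((self.natal != self.dest).sum())

    def copy(self) -> "ContributionPlan":
        return ContributionPlan(
            self.natal.copy(),
            self.sire.copy(),
            self.dam.copy(),
            self.dest.copy(),
            self.parent_deme,
            self.parent_sex,
            self.dest_sizes,
        )

    def gamete_counts(self) -> np.ndarray:
        """g[k, d]: gametes parent k contributes to destination deme d."""
        g = np.zeros((self.n_parents, self.n_demes))
        np.add.at(g, (self.sire, self.dest), 1.0)
        np.add.at(g, (self.dam, self.dest), 1.0)
        return g

    def entries(self) -> pd.DataFrame:
        """Aggregated (natal, sire, dam, dest) -> offspring count table."""
        df = pd.DataFrame(
            {
                "natal_deme": self.natal,
                "sire": self.sire,
                "dam": self.dam,
                "dest_deme": self.dest,
            }
        )
        out = (
            df.groupby(["natal_deme", "sire", "dam", "dest_deme"])
            .size()
            .rename("n_offspring")
            .reset_index()
        )
        return out

    def validate(self, migrant_total: int | None = None) -> None:
        if not (
            self.natal.shape == self.sire.shape == self.dam.shape == self.dest.shape
        ):
            raise ValueError("plan arrays have inconsistent shapes")
        if np.any(self.parent_sex[self.sire] != 1):
            raise ValueError("sires must be male")
        if np.any(self.parent_sex[self.dam] != 0):
            raise ValueError("dams must be female")
        if np.any(self.parent_deme[self.sire] != self.natal) or np.any(
            self.parent_deme[self.dam] != self.natal
        ):
            raise ValueError("sire and dam must belong to the offspring's natal deme")
        got = np.bincount(self.dest, minlength=self.n_demes)
        if not np.array_equal(got, self.dest_sizes):
            raise ValueError("per-destination offspring totals do not match")
        if migrant_total is not None and self.migrant_count != migrant_total:
            raise ValueError("migrant count does not match the budget")

    def canonical(self) -> tuple:
        """Hashable form invariant to offspring ordering (for tests/ties)."""
        recs = sorted(zip(self.dest, self.natal, self.sire, self.dam))
        return tuple((int(a), int(b), int(c), int(d)) for a, b, c, d in recs)


# ---------------------------------------------------------------------------
# plan construction


def _parent_pools(
    parent_deme: np.ndarray, parent_sex: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular (n_demes, n_per_sex) tables of female/male parent indices."""
    demes = np.unique(parent_deme)
    fem = [np.nonzero((parent_deme == d) & (parent_sex == 0))[0] for d in demes]
    mal = [np.nonzero((parent_deme == d) & (parent_sex == 1))[0] for d in demes]
    if len({f.size for f in fem}) != 1 or len({m.size for m in mal}) != 1:
        raise ValueError("demes must have equal counts of each sex")
    if fem[0].size == 0 or mal[0].size == 0:
        raise ValueError("every deme needs at least one parent of each sex")
    return np.array(fem, dtype=np.int64), np.array(mal, dtype=np.int64)


def _require_sexed(gm: GenotypeMatrix) -> None:
    if gm.sex is None:
        raise ValueError("genotype matrix must carry sexes to build plans")


def _dest_sizes(gm: GenotypeMatrix, dest_sizes) -> np.ndarray:
    if dest_sizes is None:
        return gm.deme_sizes().astype(np.int64)
    return np.asarray(dest_sizes, dtype=np.int64)


def random_plan(
    gm: GenotypeMatrix,
    rng: np.random.Generator,
    dest_sizes=None,
) -> ContributionPlan:
    """Unmanaged control: uniform parents within the natal deme, no migration."""
    _require_sexed(gm)
    sizes = _dest_sizes(gm, dest_sizes)
    pool_f, pool_m = _parent_pools(gm.deme, gm.sex)
    dest = np.repeat(np.arange(sizes.size, dtype=np.int64), sizes)
    natal = dest.copy()
    sire = pool_m[natal, rng.integers(0, pool_m.shape[1], natal.size)]
    dam = pool_f[natal, rng.integers(0, pool_f.shape[1], natal.size)]
    return ContributionPlan(
        natal, sire, dam, dest, gm.deme.astype(np.int64), gm.sex.astype(np.int64), sizes
    )


def initial_plan(
    gm: GenotypeMatrix,
    migrant_total: int,
    rng: np.random.Generator,
    dest_sizes=None,
) -> ContributionPlan:
    """Feasible starting plan with exactly ``migrant_total`` migrants."""
    plan = random_plan(gm, rng, dest_sizes)
    D = plan.n_demes
    if migrant_total > 0 and D < 2:
        raise ValueError("migration requires at least two demes")
    if migrant_total > plan.n_offspring:
        raise ValueError("migrant budget exceeds total offspring")
    pool_f, pool_m = _parent_pools(plan.parent_deme, plan.parent_sex)
    resident = np.nonzero(plan.natal == plan.dest)[0]
    slots = rng.permutation(resident)[:migrant_total]
    for i, t in enumerate(slots):
        d = plan.dest[t]
        j = int(rng.integers(0, D - 1))
        if j >= d:
            j += 1
        plan.natal[t] = j
        plan.sire[t] = pool_m[j, rng.integers(0, pool_m.shape[1])]
        plan.dam[t] = pool_f[j, rng.integers(0, pool_f.shape[1])]
    return plan


# ---------------------------------------------------------------------------
# expected-progeny quantities


def _dosage_arrays(gm: GenotypeMatrix, loci: np.ndarray):
    """Per-parent allelic dosage/2 plus het/hom carrier flags on ``loci``."""
    sel = gm.codes[:, loci, :]
    n, k, _ = sel.shape
    cnt = np.zeros(n * k * MAX_ALLELES, dtype=np.int64)
    base = np.arange(n * k) * MAX_ALLELES
    for copy in range(2):
        np.add.at(cnt, base + sel[:, :, copy].ravel().astype(np.int64), 1)
    cnt = cnt.reshape(n, k, MAX_ALLELES)
    xhalf = cnt / 2.0
    het = (cnt == 1).astype(np.uint8)
    hom = (cnt == 2).astype(np.uint8)
    return xhalf, het, hom


def expected_progeny_freqs(
    plan: ContributionPlan, gm: GenotypeMatrix, loci: np.ndarray | None = None
) -> FreqTable:
    """Expected progeny allele frequencies per destination deme.

    p'(d, l, a) = sum_k g[k, d] * x[k, l, a] / (2 N_d), where x is the
    parent's allelic dosage divided by 2 and g its gamete count into d.
    """
    loci = np.arange(gm.n_loci) if loci is None else np.asarray(loci, dtype=np.intp)
    plan.validate()
    xhalf, _, _ = _dosage_arrays(gm, loci)
    g = plan.gamete_counts()
    freqs = np.einsum("kd,kla->dla", g, xhalf) / (2.0 * plan.dest_sizes)[:, None, None]
    return FreqTable(freqs, plan.dest_sizes.copy(), loci)


def allele_loss_probs(
    plan: ContributionPlan, gm: GenotypeMatrix, loci: np.ndarray | None = None
) -> np.ndarray:
    """P_loss(d, l, a): probability allele a at locus l reaches no offspring
    in destination deme d, under independent Mendelian transmissions.

    Heterozygous carriers contribute (1/2)^g, homozygous carriers 0 (for
    g >= 1) and non-carriers 1; alleles with no contributing carrier have
    loss probability 1.
    """
    loci = np.arange(gm.n_loci) if loci is None else np.asarray(loci, dtype=np.intp)
    _, het, hom = _dosage_arrays(gm, loci)
    g = plan.gamete_counts()  # (P, D)
    S = np.einsum("kd,kla->dla", g, het.astype(float))
    hom_present = np.einsum("kd,kla->dla", (g > 0).astype(float), hom.astype(float)) > 0
    loss = np.power(0.5, S)
    loss[hom_present] = 0.0
    return loss


def allele_loss_prob(
    plan: ContributionPlan, gm: GenotypeMatrix, locus: int, allele: int, dest: int
) -> float:
    """Scalar convenience wrapper around :func:`allele_loss_probs`."""
    loss = allele_loss_probs(plan, gm, np.array([locus]))
    return float(loss[dest, 0, allele])


def objective_value(
    plan: ContributionPlan,
    gm: GenotypeMatrix,
    obj: Objective,
    loci: np.ndarray | None = None,
) -> float:
    """Reference (numpy) evaluation of the annealing objective."""
    if obj.method == "RND":
        raise ValueError("RND has no objective value")
    loci = np.arange(gm.n_loci) if loci is None else np.asarray(loci, dtype=np.intp)
    if obj.method == "maxHT":
        ft = expected_progeny_freqs(plan, gm, loci)
        h_s, d_g, _ = het_partition(ft)
        return d_g + obj.lam * h_s
    loss = allele_loss_probs(plan, gm, loci)
    R = 1.0 - loss  # retention probability per (deme, locus, allele)
    D, K, _ = R.shape
    if obj.method == "maxAT":
        a_s = R.sum() / (D * K) - 1.0
        d_a = 0.0
        if D >= 2:
            pairs = list(combinations(range(D), 2))
            acc = sum(
                (R[i] * (1 - R[j]) + R[j] * (1 - R[i])).sum() * 0.5 for i, j in pairs
            )
            d_a = acc / (K * len(pairs))
        return d_a + obj.lam * a_s
    # maxK
    return float((1.0 - np.prod(loss, axis=0)).sum() / K)


# ---------------------------------------------------------------------------
# search


def propose_move(plan: ContributionPlan, rng: np.random.Generator) -> ContributionPlan:
    """One uniformly-chosen elementary move; returns a new plan (the input is
    unchanged).  Infeasible draws return an unchanged copy.

    Moves: (a) reassign one offspring's mating (origin re-drawn among other
    demes for migrants); (b) replace the sire or dam of one whole mating;
    (c) swap destinations of two offspring from different natal demes when
    that preserves the migrant count; (d) relocate a migration.  All moves
    preserve per-destination totals and the exact total migrant count.
    """
    new = plan.copy()
    pool_f, pool_m = _parent_pools(plan.parent_deme, plan.parent_sex)
    T = plan.n_offspring
    D = plan.n_demes
    mtype = int(rng.integers(0, 4))
    if mtype == 0:
        t = int(rng.integers(T))
        d = new.dest[t]
        if new.natal[t] == d:
            j = d
        elif D >= 2:
            j = int(rng.integers(D - 1))
            if j >= d:
                j += 1
        else:
            j = new.natal[t]
        new.natal[t] = j
        new.sire[t] = pool_m[j, rng.integers(pool_m.shape[1])]
        new.dam[t] = pool_f[j, rng.integers(pool_f.shape[1])]
    elif mtype == 1:
        t = int(rng.integers(T))
        key = (new.natal[t], new.sire[t], new.dam[t], new.dest[t])
        members = (
            (new.natal == key[0])
            & (new.sire == key[1])
            & (new.dam == key[2])
            & (new.dest == key[3])
        )
        if rng.random() < 0.5:
            newp = pool_m[key[0], rng.integers(pool_m.shape[1])]
            new.sire[members] = newp
        else:
            newp = pool_f[key[0], rng.integers(pool_f.shape[1])]
            new.dam[members] = newp
    elif mtype == 2:
        t1, t2 = rng.integers(T, size=2)
        if (
            t1 != t2
            and new.natal[t1] != new.natal[t2]
            and new.dest[t1] != new.dest[t2]
        ):
            before = int(new.natal[t1] != new.dest[t1]) + int(
                new.natal[t2] != new.dest[t2]
            )
            after = int(new.natal[t1] != new.dest[t2]) + int(
                new.natal[t2] != new.dest[t1]
            )
            if before == after:
                new.dest[[t1, t2]] = new.dest[[t2, t1]]
    else:
        if D >= 2:
            mig = np.nonzero(new.natal != new.dest)[0]
            res = np.nonzero(new.natal == new.dest)[0]
            if mig.size > 0 and res.size > 0:
                t1 = int(rng.choice(mig))
                t2 = int(rng.choice(res))
                j1 = new.dest[t1]
                new.natal[t1] = j1
                new.sire[t1] = pool_m[j1, rng.integers(pool_m.shape[1])]
                new.dam[t1] = pool_f[j1, rng.integers(pool_f.shape[1])]
                j2 = int(rng.integers(D - 1))
                if j2 >= new.dest[t2]:
                    j2 += 1
                new.natal[t2] = j2
                new.sire[t2] = pool_m[j2, rng.integers(pool_m.shape[1])]
                new.dam[t2] = pool_f[j2, rng.integers(pool_f.shape[1])]
    return new


def anneal(
    gm: GenotypeMatrix,
    obj: Objective,
    loci: np.ndarray,
    schedule: AnnealSchedule,
    seed: int,
    dest_sizes=None,
) -> tuple[ContributionPlan, float]:
    """Search a contribution/migration plan maximizing the objective.

    Returns the best plan visited and its score; bitwise reproducible for a
    given ``seed``.
    """
    if obj.method == "RND":
        raise ValueError("use random_plan for the unmanaged control")
    _require_sexed(gm)
    loci = np.asarray(loci, dtype=np.intp)
    rng = np.random.default_rng(seed)
    sizes = _dest_sizes(gm, dest_sizes)
    B = obj.total_migrants(sizes.size)
    plan = initial_plan(gm, B, rng, sizes)
    xhalf, het, hom = _dosage_arrays(gm, loci)
    pool_f, pool_m = _parent_pools(plan.parent_deme, plan.parent_sex)
    b_natal, b_sire, b_dam, b_dest, best = _kernels.anneal_kernel(
        plan.natal.copy(),
        plan.sire.copy(),
        plan.dam.copy(),
        plan.dest.copy(),
        xhalf,
        het,
        hom,
        pool_f,
        pool_m,
        _METHOD_CODE[obj.method],
        float(obj.lam),
        sizes.astype(np.float64),
        schedule.t0,
        schedule.cooling,
        schedule.per_temp,
        schedule.iters,
        schedule.n_probe,
        int(rng.integers(0, 2**31 - 1)),
    )
    out = ContributionPlan(
        b_natal, b_sire, b_dam, b_dest, plan.parent_deme, plan.parent_sex, sizes
    )
    out.validate(migrant_total=B)
    return out, float(best)
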