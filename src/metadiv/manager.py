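"""The 25-generation conservation-management loop.

Each generation: optimize (or randomize) a contribution/migration plan on
the managed marker loci, realize the progeny by Mendelian sampling, and
record the diversity statistics on the configured measurement scope (the
managed loci themselves, or the whole genome).

During management there is no mutation and no recombination within a marker
locus; whole 5-SNP locus alleles assort independently across loci (free
recombination between loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divstats import DiversityReport, allele_freqs, compute_report
from .markers import GenotypeMatrix, ManagedSet
from .optimizer import (
    AnnealSchedule,
    ContributionPlan,
    Objective,
    anneal,
    random_plan,
)

__all__ = ["ManagementRun", "make_progeny", "run_management"]


@dataclass
class ManagementRun:
    """Results of one management run: per-generation reports and metadata."""

    method: str
    lam: float
    migrant_budget: float
    generations: int
    reports: list[DiversityReport]
    seed: int
    scores: list[float] = field(default_factory=list)
    plans: list[ContributionPlan] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_dict() for r in self.reports])
        df.insert(0, "method", self.method)
        df.insert(1, "lambda", self.lam)
        df.insert(2, "migration", self.migrant_budget)
        return df


def make_progeny(
    plan: ContributionPlan, gm: GenotypeMatrix, rng: np.random.Generator
) -> GenotypeMatrix:
    """Realize the progeny generation prescribed by a plan.

    Every offspring receives, independently at each locus, one of its
    sire's two locus alleles with probability 1/2 and likewise from its
    dam (independent assortment of whole 5-SNP blocks; no mutation).
    Offspring are placed in their destination demes and sexes fill each
    deme's 50/50 quota uniformly at random.
    """
    if plan.n_parents != gm.n_ind:
        raise ValueError("plan does not reference this parental generation")
    plan.validate()
    T = plan.n_offspring
    K = gm.n_loci
    sire_codes = gm.codes[plan.sire]  # (T, K, 2)
    dam_codes = gm.codes[plan.dam]
    pick_s = rng.integers(0, 2, size=(T, K, 1))
    pick_d = rng.integers(0, 2, size=(T, K, 1))
    gam_pat = np.take_along_axis(sire_codes, pick_s, axis=2)[:, :, 0]
    gam_mat = np.take_along_axis(dam_codes, pick_d, axis=2)[:, :, 0]
    codes = np.stack([gam_mat, gam_pat], axis=2)  # (T, K, 2)

    order = np.argsort(plan.dest, kind="stable")
    codes = codes[order]
    deme = plan.dest[order].astype(np.int32)
    sex = np.empty(T, dtype=np.uint8)
    start = 0
    for d, n_d in enumerate(plan.dest_sizes):
        if n_d % 2 != 0:
            raise ValueError("deme sizes must be even for 50/50 sexing")
        s = np.repeat(np.uint8([0, 1]), n_d // 2)
        sex[start : start + n_d] = rng.permutation(s)
        start += n_d
    return GenotypeMatrix(codes=codes, deme=deme, sex=sex, locus_map=gm.locus_map)


def run_management(
    founders: GenotypeMatrix,
    obj: Objective,
    gens: int,
    managed: ManagedSet,
    rng: np.random.Generator,
    schedule: AnnealSchedule | None = None,
    keep_plans: bool = False,
) -> ManagementRun:
    """Run the management loop for ``gens`` generations.

    Optimization always uses the managed loci; statistics are measured on
    the managed loci themselves or, when ``managed.measure_genome_wide``,
    on every locus of the genome.  The baseline allele set for VarFreq is
    recorded from the founders at generation 0.
    """
    if founders.sex is None:
        raise ValueError("founders must be sexed")
    measure = (
        np.arange(founders.n_loci) if managed.measure_genome_wide else managed.loci
    )
    baseline = allele_freqs(founders, measure).presence().any(axis=0)
    schedule = schedule or AnnealSchedule()
    run = ManagementRun(
        method=obj.method,
        lam=obj.lam,
        migrant_budget=obj.migrant_budget,
        generations=gens,
        reports=[compute_report(founders, measure, baseline, generation=0)],
        seed=-1,
    )
    gm = founders
    for t in range(1, gens + 1):
        if obj.method == "RND":
            plan = random_plan(gm, rng)
            score = float("nan")
        else:
            plan, score = anneal(
                gm, obj, managed.loci, schedule, seed=int(rng.integers(0, 2**31 - 1))
            )
        gm = make_progeny(plan, gm, rng)
        run.reports.append(compute_report(gm, measure, baseline, t, plan=plan))
        run.scores.append(score)
        if keep_plans:
            run.plans.append(plan)
    return run
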