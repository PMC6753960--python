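"""Gene-diversity and allelic-diversity partitions for subdivided populations.

Heterozygosity partition (Nei): per locus, the within component H_S is the
deme-mean expected heterozygosity 1 - sum_a p_a^2; the between component D_G
is Nei's minimum genetic distance D_ij = sum_a (p_ia - p_jb)^2 / 2 averaged
over all n^2 ordered deme pairs (self-pairs contribute zero).  With that
averaging convention the identity H_T = H_S + D_G holds exactly, H_T being
the expected heterozygosity of the equally-weighted pooled frequencies.

Allelic partition: A_S is the deme-mean number of segregating alleles minus
one; D_A is the mean over unordered deme pairs of the symmetrized count of
alleles private to one deme of the pair; A_T = A_S + D_A equals the mean
pair-union allele count minus one.

Demes are always weighted equally, regardless of census size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from itertools import combinations
from typing import TYPE_CHECKING

import numpy as np

from .markers import MAX_ALLELES, GenotypeMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .optimizer import ContributionPlan

__all__ = [
    "FreqTable",
    "DiversityReport",
    "allele_freqs",
    "het_partition",
    "allelic_partition",
    "total_alleles",
    "molecular_F",
    "freq_variance",
    "plan_stats",
    "compute_report",
]


@dataclass
class FreqTable:
    """Per-deme, per-locus allele frequencies on the 0..31 code alphabet."""

    freqs: np.ndarray  # (n_demes, n_loci, 32) float64, rows sum to 1
    deme_sizes: np.ndarray  # (n_demes,)
    loci: np.ndarray  # genome locus indices the table covers

    @property
    def n_demes(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[1]

    def pooled(self) -> np.ndarray:
        """Equally-weighted pooled frequencies, shape (n_loci, 32)."""
        return self.freqs.mean(axis=0)

    def presence(self) -> np.ndarray:
        """Boolean allele presence per deme, shape (n_demes, n_loci, 32)."""
        return self.freqs > 0


def allele_freqs(gm: GenotypeMatrix, loci: np.ndarray | None = None) -> FreqTable:
    """Count allele copies per (deme, locus): p = copies / (2 * deme size)."""
    loci = np.arange(gm.n_loci) if loci is None else np.asarray(loci, dtype=np.intp)
    deme_ids = gm.deme_ids
    out = np.zeros((deme_ids.size, loci.size, MAX_ALLELES))
    sizes = np.zeros(deme_ids.size, dtype=np.int64)
    for di, d in enumerate(deme_ids):
        sel = gm.codes[gm.deme == d][:, loci, :]  # (nd, k, 2)
        nd = sel.shape[0]
        if nd == 0:
            raise ValueError(f"deme {d} is empty")
        sizes[di] = nd
        li = np.repeat(np.arange(loci.size)[None, :], nd, axis=0).ravel()
        for copy in range(2):
            codes = sel[:, :, copy].ravel()
            np.add.at(out[di], (li, codes), 1.0)
        out[di] /= 2.0 * nd
    return FreqTable(out, sizes, loci)


def het_partition(ft: FreqTable, per_locus: bool = False):
    """Nei partition (H_S, D_G, H_T) averaged over loci (demes weighted equally)."""
    p = ft.freqs  # (S, K, A)
    hs_l = (1.0 - (p**2).sum(axis=2)).mean(axis=0)  # (K,)
    # mean over all S^2 ordered pairs of Nei minimum distance, incl. self-pairs
    dg_l = ((p**2).mean(axis=0) - p.mean(axis=0) ** 2).sum(axis=1)
    ht_l = hs_l + dg_l
    if per_locus:
        return hs_l, dg_l, ht_l
    return float(hs_l.mean()), float(dg_l.mean()), float(ht_l.mean())


def allelic_partition(ft: FreqTable, per_locus: bool = False):
    """Allelic partition (A_S, D_A, A_T); D_A = 0 for a single deme."""
    pres = ft.presence()
    a_s = pres.sum(axis=2).astype(float)  # (S, K)
    as_l = a_s.mean(axis=0) - 1.0
    S = ft.n_demes
    if S < 2:
        da_l = np.zeros(ft.n_loci)
    else:
        pairs = list(combinations(range(S), 2))
        d_sum = np.zeros(ft.n_loci)
        for i, j in pairs:
            shared = (pres[i] & pres[j]).sum(axis=1)
            d_sum += 0.5 * (a_s[i] + a_s[j]) - shared
        da_l = d_sum / len(pairs)
    at_l = as_l + da_l
    if per_locus:
        return as_l, da_l, at_l
    return float(as_l.mean()), float(da_l.mean()), float(at_l.mean())


def total_alleles(ft: FreqTable, per_locus: bool = False):
    """Distinct alleles in the pooled population: (mean per locus, raw total)."""
    k_l = ft.presence().any(axis=0).sum(axis=1).astype(float)
    if per_locus:
        return k_l
    return float(k_l.mean()), float(k_l.sum())


def molecular_F(gm: GenotypeMatrix, loci: np.ndarray | None = None) -> float:
    """Observed marker homozygosity: per individual, the fraction of in-scope
    loci carrying two identical allele codes (IBD plus identity in state),
    averaged over all individuals."""
    loci = np.arange(gm.n_loci) if loci is None else np.asarray(loci, dtype=np.intp)
    hom = gm.codes[:, loci, 0] == gm.codes[:, loci, 1]
    return float(hom.mean())


def freq_variance(ft: FreqTable, baseline_presence: np.ndarray) -> float:
    """Variance of pooled allele frequencies within loci.

    For each locus the population (biased) variance is taken over the pooled
    frequencies of the locus's *baseline* allele set (alleles recorded at
    management start; alleles since lost enter as p = 0); the result is the
    mean over loci.  Loci monomorphic at baseline contribute zero.
    """
    pooled = ft.pooled()  # (K, A)
    var_l = np.zeros(ft.n_loci)
    for l in range(ft.n_loci):
        vals = pooled[l, baseline_presence[l]]
        if vals.size > 0:
            var_l[l] = vals.var()
    return float(var_l.mean())


def plan_stats(plan: "ContributionPlan") -> tuple[int, float, float]:
    """(nMates, VarContFem, VarMigrants) of a contribution plan.

    nMates counts (sire, dam) pairs with at least one offspring; VarContFem
    is the population variance of per-female total offspring counts over all
    candidate females (zero-contribution females included); VarMigrants is
    the population variance across demes of incoming migrant counts.
    """
    pairs = {(int(s), int(d)) for s, d in zip(plan.sire, plan.dam)}
    n_mates = len(pairs)
    females = np.nonzero(plan.parent_sex == 0)[0]
    counts = np.bincount(plan.dam, minlength=plan.n_parents)[females]
    var_cont_fem = float(counts.astype(float).var())
    n_demes = plan.n_demes
    migrants_in = np.bincount(
        plan.dest[plan.natal != plan.dest], minlength=n_demes
    ).astype(float)
    var_migrants = float(migrants_in.var())
    return n_mates, var_cont_fem, var_migrants


@dataclass
class DiversityReport:
    """Per-generation diversity statistics of the managed metapopulation."""

    generation: int
    H_S: float
    D_G: float
    H_T: float
    A_S: float
    D_A: float
    A_T: float
    K: float
    K_total: float
    F: float
    VarFreq: float
    nMates: float = math.nan
    VarContFem: float = math.nan
    VarMigrants: float = math.nan
    Migrants: float = math.nan  # realized migrants per deme (mean)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_report(
    gm: GenotypeMatrix,
    loci: np.ndarray,
    baseline_presence: np.ndarray,
    generation: int,
    plan: "ContributionPlan | None" = None,
) -> DiversityReport:
    """Assemble the full statistics row for one generation."""
    ft = allele_freqs(gm, loci)
    h_s, d_g, h_t = het_partition(ft)
    a_s, d_a, a_t = allelic_partition(ft)
    k_mean, k_tot = total_alleles(ft)
    rep = DiversityReport(
        generation=generation,
        H_S=h_s,
        D_G=d_g,
        H_T=h_t,
        A_S=a_s,
        D_A=d_a,
        A_T=a_t,
        K=k_mean,
        K_total=k_tot,
        F=molecular_F(gm, loci),
        VarFreq=freq_variance(ft, baseline_presence),
    )
    if plan is not None:
        n_mates, vcf, vmig = plan_stats(plan)
        rep.nMates = float(n_mates)
        rep.VarContFem = vcf
        rep.VarMigrants = vmig
        rep.Migrants = float((plan.natal != plan.dest).sum() / plan.n_demes)
    return rep
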