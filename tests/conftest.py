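"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from metadiv.divstats import FreqTable
from metadiv.markers import MAX_ALLELES, GenotypeMatrix, LocusMap
from metadiv.optimizer import ContributionPlan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gm(codes, deme, sex=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from plain nested lists of allele codes."""
    codes = np.asarray(codes, dtype=np.uint8)
    return GenotypeMatrix(
        codes=codes,
        deme=np.asarray(deme, dtype=np.int32),
        sex=None if sex is None else np.asarray(sex, dtype=np.uint8),
        locus_map=LocusMap(codes.shape[1] * 5),
    )


def make_freq_table(deme_allele_freqs) -> FreqTable:
    """FreqTable from a nested list: [deme][locus] -> {allele: freq}."""
    n_demes = len(deme_allele_freqs)
    n_loci = len(deme_allele_freqs[0])
    freqs = np.zeros((n_demes, n_loci, MAX_ALLELES))
    for s, loci in enumerate(deme_allele_freqs):
        for l, dist in enumerate(loci):
            for a, p in dist.items():
                freqs[s, l, a] = p
    sizes = np.full(n_demes, 10)
    return FreqTable(freqs, sizes, np.arange(n_loci))


def random_gm(rng, n_demes=2, per_deme=8, n_loci=4, n_alleles=6, sexed=True):
    """Random sexed genotype matrix with equal-sized demes."""
    n = n_demes * per_deme
    codes = rng.integers(0, n_alleles, size=(n, n_loci, 2)).astype(np.uint8)
    deme = np.repeat(np.arange(n_demes, dtype=np.int32), per_deme)
    sex = None
    if sexed:
        sex = np.tile(
            np.repeat(np.uint8([0, 1]), per_deme // 2), n_demes
        )
    return make_gm(codes, deme, sex)


# ---------------------------------------------------------------------------
# independent oracles


def nei_partition_oracle(freqs):
    """Literal Nei partition: explicit loops over loci and ordered deme pairs."""
    S, K, A = freqs.shape
    hs = np.zeros(K)
    dg = np.zeros(K)
    for l in range(K):
        hs[l] = np.mean([1.0 - np.sum(freqs[s, l] ** 2) for s in range(S)])
        acc = 0.0
        for i in range(S):
            for j in range(S):
                acc += 0.5 * np.sum((freqs[i, l] - freqs[j, l]) ** 2)
        dg[l] = acc / S**2
    return hs.mean(), dg.mean(), (hs + dg).mean()


def pair_union_oracle(presence):
    """A_T as the mean over unordered deme pairs of (pair-union size - 1)."""
    S, K, _ = presence.shape
    if S == 1:
        return float(np.mean(presence[0].sum(axis=1) - 1))
    vals = []
    for l in range(K):
        for i in range(S):
            for j in range(i + 1, S):
                union = np.count_nonzero(presence[i, l] | presence[j, l])
                vals.append(union - 1)
    return float(np.mean(vals))


def mendelian_loss_oracle(plan: ContributionPlan, gm, locus: int, allele: int, dest: int):
    """Allele-loss probability by exhaustive enumeration of every Mendelian
    transmission outcome of the gametes entering ``dest``."""
    g = plan.gamete_counts()[:, dest]
    carriers = []  # one entry per transmitted gamete: "het" or "hom"
    for k in np.nonzero(g > 0)[0]:
        copies = int((gm.codes[k, locus, :] == allele).sum())
        if copies == 2:
            carriers.extend(["hom"] * int(g[k]))
        elif copies == 1:
            carriers.extend(["het"] * int(g[k]))
    if not carriers:
        return 1.0
    het_idx = [i for i, c in enumerate(carriers) if c == "het"]
    if len(carriers) - len(het_idx) > 0:
        return 0.0  # a homozygous carrier transmits the allele surely
    lost = 0
    total = 0
    for outcome in product([0, 1], repeat=len(het_idx)):
        total += 1
        if sum(outcome) == 0:
            lost += 1
    return lost / total


def enumerate_tiny_plans(gm, dest_sizes, migrant_total):
    """All feasible plans (canonical forms) of a tiny instance, by brute force."""
    deme = gm.deme
    sex = gm.sex
    D = len(dest_sizes)
    females = [np.nonzero((deme == d) & (sex == 0))[0] for d in range(D)]
    males = [np.nonzero((deme == d) & (sex == 1))[0] for d in range(D)]
    dest = np.repeat(np.arange(D), dest_sizes)
    T = dest.size
    per_slot = []
    for t in range(T):
        opts = []
        for j in range(D):
            for s in males[j]:
                for dm in females[j]:
                    opts.append((j, int(s), int(dm)))
        per_slot.append(opts)
    seen = {}
    for combo in product(*per_slot):
        natal = np.array([c[0] for c in combo])
        if int((natal != dest).sum()) != migrant_total:
            continue
        plan = ContributionPlan(
            natal.astype(np.int64),
            np.array([c[1] for c in combo], dtype=np.int64),
            np.array([c[2] for c in combo], dtype=np.int64),
            dest.astype(np.int64),
            deme.astype(np.int64),
            sex.astype(np.int64),
            np.asarray(dest_sizes, dtype=np.int64),
        )
        seen.setdefault(plan.canonical(), plan)
    return list(seen.values())
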