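"""Forward neutral Wright-Fisher simulation of a subdivided diploid population.

The simulator generates the base population for the management study: a
single large ancestral deme evolved to mutation-drift equilibrium, then
split into demes of unequal size that drift independently before equal-sized
samples are drawn as founders of the conservation program.

Model
-----
* Diploid individuals carry two binary haplotypes over ``seq_len``
  nucleotide sites (0 = ancestral state, 1 = derived state).
* Mutation flips the state of each site independently with probability
  ``mu`` per gamete per generation (symmetric two-state model, so every
  site stays biallelic and a 5-SNP window has at most 32 haplotype alleles).
* Recombination switches the template strand independently with probability
  ``rec`` at each of the ``seq_len - 1`` boundaries between consecutive
  sites during gamete formation.
* Generations are discrete and non-overlapping; the ancestral and split
  phases are monoecious with random mating (selfing allowed, probability
  1/N); sexes are only assigned when founders are sampled for management.

Haplotypes are stored bit-packed (8 sites per byte, ``np.packbits`` layout)
so that a full-scale run (N = 4,000 for 5,000 generations over 10 kb) takes
seconds rather than tens of minutes; use :func:`unpack_haplotypes` to obtain
plain 0/1 arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "SimParams",
    "Individual",
    "Deme",
    "Metapopulation",
    "FEMALE",
    "MALE",
    "meiosis",
    "run_ancestral",
    "found_demes",
    "sample_founders",
    "mean_site_heterozygosity",
    "derived_allele_freqs",
    "segregating_site_count",
    "equilibrium_heterozygosity",
    "pack_haplotypes",
    "unpack_haplotypes",
]

FEMALE = 0
MALE = 1


@dataclass(frozen=True)
class SimParams:
    """Parameters of the neutral sequence simulation.

    Parameters
    ----------
    seq_len:
        Number of nucleotide sites; must be >= 5 and divisible by 5 so the
        sequence tiles exactly into 5-SNP marker windows.
    mu:
        Per-site, per-generation probability that a gamete's allele flips
        state (study value 5e-5).
    rec:
        Per-boundary, per-meiosis probability of switching template strand
        between consecutive sites (study value 1e-6; variant 1e-5).
    scale:
        Down-scaling factor for desk-size runs.  Effective mutation and
        recombination rates are ``mu * scale`` and ``rec * scale``; callers
        divide population sizes and generation counts by the same factor so
        that theta = 4*N*mu and drift time T/N are preserved.
    """

    seq_len: int = 10_000
    mu: float = 5e-5
    rec: float = 1e-6
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.seq_len < 5 or self.seq_len % 5 != 0:
            raise ValueError("seq_len must be >= 5 and divisible by 5")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if not 0.0 <= self.rec <= 0.5:
            raise ValueError("rec must be in [0, 0.5]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def mu_eff(self) -> float:
        return min(self.mu * self.scale, 1.0)

    @property
    def rec_eff(self) -> float:
        return min(self.rec * self.scale, 0.5)


class Individual(NamedTuple):
    """Unpacked view of one diploid individual."""

    hap1: np.ndarray  # (seq_len,) uint8 in {0, 1}
    hap2: np.ndarray
    sex: int | None
    id: int


@dataclass
class Deme:
    """One subpopulation: bit-packed haplotypes plus optional sexes."""

    haps: np.ndarray  # (n, 2, W) uint8, W = ceil(seq_len / 8)
    sex: np.ndarray | None = None  # (n,) uint8, FEMALE/MALE

    @property
    def size(self) -> int:
        return self.haps.shape[0]


@dataclass
class Metapopulation:
    """Ordered demes of diploid individuals at one generation."""

    demes: list[Deme]
    seq_len: int
    generation: int = 0

    @property
    def n_demes(self) -> int:
        return len(self.demes)

    @property
    def deme_sizes(self) -> list[int]:
        return [d.size for d in self.demes]

    def individual(self, deme: int, i: int) -> Individual:
        d = self.demes[deme]
        h = unpack_haplotypes(d.haps[i : i + 1], self.seq_len)[0]
        sex = None if d.sex is None else int(d.sex[i])
        return Individual(h[0], h[1], sex, i)


# ---------------------------------------------------------------------------
# packed-haplotype helpers


def pack_haplotypes(bits: np.ndarray) -> np.ndarray:
    """Pack a (..., seq_len) 0/1 array into (..., ceil(L/8)) bytes."""
    return np.packbits(np.asarray(bits, dtype=np.uint8), axis=-1)


def unpack_haplotypes(packed: np.ndarray, seq_len: int) -> np.ndarray:
    """Unpack (..., W) bytes back into a (..., seq_len) 0/1 uint8 array."""
    return np.unpackbits(packed, axis=-1, count=seq_len)


def _monomorphic(n: int, seq_len: int) -> np.ndarray:
    w = (seq_len + 7) // 8
    return np.zeros((n, 2, w), dtype=np.uint8)


# ---------------------------------------------------------------------------
# meiosis


def meiosis(parent: Individual, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Form one gamete from an individual's two haplotypes.

    The gamete starts on a uniformly chosen parental haplotype, switches
    strands independently with probability ``rec`` at each inter-site
    boundary, and finally flips each site independently with probability
    ``mu``.  Returns an unpacked (seq_len,) 0/1 array.
    """
    L = params.seq_len
    if parent.hap1.shape != (L,) or parent.hap2.shape != (L,):
        raise ValueError("parent haplotypes do not match seq_len")
    haps = np.stack([parent.hap1, parent.hap2]).astype(np.uint8)
    start = int(rng.integers(0, 2))
    rec = params.rec_eff
    if rec > 0:
        switches = rng.random(L - 1) < rec
        strand = np.empty(L, dtype=np.intp)
        strand[0] = start
        strand[1:] = (start + np.cumsum(switches)) % 2
        gam = haps[strand, np.arange(L)]
    else:
        gam = haps[start].copy()
    mu = params.mu_eff
    if mu > 0:
        gam ^= (rng.random(L) < mu).astype(np.uint8)
    return gam


def _bulk_gametes(
    strands: np.ndarray,  # (2n, W) packed parental strands
    parent_idx: np.ndarray,  # (m,) parent indices in [0, n)
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Packed gametes for many meioses at once (mutation applied by caller)."""
    L = params.seq_len
    m = parent_idx.size
    start = rng.integers(0, 2, size=m)
    gam = strands[2 * parent_idx + start]
    rec = params.rec_eff
    if rec > 0:
        n_switch = rng.binomial(L - 1, rec, size=m)
        for i in np.nonzero(n_switch)[0]:
            # with-replacement draw + dedup: collision odds are negligible at
            # the few-switch counts these rates produce
            pos = np.unique(rng.integers(0, L - 1, size=n_switch[i]))
            marks = np.zeros(L, dtype=np.intp)
            marks[pos + 1] = 1
            strand = (start[i] + np.cumsum(marks)) % 2
            pair = unpack_haplotypes(strands[2 * parent_idx[i] : 2 * parent_idx[i] + 2], L)
            gam[i] = pack_haplotypes(pair[strand, np.arange(L)])
    return gam


def _mutate_packed(gam: np.ndarray, params: SimParams, rng: np.random.Generator) -> None:
    """Flip each (gamete, site) independently with probability mu, in place."""
    mu = params.mu_eff
    if mu == 0:
        return
    L = params.seq_len
    m = gam.shape[0]
    k = rng.binomial(m * L, mu)
    if k == 0:
        return
    pos = np.unique(rng.integers(0, m * L, size=k))
    gi, si = pos // L, pos % L
    np.bitwise_xor.at(gam, (gi, si >> 3), (128 >> (si & 7)).astype(np.uint8))


def _wf_generation(
    haps: np.ndarray,  # (n, 2, W)
    n_offspring: int,
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation of random-mating Wright-Fisher reproduction."""
    n = haps.shape[0]
    strands = haps.reshape(2 * n, -1)
    mothers = rng.integers(0, n, size=n_offspring)
    fathers = rng.integers(0, n, size=n_offspring)
    gam1 = _bulk_gametes(strands, mothers, params, rng)
    gam2 = _bulk_gametes(strands, fathers, params, rng)
    new = np.empty((n_offspring, 2, haps.shape[2]), dtype=np.uint8)
    new[:, 0, :] = gam1
    new[:, 1, :] = gam2
    _mutate_packed(new.reshape(2 * n_offspring, -1), params, rng)
    return new


# ---------------------------------------------------------------------------
# population histories


def run_ancestral(
    params: SimParams,
    n: int,
    generations: int,
    rng: np.random.Generator,
    initial: np.ndarray | None = None,
) -> Metapopulation:
    """Evolve a single random-mating deme of constant size ``n``.

    Starts from a monomorphic population (all-ancestral sequence) unless
    ``initial`` packed haplotypes are given.  Parents are drawn uniformly
    with replacement for every offspring (monoecious, selfing allowed).
    """
    if n < 2:
        raise ValueError("ancestral deme size must be >= 2")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    haps = _monomorphic(n, params.seq_len) if initial is None else initial.copy()
    if haps.shape[0] != n:
        raise ValueError("initial population size mismatch")
    for _ in range(generations):
        haps = _wf_generation(haps, n, params, rng)
    return Metapopulation([Deme(haps)], params.seq_len, generation=generations)


def found_demes(
    source: Metapopulation,
    sizes: Sequence[int],
    generations: int,
    params: SimParams,
    rng: np.random.Generator,
) -> Metapopulation:
    """Found demes from a single source deme and drift them independently.

    Each deme is founded by uniform sampling of individuals *without
    replacement* from the source; founder draws are disjoint across demes.
    Demes then evolve at constant size with no migration.
    """
    if source.n_demes != 1:
        raise ValueError("source must have exactly one deme")
    total = int(np.sum(sizes))
    n_src = source.demes[0].size
    if total > n_src:
        raise ValueError(f"cannot draw {total} founders from source of size {n_src}")
    order = rng.permutation(n_src)[:total]
    demes: list[Deme] = []
    offset = 0
    for sz in sizes:
        haps = source.demes[0].haps[order[offset : offset + sz]].copy()
        offset += sz
        for _ in range(generations):
            haps = _wf_generation(haps, sz, params, rng)
        demes.append(Deme(haps))
    return Metapopulation(demes, source.seq_len, generation=source.generation + generations)


def sample_founders(
    metapop: Metapopulation, n_per_deme: int, rng: np.random.Generator
) -> Metapopulation:
    """Sample founders for management: ``n_per_deme`` per deme, sexed 50/50.

    Individuals are drawn uniformly without replacement within each deme and
    assigned sexes so that exactly half are female and half male.
    """
    if n_per_deme % 2 != 0:
        raise ValueError("n_per_deme must be even (equal sex ratio)")
    demes = []
    for d in metapop.demes:
        if d.size < n_per_deme:
            raise ValueError("deme smaller than requested sample")
        pick = rng.choice(d.size, size=n_per_deme, replace=False)
        sex = np.repeat(np.uint8([FEMALE, MALE]), n_per_deme // 2)
        demes.append(Deme(d.haps[pick].copy(), rng.permutation(sex)))
    return Metapopulation(demes, metapop.seq_len, generation=metapop.generation)


# ---------------------------------------------------------------------------
# sequence-level statistics


def derived_allele_freqs(metapop: Metapopulation) -> np.ndarray:
    """Pooled per-site derived-allele frequency across all demes."""
    counts = np.zeros(metapop.seq_len)
    n_tot = 0
    for d in metapop.demes:
        bits = unpack_haplotypes(d.haps, metapop.seq_len)
        counts += bits.sum(axis=(0, 1))
        n_tot += 2 * d.size
    return counts / n_tot


def mean_site_heterozygosity(metapop: Metapopulation) -> float:
    """Mean over sites of 2p(1-p) on pooled derived-allele frequencies."""
    p = derived_allele_freqs(metapop)
    return float(np.mean(2.0 * p * (1.0 - p)))


def segregating_site_count(metapop: Metapopulation) -> int:
    p = derived_allele_freqs(metapop)
    return int(np.count_nonzero((p > 0) & (p < 1)))


def equilibrium_heterozygosity(theta: float) -> float:
    """Diffusion equilibrium per-site heterozygosity for symmetric two-state
    mutation, ``E[2pq] = theta / (1 + 2 theta)`` with ``theta = 4 N mu``
    (stationary allele frequency ~ Beta(theta, theta))."""
    return theta / (1.0 + 2.0 * theta)
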