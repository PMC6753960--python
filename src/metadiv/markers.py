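"""Multiallelic marker loci built from haplotypes of five consecutive SNPs.

Each non-overlapping window of five consecutive nucleotide sites defines one
marker locus; the 5-bit haplotype pattern within the window (leftmost site =
most significant bit) is the allele, giving at most 32 alleles per locus.
Windows are fixed on the sequence regardless of polymorphism, so a 10 kb
sequence yields 2,000 candidate loci; management uses a thinned subset of
the loci that segregate in the pooled population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wfsim import Metapopulation, unpack_haplotypes

__all__ = [
    "WINDOW",
    "MAX_ALLELES",
    "LocusMap",
    "GenotypeMatrix",
    "ManagedSet",
    "build_locus_map",
    "encode_genotypes",
    "decode_allele",
    "segregating_loci",
    "select_managed",
]

WINDOW = 5
MAX_ALLELES = 2**WINDOW
_BITVAL = np.array([16, 8, 4, 2, 1], dtype=np.uint8)


@dataclass(frozen=True)
class LocusMap:
    """Tiling of the sequence into consecutive 5-site marker windows."""

    seq_len: int

    def __post_init__(self) -> None:
        if self.seq_len % WINDOW != 0 or self.seq_len < WINDOW:
            raise ValueError("seq_len must be a positive multiple of 5")

    @property
    def n_loci(self) -> int:
        return self.seq_len // WINDOW

    def windows(self) -> list[tuple[int, int]]:
        """Half-open site ranges [5k, 5k+5) in genomic order."""
        return [(WINDOW * k, WINDOW * (k + 1)) for k in range(self.n_loci)]

    def map_length_morgans(self, rec: float) -> float:
        """Genetic map length implied by a per-boundary recombination rate."""
        return (self.seq_len - 1) * rec


def build_locus_map(seq_len: int) -> LocusMap:
    return LocusMap(seq_len)


@dataclass
class GenotypeMatrix:
    """Per-individual, per-locus pairs of allele codes with deme/sex labels.

    ``codes`` has shape (n_individuals, n_loci, 2) with values in [0, 31];
    the two positions along the last axis are the maternal- and paternal-
    derived locus haplotypes (phase is preserved from the simulation).
    """

    codes: np.ndarray  # (n, n_loci, 2) uint8
    deme: np.ndarray  # (n,) int32
    sex: np.ndarray | None  # (n,) uint8 or None if unsexed
    locus_map: LocusMap

    def __post_init__(self) -> None:
        if self.codes.ndim != 3 or self.codes.shape[2] != 2:
            raise ValueError("codes must have shape (n, n_loci, 2)")
        if self.codes.shape[1] != self.locus_map.n_loci:
            raise ValueError("codes/locus_map dimension mismatch")
        if self.codes.max(initial=0) >= MAX_ALLELES:
            raise ValueError("allele codes must be < 32")
        if self.deme.shape[0] != self.codes.shape[0]:
            raise ValueError("deme labels do not match individuals")

    @property
    def n_ind(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def deme_ids(self) -> np.ndarray:
        return np.unique(self.deme)

    @property
    def n_demes(self) -> int:
        return self.deme_ids.size

    def deme_sizes(self) -> np.ndarray:
        return np.array([(self.deme == d).sum() for d in self.deme_ids])


@dataclass(frozen=True)
class ManagedSet:
    """Ordered locus indices used for management plus measurement scope."""

    loci: np.ndarray  # sorted ascending locus indices
    measure_genome_wide: bool = False

    def __post_init__(self) -> None:
        loci = np.asarray(self.loci, dtype=np.intp)
        if loci.size == 0:
            raise ValueError("managed set is empty")
        if np.any(np.diff(loci) <= 0):
            raise ValueError("managed loci must be strictly ascending")
        object.__setattr__(self, "loci", loci)

    @property
    def n_loci(self) -> int:
        return self.loci.size


def encode_genotypes(metapop: Metapopulation, lmap: LocusMap) -> GenotypeMatrix:
    """Encode every haplotype window of bits b0..b4 as allele sum(b_i 2^(4-i))."""
    if metapop.seq_len != lmap.seq_len:
        raise ValueError("locus map does not cover the sequence")
    codes_parts, deme_parts, sex_parts = [], [], []
    sexed = all(d.sex is not None for d in metapop.demes)
    for di, d in enumerate(metapop.demes):
        bits = unpack_haplotypes(d.haps, lmap.seq_len)  # (n, 2, L)
        wins = bits.reshape(d.size, 2, lmap.n_loci, WINDOW)
        codes = np.einsum("ishw,w->ish", wins, _BITVAL, dtype=np.uint8).astype(np.uint8)
        codes_parts.append(codes.transpose(0, 2, 1))  # (n, n_loci, 2)
        deme_parts.append(np.full(d.size, di, dtype=np.int32))
        if sexed:
            sex_parts.append(d.sex)
    return GenotypeMatrix(
        codes=np.concatenate(codes_parts),
        deme=np.concatenate(deme_parts),
        sex=np.concatenate(sex_parts) if sexed else None,
        locus_map=lmap,
    )


def decode_allele(code: int) -> np.ndarray:
    """Inverse of the 5-bit encoding: allele code -> window bits b0..b4."""
    if not 0 <= code < MAX_ALLELES:
        raise ValueError("allele code out of range")
    return (code >> np.arange(WINDOW - 1, -1, -1)) & 1


def segregating_loci(gm: GenotypeMatrix) -> np.ndarray:
    """Loci with >= 2 distinct allele codes in the pooled metapopulation."""
    ref = gm.codes[0, :, 0]
    seg = (gm.codes != ref[None, :, None]).any(axis=(0, 2))
    return np.nonzero(seg)[0]


def select_managed(
    segregating: np.ndarray, every_nth: int, measure_genome_wide: bool = False
) -> ManagedSet:
    """Thin the segregating-locus list: positions 0, n, 2n, ... in genomic order."""
    if every_nth < 1:
        raise ValueError("every_nth must be >= 1")
    segregating = np.asarray(segregating)
    if segregating.size == 0:
        raise ValueError("no segregating loci to select from")
    return ManagedSet(segregating[::every_nth].copy(), measure_genome_wide)
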