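"""Readers and writers for genotype tables, plans, VCF export and configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .markers import WINDOW, GenotypeMatrix, LocusMap
from .optimizer import ContributionPlan
from .wfsim import Metapopulation, unpack_haplotypes

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_plan_tsv",
    "read_plan_tsv",
    "write_vcf",
    "load_config",
    "save_config",
]


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> Path:
    """One row per individual: deme, individual, sex, then per-locus allele
    code pairs.  The leading comment line records the 0-based half-open
    window coordinates of every locus."""
    path = Path(path)
    wins = ";".join(f"{a}:{b}" for a, b in gm.locus_map.windows())
    cols = {"deme": gm.deme, "individual": np.arange(gm.n_ind)}
    cols["sex"] = gm.sex if gm.sex is not None else np.full(gm.n_ind, -1)
    data = {}
    for l in range(gm.n_loci):
        data[f"L{l:05d}_a"] = gm.codes[:, l, 0]
        data[f"L{l:05d}_b"] = gm.codes[:, l, 1]
    df = pd.DataFrame({**cols, **data})
    with open(path, "w") as fh:
        fh.write(f"# windows={wins}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# windows="):
            raise ValueError("missing window coordinates header")
        n_loci = len(header.strip().split("=", 1)[1].split(";"))
        df = pd.read_csv(fh, sep="\t")
    codes = np.empty((len(df), n_loci, 2), dtype=np.uint8)
    for l in range(n_loci):
        codes[:, l, 0] = df[f"L{l:05d}_a"]
        codes[:, l, 1] = df[f"L{l:05d}_b"]
    sex = df["sex"].to_numpy()
    return GenotypeMatrix(
        codes=codes,
        deme=df["deme"].to_numpy(dtype=np.int32),
        sex=None if (sex < 0).any() else sex.astype(np.uint8),
        locus_map=LocusMap(n_loci * WINDOW),
    )


def write_plan_tsv(plan: ContributionPlan, path: str | Path) -> Path:
    path = Path(path)
    plan.entries().to_csv(path, sep="\t", index=False)
    return path


def read_plan_tsv(path: str | Path, gm: GenotypeMatrix, dest_sizes=None) -> ContributionPlan:
    """Expand an aggregated plan table against its parental genotype matrix."""
    df = pd.read_csv(path, sep="\t")
    natal = np.repeat(df["natal_deme"].to_numpy(np.int64), df["n_offspring"])
    sire = np.repeat(df["sire"].to_numpy(np.int64), df["n_offspring"])
    dam = np.repeat(df["dam"].to_numpy(np.int64), df["n_offspring"])
    dest = np.repeat(df["dest_deme"].to_numpy(np.int64), df["n_offspring"])
    if gm.sex is None:
        raise ValueError("genotype matrix must carry sexes")
    if dest_sizes is None:
        sizes = np.bincount(dest, minlength=gm.n_demes).astype(np.int64)
    else:
        sizes = np.asarray(dest_sizes, dtype=np.int64)
    plan = ContributionPlan(
        natal, sire, dam, dest, gm.deme.astype(np.int64), gm.sex.astype(np.int64), sizes
    )
    plan.validate()
    return plan


def write_vcf(metapop: Metapopulation, path: str | Path) -> Path:
    """Export segregating sites as phased VCF 4.2 (contig "sim", 1-based)."""
    import pysam

    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID=sim,length={metapop.seq_len}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    names = []
    for di, d in enumerate(metapop.demes):
        for i in range(d.size):
            names.append(f"d{di}_i{i}")
    for n in names:
        header.add_sample(n)
    bits = np.concatenate(
        [unpack_haplotypes(d.haps, metapop.seq_len) for d in metapop.demes]
    )  # (n_tot, 2, L)
    freq = bits.mean(axis=(0, 1))
    seg = np.nonzero((freq > 0) & (freq < 1))[0]
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for site in seg:
            rec = vf.new_record(
                contig="sim", start=int(site), stop=int(site) + 1, alleles=("A", "T")
            )
            for i in range(bits.shape[0]):
                rec.samples[i]["GT"] = (int(bits[i, 0, site]), int(bits[i, 1, site]))
                rec.samples[i].phased = True
            vf.write(rec)
    return path


def load_config(path: str | Path):
    from .experiment import StudyConfig

    with open(path) as fh:
        return StudyConfig.from_dict(yaml.safe_load(fh))


def save_config(cfg, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return path
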