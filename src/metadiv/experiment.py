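"""Replication harness: base populations x samplings x management settings.

Reproduces the study design: several replicate base populations are
simulated; from each, several independent founder samplings are drawn; and
every sampling is managed under the full factorial of requested methods,
lambda weights, migration levels and marker scenarios.  Results are
aggregated into per-generation means and standard errors.

Seeding: every unit of work derives its generator from the master seed and
its own coordinates (replicate, sampling, cell index) via
``np.random.SeedSequence`` spawn keys, so the output is byte-identical
regardless of execution order and any single run can be re-executed alone.
"""

from __future__ import annotations

import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .manager import run_management
from .markers import ManagedSet, build_locus_map, encode_genotypes, segregating_loci, select_managed
from .optimizer import AnnealSchedule, Objective
from .wfsim import Metapopulation, SimParams, found_demes, run_ancestral, sample_founders

__all__ = [
    "Scenario",
    "StudyConfig",
    "SummaryTable",
    "desk_profile",
    "paper_profile",
    "simulate_base",
    "sample_and_encode",
    "run_study",
    "write_outputs",
    "plot_trajectories",
]

STAT_COLUMNS = [
    "H_S",
    "D_G",
    "H_T",
    "A_S",
    "D_A",
    "A_T",
    "K",
    "K_total",
    "F",
    "VarFreq",
    "nMates",
    "VarContFem",
    "VarMigrants",
    "Migrants",
]


@dataclass(frozen=True)
class Scenario:
    """Marker scenario: thinning of the segregating loci and measurement scope."""

    every_nth: int
    genome_wide: bool = False

    @property
    def label(self) -> str:
        scope = "genome" if self.genome_wide else "managed"
        return f"every{self.every_nth}_{scope}"


@dataclass
class StudyConfig:
    """Full description of a replicated management study."""

    sim: SimParams = field(default_factory=SimParams)
    ancestral_n: int = 4000
    ancestral_gens: int = 5000
    deme_sizes: tuple = (2000, 100, 100, 100, 100)
    split_gens: int = 25
    sample_size: int = 40  # founders per deme (half each sex)
    manage_gens: int = 25
    methods: tuple = ("maxHT", "maxAT", "maxK", "RND")
    lambdas: tuple = (1.0,)
    migrations: tuple = (1.0,)
    scenarios: tuple = (Scenario(100, False), Scenario(10, True))
    n_base_replicates: int = 10
    n_samplings: int = 10
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("methods", "lambdas", "migrations", "scenarios"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if min(self.n_base_replicates, self.n_samplings) < 1:
            raise ValueError("replicate counts must be >= 1")

    def cells(self) -> list[tuple[str, float, float, Scenario]]:
        return [
            (m, lam, mig, sc)
            for m in self.methods
            for lam in self.lambdas
            for mig in self.migrations
            for sc in self.scenarios
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenarios"] = [asdict(s) for s in self.scenarios]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimParams(**d["sim"])
        if "schedule" in d:
            d["schedule"] = AnnealSchedule(**d["schedule"])
        if "scenarios" in d:
            d["scenarios"] = tuple(Scenario(**s) for s in d["scenarios"])
        for key in ("deme_sizes", "methods", "lambdas", "migrations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def paper_profile(seed: int = 0) -> StudyConfig:
    """The full-scale study conditions."""
    return StudyConfig(master_seed=seed)


def desk_profile(seed: int = 0) -> StudyConfig:
    """Down-scaled profile for desk runs and CI.

    Scale factor 10 on the ancestral phase (N = 400 for 500 generations
    with mutation and recombination rates x10, preserving theta = 4*N*mu
    and drift time), deme scheme scaled to (200, 10, 10, 10, 10), samples
    of 8 founders per deme, and a shorter annealing schedule.
    """
    return StudyConfig(
        sim=SimParams(seq_len=10_000, mu=5e-5, rec=1e-6, scale=10.0),
        ancestral_n=400,
        ancestral_gens=500,
        deme_sizes=(200, 10, 10, 10, 10),
        split_gens=25,
        sample_size=8,
        manage_gens=25,
        scenarios=(Scenario(200, False),),
        n_base_replicates=5,
        n_samplings=10,
        schedule=AnnealSchedule(iters=2500, per_temp=100),
        master_seed=seed,
    )


# ---------------------------------------------------------------------------
# study execution


def _rng(cfg: StudyConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(cfg.master_seed, spawn_key=key)
    )


def simulate_base(cfg: StudyConfig, replicate: int) -> Metapopulation:
    """Ancestral phase plus deme founding for one base replicate."""
    rng = _rng(cfg, 0, replicate)
    anc = run_ancestral(cfg.sim, cfg.ancestral_n, cfg.ancestral_gens, rng)
    return found_demes(anc, cfg.deme_sizes, cfg.split_gens, cfg.sim, rng)


def sample_and_encode(cfg: StudyConfig, base: Metapopulation, replicate: int, sampling: int):
    """Draw one founder sample and encode it as a genotype matrix."""
    rng = _rng(cfg, 1, replicate, sampling)
    founders = sample_founders(base, cfg.sample_size, rng)
    lmap = build_locus_map(cfg.sim.seq_len)
    return encode_genotypes(founders, lmap)


@dataclass
class SummaryTable:
    """Raw per-run trajectories and their mean/SE aggregation."""

    runs: pd.DataFrame
    summary: pd.DataFrame


_CELL_KEYS = ["method", "lambda", "migration", "scenario", "generation"]


def summarize(runs: pd.DataFrame) -> pd.DataFrame:
    stats = [c for c in STAT_COLUMNS if c in runs.columns]
    g = runs.groupby(_CELL_KEYS, sort=True)[stats]
    mean = g.mean()
    n = g.size()
    se = g.std(ddof=1).div(np.sqrt(n), axis=0).fillna(0.0)
    out = mean.join(se, rsuffix="_se")
    out["n_runs"] = n
    return out.reset_index()


def run_study(cfg: StudyConfig, verbose: bool = False) -> SummaryTable:
    """Run the full factorial study; deterministic given the master seed."""
    rows = []
    cells = cfg.cells()
    for rep in range(cfg.n_base_replicates):
        t0 = time.time()
        base = simulate_base(cfg, rep)
        if verbose:
            print(f"[metadiv] base replicate {rep}: {time.time()-t0:.1f}s", file=sys.stderr)
        for samp in range(cfg.n_samplings):
            gm = sample_and_encode(cfg, base, rep, samp)
            seg = segregating_loci(gm)
            for ci, (method, lam, mig, sc) in enumerate(cells):
                try:
                    managed = select_managed(seg, sc.every_nth, sc.genome_wide)
                    rng = _rng(cfg, 2, rep, samp, ci)
                    run = run_management(
                        gm,
                        Objective(method, lam, mig),
                        cfg.manage_gens,
                        managed,
                        rng,
                        schedule=cfg.schedule,
                    )
                except Exception as exc:  # surface the failing cell
                    raise RuntimeError(
                        f"study cell failed: replicate={rep} sampling={samp} "
                        f"method={method} lambda={lam} migration={mig} "
                        f"scenario={sc.label}: {exc}"
                    ) from exc
                df = run.to_frame()
                df.insert(0, "replicate", rep)
                df.insert(1, "sampling", samp)
                df.insert(5, "scenario", sc.label)
                rows.append(df)
        if verbose:
            print(
                f"[metadiv] replicate {rep} done: {time.time()-t0:.1f}s", file=sys.stderr
            )
    runs = pd.concat(rows, ignore_index=True)
    return SummaryTable(runs=runs, summary=summarize(runs))


# ---------------------------------------------------------------------------
# outputs


def write_outputs(
    table: SummaryTable,
    outdir: str | Path,
    config: StudyConfig | None = None,
    plots: bool = False,
) -> list[Path]:
    """Write tidy CSVs (one row per cell per generation), a config echo,
    and optionally trajectory plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    summary_path = outdir / "summary.csv"
    table.summary.to_csv(summary_path, index=False)
    written.append(summary_path)
    runs_path = outdir / "runs.csv"
    table.runs.to_csv(runs_path, index=False)
    written.append(runs_path)
    if config is not None:
        import yaml

        cfg_path = outdir / "config.yaml"
        cfg_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
        written.append(cfg_path)
    if plots:
        written.append(plot_trajectories(table.summary, outdir / "trajectories.png"))
    return written


def plot_trajectories(summary: pd.DataFrame, path: str | Path):
    """Panel of per-statistic trajectories by method (one facet per statistic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats = [c for c in STAT_COLUMNS if c in summary.columns and c != "K_total"]
    ncol = 4
    nrow = (len(stats) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow), squeeze=False)
    colors = {"maxHT": "tab:blue", "maxAT": "tab:green", "maxK": "tab:red", "RND": "black"}
    for ax, stat in zip(axes.ravel(), stats):
        for (method, scen), sub in summary.groupby(["method", "scenario"]):
            ax.plot(
                sub["generation"],
                sub[stat],
                label=method,
                color=colors.get(method, None),
                linestyle=":" if method == "RND" else "-",
            )
        ax.set_title(stat, fontsize=9)
        ax.set_xlabel("t", fontsize=8)
    for ax in axes.ravel()[len(stats) :]:
        ax.axis("off")
    handles, labels = axes[0, 0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
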