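"""Seeded generator of Cq datasets with known ground truth.

The generator draws Cq values from the variance-component model every
stability algorithm implicitly assumes:

    Cq_igjr = mu_i + L_gj + delta_ig + eta_igj + p_plate + eps_igjr

with per-gene baseline mu_i, a shared per-sample loading effect
L ~ N(0, loading_sd²) (RNA input differences), a gene x group effect
delta ~ N(0, tau_i²) (systematic regulation across groups — instability),
a gene x sample effect eta ~ N(0, sigma_i²) (biological noise), an
optional plate shift, and technical noise eps ~ N(0, tech_sd²) per
replicate well.  A gene's true stability is sqrt(tau_i² + sigma_i²).

Defaults emulate the developmental-stage study design this package was
built around: 7 candidate genes x 8 stage/sex groups x 3 biological x 3
technical replicates, loading SD 0.5 cycles, technical SD 0.1 cycles,
true stabilities spanning 0.1–1.0 cycles, baselines near the observed
median Cq of the real candidates (16–22 cycles).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cq_data import RawCqRecord
from .standard_curve import DilutionSeries

__all__ = [
    "GeneSpec",
    "SimConfig",
    "SimulationTruth",
    "CqDataset",
    "default_config",
    "generate_cq_dataset",
    "generate_dilution_series",
    "inject_target_gene",
]

#: the threefold dilution ladder used for standard curves
THREEFOLD_LEVELS = tuple(3.0**-k for k in range(1, 9))  # 1/3 ... 1/6561

DEFAULT_GROUPS = ("N1", "N2m", "N2f", "N3m", "N3f", "N4m", "Am", "Af")


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: baseline Cq and its two instability components."""

    name: str
    mu: float  # baseline Cq, cycles
    tau: float  # group-effect SD, cycles (systematic regulation)
    sigma: float  # sample-level SD, cycles (biological noise)

    @property
    def true_stability(self) -> float:
        return float(np.hypot(self.tau, self.sigma))


@dataclass
class SimConfig:
    genes: list[GeneSpec]
    groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    n_per_group: int = 3
    loading_sd: float = 0.5  # cycles, shared per-sample effect
    tech_sd: float = 0.1  # cycles, per technical replicate
    tech_reps: int = 3
    n_plates: int = 1
    plate_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.tau < 0 or g.sigma < 0:
                raise ValueError(f"{g.name}: SDs must be >= 0")
        if min(self.loading_sd, self.tech_sd, self.plate_shift_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if len(self.groups) < 1 or self.n_per_group < 1 or self.tech_reps < 1:
            raise ValueError("need >= 1 group, sample and replicate")
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene names")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    true_stability: dict[str, float]  # per gene, sqrt(tau² + sigma²) cycles
    stability_order: list[str]  # most stable first, ties by name
    loading: pd.Series  # realized per-sample loading effect L_gj
    group_of: pd.Series  # sample -> group
    true_fold: dict[str, dict[str, float]] = field(default_factory=dict)
    true_efficiency: dict[str, float] = field(default_factory=dict)


@dataclass
class CqDataset:
    """Raw records plus the generating truth and metadata."""

    records: list[RawCqRecord]
    truth: SimulationTruth
    meta: pd.DataFrame  # sample -> group, biological_rep
    config: SimConfig


def default_config(seed: int = 0) -> SimConfig:
    """The study-shaped default: 7 genes x 8 groups x 3 x 3.

    True stabilities are spread evenly over 0.1–1.0 cycles, split between
    the group (tau) and sample (sigma) components; baselines sit at the
    observed median Cq of typical insect reference genes.
    """
    total = np.linspace(0.1, 1.0, 7)  # target sqrt(tau² + sigma²)
    mus = [16.4, 17.5, 18.2, 18.9, 19.6, 20.3, 21.5]
    names = ["g1", "g2", "g3", "g4", "g5", "g6", "g7"]
    genes = [
        GeneSpec(
            name=n,
            mu=mu,
            tau=float(t * np.sqrt(0.5)),
            sigma=float(t * np.sqrt(0.5)),
        )
        for n, mu, t in zip(names, mus, total)
    ]
    return SimConfig(genes=genes, seed=seed)


def _sample_ids(config: SimConfig) -> list[tuple[str, str, int]]:
    """(sample_id, group, biological_rep) for every biological sample."""
    out = []
    for group in config.groups:
        for j in range(1, config.n_per_group + 1):
            out.append((f"{group}_b{j}", group, j))
    return out


def generate_cq_dataset(config: SimConfig) -> CqDataset:
    """Draw one dataset from the variance-component model, reproducibly."""
    rng = np.random.default_rng(config.seed)
    samples = _sample_ids(config)
    genes = config.genes
    K, n, G = len(config.groups), config.n_per_group, len(genes)

    loading = rng.normal(0.0, config.loading_sd, size=len(samples))
    delta = {
        (g.name, group): rng.normal(0.0, g.tau)
        for g in genes
        for group in config.groups
    }
    plate_of = {
        sid: f"plate{1 + (i * config.n_plates) // len(samples)}"
        for i, (sid, _, _) in enumerate(samples)
    }
    plate_shift = {
        f"plate{p + 1}": rng.normal(0.0, config.plate_shift_sd)
        for p in range(config.n_plates)
    }

    records: list[RawCqRecord] = []
    for g in genes:
        for s_idx, (sid, group, _) in enumerate(samples):
            eta = rng.normal(0.0, g.sigma)
            base = (
                g.mu
                + loading[s_idx]
                + delta[(g.name, group)]
                + eta
                + plate_shift[plate_of[sid]]
            )
            for r in range(1, config.tech_reps + 1):
                records.append(
                    RawCqRecord(
                        sample_id=sid,
                        gene=g.name,
                        technical_rep=r,
                        plate=plate_of[sid],
                        Cq=float(base + rng.normal(0.0, config.tech_sd)),
                    )
                )

    stability = {g.name: g.true_stability for g in genes}
    order = sorted(stability, key=lambda name: (stability[name], name))
    meta = pd.DataFrame(
        {
            "group": [grp for _, grp, _ in samples],
            "biological_rep": [b for _, _, b in samples],
        },
        index=pd.Index([sid for sid, _, _ in samples], name="sample"),
    )
    truth = SimulationTruth(
        true_stability=stability,
        stability_order=order,
        loading=pd.Series(loading, index=meta.index, name="loading"),
        group_of=meta["group"],
    )
    return CqDataset(records=records, truth=truth, meta=meta, config=config)


def generate_dilution_series(
    gene: str,
    true_efficiency_percent: float = 100.0,
    cq_at_unity: float = 14.0,
    levels: tuple[float, ...] = THREEFOLD_LEVELS,
    reps: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> DilutionSeries:
    """Dilution-series Cq with a known true efficiency.

    Cq = cq_at_unity − log(amount)/log(1 + E/100) + N(0, noise_sd²): each
    dilution step of factor f raises Cq by log_B(f) cycles with per-cycle
    amplification factor B = 1 + E/100.
    """
    if true_efficiency_percent <= 0:
        raise ValueError("efficiency must be positive")
    rng = np.random.default_rng(seed)
    base = 1.0 + true_efficiency_percent / 100.0
    cq = [
        cq_at_unity
        - np.log(level) / np.log(base)
        + rng.normal(0.0, noise_sd, size=reps)
        for level in levels
    ]
    return DilutionSeries(gene=gene, relative_amounts=np.asarray(levels), cq=cq)


def inject_target_gene(
    dataset: CqDataset,
    name: str,
    fold_pattern: dict[str, float],
    base_cq: float = 24.0,
    sigma: float = 0.1,
) -> CqDataset:
    """Add a differentially expressed target gene to a simulated dataset.

    The target shares the dataset's per-sample loading effects and
    technical-noise level; its Cq is lowered by log2(fold) in each group
    relative to ``base_cq`` (fold 1.0 everywhere = behaves like a
    reference gene).  Returns a new dataset; truth records the folds.
    """
    unknown = set(fold_pattern) - set(dataset.config.groups)
    if unknown:
        raise ValueError(f"unknown groups in fold pattern: {sorted(unknown)}")
    if any(f <= 0 for f in fold_pattern.values()):
        raise ValueError("folds must be positive")

    name_key = zlib.crc32(name.encode()) % 2**31  # stable across processes
    rng = np.random.default_rng(
        np.random.SeedSequence([dataset.config.seed, name_key])
    )
    cfg = dataset.config
    records = list(dataset.records)
    plate_of = {r.sample_id: r.plate for r in dataset.records}
    for sid, row in dataset.meta.iterrows():
        group = row["group"]
        fold = fold_pattern.get(group, 1.0)
        base = (
            base_cq
            + float(dataset.truth.loading[sid])
            - np.log2(fold)
            + rng.normal(0.0, sigma)
        )
        for r in range(1, cfg.tech_reps + 1):
            records.append(
                RawCqRecord(
                    sample_id=sid,
                    gene=name,
                    technical_rep=r,
                    plate=plate_of.get(sid, "plate1"),
                    Cq=float(base + rng.normal(0.0, cfg.tech_sd)),
                )
            )
    truth = replace(dataset.truth)
    truth.true_fold = dict(dataset.truth.true_fold)
    truth.true_fold[name] = {
        g: float(fold_pattern.get(g, 1.0)) for g in cfg.groups
    }
    return CqDataset(records=records, truth=truth, meta=dataset.meta, config=cfg)
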