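"""Synthetic longitudinal skin-microbiome cohorts with ground truth.

The generator emulates the statistical structure of forehead 16S profiles:

* one dominant OTU (the *Cutibacterium/Propionibacterium acnes* role) at
  ~90% mean relative abundance,
* a few common OTUs shared by everyone at percent-level abundance,
* a long sparse tail of rare background OTUs whose presence pattern is
  individual-specific,
* planted "personal" OTUs — rare taxa (1e-5..1e-3) on disjoint supports,
  present at every timepoint of their owner and nowhere else,
* within-individual stability modelled as a Dirichlet-multinomial: each
  sample's composition is Dirichlet(concentration x individual baseline)
  and its counts are a multinomial draw at the configured read depth,
* mild between-period (year) drift of each individual's baseline.

This is a test fixture with controllable structure, not a fitted model of
any real cohort; what it does and does not reproduce is discussed in the
methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import OtuTable


@dataclass
class SyntheticConfig:
    n_individuals: int = 11
    n_timepoints_per_period: int = 3
    n_periods: int = 2
    n_otus: int = 300
    dominant_mean_share: float = 0.9
    dominant_share_sd: float = 0.03
    n_common_otus: int = 3
    n_personal_otus_per_individual: int = 5
    personal_abundance_range: tuple[float, float] = (1e-5, 1e-3)
    background_presence_prob: float = 0.15
    background_abundance_range: tuple[float, float] = (1e-5, 3e-4)
    stability_concentration: float = 300.0
    period_drift: float = 0.3
    read_depth: int = 20000
    guarantee_presence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.n_otus < 10:
            raise ValueError("need at least 10 OTUs")
        if not (0 < self.dominant_mean_share < 1):
            raise ValueError("dominant_mean_share must be in (0, 1)")
        lo, hi = self.personal_abundance_range
        if not (0 < lo <= hi < 1):
            raise ValueError("personal_abundance_range must satisfy 0 < low <= high < 1")
        reserved = (1 + self.n_common_otus
                    + self.n_individuals * self.n_personal_otus_per_individual)
        if reserved > self.n_otus:
            raise ValueError(
                f"OTU budget infeasible: 1 dominant + {self.n_common_otus} common + "
                f"{self.n_individuals}x{self.n_personal_otus_per_individual} personal "
                f"= {reserved} > n_otus = {self.n_otus}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["personal_abundance_range"] = list(self.personal_abundance_range)
        d["background_abundance_range"] = list(self.background_abundance_range)
        return d


@dataclass
class GroundTruth:
    """What the generator planted: owners, personal OTUs, baselines."""

    sample_owner: dict[str, str]
    personal_otus: dict[str, set[str]]
    baselines: dict[str, list[float]]  # year-1 baseline composition per individual
    config: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "sample_owner": self.sample_owner,
            "personal_otus": {k: sorted(v) for k, v in self.personal_otus.items()},
            "baselines": self.baselines,
            "config": self.config,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            sample_owner=d["sample_owner"],
            personal_otus={k: set(v) for k, v in d["personal_otus"].items()},
            baselines=d["baselines"],
            config=d.get("config", {}),
        )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_cohort(config: SyntheticConfig | None = None) -> tuple[OtuTable, GroundTruth]:
    """Generate a cohort table (counts) plus ground truth, deterministically.

    Sample count = n_individuals x n_timepoints_per_period x n_periods; every
    sample's counts sum exactly to ``read_depth``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n_ind = config.n_individuals
    n_otus = config.n_otus

    otu_ids = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    individuals = [f"I{i + 1:02d}" for i in range(n_ind)]

    dominant_idx = 0
    common_idx = np.arange(1, 1 + config.n_common_otus)
    personal_blocks: dict[str, np.ndarray] = {}
    cursor = 1 + config.n_common_otus
    for ind in individuals:
        personal_blocks[ind] = np.arange(cursor, cursor + config.n_personal_otus_per_individual)
        cursor += config.n_personal_otus_per_individual
    background_idx = np.arange(cursor, n_otus)

    lo, hi = config.personal_abundance_range
    bg_lo, bg_hi = config.background_abundance_range

    # per-individual year-1 baselines
    baselines: dict[str, np.ndarray] = {}
    for ind in individuals:
        base = np.zeros(n_otus)
        share = float(np.clip(
            rng.normal(config.dominant_mean_share, config.dominant_share_sd),
            0.5, 0.98))
        base[common_idx] = rng.uniform(0.01, 0.04, size=len(common_idx))
        base[personal_blocks[ind]] = _log_uniform(rng, lo, hi,
                                                  size=len(personal_blocks[ind]))
        if len(background_idx):
            present = rng.random(len(background_idx)) < config.background_presence_prob
            abund = _log_uniform(rng, bg_lo, bg_hi, size=len(background_idx))
            base[background_idx] = np.where(present, abund, 0.0)
        # tail scaled to the dominant share's complement, so the dominant
        # OTU's expected relative abundance is exactly `share`
        base *= (1.0 - share) / base.sum()
        base[dominant_idx] = share
        baselines[ind] = base

    # per-(individual, period) baselines with drift after period 1
    period_baselines: dict[tuple[str, int], np.ndarray] = {}
    for ind in individuals:
        period_baselines[(ind, 1)] = baselines[ind]
        for period in range(2, config.n_periods + 1):
            drifted = baselines[ind].copy()
            nz = drifted > 0
            drifted[nz] *= np.exp(config.period_drift * rng.normal(size=nz.sum()))
            if len(background_idx) and config.period_drift > 0:
                redraw = rng.random(len(background_idx)) < min(1.0, config.period_drift)
                present = rng.random(len(background_idx)) < config.background_presence_prob
                fresh = _log_uniform(rng, bg_lo, bg_hi, size=len(background_idx))
                bg = drifted[background_idx]
                bg = np.where(redraw, np.where(present, fresh, 0.0), bg)
                drifted[background_idx] = bg
            # personal OTUs persist across periods by construction
            drifted[personal_blocks[ind]] = np.maximum(
                drifted[personal_blocks[ind]], lo)
            period_baselines[(ind, period)] = drifted / drifted.sum()

    # samples
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for ind in individuals:
        tp_global = 0
        for period in range(1, config.n_periods + 1):
            base = period_baselines[(ind, period)]
            support = base > 0
            alpha = config.stability_concentration * base[support]
            for _ in range(config.n_timepoints_per_period):
                tp_global += 1
                comp = rng.dirichlet(alpha)
                counts = np.zeros(n_otus, dtype=np.int64)
                counts[support] = rng.multinomial(config.read_depth, comp)
                if config.guarantee_presence:
                    for j in personal_blocks[ind]:
                        if counts[j] == 0 and counts[dominant_idx] > 1:
                            counts[j] = 1
                            counts[dominant_idx] -= 1
                sid = f"{ind}_y{period}_t{tp_global}"
                columns[sid] = counts
                meta_rows.append({
                    "sample_id": sid,
                    "individual_id": ind,
                    "timepoint": tp_global,
                    "period": f"year{period}",
                })

    data = pd.DataFrame(columns, index=otu_ids, dtype=float)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    table = OtuTable(
        data=data,
        metadata=metadata,
        value_kind="counts",
        provenance=[
            "synthetic Dirichlet-multinomial cohort "
            f"(seed {config.seed}, depth {config.read_depth}, "
            f"concentration {config.stability_concentration}, "
            f"drift {config.period_drift}, "
            f"guarantee_presence {config.guarantee_presence})"
        ],
    )
    truth = GroundTruth(
        sample_owner={r["sample_id"]: r["individual_id"] for r in meta_rows},
        personal_otus={
            ind: {otu_ids[j] for j in personal_blocks[ind]} for ind in individuals
        },
        baselines={ind: baselines[ind].tolist() for ind in individuals},
        config=config.to_dict(),
    )
    return table, truth


def default_cohort_config(seed: int = 0) -> SyntheticConfig:
    """The standard study condition: 11 individuals sampled 3x in each of two
    years (66 samples), 5 planted personal OTUs per individual, 20,000 reads
    per sample — the cohort geometry used throughout the worked examples."""
    return SyntheticConfig(seed=seed)


def noisy_cohort_config(seed: int = 0) -> SyntheticConfig:
    """A larger, noisier single-period cohort (15 individuals x 7 timepoints,
    10,000 reads, no presence floor for personal OTUs, wider background
    abundances). Identification accuracy sits mid-range here, which is the
    regime where the number of reference samples and the sequencing depth
    visibly matter."""
    return SyntheticConfig(
        n_individuals=15,
        n_timepoints_per_period=7,
        n_periods=1,
        n_personal_otus_per_individual=3,
        stability_concentration=300.0,
        read_depth=10000,
        guarantee_presence=False,
        background_abundance_range=(1e-5, 1e-3),
        seed=seed,
    )


def config_from_yaml(path: str | Path, **overrides) -> SyntheticConfig:
    """Load a SyntheticConfig from YAML, with keyword overrides winning."""
    import yaml

    raw: Mapping = yaml.safe_load(Path(path).read_text()) or {}
    merged = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    if "personal_abundance_range" in merged:
        merged["personal_abundance_range"] = tuple(merged["personal_abundance_range"])
    return SyntheticConfig(**merged)
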