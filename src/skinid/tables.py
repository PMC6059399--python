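"""OTU tables: data model, TSV I/O, and the standard preprocessing transforms.

The unit of analysis is an OTU count (or relative-abundance) table over a
shared, ordered OTU universe, with per-sample metadata identifying the owner
(individual), the timepoint index and the sampling period (e.g. year).
Absent OTUs are stored densely as zeros so that every pair of samples is
aligned coordinate-by-coordinate, which the Canberra distance requires.

Transforms provided here mirror common 16S workflow steps:

* :func:`to_relative_abundance` — per-sample total-sum scaling,
* :func:`apply_cutoff` — zeroing of relative abundances below a threshold
  (without renormalisation: zeroing rare taxa must not change the value
  recorded for the dominant taxon),
* :func:`rarefy` — uniform subsampling of reads without replacement to a
  fixed depth,
* :func:`shannon_index` — the Shannon α-diversity of one sample
  (natural log).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "individual_id", "timepoint", "period")

ValueKind = Literal["counts", "proportions"]


@dataclass(frozen=True)
class OtuProfile:
    """One sample's abundance vector over a shared OTU universe."""

    sample_id: str
    individual_id: str
    timepoint: int
    period: str
    values: np.ndarray
    value_kind: ValueKind = "counts"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("profile values must be a 1-D vector")
        if np.any(values < 0):
            raise ValueError(f"sample {self.sample_id!r}: negative abundance")
        if self.value_kind == "counts" and not np.allclose(values, np.round(values)):
            raise ValueError(f"sample {self.sample_id!r}: counts must be integers")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class OtuTable:
    """A cohort of profiles sharing one ordered OTU universe.

    ``data`` is an (OTUs x samples) DataFrame whose index is the OTU-id list
    and whose columns are sample ids; ``metadata`` is indexed by sample_id
    with columns individual_id, timepoint, period. ``provenance`` is a
    free-text record of the transforms applied, appended to by every
    transform so reports can state exactly what was run.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame
    value_kind: ValueKind = "counts"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- integrity ---------------------------------------------------------

    def validate(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dupes}")
        missing = set(self.data.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(
                f"samples present in counts but absent from metadata: {sorted(missing)}"
            )
        extra = set(self.metadata.index) - set(self.data.columns)
        if extra:
            raise ValueError(
                f"samples present in metadata but absent from counts: {sorted(extra)}"
            )
        if (self.data.values < 0).any():
            r, c = np.argwhere(self.data.values < 0)[0]
            raise ValueError(
                f"negative abundance at OTU {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.metadata["individual_id"].astype(str).str.len().eq(0).any():
            raise ValueError("every profile needs a non-empty individual_id")
        # keep metadata in column order of the data for stable iteration
        self.metadata = self.metadata.loc[self.data.columns]

    # -- views -------------------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.metadata["individual_id"]:
            seen.setdefault(str(ind), None)
        return list(seen)

    def samples_of(self, individual_id: str) -> list[str]:
        mask = self.metadata["individual_id"].astype(str) == str(individual_id)
        return list(self.metadata.index[mask])

    def profile(self, sample_id: str) -> OtuProfile:
        if sample_id not in self.data.columns:
            raise KeyError(f"unknown sample {sample_id!r}")
        meta = self.metadata.loc[sample_id]
        return OtuProfile(
            sample_id=str(sample_id),
            individual_id=str(meta["individual_id"]),
            timepoint=int(meta["timepoint"]),
            period=str(meta["period"]),
            values=self.data[sample_id].to_numpy(dtype=float),
            value_kind=self.value_kind,
        )

    def profiles(self) -> Iterator[OtuProfile]:
        for sid in self.data.columns:
            yield self.profile(sid)

    def subset(self, sample_ids: list[str]) -> "OtuTable":
        """A new table restricted to the given samples (order preserved)."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return OtuTable(
            data=self.data[sample_ids].copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
            value_kind=self.value_kind,
            provenance=self.provenance + [f"subset to {len(sample_ids)} samples"],
        )

    def matrix(self) -> np.ndarray:
        """(samples x OTUs) float array, rows ordered as ``sample_ids``."""
        return self.data.to_numpy(dtype=float).T


# -- I/O -------------------------------------------------------------------


def read_otu_table(
    counts_path: str | Path,
    metadata_path: str | Path,
    transpose: bool = False,
) -> OtuTable:
    """Read a counts TSV (OTUs as rows, samples as columns) plus metadata TSV.

    ``transpose=True`` accepts the other dialect (samples as rows). Metadata
    must carry columns sample_id, individual_id, timepoint, period. Samples
    must match one-to-one between the two files.
    """
    data = pd.read_csv(counts_path, sep="\t", index_col=0)
    if transpose:
        data = data.T
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    for col in data.columns:
        coerced = pd.to_numeric(data[col], errors="coerce")
        if coerced.isna().any():
            row = data.index[coerced.isna()][0]
            raise ValueError(
                f"non-numeric cell at OTU {row!r}, sample {col!r} in {counts_path}"
            )
        data[col] = coerced

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    meta = meta.set_index("sample_id")
    meta["individual_id"] = meta["individual_id"].astype(str)
    meta["period"] = meta["period"].astype(str)

    float_vals = data.to_numpy(dtype=float)
    kind: ValueKind = "counts" if np.allclose(float_vals, np.round(float_vals)) else "proportions"
    return OtuTable(
        data=data.astype(float),
        metadata=meta,
        value_kind=kind,
        provenance=[f"read from {counts_path}"],
    )


def write_table(
    table: OtuTable,
    out_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Serialise to TSV readable by :func:`read_otu_table`.

    Values are written with 12 significant digits so 1e-6-scale minor taxa
    survive a round trip; metadata goes to ``metadata_path`` (default:
    ``<out_path stem>.meta.tsv`` alongside the counts file).
    """
    out_path = Path(out_path)
    if metadata_path is None:
        metadata_path = out_path.with_suffix(".meta.tsv")
    if table.value_kind == "counts":
        df = table.data.astype(int)
        df.index.name = "otu_id"
        df.to_csv(out_path, sep="\t", lineterminator="\n")
    else:
        df = table.data.copy()
        df.index.name = "otu_id"
        df.to_csv(out_path, sep="\t", float_format="%.12g", lineterminator="\n")
    meta = table.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t", lineterminator="\n")


# -- transforms ------------------------------------------------------------


def to_relative_abundance(table: OtuTable) -> OtuTable:
    """Divide each sample by its own total; output columns sum to 1."""
    if table.value_kind != "counts":
        raise ValueError("table is already proportion-valued")
    totals = table.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    return OtuTable(
        data=table.data / totals,
        metadata=table.metadata.copy(),
        value_kind="proportions",
        provenance=table.provenance + ["total-sum scaled to relative abundance"],
    )


def apply_cutoff(table: OtuTable, cutoff: float) -> OtuTable:
    """Zero every relative abundance strictly below ``cutoff``.

    No renormalisation is applied afterwards: the point of the cut-off is to
    discard putative noise taxa, not to inflate what remains. ``cutoff=0`` is
    the identity.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if table.value_kind != "proportions":
        raise ValueError("cut-offs are defined on relative abundance; "
                         "call to_relative_abundance first")
    data = table.data.where(table.data >= cutoff, 0.0)
    return OtuTable(
        data=data,
        metadata=table.metadata.copy(),
        value_kind="proportions",
        provenance=table.provenance + [f"abundance cutoff {cutoff:g}"],
    )


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample's reads uniformly *without replacement* to ``depth``.

    Samples with fewer than ``depth`` reads are dropped (their ids are logged
    and recorded in provenance). Deterministic for a fixed seed. Raises if no
    sample survives.
    """
    if table.value_kind != "counts":
        raise ValueError("rarefaction is defined on counts")
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    rng = np.random.default_rng(seed)
    totals = table.data.sum(axis=0)
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if dropped:
        logger.warning("rarefy(depth=%d): dropped %d shallow sample(s): %s",
                       depth, len(dropped), dropped)
    if not kept:
        raise ValueError(f"rarefaction depth {depth} drops every sample")
    out = pd.DataFrame(0.0, index=table.data.index, columns=kept)
    for s in kept:
        counts = table.data[s].to_numpy(dtype=np.int64)
        out[s] = rng.multivariate_hypergeometric(counts, depth).astype(float)
    note = f"rarefied to depth {depth} (seed {seed})"
    if dropped:
        note += f"; dropped shallow samples {dropped}"
    return OtuTable(
        data=out,
        metadata=table.metadata.loc[kept].copy(),
        value_kind="counts",
        provenance=table.provenance + [note],
    )


def shannon_index(profile: OtuProfile) -> float:
    """Shannon diversity H = −Σ p_i ln p_i over the sample's composition.

    Natural logarithm; zero-abundance OTUs contribute nothing, so the value
    is invariant to padding the OTU universe.
    """
    total = profile.total
    if total <= 0:
        raise ValueError(f"sample {profile.sample_id!r} has zero total abundance")
    p = profile.values[profile.values > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: OtuTable) -> pd.Series:
    """Shannon index of every sample in the table, as a Series."""
    return pd.Series(
        {p.sample_id: shannon_index(p) for p in table.profiles()}, name="shannon"
    )
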