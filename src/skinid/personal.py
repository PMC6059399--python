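"""Detection of "personal OTUs" — taxa that individualise a skin microbiome.

An OTU is personal to an individual when it is present (abundance > 0) at
every one of that individual's sampled timepoints and is not similarly
omnipresent for any other individual. Optionally the OTU must also be at
least two-fold enriched (log2 fold change >= 1, inclusive) in the owner's
median abundance relative to the pooled median over all other individuals'
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .tables import OtuTable


@dataclass(frozen=True)
class PersonalOtuRecord:
    otu_id: str
    individual_id: str
    median_abundance_owner: float
    median_abundance_others: float
    log2_fold_change: float  # +inf when others' median is 0
    passed_fc_filter: bool
    origin: str | None = None

    def to_row(self) -> dict:
        return {
            "otu_id": self.otu_id,
            "individual_id": self.individual_id,
            "median_abundance_owner": self.median_abundance_owner,
            "median_abundance_others": self.median_abundance_others,
            "log2_fold_change": ("inf" if math.isinf(self.log2_fold_change)
                                 else self.log2_fold_change),
            "passed_fc_filter": self.passed_fc_filter,
            "origin": self.origin if self.origin is not None else "",
        }


def detect_personal_otus(
    table: OtuTable,
    require_fold_change: bool = False,
    fc_log2_min: float = 1.0,
    unique_to_one: bool = True,
    origin_annotations: Mapping[str, str] | None = None,
) -> list[PersonalOtuRecord]:
    """Find OTUs present at every timepoint of exactly one individual.

    ``unique_to_one=False`` relaxes the uniqueness clause to
    owner-complete-presence only (an OTU omnipresent in two individuals is
    then reported for both). The fold-change filter compares the owner's
    median abundance to the median over ALL other individuals' samples
    pooled; the >= comparison is inclusive, so a ratio of exactly 2 passes
    the default filter. ``origin_annotations`` is an optional otu_id ->
    isolation-source-category map joined onto the records.

    Records are sorted by individual, then descending fold change (+inf
    first), then otu_id. Output is invariant to sample and OTU order.
    """
    if table.n_samples == 0:
        raise ValueError("table has no samples")
    values = table.data  # OTUs x samples
    meta = table.metadata
    individuals = table.individuals

    present = values > 0
    complete: dict[str, pd.Series] = {}
    for ind in individuals:
        cols = table.samples_of(ind)
        complete[ind] = present[cols].all(axis=1)

    records: list[PersonalOtuRecord] = []
    sample_owner = meta["individual_id"].astype(str)
    for ind in individuals:
        mask = complete[ind].copy()
        if unique_to_one:
            for other in individuals:
                if other != ind:
                    mask &= ~complete[other]
        if not mask.any():
            continue
        own_cols = values.columns[sample_owner == ind]
        other_cols = values.columns[sample_owner != ind]
        own_median = values.loc[mask, own_cols].median(axis=1)
        other_median = (values.loc[mask, other_cols].median(axis=1)
                        if len(other_cols) else pd.Series(0.0, index=values.index[mask]))
        for otu in values.index[mask]:
            mo = float(own_median[otu])
            mt = float(other_median[otu])
            if mt == 0.0:
                fc = math.inf
            else:
                fc = math.log2(mo / mt) if mo > 0 else -math.inf
            passed = fc >= fc_log2_min
            if require_fold_change and not passed:
                continue
            records.append(PersonalOtuRecord(
                otu_id=str(otu),
                individual_id=ind,
                median_abundance_owner=mo,
                median_abundance_others=mt,
                log2_fold_change=fc,
                passed_fc_filter=passed,
                origin=(origin_annotations or {}).get(str(otu)),
            ))
    records.sort(key=lambda r: (r.individual_id, -r.log2_fold_change, r.otu_id))
    return records


def read_origin_annotations(path: str | Path) -> dict[str, str]:
    """Read a user-supplied otu_id -> origin-category TSV (two columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation TSV needs columns otu_id and category")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_personal_otus(records: list[PersonalOtuRecord], path: str | Path) -> None:
    """Export records as TSV (otu, individual, medians, fold change, origin)."""
    pd.DataFrame([r.to_row() for r in records]).to_csv(
        path, sep="\t", index=False, float_format="%.12g", lineterminator="\n")


def detection_metrics(
    records: list[PersonalOtuRecord],
    truth: Mapping[str, set[str]],
) -> dict[str, float]:
    """Precision/recall of detected (individual, otu) pairs against a
    planted ground-truth map individual_id -> set of otu_ids."""
    detected = {(r.individual_id, r.otu_id) for r in records}
    planted = {(ind, otu) for ind, otus in truth.items() for otu in otus}
    tp = len(detected & planted)
    precision = tp / len(detected) if detected else 0.0
    recall = tp / len(planted) if planted else 1.0
    return {"precision": precision, "recall": recall,
            "n_detected": len(detected), "n_planted": len(planted)}
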