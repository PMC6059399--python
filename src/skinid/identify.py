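"""The nearest-mean classifier over microbiome distances.

A query sample is scored against every reference individual by the
arithmetic mean distance to that individual's reference samples,

    D_individual(q, r_individual) = (1/n) * sum_i D(q, r_i),

and assigned to the individual attaining the minimum (closed-set). The
open-set variant additionally rejects the assignment when the minimum mean
distance is not strictly below a distance threshold, which makes true
negatives possible when the query's owner is absent from the reference
panel. Accuracy is tallied as

    accuracy = N_TP / (N_TP + N_FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .distances import get_metric
from .tables import OtuProfile, OtuTable

REJECTED = "REJECTED"

#: two mean distances closer than this are considered tied
TIE_TOL = 1e-12


@dataclass
class ReferenceSet:
    """Reference profiles grouped by individual.

    ``space`` records whether the vectors are counts or proportions — the
    Canberra distance is per-term scale invariant, so for equal-depth
    samples the two spaces give identical distances, but reports carry the
    choice for reproducibility.
    """

    references: dict[str, list[OtuProfile]]
    metric: str = "canberra"
    space: str = "proportions"

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("reference set has no individuals")
        lengths = set()
        for ind, profiles in self.references.items():
            if not profiles:
                raise ValueError(f"individual {ind!r} has an empty reference list")
            for p in profiles:
                if p.individual_id != ind:
                    raise ValueError(
                        f"profile {p.sample_id!r} has owner {p.individual_id!r} "
                        f"but is listed under {ind!r}"
                    )
                lengths.add(len(p.values))
        if len(lengths) > 1:
            raise ValueError(f"reference profiles disagree on OTU universe size: {lengths}")
        self._vector_length = lengths.pop()

    @classmethod
    def from_table(
        cls,
        table: OtuTable,
        metric: str = "canberra",
        exclude: Sequence[str] = (),
        include_individuals: Sequence[str] | None = None,
    ) -> "ReferenceSet":
        """Build a reference set from a table, optionally excluding samples
        (e.g. the current query in leave-one-out) or whole individuals."""
        excluded = set(exclude)
        refs: dict[str, list[OtuProfile]] = {}
        for p in table.profiles():
            if p.sample_id in excluded:
                continue
            if include_individuals is not None and p.individual_id not in include_individuals:
                continue
            refs.setdefault(p.individual_id, []).append(p)
        return cls(references=refs, metric=metric, space=table.value_kind)

    @property
    def individuals(self) -> list[str]:
        return list(self.references)


@dataclass
class IdentificationResult:
    query_sample_id: str
    mean_distances: dict[str, float]
    predicted: str
    min_distance: float
    tie: bool
    threshold_used: float | None = None
    true_owner: str | None = None

    @property
    def rejected(self) -> bool:
        return self.predicted == REJECTED

    def to_row(self) -> dict:
        return {
            "query_sample_id": self.query_sample_id,
            "true_owner": self.true_owner if self.true_owner is not None else "",
            "predicted": self.predicted,
            "min_distance": self.min_distance,
            "tie": self.tie,
            "threshold": self.threshold_used if self.threshold_used is not None else "",
        }


@dataclass
class ConfusionCounts:
    """TP/FN/FP/TN tallies for the identification protocols."""

    n_tp: int = 0
    n_fn: int = 0
    n_fp: int = 0
    n_tn: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tp", "n_fn", "n_fp", "n_tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.n_tp + self.n_fn + self.n_fp + self.n_tn

    def to_dict(self) -> dict[str, int]:
        return {"n_tp": self.n_tp, "n_fn": self.n_fn, "n_fp": self.n_fp, "n_tn": self.n_tn}


def mean_distance_to_individual(
    query: OtuProfile, refs: Sequence[OtuProfile], metric: str = "canberra"
) -> float:
    """Arithmetic mean distance from a query to one individual's references."""
    if not refs:
        raise ValueError("reference list is empty")
    dist = get_metric(metric)
    return float(np.mean([dist(query.values, r.values) for r in refs]))


def _argmin_with_tie(mean_distances: Mapping[str, float]) -> tuple[str, float, bool]:
    """Lexicographically-first argmin plus a flag for ties within TIE_TOL."""
    best = min(mean_distances.values())
    winners = sorted(ind for ind, d in mean_distances.items() if d - best <= TIE_TOL)
    return winners[0], best, len(winners) > 1


def classify_closed(
    query: OtuProfile, refset: ReferenceSet, true_owner: str | None = None
) -> IdentificationResult:
    """Closed-set assignment: the individual with minimum mean distance.

    Ties are broken deterministically by lexicographic individual id and
    flagged in the result.
    """
    if len(query.values) != refset._vector_length:
        raise ValueError(
            f"query {query.sample_id!r} has {len(query.values)} OTUs but the "
            f"reference universe has {refset._vector_length}"
        )
    means = {
        ind: mean_distance_to_individual(query, refs, refset.metric)
        for ind, refs in refset.references.items()
    }
    predicted, best, tie = _argmin_with_tie(means)
    return IdentificationResult(
        query_sample_id=query.sample_id,
        mean_distances=means,
        predicted=predicted,
        min_distance=best,
        tie=tie,
        threshold_used=None,
        true_owner=true_owner,
    )


def classify_open(
    query: OtuProfile,
    refset: ReferenceSet,
    threshold: float,
    true_owner: str | None = None,
) -> IdentificationResult:
    """Open-set assignment: reject unless min mean distance < threshold (strict)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    result = classify_closed(query, refset, true_owner=true_owner)
    result.threshold_used = float(threshold)
    if not result.min_distance < threshold:
        result.predicted = REJECTED
    return result


def score_confusion(
    results: Sequence[IdentificationResult], owner_present: bool = True
) -> ConfusionCounts:
    """Tally results under the owner-present or owner-absent protocol.

    Owner present: assigned-to-owner → TP, assigned-to-other → FP,
    rejected → FN. Owner absent: any assignment → FP, rejected → TN.
    Closed-set results (no threshold) tally assigned-to-owner → TP and any
    misassignment → FN, so accuracy = correct/total.
    """
    counts = ConfusionCounts()
    for r in results:
        if owner_present:
            if r.true_owner is None:
                raise ValueError(
                    f"result for {r.query_sample_id!r} lacks true_owner under the "
                    "owner-present protocol"
                )
            if r.threshold_used is None:
                if r.predicted == r.true_owner:
                    counts.n_tp += 1
                else:
                    counts.n_fn += 1
            elif r.rejected:
                counts.n_fn += 1
            elif r.predicted == r.true_owner:
                counts.n_tp += 1
            else:
                counts.n_fp += 1
        else:
            if r.rejected:
                counts.n_tn += 1
            else:
                counts.n_fp += 1
    return counts


def accuracy(counts: ConfusionCounts) -> float:
    """True-positive rate N_TP / (N_TP + N_FN)."""
    denom = counts.n_tp + counts.n_fn
    if denom == 0:
        raise ValueError("accuracy undefined: no owner-present queries tallied")
    return counts.n_tp / denom
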