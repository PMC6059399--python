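"""Validation experiments for the identification method.

Every experiment reduces to the same primitive: score queries against
reference panels by mean distance and count correct assignments. All
experiments therefore share one precomputed pairwise distance matrix per
table, which makes leave-one-out and the 100-trial randomised designs cheap;
tests assert that the matrix fast path agrees with per-query classification.

Experiments provided:

* :func:`leave_one_out` — each sample is the query once, excluded from its
  owner's reference list (closed-set).
* :func:`cross_period_eval` — references from one period (e.g. year 1),
  queries from another.
* :func:`time_effect_trials` — randomised same-period vs cross-period
  reference/query pairs, repeated trials.
* :func:`reference_count_trials` — accuracy as a function of the number of
  reference samples per individual (1–5), repeated trials.
* :func:`cutoff_sweep` — leave-one-out accuracy after zeroing abundances
  below each cut-off.
* :func:`rarefaction_sweep` — leave-one-out accuracy after rarefying to
  each read depth, replicated.
* :func:`open_set_threshold_sweep` — TP-ratio (owner present) and TN-ratio
  (owner absent) curves over a grid of rejection thresholds.
* :func:`metrics_compare` — leave-one-out under Canberra, Bray–Curtis and
  Jaccard side by side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import METRICS, pairwise_distance_matrix
from .identify import (
    REJECTED,
    ConfusionCounts,
    IdentificationResult,
    _argmin_with_tie,
    accuracy,
    score_confusion,
)
from .tables import OtuTable, apply_cutoff, rarefy

DEFAULT_CUTOFFS = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 0.0)
DEFAULT_DEPTHS = (100, 1000, 10000, 20000)
DEFAULT_THRESHOLD_GRID = tuple(float(t) for t in range(14000, 18001, 100))


@dataclass
class EvalConfig:
    """Knobs shared by the experiments; every report echoes its config."""

    metric: str = "canberra"
    cutoff: float = 0.0
    threshold: float | None = None
    thresholds: Sequence[float] | None = None
    ref_count: int = 5
    n_trials: int = 100
    depths: Sequence[int] = DEFAULT_DEPTHS
    n_reps: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depths"] = list(self.depths)
        d["thresholds"] = list(self.thresholds) if self.thresholds is not None else None
        return d


@dataclass
class EvalReport:
    """Machine-readable result of one experiment.

    ``rows`` holds per-query (or per-grid-point) records; ``conditions``
    holds per-parameter summaries for sweeps and trial designs. The summary
    accuracy is always recomputable from the stored rows/counts.
    """

    experiment: str
    config: dict
    rows: list[dict] = field(default_factory=list)
    confusion: ConfusionCounts | None = None
    accuracy: float | None = None
    conditions: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "config": self.config,
            "confusion": self.confusion.to_dict() if self.confusion else None,
            "accuracy": self.accuracy,
            "conditions": self.conditions,
            "notes": self.notes,
            "n_rows": len(self.rows),
        }

    def write(self, out_dir: str | Path, stem: str | None = None) -> dict[str, Path]:
        """Write report JSON + per-query TSV + tidy long-format TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = stem or self.experiment
        paths: dict[str, Path] = {}
        jpath = out_dir / f"{stem}.report.json"
        payload = self.to_dict()
        payload["rows"] = self.rows
        jpath.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        paths["json"] = jpath
        if self.rows:
            rpath = out_dir / f"{stem}.rows.tsv"
            pd.DataFrame(self.rows).to_csv(rpath, sep="\t", index=False,
                                           float_format="%.12g", lineterminator="\n")
            paths["rows"] = rpath
        if self.conditions:
            tidy = self.tidy()
            tpath = out_dir / f"{stem}.tidy.tsv"
            tidy.to_csv(tpath, sep="\t", index=False,
                        float_format="%.12g", lineterminator="\n")
            paths["tidy"] = tpath
        return paths

    def tidy(self) -> pd.DataFrame:
        """Long-format (parameter, value, trial, accuracy) frame for plotting."""
        records = []
        for cond in self.conditions:
            param = cond.get("parameter", "condition")
            value = cond.get("value")
            accs = cond.get("accuracies")
            if accs is None:
                records.append(
                    {"parameter": param, "value": value, "trial": 0,
                     "accuracy": cond.get("accuracy")}
                )
            else:
                for t, a in enumerate(accs):
                    records.append(
                        {"parameter": param, "value": value, "trial": t, "accuracy": a}
                    )
        return pd.DataFrame.from_records(records)


# -- internals -------------------------------------------------------------


def _samples_by_individual(table: OtuTable) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for sid, ind in table.metadata["individual_id"].astype(str).items():
        groups.setdefault(ind, []).append(sid)
    return groups


def _require_min_samples(groups: Mapping[str, list[str]], k: int, why: str) -> None:
    thin = sorted(ind for ind, ids in groups.items() if len(ids) < k)
    if thin:
        raise ValueError(f"individual(s) {thin} have fewer than {k} samples ({why})")


def _classify_row(
    drow: pd.Series,
    ref_ids: Mapping[str, Sequence[str]],
    query_id: str,
    true_owner: str | None,
    threshold: float | None = None,
) -> IdentificationResult:
    """Classify one query from its row of the precomputed distance matrix."""
    means = {ind: float(drow[list(ids)].mean()) for ind, ids in ref_ids.items() if len(ids)}
    predicted, best, tie = _argmin_with_tie(means)
    if threshold is not None and not best < threshold:
        predicted = REJECTED
    return IdentificationResult(
        query_sample_id=query_id,
        mean_distances=means,
        predicted=predicted,
        min_distance=best,
        tie=tie,
        threshold_used=threshold,
        true_owner=true_owner,
    )


def _closed_set_report(results: list[IdentificationResult], experiment: str,
                       config: EvalConfig, extra_config: dict | None = None) -> EvalReport:
    confusion = score_confusion(results, owner_present=True)
    cfg = config.to_dict()
    cfg.update(extra_config or {})
    return EvalReport(
        experiment=experiment,
        config=cfg,
        rows=[r.to_row() for r in results],
        confusion=confusion,
        accuracy=accuracy(confusion),
    )


def _trial_rng(seed: int, *path: int) -> np.random.Generator:
    """Per-trial generator: the master seed spawns independent sub-streams so
    any single trial is reproducible in isolation."""
    return np.random.default_rng(np.random.SeedSequence([seed, *path]))


def _trial_accuracy(
    Dv: np.ndarray,
    pos: Mapping[str, int],
    refs: Mapping[str, Sequence[str]],
    queries: Sequence[tuple[str, str]],
) -> float:
    """Fraction of (owner, query) pairs whose argmin mean distance is the
    owner, computed on the raw distance array (fast path for trial designs;
    ties resolve lexicographically exactly as in classify_closed)."""
    inds = sorted(refs)
    n_ind = len(inds)
    q_rows = np.array([pos[q] for _, q in queries])
    means = np.empty((len(queries), n_ind))
    for j, ind in enumerate(inds):
        cols = np.array([pos[s] for s in refs[ind]])
        means[:, j] = Dv[np.ix_(q_rows, cols)].mean(axis=1)
    # lexicographic tie-break: inds is sorted, argmin takes the first minimum
    best = np.argmin(means, axis=1)
    correct = sum(inds[b] == owner for b, (owner, _) in zip(best, queries))
    return correct / len(queries)


# -- experiments -----------------------------------------------------------


def leave_one_out(table: OtuTable, config: EvalConfig | None = None) -> EvalReport:
    """Closed-set leave-one-out: each sample queried against all the rest."""
    config = config or EvalConfig()
    groups = _samples_by_individual(table)
    _require_min_samples(groups, 2, "leave-one-out needs a non-empty reference "
                                    "after removing the query")
    D = pairwise_distance_matrix(table, config.metric)
    results = []
    for sid in table.sample_ids:
        owner = str(table.metadata.loc[sid, "individual_id"])
        ref_ids = {ind: [s for s in ids if s != sid] for ind, ids in groups.items()}
        results.append(_classify_row(D.loc[sid], ref_ids, sid, owner))
    report = _closed_set_report(results, "leave_one_out", config,
                                {"space": table.value_kind})
    report.notes.extend(table.provenance)
    return report


def cross_period_eval(
    table: OtuTable, ref_period: str, query_period: str,
    config: EvalConfig | None = None,
) -> EvalReport:
    """References drawn from one period, queries from another (closed-set)."""
    config = config or EvalConfig()
    periods = set(table.metadata["period"].astype(str))
    for p in (ref_period, query_period):
        if p not in periods:
            raise ValueError(f"period {p!r} not present (have {sorted(periods)})")
    meta = table.metadata
    ref_mask = meta["period"].astype(str) == ref_period
    query_mask = meta["period"].astype(str) == query_period
    groups = _samples_by_individual(table)
    for ind, ids in groups.items():
        for p, mask in ((ref_period, ref_mask), (query_period, query_mask)):
            if not any(s in set(meta.index[mask]) for s in ids):
                raise ValueError(f"individual {ind!r} has no sample in period {p!r}")
    D = pairwise_distance_matrix(table, config.metric)
    ref_samples = set(meta.index[ref_mask])
    results = []
    for sid in meta.index[query_mask]:
        owner = str(meta.loc[sid, "individual_id"])
        ref_ids = {
            ind: [s for s in ids if s in ref_samples and s != sid]
            for ind, ids in groups.items()
        }
        ref_ids = {ind: ids for ind, ids in ref_ids.items() if ids}
        results.append(_classify_row(D.loc[sid], ref_ids, sid, owner))
    return _closed_set_report(
        results, "cross_period_eval", config,
        {"ref_period": ref_period, "query_period": query_period,
         "space": table.value_kind},
    )


def time_effect_trials(
    table: OtuTable, pairing: str, config: EvalConfig | None = None
) -> EvalReport:
    """Randomised one-reference/one-query trials, same-period or cross-period.

    Per trial: a reference period is drawn uniformly; each individual
    contributes one random reference sample from it and one random query
    from the same period (``pairing="same_period"``) or from a uniformly
    chosen different period (``pairing="cross_period"``). The per-trial
    accuracy denominator is the number of individuals.
    """
    if pairing not in ("same_period", "cross_period"):
        raise ValueError("pairing must be 'same_period' or 'cross_period'")
    config = config or EvalConfig()
    meta = table.metadata
    periods = sorted(set(meta["period"].astype(str)))
    groups = _samples_by_individual(table)
    by_ind_period: dict[str, dict[str, list[str]]] = {
        ind: {
            p: [s for s in ids if str(meta.loc[s, "period"]) == p] for p in periods
        }
        for ind, ids in groups.items()
    }
    for ind, per in by_ind_period.items():
        if pairing == "same_period" and not any(len(v) >= 2 for v in per.values()):
            raise ValueError(f"individual {ind!r} lacks 2 samples in any one period")
        if pairing == "cross_period" and sum(bool(v) for v in per.values()) < 2:
            raise ValueError(f"individual {ind!r} lacks samples in 2 periods")
    D = pairwise_distance_matrix(table, config.metric)
    Dv = D.to_numpy()
    pos = {sid: i for i, sid in enumerate(D.index)}
    accs = []
    for t in range(config.n_trials):
        rng = _trial_rng(config.seed, 0, t)
        if pairing == "same_period":
            candidates = [p for p in periods
                          if all(len(per[p]) >= 2 for per in by_ind_period.values())]
        else:
            candidates = [
                p for p in periods
                if all(per[p] and any(per[q] for q in periods if q != p)
                       for per in by_ind_period.values())
            ]
        if not candidates:
            raise ValueError(f"no period supports the {pairing} design for every individual")
        ref_period = candidates[rng.integers(len(candidates))]
        refs: dict[str, list[str]] = {}
        queries: list[tuple[str, str]] = []
        for ind in groups:
            per = by_ind_period[ind]
            ref_sample = per[ref_period][rng.integers(len(per[ref_period]))]
            refs[ind] = [ref_sample]
            if pairing == "same_period":
                pool = [s for s in per[ref_period] if s != ref_sample]
            else:
                other = [p for p in periods if p != ref_period and per[p]]
                pool = per[other[rng.integers(len(other))]]
            queries.append((ind, pool[rng.integers(len(pool))]))
        accs.append(_trial_accuracy(Dv, pos, refs, queries))
    return EvalReport(
        experiment="time_effect_trials",
        config={**config.to_dict(), "pairing": pairing, "space": table.value_kind},
        conditions=[{
            "parameter": "pairing", "value": pairing, "accuracies": accs,
            "mean_accuracy": float(np.mean(accs)), "sd_accuracy": float(np.std(accs, ddof=1)),
        }],
    )


def reference_count_trials(
    table: OtuTable,
    config: EvalConfig | None = None,
    ref_counts: Sequence[int] | None = None,
) -> EvalReport:
    """Accuracy vs number of reference samples per individual.

    For each reference count r (default 1..config.ref_count): per trial,
    r random reference samples per individual and one random query per
    individual from that individual's remaining samples.
    """
    config = config or EvalConfig()
    ref_counts = list(ref_counts) if ref_counts is not None else list(
        range(1, config.ref_count + 1))
    groups = _samples_by_individual(table)
    max_rc = max(ref_counts)
    _require_min_samples(groups, max_rc + 1,
                         f"reference count {max_rc} plus one query")
    D = pairwise_distance_matrix(table, config.metric)
    Dv = D.to_numpy()
    pos = {sid: i for i, sid in enumerate(D.index)}
    conditions = []
    for rc in ref_counts:
        accs = []
        for t in range(config.n_trials):
            rng = _trial_rng(config.seed, 1, rc, t)
            refs: dict[str, list[str]] = {}
            queries: list[tuple[str, str]] = []
            for ind, ids in groups.items():
                picked = rng.choice(len(ids), size=rc, replace=False)
                refs[ind] = [ids[i] for i in picked]
                remainder = [s for s in ids if s not in set(refs[ind])]
                queries.append((ind, remainder[rng.integers(len(remainder))]))
            accs.append(_trial_accuracy(Dv, pos, refs, queries))
        conditions.append({
            "parameter": "ref_count", "value": rc, "accuracies": accs,
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        })
    return EvalReport(
        experiment="reference_count_trials",
        config={**config.to_dict(), "ref_counts": ref_counts, "space": table.value_kind},
        conditions=conditions,
    )


def cutoff_sweep(
    table: OtuTable,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    config: EvalConfig | None = None,
) -> EvalReport:
    """Leave-one-out accuracy after zeroing abundances below each cut-off."""
    config = config or EvalConfig()
    if table.value_kind != "proportions":
        raise ValueError("cutoff_sweep needs a relative-abundance table")
    conditions = []
    for cutoff in cutoffs:
        filtered = apply_cutoff(table, cutoff) if cutoff > 0 else table
        loo = leave_one_out(filtered, config)
        conditions.append({
            "parameter": "cutoff", "value": float(cutoff), "accuracy": loo.accuracy,
            "confusion": loo.confusion.to_dict(),
        })
    return EvalReport(
        experiment="cutoff_sweep",
        config={**config.to_dict(), "cutoffs": [float(c) for c in cutoffs]},
        conditions=conditions,
    )


def rarefaction_sweep(
    table: OtuTable,
    depths: Sequence[int] | None = None,
    n_reps: int | None = None,
    config: EvalConfig | None = None,
) -> EvalReport:
    """Leave-one-out accuracy after rarefying to each depth, replicated.

    Each (depth, replicate) uses an independently derived sub-seed, so the
    whole sweep is reproducible from the single master seed.
    """
    config = config or EvalConfig()
    depths = list(depths) if depths is not None else list(config.depths)
    n_reps = n_reps if n_reps is not None else config.n_reps
    if table.value_kind != "counts":
        raise ValueError("rarefaction_sweep needs a counts table")
    conditions = []
    for depth in depths:
        accs = []
        for rep in range(n_reps):
            sub_seed = int(np.random.SeedSequence(
                [config.seed, 2, int(depth), rep]).generate_state(1)[0] % (2**31))
            rare = rarefy(table, depth, seed=sub_seed)
            accs.append(leave_one_out(rare, config).accuracy)
        conditions.append({
            "parameter": "depth", "value": int(depth), "accuracies": accs,
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        })
    return EvalReport(
        experiment="rarefaction_sweep",
        config={**config.to_dict(), "depths": depths, "n_reps": n_reps},
        conditions=conditions,
    )


def open_set_threshold_sweep(
    table: OtuTable,
    thresholds: Sequence[float] | None = None,
    config: EvalConfig | None = None,
) -> EvalReport:
    """TP-ratio and TN-ratio curves over a grid of rejection thresholds.

    Owner-present protocol: leave-one-out with open-set classification;
    TP ratio = fraction of queries assigned to their owner below threshold.
    Owner-absent protocol: the owner's entire reference list is removed
    before classifying; TN ratio = fraction of queries rejected. Each query
    flips at a single threshold, so the TP curve is non-decreasing and the
    TN curve non-increasing in the threshold.
    """
    config = config or EvalConfig()
    if thresholds is None:
        thresholds = (list(config.thresholds) if config.thresholds is not None
                      else list(DEFAULT_THRESHOLD_GRID))
    groups = _samples_by_individual(table)
    _require_min_samples(groups, 2, "open-set sweep runs leave-one-out")
    if len(groups) < 2:
        raise ValueError("owner-absent protocol needs at least 2 individuals")
    D = pairwise_distance_matrix(table, config.metric)
    per_query = []
    for sid in table.sample_ids:
        owner = str(table.metadata.loc[sid, "individual_id"])
        present_refs = {ind: [s for s in ids if s != sid] for ind, ids in groups.items()}
        present = _classify_row(D.loc[sid], present_refs, sid, owner)
        absent_refs = {ind: ids for ind, ids in groups.items() if ind != owner}
        absent = _classify_row(D.loc[sid], absent_refs, sid, owner)
        per_query.append({
            "query_sample_id": sid,
            "true_owner": owner,
            "present_predicted": present.predicted,
            "present_correct": present.predicted == owner,
            "present_min_distance": present.min_distance,
            "absent_min_distance": absent.min_distance,
        })
    correct = np.array([q["present_correct"] for q in per_query])
    d_present = np.array([q["present_min_distance"] for q in per_query])
    d_absent = np.array([q["absent_min_distance"] for q in per_query])
    conditions = []
    for thr in thresholds:
        tp_ratio = float(np.mean(correct & (d_present < thr)))
        tn_ratio = float(np.mean(~(d_absent < thr)))
        conditions.append({
            "parameter": "threshold", "value": float(thr),
            "tp_ratio": tp_ratio, "tn_ratio": tn_ratio,
        })
    return EvalReport(
        experiment="open_set_threshold_sweep",
        config={**config.to_dict(), "thresholds": [float(t) for t in thresholds],
                "space": table.value_kind},
        rows=per_query,
        conditions=conditions,
    )


def metrics_compare(
    table: OtuTable, metrics: Sequence[str] = METRICS,
    config: EvalConfig | None = None,
) -> EvalReport:
    """Leave-one-out accuracy under each distance metric, side by side."""
    config = config or EvalConfig()
    conditions = []
    for metric in metrics:
        cfg = EvalConfig(**{**config.to_dict(), "metric": metric,
                            "thresholds": None, "depths": config.depths})
        loo = leave_one_out(table, cfg)
        conditions.append({
            "parameter": "metric", "value": metric, "accuracy": loo.accuracy,
            "confusion": loo.confusion.to_dict(),
        })
    return EvalReport(
        experiment="metrics_compare",
        config={**config.to_dict(), "metrics": list(metrics)},
        conditions=conditions,
    )
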