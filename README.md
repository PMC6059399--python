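# skinid

Personal identification from skin-microbiome OTU profiles.

The human forehead microbiome is dominated by a single taxon
(*Cutibacterium acnes*, typically ~90% of reads), yet the long tail of
minor taxa differs between people and is stable enough within a person —
even across years — to act as a fingerprint. `skinid` implements a
nearest-mean classifier over the Canberra distance that exploits exactly
this: because every OTU contributes at most one unit to the distance
regardless of its abundance, rare taxa weigh as much as the dominant one.

## The method

For aligned OTU abundance vectors *X*, *Y* the Canberra distance is

```
D(X, Y) = Σ_i |x_i − y_i| / (|x_i| + |y_i|)        (0/0 terms contribute 0)
```

A query sample *q* is scored against each enrolled individual by the mean
distance to that individual's *n* reference samples,

```
D_individual(q, r_individual) = (1/n) Σ_i D(q, r_i)
```

and assigned to the individual with the smallest mean (closed-set). In the
open-set variant the assignment is kept only when the minimum mean distance
is strictly below a threshold *d*; otherwise the query is rejected as
"not enrolled", which makes true negatives possible. Accuracy is the
true-positive rate

```
accuracy = N_TP / (N_TP + N_FN)
```

The package also ships the full sensitivity harness around the classifier
(leave-one-out, same-year vs cross-year splits, 1–5 reference-sample
trials, abundance cut-off sweep, rarefaction sweep, rejection-threshold
sweep, Canberra vs Bray–Curtis vs Jaccard), a detector for "personal OTUs"
(taxa present at every timepoint of exactly one individual), Shannon
diversity, and a Dirichlet-multinomial generator of longitudinal skin
cohorts with planted ground truth so everything is testable without
external data.

## Worked example

```python
from skinid import EvalConfig, cross_period_eval, leave_one_out, to_relative_abundance
from skinid.simulate import default_cohort_config, generate_cohort

table, truth = generate_cohort(default_cohort_config(seed=0))
rel = to_relative_abundance(table)
print(leave_one_out(rel, EvalConfig(seed=0)).accuracy)
print(cross_period_eval(rel, "year1", "year2", EvalConfig(seed=0)).accuracy)
```

On the standard synthetic cohort (11 individuals sampled three times in
each of two years, 20,000 reads per sample, five planted personal OTUs per
individual) this prints:

```
1.0
1.0
```

meaning every one of the 66 leave-one-out queries, and every year-2 query
classified from year-1 references only, was assigned to its true owner.
The sensitivity scripts under `examples/` show the regimes where accuracy
degrades; e.g. `examples/02_sensitivity_sweeps.py` prints (abridged):

```
reference-count trials (mean accuracy over 100 random splits):
  1 reference(s): 0.418 +/- 0.183
  5 reference(s): 0.597 +/- 0.150
abundance cut-off sweep (leave-one-out accuracy):
  cutoff 0.1: 0.364
  cutoff 0: 1.000
rarefaction sweep (mean accuracy over 5 subsampling replicates):
  depth 100: 0.252
  depth 20000: 1.000
```

— more reference samples per individual, no abundance cut-off, and deeper
sequencing all help, because the discriminative signal lives in the rare
taxa.

## Command line

Every experiment is a subcommand of the `skinid` console script
(`simulate`, `identify`, `loo`, `cross-period`, `time-effect`, `ref-count`,
`cutoff-sweep`, `rarefy-sweep`, `open-set`, `metrics-compare`,
`personal-otus`). Inputs are a counts TSV (OTU rows, sample columns) plus
a metadata TSV (`sample_id  individual_id  timepoint  period`); outputs
are JSON reports and TSV tables that echo the full seeded configuration.

```bash
skinid simulate --seed 7 --out cohort/
skinid loo --counts cohort/counts.tsv --meta cohort/metadata.tsv --out results/
```

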