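# Methods

## The classifier

`skinid` identifies the owner of a skin-microbiome sample by nearest-mean
classification over the Canberra distance. All samples live on one shared,
ordered OTU universe stored densely (absent taxon = 0), because the
Canberra sum requires aligned coordinates. A query is scored per enrolled
individual by the arithmetic mean of its pairwise distances to that
individual's reference samples and assigned to the argmin; the open-set
variant rejects the assignment unless the minimum mean distance is
*strictly* below the threshold (an exactly-equal distance is rejected).

Numerical conventions that implementations commonly disagree on:

* **0/0 Canberra terms contribute 0** — equivalent to dropping
  coordinates absent from both samples. Consequently the distance is
  invariant to padding the OTU universe, and each term is at most 1, so
  the distance is bounded by the size of the union support.
* **Counts vs proportions.** Each Canberra term is scale-invariant, so
  equal-depth count vectors and their proportion counterparts give
  identical distances. Tables carry a `value_kind` and every report echoes
  which space was used; the harness defaults to relative abundance.
* **Ties** (mean distances within 1e-12) are broken by lexicographic
  individual id and flagged, so runs are reproducible; duplicated
  reference lists and reference order never change a result.
* **Confusion accounting.** Closed-set runs tally assigned-to-owner as TP
  and any misassignment as FN, so `accuracy = N_TP/(N_TP+N_FN)` reduces to
  correct/total. Open-set owner-present runs distinguish FP
  (assigned to the wrong individual below threshold) from FN (rejected);
  owner-absent runs tally rejection as TN and any assignment as FP.

## Preprocessing

* `to_relative_abundance` — per-sample total-sum scaling.
* `apply_cutoff` — zeroes relative abundances strictly below the cut-off
  and does **not** renormalise: the cut-off models discarding suspected
  noise reads, and renormalising would silently change the recorded value
  of the dominant taxon.
* `rarefy` — uniform subsampling **without replacement** (multivariate
  hypergeometric) to a fixed depth; samples shallower than the target are
  dropped with a logged warning and their ids recorded in provenance.
* `shannon_index` — −Σ p ln p with the natural logarithm.

## Evaluation harness

Every experiment reduces to mean-distance scoring, so each computes the
pairwise distance matrix once and then works on it; tests assert the fast
path agrees with per-query classification. Randomised designs
(reference-count trials, time-effect trials, rarefaction replicates)
derive one sub-seed per trial from the master seed, so any individual
trial is reproducible in isolation and whole sweeps are bit-identical on
re-run. The per-trial accuracy denominator is the number of individuals
(one query each).

Design points that were genuinely open:

* **Open-set owner-absent protocol** removes the owner's entire reference
  list; the other individuals' lists are untouched.
* **Time-effect trials**: each trial draws the reference period uniformly
  at random, one reference sample per individual from it, and one query
  per individual from the same period (same-period arm) or a uniformly
  chosen different period (cross-period arm).
* **Threshold sweep grids** are configurable; the conventional grid
  14,000–18,000 in steps of 100 reflects cohorts with ~10^5-OTU
  universes, where distances are dominated by taxa present in exactly one
  sample of a pair. On the synthetic cohorts here (300 OTUs) distances top
  out near 40, so the examples and acceptance script scale the grid to
  the observed distances.
* The TP-ratio curve is non-decreasing and the TN-ratio curve
  non-increasing in the threshold by construction: each query's decision
  flips at a single threshold. The endpoints are forced: below every
  observed distance TP = 0 and TN = 1; above all of them TP equals the
  closed-set leave-one-out accuracy and TN = 0.

## Personal-OTU detection

An OTU is personal to individual *i* when it is present (> 0) in every
sample of *i* and not similarly complete in any other individual
("complete presence in exactly one individual"); a flag relaxes the
uniqueness clause to owner-completeness only. The optional enrichment
filter requires the owner's median abundance to be at least 2^k times the
median over **all other individuals' samples pooled** (default k = 1); the
comparison is inclusive, so a ratio of exactly 2 passes, and the fold
change is +inf when the others' median is 0.

## The synthetic cohort generator

The generator is a test fixture with controllable structure, not a fitted
model. Per individual it builds a baseline composition: a dominant OTU
whose share is drawn from N(0.90, 0.03) (clipped), a few common OTUs
shared by everyone at percent level, planted personal OTUs on disjoint
per-individual supports with log-uniform abundances in 1e-5…1e-3, and a
sparse background of rare taxa each present in a given individual's
baseline with probability 0.15. The tail is scaled to the dominant
share's complement, so the dominant OTU's expected relative abundance is
exactly its drawn share. Samples are Dirichlet-multinomial draws:
composition ~ Dirichlet(concentration × baseline), counts ~
multinomial(read depth). Later periods perturb the baseline by
multiplicative log-normal drift and re-draw a fraction of background
presences, modelling mild between-year turnover; personal OTUs persist
across periods. With `guarantee_presence` (default on) a personal OTU that
the multinomial missed is floored to one read taken from the dominant OTU,
keeping column sums exact — this models the defining property of a
personal taxon (observed at every timepoint) rather than a sequencing
guarantee, and is switched off when studying dropout regimes.

Two named study conditions are used throughout:

* **default cohort** (`default_cohort_config`): 11 individuals × 3
  timepoints × 2 years (66 samples), 300 OTUs, 5 personal OTUs each,
  depth 20,000, concentration 300, drift 0.3. Identification here is at
  ceiling (leave-one-out accuracy 1.0), which is the regime the cut-off
  and rarefaction sweeps then degrade.
* **noisy cohort** (`noisy_cohort_config`): 15 individuals × 7 timepoints,
  one period, 3 personal OTUs, depth 10,000, no presence floor, wider
  background abundances (1e-5…1e-3). Accuracy sits mid-range
  (~0.4–0.8), which is where the number of reference samples visibly
  matters; this cohort plays the role of a larger, messier public panel.

What the generator reproduces: a single ~90% dominant taxon; a long tail
of minor taxa; intra-individual Canberra distances below inter-individual
ones; individual-specific rare taxa present at every timepoint; mild
between-year drift; accuracy that rises with reference count and
sequencing depth and falls under abundance cut-offs. What it does not:
real taxonomies or phylogenies, compositional interactions between taxa,
primer or batch effects, antibiotic perturbations, or community sizes near
10^5 OTUs — so passing tests demonstrate correctness and the direction of
the sensitivity effects, not field-scale error rates. One visible
artefact: cut-offs near the personal-OTU abundance scale (1e-3…1e-4)
can score *worse* than coarser cut-offs, because taxa fluctuating around
the threshold flip in and out of the support and inject presence noise
into the distance.

## Problem sizes

The test suite and `scripts/acceptance.py` run the experiments at the
study conditions above: 100 trials per reference count, 10 rarefaction
replicates per depth, 41-point threshold grids — the full published
protocol shapes at synthetic-cohort scale. The two accuracy worked
examples (63 of 66 and 28 of 33 correct) are computed from their confusion
counts directly, since they are fixed inputs rather than simulation
outputs.

## Known limitations

* The classifier is purely distance-based; it produces no calibrated
  probability of identity.
* Distances on unequal-depth count tables mix depth effects into the
  Canberra terms; rarefy or convert to relative abundance first (the
  harness does the latter by default).
* Personal-OTU detection is sensitive to a single dropout at any owner
  timepoint; on real data an occupancy threshold below 100% may be more
  robust than the strict all-timepoints rule implemented here.
* The open-set threshold is chosen by sweeping, not estimated from a null
  model; transferring a threshold between cohorts with different OTU
  universe sizes is not meaningful.
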