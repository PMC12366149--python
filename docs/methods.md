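# Methods

## Problem and model

Short-read SV callers produce partially overlapping, noisy call sets for
deletions (DEL) and insertions including duplications (INS) of ≥ 50 bp.
`svmeta` treats consensus building as a supervised problem: cluster the
calls, describe each cluster by the contributing callers' own quality
metrics, and learn from a truth-labeled sample how those metrics map to the
probability that the cluster represents a real variant. Two models are
maintained per SV type: the *full model* (FM) on harmonized quality
metrics + SV length, and a *basic model* (BM) on SV length + per-caller
presence flags only, whose role is purely to quantify the added value of
the metrics.

## Coordinates and filtering

All coordinates follow the VCF convention (1-based POS, inclusive END);
contig names are compared after stripping any `chr` prefix, and autosomes
are `1`–`22`. Deletion length is defined as `end − pos + 1`; when a record
carries SVLEN, the parser anchors `end = pos + |SVLEN| − 1` (htslib
recomputes a record's span from SVLEN when both SVLEN and END are present,
so END alone is not a reliable source). Insertions have `end = pos` and
take their length from |SVLEN|. DUP records are folded into INS at parse
time, permanently. Unparseable or undeclared metric fields become missing
values — never 0 — so "caller silent" and "caller reported 0" stay
distinguishable all the way into the classifier.

Default filter: DEL/INS, length ≥ 50 bp (inclusive), autosomes only;
optional BED restriction (both breakpoints must fall inside covered bases)
and a non-reference-genotype requirement (applied to truth sets during
training, not to caller outputs, since several callers genotype
unreliably).

## Caller dialects

A data-driven registry maps each caller's VCF fields (INFO/FORMAT/QUAL) to
harmonized metric names with a normalization kind: `coverage` (divided by
sample mean coverage), `read_length` (divided by read length), or `none`.
The default registry covers six DEL callers (3 BreakDancer + 10 Delly +
7 LUMPY + 7 Manta + 3 Pindel + 4 TARDIS metrics = 34, + SV length = 35
FM features) and five INS callers (6 Delly + 18 INSurVeyor + 6 Manta +
3 Pindel + 2 TARDIS = 35, + SV length = 36). The PRECISE/IMPRECISE status
is exposed as an INFO-flag-backed 0/1 metric. Exact field lists are
configuration, not parser logic; a content hash of the feature registry is
stored in every model artifact, and prediction refuses a matrix built
under a different registry.

## Merging

Two same-type calls on one contig are linked when |Δpos| ≤ `max_dist` AND
|Δend| ≤ `max_dist` (default 1000 bp); clusters are the connected
components of this relation (transitive closure), computed by union-find
over a position-sorted sweep. Requiring both breakpoints prevents chaining
a short DEL to a long one through a shared breakpoint. Representative
`pos`/`end` are member-wise lower medians; DEL `svlen` is then defined as
`end − pos + 1` (keeping the coordinate identity exact through VCF
round-trips), while INS `svlen` is the member-wise lower median. When one
caller contributes several calls to a cluster the member nearest the
representative (L1 distance on breakpoints, ties by ID) is that caller's
feature source; all member IDs are retained in the output. Default
`min_support = 1`: single-caller calls are deliberately kept and scored
rather than discarded. The implementation is checked against an
independent all-pairs transitive-closure oracle on 1000 random instances.

## Features and pre-selection

One row per consensus call; per registry entry, the normalized metric of
the caller's representative member or NaN. NaN is consumed natively by the
tree learner (no imputation). Because coverage-type metrics are divided by
mean coverage, multiplying all such raw metrics and the configured
coverage by one constant leaves the matrix bit-identical (exact for
power-of-two factors).

Before training, a correlation filter prunes redundancy: constant columns
are dropped; for each pair with |Pearson r| > 0.90 on pairwise-complete
rows, the column less |correlated| with the label is dropped
(lexicographic tie-break). The threshold is deliberately loose — the
learner's own importance-based pruning does the fine-grained selection.

## Classifier

XGBoost, `gbtree`, exact greedy splits, `binary:logistic`, single thread.
Hyperparameters are chosen by mean AUC over stratified 5-fold CV with a
fixed seed; ties keep the earlier grid point, making training fully
deterministic. The default grid is max_depth {3,5,7} × learning_rate
{0.05,0.1,0.3} × rounds {100,300} × min_child_weight {1,5}; CLI, tests
and the acceptance script use a reduced grid (depth {3,5}, rate {0.1,0.3},
100 rounds, mcw 1) to keep single-CPU runtimes in minutes — the grid is
configuration and is recorded in the artifact. After fitting, features
with zero gain importance are dropped and the search re-run until a
fixpoint (cap: 5 iterations); features with positive gain are never
removed. Classification is positive iff probability ≥ 0.5, inclusive.
Artifacts are the booster's JSON serialization plus a sidecar (feature
list, normalized gain importances, hyperparameters, CV AUC, registry hash,
seed); loading reproduces probabilities exactly. No probability
calibration is applied.

## Benchmarking

A call and truth record match when they share contig and type,
|Δpos| ≤ 500, |Δend| ≤ 500 and min(len)/max(len) ≥ 0.7 (sequence
comparison disabled). Assignment is one-to-one, greedy by ascending
|Δpos| + |Δend| with deterministic tie-breaks (smaller truth pos, smaller
call pos, then IDs); on small fixtures it is verified against maximum
bipartite matching. FN counts include truth SVs that no caller reported.
Precision/recall/F1 are kept at full precision internally and rounded
half-up to 2 decimals only at reporting boundaries. ROC AUC uses the
rank-statistic form (ties = ½), cross-checked against scikit-learn. The
decile report bins probabilities into [0,0.1), …, [0.9,1.0] (top bin
closed).

## Synthetic data

The simulator emulates the *structure* of multi-caller call sets, not
sequences or reads:

* truth sets: per type, positions uniform over configurable contigs
  (default two 10 Mb contigs, 2000 SVs per type), DEL non-overlapping by
  rejection sampling, lengths log-uniform on [50, 10 000] bp; default
  sequencing stats 35× coverage, 250 bp reads (typical high-quality
  training data).
* a `hard_fraction` of truth SVs (0.21 DEL / 0.52 INS) is invisible to
  every caller — matching the observation that roughly this share of known
  SVs is missed by all short-read callers — which drives realistic union
  recall and FN accounting.
* per-caller profiles (sensitivity per type, breakpoint jitter SD,
  FP rate per Mb) are ordered like the published heterogeneity of the
  seven callers: e.g. a manta-like balanced high-F1 profile (DEL
  sensitivity 0.65, small jitter, low FP rate) versus a tardis-like
  high-precision/low-recall one and a breakdancer-like noisy one. Jitter
  is rounded zero-mean Gaussian truncated at 6 SD.
* metrics are Gaussian with TP- and FP-conditional means: the first two
  metrics of each caller are separated by 2 SD, the rest by 0.3 SD;
  coverage-kind metrics are drawn as depth ratios and multiplied by mean
  coverage (so normalization inverts generation exactly); the
  PRECISE flag is Bernoulli (0.85 TP / 0.35 FP). Each variant carries a
  latent quality factor inducing correlation ρ = 0.7 of metric deviations
  across callers at the same site — variant quality is a property of the
  locus — without changing any marginal distribution. Each metric is
  independently omitted with probability 0.15, as real VCFs omit fields.
* false positives: half of each caller's FPs fall on a shared pool of
  recurrent artifact loci (4/Mb DEL, 3/Mb INS) that multiple callers
  co-report, the rest are placed independently; FP lengths follow the
  truth length distribution so the classifier cannot solve the task from
  length alone. A configurable fraction of detected insertions is emitted
  with the DUP type token to exercise DUP folding.

What passing tests on this generator do **not** show: performance on real
genomes (no sequence context, no alignment artifacts correlated with
genomic features, no caller-specific systematic biases beyond the modeled
ones, no non-autosomal contigs). The generator's role is to make the
pipeline's contracts and qualitative behavior (metrics beat presence
flags; probability works as a ranking score) testable end-to-end.

## Problem sizes in tests and acceptance

Training uses one simulated sample (2000 truth SVs per type, ≈ 2000–2600
consensus calls per type). Evaluation pools 40 independently simulated
samples (≈ 75 000 DEL and 44 000 INS consensus calls): decile TP
proportions are binomial estimates, and the middle deciles hold only a few
per mille of calls each, so a pooled cohort of this size is needed before
adjacent-decile differences (≈ 0.04–0.1) exceed sampling noise. The unit
suite uses 100–2000-row problems throughout.

## Known limitations

* Breakend (BND) notation, inversions and translocations are out of scope;
  non-autosomal contigs are filtered.
* The greedy matcher approximates (and is only verified to equal on small
  fixtures) maximum bipartite matching; pathological tie structures could
  differ from other benchmarking tools.
* Probabilities are uncalibrated model outputs; decile monotonicity holds
  but the identity E[TP | p] = p is only approximate.
* The default dialect registry's field lists are plausible per-caller
  configurations, not transcriptions of each tool's documentation; real
  deployments should adapt the registry to the exact caller versions in
  use.
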