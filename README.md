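# svmeta

Meta-calling for structural variants (SVs) from short-read whole-genome
sequencing. Individual SV callers (BreakDancer, Delly, LUMPY, Manta,
Pindel, TARDIS, INSurVeyor) disagree wildly on deletions and insertions
≥ 50 bp: some are precise but insensitive, others the reverse, and classic
consensus tools reduce each caller's evidence to a present/absent vote.
`svmeta` instead merges the callers' VCF outputs into a breakpoint-proximity
consensus and scores every consensus call with a gradient-boosted tree
classifier built on the callers' own *quality metrics* — supporting
read-pair and split-read counts, assigned qualities, microhomology lengths,
genotype qualities, local depths — harmonized across callers by normalizing
coverage-type metrics with the sample's mean coverage and edit-distance
metrics with the read length. The result is a consensus VCF whose QUAL
column is the probability that each call is a true positive, usable as a
continuous ranking/filter score.

It is aimed at people building or evaluating SV call sets from short reads:
the library exposes each stage (dialect-aware VCF parsing, filtering,
merging, feature extraction, training, scoring, benchmarking), and a small
CLI ties them together.

## Method

1. **Filter**: per-caller VCFs are reduced to autosomal DEL and INS
   (duplications folded into INS) calls of length ≥ 50 bp.
2. **Merge**: calls of identical type are clustered when *both* breakpoints
   lie within `max_dist` (default 1000 bp); clusters are connected
   components of this relation, coordinates are member-wise lower medians.
   Single-caller calls are kept — the classifier, not a vote count, decides
   their fate.
3. **Features**: one row per consensus call. Per caller and metric
   *m*: `m / mean_coverage` for coverage-type metrics, `m / read_length`
   for edit-distance metrics, `m` otherwise; NaN whenever a caller did not
   support the call (missing ≠ 0). Plus the SV length. Defaults: 35
   features for DEL, 36 for INS.
4. **Classify**: per SV type, an XGBoost classifier (exact greedy splits,
   `binary:logistic`) trained on truth-labeled consensus calls;
   hyperparameters by stratified cross-validated AUC over a grid,
   zero-gain features iteratively pruned. A *basic model* (SV length +
   per-caller presence flags only) is trained alongside to quantify what
   the quality metrics add.
5. **Benchmark**: calls match truth records of the same type when both
   breakpoint distances are ≤ 500 bp and size similarity
   min(len)/max(len) ≥ 0.7 (sequence comparison off); precision = TP/(TP+FP),
   recall = TP/(TP+FN), F1 = 2·TP/(2·TP+FP+FN), with truth SVs missed by
   every caller counted among the FN.

A seeded simulator (`svmeta.sim`) generates truth sets and per-caller VCFs
with realistic heterogeneity (per-caller sensitivity and false-positive
rates, breakpoint jitter, shared artifact loci, TP/FP-conditional metric
distributions with a per-variant latent quality factor), so the entire
train → score → benchmark loop runs without any external data.

## Worked example

```sh
svmeta simulate --seed 7 --n-truth 500 --out sim
svmeta train   --vcf manta=sim/manta.vcf --vcf delly=sim/delly.vcf \
               --vcf lumpy=sim/lumpy.vcf --vcf pindel=sim/pindel.vcf \
               --vcf tardis=sim/tardis.vcf --vcf breakdancer=sim/breakdancer.vcf \
               --vcf insurveyor=sim/insurveyor.vcf \
               --truth sim/truth.vcf --mean-coverage 35 --read-length 250 \
               --seed 7 --out models
```

prints, per SV type, the consensus size, the feature count after
zero-importance pruning, and the cross-validated AUC of the full model (FM)
versus the basic model (BM):

```json
{
 "DEL": {"n_consensus": 776, "final_features": 33,
         "fm_cv_auc": 0.9866, "bm_cv_auc": 0.9638},
 "INS": {"n_consensus": 499, "final_features": 29,
         "fm_cv_auc": 0.9726, "bm_cv_auc": 0.8950}
}
```

— the quality metrics add discrimination beyond presence + length for both
types, most strongly for insertions. Scoring and benchmarking:

```sh
svmeta predict --vcf ... --mean-coverage 35 --read-length 250 \
               --model models --out consensus.vcf
svmeta bench --calls consensus.vcf --truth sim/truth.vcf --out bench.json
```

The consensus VCF carries the TP probability as QUAL and lists every
contributing caller-local record ID:

```text
1  29020  cons_DEL_00000  N  <DEL>  0.0612  PASS  SVTYPE=DEL;END=30357;SVLEN=1338;SUPP=1;CALLERS=tardis;MEMBER_IDS=tardis:tardis_000203
```

`bench` reports the unfiltered union's counts and metrics (here DEL:
tp=392, fp=384, fn=108 → precision 0.51, recall 0.78, F1 0.61) together
with the ranking AUC of the QUAL scores; thresholding QUAL trades
precision against recall continuously.

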