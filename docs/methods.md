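# Methods

## Model and procedure

`lncnet` analyses a two-group (case vs control) expression study on the
log2 scale.  The input contract is a probes × samples matrix of log2
intensities — fold changes are reconstructed as `2**(mean_case −
mean_control)`, so linearly scaled input would be mis-interpreted; the
loaders validate finiteness but cannot detect the scale, which is why
the contract is stated here and in the README.  Probe identity maps to
gene symbols through the annotation table; multiple probes per symbol
are allowed, and gene-level sets use the union of their probes'
evidence, with the minimum-p probe standing for the gene where a single
value is needed.

The stage sequence and the statistical choices:

* **Differential calling.**  Pooled-variance Student's *t* (df =
  n₁+n₂−2), read literally from the field's standard "Student's t-test";
  Welch is available behind `welch: true`.  The FDR procedure is
  Benjamini–Hochberg step-up (the standard microarray choice when a
  study reports only "FDR"), applied separately within each biotype because
  the lncRNA and mRNA panels are reported as parallel experiments; a
  `bh_global` flag collapses the strata.  Selection is |FC| ≥
  `fc_threshold` (inclusive) AND q < `fdr_threshold` (exclusive).
  Selected probes are ranked by ascending p with ties broken by larger
  |FC| then probe id, so top-200 lists are byte-stable.  Probes with
  zero pooled variance are flagged `degenerate` and given sentinel
  statistics (t = 0, p = 1 when means agree; ±inf, p = 0 when they do
  not) rather than epsilon-smoothed, so tests can assert exact
  behaviour.
* **ΔΔCt.**  Multiple reference genes are combined by the arithmetic
  mean of their Ct values — equivalent to the geometric mean of their
  expression — since assays routinely name two reference genes without
  a combination rule.  The control group is the calibrator.
* **Co-expression.**  Pearson r over all 12 samples (both groups
  pooled), p from the t-transform on n−2 df.  The edge gate defaults to
  the raw p ≤ 0.05 with |r| ≥ 0.8 (both inclusive); `corr_adjust: bh`
  instead gates on the BH q computed within each lncRNA's edge family.
  Both modes exist because the two wordings (raw p vs FDR) both occur in
  this literature for the same filter; the ambiguity is exposed as
  configuration rather than silently resolved.  Constant probes are
  excluded with a logged count.
* **Cluster order.**  Average-linkage agglomerative clustering under
  1 − r distance (scipy linkage); the leaf order is made deterministic
  by placing, at every merge, the subtree containing the smallest
  original index first.  Constant profiles get the maximal distance 2.0.
  Rendering is out of scope; the ordered ids and the linkage trace are
  the output.
* **Enrichment.**  The hypergeometric upper tail is computed by exact
  integer summation (`math.comb`), so small-universe values agree with
  enumeration to machine precision and large-universe values carry no
  cancellation error.  The enriched flag uses raw p < 0.05, as
  guilt-by-association pipelines in this area do; BH q over the
  collection is reported alongside, never silently substituted.  The
  universe defaults to the annotated mRNA genes measured on the array —
  enrichment against the measured background, not the genome.  Term-size
  bounds (min 3, max 2000) are applied when the pipeline loads term
  collections, preventing single-gene terms from dominating; the bare
  GMT loader is permissive so that set algebra remains testable.
* **Function prediction.**  All (DEL, term, p < 0.05) pairs are pooled
  globally (not per direction), sorted by ascending p with deterministic
  ties (lncRNA id, then term id), truncated to `top_pairs` = 200; term
  frequencies are counted over the kept pairs and the `top_terms` = 30
  most frequent reported, ties broken by smaller minimum p then term id.
* **Cis windows.**  Candidacy is measured from the lncRNA's interval
  ends (not the TSS): an mRNA on the same chromosome is a candidate when
  the number of bases strictly between the two intervals (gap; −1
  denotes overlap) is at most the window, boundary inclusive — a gap of
  exactly 300 000 bp qualifies, 300 001 does not, and overlapping loci
  always qualify.  Strand is ignored.  The correlation gate is the raw
  Pearson p ≤ 0.05, independent of the co-expression adjust mode, and
  the sign of r labels the pair positively or negatively cis-regulated.
* **Trans associations.**  Each DEL's passing co-expressed mRNA genes —
  restricted by the pipeline to differential mRNAs, relaxable via
  `trans_restrict_to_de: false` or by passing `de_genes=None` to the
  library call — are tested against every TF target set with the same
  enrichment engine (one implementation, verified by a composition
  test).  Associations at p ≤ 0.05 feed the tri-network: targets are the
  intersection of the TF's target set with the DEL's top-30 co-expressed
  differential mRNAs, and edges are tf_lncrna, lncrna_target and
  tf_target with duplicates collapsed.  Export is SIF plus node/edge
  attribute TSVs in lexicographic order, so re-exports are
  byte-identical.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
6 case vs 6 control samples; per-probe baseline means
Normal(8, 2²) with per-sample noise Normal(0, 0.5²) on the log2 scale
(a lognormal intensity model — the package's own assumption, since
array platforms are not distributionally specified); additive
differential effects of ±1.5 log2 units (|FC| ≈ 2.83, safely beyond the
1.5 cutoff) added to the case samples and split evenly up/down among a
`de_fraction` of free probes; correlation modules built from one latent
factor per hub, with hub = z and member = ρ·z + √(1−ρ²)·ε so hub–member
correlation is exactly ρ in expectation and member–member is ρ²; cis
pairs realized with exactly the configured genomic gaps on private
chromosomes while background loci sit 700 kb apart (beyond twice the
300-kb window, so no unplanted pair can ever be a candidate); and
TF/term gene sets drawing a configured fraction of their members from a
module's mRNAs.  With `plant_de_on_structures` (default) the hubs,
members and cis probes are themselves differential — with the sign of
the planted correlation — which is what makes them discoverable by the
full pipeline; calibration tests turn the flag off to measure pure
correlations.

`de_fraction` defaults to 0.2: the pipeline is designed for studies with
broad transcriptome dysregulation (the disease-vs-normal profiling
setting reports hundreds of differential probes per biotype beyond its
top-200 lists), and BH power depends on that fraction — at 0.2 the
caller reaches ~0.95 sensitivity at ~0.03 realized FDP under the default
effect and noise, while sparse-signal regimes (≤ 5% differential) sit
nearer 0.80 sensitivity.  Users studying sparse signals should set the
fraction accordingly and expect lower recall at the same FDR.

What the generator does **not** model: probe-level artifacts, dye bias,
batch effects, missing values, heavy-tailed noise, sample outliers, or
correlation between differential status and baseline intensity.
Passing recovery tests therefore demonstrate correctness of the
statistics and the plumbing under the stated model — not robustness of
the biology on real arrays.

## Numerical choices

Thresholds follow the stated inclusivity exactly (|FC| ≥, q <, |r| ≥,
p ≤; window gap ≤).  All orderings that feed truncated lists have total,
deterministic tie-breaks.  BH delegates to statsmodels; t and
correlation p-values to scipy; the hypergeometric tail is exact integer
arithmetic.  All randomness flows from numpy Generators seeded from the
config (`default_rng([seed, stream])`), with no global state: identical
configs give byte-identical fixture bundles, and the pipeline writes
with fixed float formatting so repeated runs are byte-identical.
Degenerate inputs (constant probes, empty DEL sets, empty networks)
produce empty outputs with logged warnings rather than errors, so a
threshold sweep degrades gracefully.

## Acceptance problem sizes

`scripts/acceptance.py` measures: null false-positive fraction and
planted-effect sensitivity/FDP over 50 fixtures of 2000 probes each;
p-value uniformity (KS distance) on a 10 000-probe null fixture;
hub-member and null edge pass rates over 100 replicates of a ρ = 0.9,
30-member module (expected hub pass rate ≈ 0.87 by the Fisher-z tail
P(r̂ ≥ 0.8 | ρ = 0.9, n = 12); observed ≈ 0.93 including the p-gate's
negligible effect); the 300-kb boundary verdicts; planted-TF top-rank
rate over 100 replicates of a 40-gene module against 20 background TFs
in a 1000-gene universe; prediction-pair survival over 30 replicates of
two module-wired terms against 50 background terms; and a repeated
default-fixture pipeline run compared byte for byte.  These replicate
counts are the package's standard quick-verification sizes; the test
suite runs the same checks at up to 200 replicates.

## Known limitations

No moderated (shrinkage) variance estimation — at n = 6 + 6 limma-style
moderation would be more powerful; the package implements the plain
Student's test its design calls for.  No paired designs, batch
covariates, or normalization (input is assumed normalized).  GO graph
topology is ignored (terms are flat sets).  The cis search is
window-based only; enhancer–promoter contact data are out of scope.
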