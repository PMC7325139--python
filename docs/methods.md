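# Methods

This note documents the models behind `coldsrna`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter when reproducing results.

## Study design assumed throughout

Two conditions (control at 22 °C, cold at 4 °C) × three time points
(3 h, 6 h, 2 d) × three biological replicates, with sRNA clusters and
mRNA/lncRNA transcripts quantified as feature-level counts from the same
RNA pools. All differential comparisons are cold vs control *within* a
time point; cross-time "non-redundant" tallies deduplicate by feature or
pair id.

## Count model and differential expression

Counts are modeled as negative binomial with Var = μ + αμ². For feature
i in sample j, μ_ij = s_j · q_i · 2^(β_i · x_j), where s_j is the
sample's library-size factor, q_i the feature's base mean, β_i the log2
fold change of the cold effect, and x_j the cold indicator at the tested
time point.

- **Size factors**: median-of-ratios (each sample's median ratio to the
  per-feature geometric mean over features nonzero everywhere), rescaled
  to geometric mean 1. The median is taken on the linear ratio scale.
  With no all-nonzero feature the estimator falls back to total-count
  scaling and warns — adequate for the sparse corner case, biased if
  composition differs strongly between samples.
- **Dispersion**: per-feature method-of-moments α̂ = max(0, (s² − μ̄)/μ̄²)
  with the variance pooled across the two condition groups, then shrunk
  50/50 toward a fitted mean-dispersion trend α(μ) = a + b/μ (least
  squares on features with μ̄ ≥ 1, coefficients clipped at 0). The
  50/50 weight is a deliberate middle ground: pure per-feature estimates
  are far too noisy at n = 3 vs 3, pure trend ignores genuine
  feature-level differences. Estimated dispersions are floored at 1e−8.
- **Testing**: a 2-parameter NB GLM (intercept + cold effect, log link,
  offset log s_j) fitted by iteratively reweighted least squares,
  vectorized across features; convergence at max|Δβ| < 1e−8, at most 100
  iterations, coefficients clamped to |β| ≤ 15 on the natural-log scale
  (features pinned at the clamp or non-converged get p = NA and status
  unchanged, logged). Wald z = β̂/SE(β̂), two-sided normal p, BH step-up
  within the analysis batch. BH is applied per feature-class × time-point
  batch in the pipeline (per-batch choice recorded in output metadata);
  whether correction should instead be global is genuinely open, and the
  batch argument makes either choice available.
- **Status call**: `up`/`down` need |log2FC| ≥ 1 (fold change ≥ 2 or
  ≤ −2) *and* BH-adjusted p ≤ 0.05 at base mean ≥ 5 normalized counts;
  base mean < 5 is `undetected` (the conventional very-low-expression
  bin); everything else `unchanged`. Fold changes are unshrunk; when one
  group is all zero the reported log2FC uses a +0.5 pseudo-mean floor.

Calibration measured by the test suite on the generator's own model
(5000 null features, 3 vs 3, mixed dispersions): raw-p type-I error
0.048 at nominal 0.05; planted |log2FC| = 2 at base mean 100 recovered
for 89% of features with empirical FDR 0.057.

## miRNA target scoring

The expectation score is a penalty sum over the ungapped antiparallel
duplex: Watson–Crick pair 0, G:U wobble 0.5, mismatch 1.0, penalties
doubled at miRNA positions 2–13 from the 5′ end (the seed). Every
transcript window of miRNA length is scored; windows at or below the
cutoff (default 2.5, the stringent setting) are reported after reducing
overlapping windows of the same pair to the best-scoring one, ties to
the leftmost. T and U are interchangeable on input. Sites with miRNA
positions 9–11 all paired are annotated `cleavage`, otherwise
`translation`.

Gapped/bulged duplexes are deliberately excluded from the core scorer:
the ungapped scorer is exactly checkable against a brute-force
all-windows oracle, and in the stringent-cutoff regime (≤ 2.5) a bulge
penalty of 2 per gap leaves almost no additional hits. Target-site
accessibility (UPE, the energy to open the site, kcal/mol-like) is
consumed from a user-supplied table and used purely as a filter
(default max 25); computing it would require partition-function folding,
which is out of scope.

## Pair classification and the classical nat-siRNA regulon

miRNA:mRNA pairs (only DE miRNAs enter) receive exactly one category per
time point; "inverse" covers both ↑↓ and ↓↑ since the defining property
is anticorrelation. NAT pairs with a DE siRNA cluster get the unordered
transcript-status pattern; a both-down pair joins the down-involving bin.

The classical regulon — a stimulus-induced transcript driving siRNA
production that represses its antisense partner — has two detection
modes because published example sets routinely include partners whose
repression is clear in sign but below the 2-fold bar: `relaxed`
(default) requires the siRNA cluster and the driver significantly up
(FC ≥ 2, BH p ≤ 0.05) and merely a negative partner fold change;
`strict` additionally requires partner FC ≤ −2 with BH p ≤ 0.05. Both
are exposed; neither is claimed to be the single correct reading.

The package ships a curated example table of cis-NAT pair fold changes
(one 6 h pair, nine 2 d pairs, all siRNA clusters significantly up).
Significance in that table is encoded at the decision boundary:
transcripts reported as passing |FC| ≥ 2 with BH p ≤ 0.05 carry
padj = 0.05, others 1.0, and siRNA clusters carry (FC, padj) =
(2.0, 0.05) — the minimal values satisfying "significantly up".

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) per term, BH across
reported terms, terms without overlap omitted. The default background
is the expression-aware detected set (base mean ≥ 5), which avoids
detection bias; offline reproduction of a web tool's internal background
is not attempted.

## Regulatory network

Edges carry one of four evidence sources. Duplicate (regulator, target)
rows collapse to the highest-confidence TF source
(validated > CE > FunTFBS); miRNA edges never collide with TF edges
because regulator identities are disjoint. Network versions are nested
on the validated base — validated_only ⊂ +CE ⊂ +FunTFBS ⊂ combined
(adding miRNA edges) — so each version's predictive power isolates the
contribution of one evidence tier.

**Module detection** is Louvain-style greedy modularity maximization
implemented in-package (local moves to the best neighboring community,
then aggregation, repeated until Q stops improving), on the undirected
projection, with Q = Σ_c (e_c/m − (d_c/2m)²) evaluated via networkx.
Eight seeded node-order restarts are taken and the best partition kept;
move gains use a 1e−12 improvement epsilon and ties keep the current
community, making results deterministic given the seed. On all tested
graphs of ≤ 8 nodes the result matches exhaustive best-partition search
to 1e−9.

**Predictive power**: rows are (target gene, sample) pairs; features are
the time-point one-hot, per-regulator-family sums of the family members'
expression restricted to the target's own regulators, and the target's
pooled binding-site count (pooling across sources is a choice; per-source
counts were the alternative). The learner is gradient-boosted regression
trees (200 rounds, learning rate 0.1, depth 3 — depth kept small because
the planted signal is additive and deeper trees only add variance).
Cross-validation is partitioned by target gene (5 folds, seeded target
shuffle): the quantity reported is how well regulation *transfers to
unseen genes*, which is the stricter and more informative reading of
edge validation. Mean out-of-fold Pearson r is the average of per-target
correlations over each target's held-out samples.

**Cold subnetwork**: DE miRNAs, their targets DE at ≥ 1 time point, TF
intermediaries among those targets, and such TFs' own DE downstream
targets, with all induced edges.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the analysis assumes:
NB counts with log-normal base means, per-feature dispersions log-uniform
in [0.01, 0.5] (the typical bulk RNA-seq overdispersion range), log-normal
(σ = 0.15) library-size factors, planted time-point-specific fold
changes (default log2FC ±2 on 15% of features), planted miRNA→target
anticorrelation (target mean scaled by 2^(−coupling·β), coupling 0.8),
classical regulons planted on half the cis-NAT pairs (driver up, partner
down, siRNA cluster up at one time point), and 20–24 nt mature miRNAs
whose (near-)reverse complements are embedded in target transcripts with
0–2 non-seed mismatches. Default library size is 1e6 assigned
feature-level reads; real library depth beyond a lower bound is not
published, so the default is a convenient RPM-scale choice, not a
calibration. Features carrying planted effects have base means floored
at 100 normalized counts: an effect planted below the detection bin
would be invisible by construction and would test nothing.

Regulator-driven expression is log-scale: regulators get a mild
per-time-point level (σ = 0.3) plus dominant replicate scatter (σ = 1.0)
— deliberately, so that no target is predictable from the time point
alone and a permutation null lands near zero; targets are the
family-weighted sum of their regulators plus Gaussian noise. Family
weights (|w| ∈ [0.5, 1.5], random sign) are shared per regulator family
rather than per target: with per-target weights no model could
generalize across held-out genes and cross-validated edge validation
would be meaningless. Edge tables assign each target one TF round-robin,
so with n_tf ≥ n_targets regulators are private to their targets and
held-out genes are genuinely unseen. The optional `ceiling_r` argument
sets per-target noise SD so the analytic Pearson ceiling
√(Var_sig/(Var_sig + σ²)) is exact — used to verify that the validation
pipeline recovers a known answer (0.8 recovered as 0.78 on average over
three seeds).

Not emulated: read-level artifacts (adapters, mapping ambiguity,
multi-mapping), sequence-driven sRNA biogenesis, genuine GO structure,
signed activation/repression, and the scale of real regulatory maps.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated model, not performance on real libraries.

A null configuration (`de_fraction = 0`) plants nothing, so type-I error
and exchangeability can be measured; the planted-regulon completeness
property is asserted under a strong-signal configuration (log2FC 3,
dispersion 0.05) where the DE engine has essentially full power —
completeness there is a plumbing property of the classifier chain, while
power under realistic noise is measured separately.

## Problem sizes used by the test and acceptance runs

Null calibration uses 5000 features at 3 vs 3; power runs 2000 features
with 300 planted; predictive-power studies use 100 target genes × 18
samples over three seeds; module-detection oracles cover all partitions
of graphs up to 8 nodes; the end-to-end determinism check runs the
default pipeline (about 220 catalog features) twice. These sizes give
stable estimates while keeping a full test run in the low minutes.

## Known limitations

- The Wald test is anticonservative for very low counts; the detection
  floor masks most of this but p-values for features near base mean 5
  should not be over-interpreted.
- The dispersion trend is a two-parameter curve without outlier
  rejection; heavy-tailed dispersion distributions will pull it.
- The target scorer reproduces a published scoring scheme's stringent
  regime, not any web service's exact hit list (seeding heuristics and
  gapped alignments differ).
- Predictive power depends on the regressor's inductive bias; values are
  comparable across network versions within a run, not across learners.
- ΔΔCt assumes amplification efficiency 2 for every assay; no
  efficiency-corrected mode is provided.
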