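# Methods

This note documents the models, estimators and design choices behind
`mirpanel`, what the synthetic-cohort generator does and does not emulate,
and the numerical conventions that make runs reproducible.

## Synthetic cohort model

The generator produces a three-phase case/control study (discovery,
validation 1, validation 2) drawn from configurable sample sources. The true
serum concentration of miRNA *m* in sample *i* is log-normal:

    log2 c_im = baseline_m + batch(source_i, m) + effect(m, i)
                + input_i + e_im

* `baseline_m` — per-assay abundance, uniform on log10 copies/ml
  (default 10^4.5–10^7.5), spanning the interpolable range of the standard
  curves.
* `batch(source, m)` — a per-source, per-miRNA shift, N(0, batch_sd²),
  default 0.25 log2 units. Batch shifts are class-balanced within a source,
  emulating pre-analytic site effects rather than confounding.
* `effect(m, i)` — the planted class effect: cancer samples of a
  differential miRNA are shifted by its signed `true_log2fc` (defaults: 30
  markers, magnitudes evenly spaced 0.5–1.5, alternating signs), optionally
  scaled by a per-stage multiplier (default 1.0 for every stage, so stage
  labels are pure annotations).
* `input_i` — a per-sample global serum-content shift, N(0, 0.3²) log2
  units, shared by every miRNA of the sample. Spike-ins are added at lysis
  and therefore cannot correct it; it is exactly the variation endogenous
  reference normalization exists to remove.
* `e_im` — between-subject biological noise, N(0, bio_sd²) with
  bio_sd = 1.0 log2 units; planted reference miRNAs instead use
  ref_bio_sd = 0.15, making them genuinely more stable than null markers
  (otherwise reference recovery would be untestable).

Tumour stages are sampled from the pooled case distribution of the default
cohort layout (7% stage 0, 32% I, 37% II, 8% III, 1% IV, 16% unknown);
controls carry `not_applicable`. Ages are annotations only.

The measurement model pushes concentrations through the assay:
reacted copies = copies/ml x 0.2 ml serum x isolation efficiency
(uniform 0.5–1.0 per sample) x 2/25 RT input fraction; observed
Ct = slope·log10(reacted) + intercept + N(0, ct_sd²) per technical
duplicate (ct_sd = 0.25 cycles), with per-assay slopes uniform in
[−3.6, −3.2] and intercepts in [37, 40]. Reacted copies below one template
are emitted as undetected. The three spike-ins (2x10⁵ / 2x10⁴ / 2x10³
copies) pass through the same curves with the sample's isolation efficiency
but without the serum-volume term. Standard-curve wells are generated at the
six dilution levels with the same Ct noise. The 14-cycle pre-amplification
present in the wet protocol is folded into the curve intercepts: samples and
standards are pre-amplified identically, so the factor cancels by
construction.

Randomness uses two substreams (cohort, assay) spawned from the single
configured seed, so changing assay-noise parameters never perturbs the
cohort draw. All outputs are bitwise reproducible given the seed.

**What the generator does not emulate:** correlation between markers (each
miRNA's biological noise is independent, which makes multi-marker panels
*more* powerful than on real serum data — synthetic validation AUCs near
0.99 should be read as "the pipeline recovers what was planted", not as a
clinical performance claim); primer cross-reactivity between multiplex RT
pools; carrier-RNA effects; sequence-level realism (miRNA ids are opaque
strings); missingness mechanisms other than falling below one template.

## Quantification

Standard curves are ordinary least squares of Ct on log10(input copies);
fits with fewer than two distinct levels or a non-negative slope are
rejected. Quantifying each assay against its own curve is what correcting
for per-assay RT-qPCR efficiency operationally means; no second correction
is applied. Technical duplicates are averaged on the Ct scale (the
instrument's near-Gaussian scale), not the copy scale; duplicates more than
2 cycles apart are logged as discordant but still averaged. Spike-in
recovery is the geometric mean over observed spikes of measured/expected
copies; samples with all spikes undetected are excluded. Cells undetected in
every duplicate are set to the detection floor (the bottom curve level
rescaled like any other cell) and flagged `floored`, keeping the matrix
complete for clustering and regression. Cells are flagged
`interpolated` / `extrapolated_low` / `extrapolated_high` relative to the
curve's dilution range, with a 1e-9 relative tolerance at the boundaries so
values at exactly a dilution level count as interpolated.

## Reference selection and normalization

Stability is computed on log2 copies/ml of all discovery samples (cases and
controls pooled), over candidates detected (non-floored) in at least 90% of
samples. geNORM's M is computed from the candidate covariance matrix
(SD(x_j − x_k) = sqrt(C_jj + C_kk − 2C_jk)), making the 324-candidate
iterative exclusion O(k³) instead of O(k⁴); a brute-force pairwise
implementation verifies equality to 1e-12 in the tests. Exclusion ties
remove the lexicographically larger id. The final pair, which geNORM cannot
separate, receives ranks 1 and 2 ordered by final-round M (keeping ranks a
permutation). Pairwise variations V(n, n+1) are reported.

The NormFinder-style score is a simplified variance-decomposition estimator:
after centering each sample across candidates (removing the sample level),
rho_g = mean over groups of |group-mean deviation| + sqrt(within-group
variance / group size). It omits the original publication's small-sample
variance corrections but preserves the ranking behaviour; with a single
group it reduces to sqrt(w/n).

References are chosen by consensus: rank-sum of geNORM rank and NormFinder
rank, ties lexicographic, top k (default 3). Normalization divides each
sample by the geometric mean of its reference values (equivalently subtracts
the mean reference log2), which removes any per-sample multiplicative
distortion exactly; reference columns are retained.

## Differential screening

Statistics are computed on log2 normalized values: group-mean log2FC,
pooled-variance Student's t-test (Welch available via `equal_var=False`),
Benjamini–Hochberg q-values across all assayed miRNAs, and the Mann–Whitney
AUC (ties count one half). Discovery selection applies strict inequalities
to the *raw* p-value (q-values are reported alongside and `use_q` switches
selection to them), |log2FC|, and the *directional* AUC — the AUC oriented
by the fold-change sign — so markers whose rank separation contradicts their
fold change are dropped. Validation confirms candidates at the relaxed
threshold with a consistent sign; exclusions carry reasons
(`not_significant`, `small_fold_change`, `sign_flip`). Hierarchical
clustering uses Euclidean distance with average linkage on values
standardized per miRNA to zero mean, on both axes.

## Panel optimization

The risk model is logistic regression on log2 normalized expression with a
ridge penalty of lambda = 1e-6 applied to standardized coefficients (never
the intercept), fitted by damped Newton iterations with an Armijo line
search. The penalty guarantees a finite optimum under the near-separation
that strong panels produce; coefficients are mapped back to the log2 scale.
The in-package solver exists because the cross-validation x SFFS loop
performs on the order of a million small fits; scikit-learn's estimator is
the independent cross-check in the test suite, and a 2x2-table fit
reproduces the closed-form log odds ratio to 1e-6. Search-time fits use a
looser cap (50 iterations, gradient 1e-8) than final refits (100, 1e-10);
hitting the cap returns the capped estimate flagged `converged=False`
rather than raising, because near-separable subsets converge slowly in
coefficient norm while their score ordering — all the criterion uses —
stabilizes early. `strict=True` restores a hard convergence error.

SFFS grows panels by the classic add-one/conditionally-remove dynamics with
the training-fold AUC of the refit model as criterion (the workflow reports
train/test AUC per fold and has no inner loop, so the honest test surface is
the held-out fold). Two refinements:

* The best-of-size memory is seeded with a plain greedy forward sweep
  (sharing the criterion cache, so the extra cost is negligible). Classic
  floating search does not guarantee dominance over greedy at every size —
  an accepted removal can divert the forward path — and this makes the
  guarantee structural: SFFS's best-of-size is never worse than greedy's,
  while floating removals can still escape greedy traps (verified on
  constructed jointly-informative pairs hidden behind a decoy).
* Exact duplicate columns of already-selected features are excluded from
  the forward candidate list: a duplicate adds zero information yet could
  otherwise be chosen when every remaining candidate lowers the training
  AUC.

Ties everywhere break toward lexicographic ids.

Cross-validation partitions the training samples (discovery + validation 1)
into two equal groups stratified by source x class: each cell is shuffled
and split evenly, with odd-cell leftovers balanced within the source, so
per-cell and per-source imbalance never exceeds one. Each iteration runs
SFFS on group A, scores the refit panels on group B, and swaps — two records
per size per iteration, 200 iterations by default. Every iteration draws its
partition from an independent substream of the master seed, so the whole CV
is bitwise reproducible.

The optimal size is the smallest s for which the s→s+1 increase in held-out
AUC is not significant (two-sided t-test at alpha = 0.001, requiring a
positive mean increase); per-record AUCs are treated as independent, as the
plateau annotation in this study design conventionally does, ignoring the
dependence between swapped folds. The final panel refits every distinct
candidate of the optimal size on discovery, ranks by the mean of the
discovery and validation-1 AUCs (the stated bivariate criterion needs an
aggregation rule; the mean is the recorded choice), and refits the winner on
both cohorts combined. The score cutoff stored with the model is the
maximum-accuracy threshold on the combined training cohorts.

## Evaluation

AUC confidence intervals use DeLong's structural-components estimator with a
normal approximation clipped to [0, 1]; a seeded two-stratum bootstrap
(2000 resamples) is available as a cross-check and as a fallback when the
DeLong variance degenerates. Proportion CIs are Wilson score intervals, with
the k=0 and k=n endpoints snapped to their exact values 0 and 1. The
maximum-accuracy cutoff scans midpoints between adjacent distinct scores
plus the two trivial extremes (so accuracy never falls below prevalence);
the rule is score >= cutoff => cancer, and accuracy ties resolve toward
higher specificity. Trapezoid ROC area is asserted equal to the Mann–Whitney
statistic on every call.

Stratified reporting: per source, that source's cases against its own
controls; per stage, the stage's cases against *all* cohort controls (the
comparison a screening context implies), plus early (0–II) and late
(III–IV) composites; strata with fewer than two cases are skipped with a
log entry. The held-out report derives its operating point on the held-out
scores (the operating point such studies print); the frozen training cutoff
is reported alongside.

## Pipeline contracts

References and the final model are frozen on the training cohorts and
applied unchanged to validation 2, which no earlier stage may read — a
guard raises `CohortLeakageError` if a validation-2 sample reaches the
panel stage. All artifacts are tab-delimited UTF-8 or sorted-key JSON with
deterministic formatting; the manifest records package version, seed and a
config hash, and the run log carries no timestamps, so identically seeded
runs are bitwise identical.

## Problem sizes used in the checks

The test suite exercises the full workflow at reduced, fixed sizes chosen
as the package's own verification conditions: the planted-panel recovery
check uses 120 assayed miRNAs, 30 differential markers (8 strong at
|log2FC| = 1.2, 22 weak at 0.55–0.80), 150 cases / 150 controls per cohort
analog, panel sizes 2–10 and cross-validation scaled to 50 iterations over
20 master seeds; null-calibration checks permute class labels within
cohorts and verify held-out AUCs centred on one half. The acceptance script
runs the default 324-miRNA, 1042-sample layout with 50 CV iterations.

## Known limitations

* Independent planted markers overstate multi-marker performance relative
  to correlated real serum miRNAs; recovery rates and calibration, not
  absolute AUCs, are the meaningful synthetic results.
* The log-normal abundance model and uniform efficiency/curve parameter
  ranges are assumptions of this package, not measured properties.
* The NormFinder score is the simplified estimator described above.
* Plateau detection inherits the independence approximation across CV
  records; its alpha is a convention, not an error rate with guarantees.
* The t-test and BH corrections assume approximate log-normality; heavy
  tails in real data would favour the rank-based statistics also reported.
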