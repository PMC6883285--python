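# Methods

This note documents the statistical models, estimators, defaults and
numerical choices behind `refstab`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Data model

A `CqDataset` is a samples × genes matrix of quantitation cycles (Cq) with
one experimental-group label per sample, an optional tissue label, a
`setting` tag recording how the Cq values were extracted
(`common_threshold` for a fixed fluorescence threshold with efficiency
assumed 2, `regression_corrected` for window-of-linearity regression Cq),
and optionally the pre-aggregation technical replicates. Cq values must lie
in (0, 45); undetermined wells are missing (NaN), never imputed as the
cycle count, because imputing 40 fabricates variance. Long (tidy) delimited
text is the canonical interchange format; a wide samples × genes layout is
accepted because supplementary tables commonly ship that way. The delimiter
is sniffed among comma/tab/semicolon; the decimal separator is fixed to
`.`.

## Efficiency and Cq from amplification curves

Each well's fluorescence series F₁..F_C (C ≥ 10, typically 40) is
processed as:

1. **Baseline**: subtract the mean fluorescence over early cycles
   (default 3–15, matching common instrument auto-baselining). A curve
   whose maximum never exceeds baseline + 3 early-cycle SDs is flagged
   non-amplifying. An optional refinement re-fits the constant to maximize
   the best window's R²; its search is confined between the curve minimum
   and the early-cycle mean, because the true constant background cannot
   exceed the curve minimum and a wider search would chase spuriously
   linear stretches of the plateau.
2. **Window of linearity** (default 4 points): among contiguous windows
   with strictly positive, strictly increasing corrected fluorescence, all
   below 90% of the curve maximum (plateau guard), choose the one
   maximizing R² of log₁₀F vs cycle; ties break toward earlier cycles so
   output is deterministic.
3. **Efficiency and Cq**: E = 10^slope of the window regression
   (per-cycle fold change; 2 = perfect doubling). The regression Cq is the
   fractional cycle where the fitted line crosses log₁₀(threshold); the
   fixed-threshold Cq interpolates log fluorescence between the bracketing
   cycles (threshold default 0.1). Non-positive slope flags a failed
   reaction; an uncrossed threshold leaves the fixed-threshold Cq missing.
4. **Flags and summaries**: a reaction is `no_plateau` when its last five
   cycles still rise on average by more than 5% of the curve amplitude per
   cycle (the exclusion is standard; the criterion here is ours).
   Efficiency outliers are |E − median E| > 3 MAD per amplicon, and the
   per-amplicon mean efficiency excludes `no_plateau` wells but includes
   outliers by default — the reference policy in the field. `below_r2`
   flags fits under R² = 0.998 without excluding them.

On noiseless exponentials the pipeline recovers E to machine precision and
both Cq variants agree with the closed form. On saturating, noisy curves
the max-R² window drifts toward the smooth plateau knee and E comes out
slightly *below* truth (about 0.05–0.15 on the default synthetic curves).
We kept the simple, documented selector rather than a proprietary window
heuristic: the downward bias mirrors what regression-based estimators show
on real hydrolysis-probe data, and no analysis step downstream consumes
the absolute E by default.

## Replicate QC

Technical duplicates are averaged arithmetically on the Cq scale; the pair
SD uses the n−1 denominator, so for two values it is |Δ|/√2. A pair with a
single surviving replicate keeps its value as the mean but contributes no
SD (fabricating zero variability would bias the screen). The tissue-level
summary per gene is the arithmetic mean of per-sample SDs (a median option
exists); a gene is excluded when that summary exceeds 0.167 cycles — the
largest duplicate SD that still resolves a 2-fold change in ~99.7% of
cases. The keep-override exists because retention despite a flag is a
judgment call, not an algorithm, and it is logged as such.

## Stability statistics

All four methods consume the aggregated Cq matrix with no missing values;
missing cells are a hard error directing the user to impute or drop
upstream, never silently patched.

**BestKeeper.** Per-gene SD of Cq across all samples pooled over groups
(n−1); the BestKeeper index (BKI) is the per-sample geometric mean of Cq
over all evaluated genes; each gene's Pearson r (and two-sided p) against
the BKI. Genes rank ascending by SD and descending by r (ties averaged),
and the method's score is the mean of the two ranks — possibly fractional.
SD > 1 cycle marks a candidate inappropriate for normalization: it loses
its ranks but stays inside the BKI (the cutoff governs eligibility, not
BKI membership). Non-significant correlations still rank by their r value;
an option ranks by |r| should negative correlations appear.

**Comparative ΔCq.** For every ordered pair (g, h), ΔCq_s = Cq[s,g] −
Cq[s,h]; the pair SD (n−1) fills a symmetric zero-diagonal matrix, and a
gene's score is the mean of its off-diagonal row. Per-sample loading
shifts cancel exactly in the difference — the method's core robustness
property, exercised end-to-end against the generator's loading term. With
two genes both receive the tied rank 1.5, forced by symmetry.

**geNorm.** Expression ratios on the log₂ scale: with E = 2 the log₂
ratio of genes (g, h) in sample s is Cq[s,h] − Cq[s,g]; with per-amplicon
efficiencies, relative quantities q[s,g] = E_g^(mean Cq_g − Cq[s,g]) are
used. M_g is the mean over partners of SD_s of the log ratio, so with
E = 2, M equals the ΔCq mean SD element-wise — an identity the test suite
checks across random matrices, cross-validating both modules. Stepwise
exclusion removes the argmax-M gene (ties break toward the larger Cq SD,
then lexicographically, and are logged) until two genes remain; geNorm
cannot order the final pair, which is reported tied at rank 1.5 — the only
convention consistent with half-integer consensus scores. The
normalization factor NF_n is the geometric mean of the n best genes'
relative quantities; V(n/n+1) = SD_s(log₂(NF_n/NF_{n+1})), and the optimal
reference count is the smallest n with V < 0.15 (configurable). The
per-gene reference point (mean Cq) cancels in every ratio and in V; a test
asserts this shift-invariance explicitly. M values above 1.5 are reported
as warnings per the method's guideline.

**NormFinder.** Cq values are treated as log-scale expression (sign
conventions cancel in variances). Within each group g of size n_g, the
samples × genes submatrix is double-centered; with k genes the naive
per-gene residual variance v_i = Σ_j z²_ij/(n_g−1) mixes the other genes'
noise through the centering, and moment-matching
E[v_i] = σ²_i(k−2)/k + S/k² (S = Σσ²) gives the bias-corrected estimator

    σ̂²_i = k/(k−2)·v_i − Σv/((k−1)(k−2)),   floored at 0,

which requires k ≥ 3. The inter-group deviation d_ig is the gene's
group-centered mean minus its group-size-weighted average over groups (so
Σ_g n_g d_ig = 0 per gene). The prior variance of true deviations is
estimated by moments, γ̂² = max(0, Σd²/((G−1)(k−1)) − mean(σ̂²_ig/n_g));
each d is shrunk by γ̂²/(γ̂² + u_ig) with u_ig = σ̂²_ig/n_g (the
empirical-Bayes posterior mean), and the stability value is

    ρ_i = mean over groups of ( |d̃_ig| + sqrt(γ̂²·u_ig/(γ̂² + u_ig)) ),

i.e. shrunken bias plus posterior SD; low ρ = stable. When γ̂² floors at 0
(no detectable inter-group variation) stability degrades to √u_ig, flagged
in the result. The best two-gene combination averages the members'
shrunken deviations and propagates a quarter of the summed posterior
variances, searched exhaustively over pairs; two genes with mirror-image
deviations therefore beat either member alone. With a single group the
method falls back to ρ = bias-corrected residual SD, flagged; its ordering
equals the residual-variance ordering by construction. ρ is exactly
invariant to per-sample (loading) and per-gene (abundance) shifts.

**Consensus.** Each method contributes one score per gene — BestKeeper its
fractional mean-of-ranks, ΔCq and NormFinder their ordinal ranks, geNorm
its final ranking with the pair tied at 1.5 — and the overall score is
their arithmetic mean (all methods equally weighted); ties get average
overall ranks. A geometric-mean variant exists but is not the default
because it dampens extreme scores. Genes flagged inappropriate by
BestKeeper (SD > 1) carry no BestKeeper rank, so the suite driver removes
them from the panel and re-evaluates the survivors — the action a
practitioner would take with an unfit candidate; replicate-QC exclusions
likewise simply never enter any method. `compare_settings` reports
per-gene rank deltas and the Spearman correlation of overall scores
between two settings (e.g. fixed-threshold vs regression-corrected Cq).

## Quantification

ΔCq[s] = Cq_target[s] − mean over references of Cq_ref[s] (the arithmetic
mean of Cq equals the geometric mean of quantities under E = 2);
ΔΔCq subtracts the calibrator group's mean ΔCq; the fold change is
2^–ΔΔCq, so the calibrator's geometric-mean fold change is 1 by
construction. k identical references reduce exactly to one, and joint
target+reference loading shifts cancel exactly. Group testing is one-way
ANOVA on the linear fold changes — the conventional presentation — with a
`log_scale` option that better matches homoscedasticity and is recommended
for small groups; degrees of freedom always reflect the actual input
sizes. Tukey HSD p-values are always computed, with a flag recording
whether the omnibus p cleared α (default 0.05). A fully degenerate input
(zero variance everywhere) reports F = 0, p = 1 rather than an error.

## Synthetic data generator

Cq values are built additively on the Cq scale (multiplicative on the
quantity scale, the scale every statistic consumes):

    Cq[s,g,rep] = baseline_cq_g + group_effect_{g,grp(s)} + loading_s
                  + gene_noise_{s,g} + replicate_noise_{s,g,rep}

with Gaussian terms of configurable SD and a fixed seed giving
bit-identical output. The loading term is exactly the perturbation that
ΔCq, geNorm and NormFinder are invariant to, enabling end-to-end
invariance tests against known truth. The ground-truth record carries each
gene's total planted perturbation — √(noise² + group-effect variance
across samples + replicate_sd²/n_rep) — and the implied stability
ordering. Amplification curves are F_c = baseline + sat(F₀·E^c) + noise
with a smooth hyperbolic ceiling x/(1 + x/plateau) (enough to exercise
plateau flagging without kinetic realism), recording true E and the
analytic threshold crossing.

The default (`paper_like_config`) emulates a published 11-candidate
evaluation in 16 mice: groups non-treated/sham/SNI of 5/6/5, technical
duplicates, gene mean Cq 18.4–31.6 (sno202 most abundant, sno412 least),
a per-gene noise ladder 0.10–0.60 cycles in 0.05 steps ordered by the
study's observed stability, loading SD 0.3, replicate SD 0.08, and a
+0.8-cycle injury (SNI) shift planted on sno292 — the candidate the study
itself flagged as likely treatment-regulated. These values were fixed as
the study conditions before testing and are not tuned.

What the generator does **not** emulate: pipetting failures and dropouts,
inhibitor-driven efficiency variation correlated with RNA integrity,
between-day batch effects, non-Gaussian heavy-tailed noise, and
plate-position effects. Tests passing on this generator therefore show the
estimators implement their definitions and honor their invariances — not
that any particular candidate is stable in real tissue.

## Detection limits of the default scenario

With groups of 5/6/5, a +0.8-cycle shift planted on a gene whose own noise
(0.55) sits near the top of the ladder is not reliably separable from the
noisiest unshifted gene: across 200 seeded replicates NormFinder names the
shifted gene worst in about 60% of runs, and even ranking directly by the
raw inter-group deviation |d| — an upper bound for any deviation-driven
statistic — reaches only ~82%. Detection approaches certainty only when
the shift is planted on a low-noise gene, but then the gene's total
perturbation is mid-ladder and it cannot fall to the bottom of the
consensus. This trade-off is a property of the sample sizes, not of the
implementation; the companion behaviors hold robustly (the shifted gene
lands in the consensus bottom two in ~90% of runs, the consensus recovers
the planted noise ladder with median Spearman ρ ≈ 0.93, and the geNorm
V-rule returns 2 references). The acceptance suite asserts the stricter
95% detection bound anyway and documents the shortfall rather than
adjusting the scenario after the fact.

## Numerical choices and edge cases

* Ranks use average ties throughout (`scipy.stats.rankdata`).
* SDs use the n−1 denominator everywhere, matching spreadsheet
  conventions for these methods.
* "Exact" invariances are asserted to 1e-12 absolute — adding a float
  constant and re-summing legitimately moves results by ~1 ulp.
* geNorm's worst-M tie-break (larger Cq SD, then name) and the final-pair
  ordering (smaller Cq SD first) exist purely for deterministic output.
* Problem sizes in tests (16 × 11 study scale; 200-replicate studies;
  500-replicate recovery checks at n = 20/group) were chosen so the whole
  suite runs in well under a minute while keeping binomial/Monte-Carlo
  margins meaningful.
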