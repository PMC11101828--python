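# Methods

## Model and assumptions

All computation happens at the summary level. For variant *j*, the
two-sample MR model is

    Γⱼ = θ·γⱼ + αⱼ

with γⱼ the true variant–exposure effect, Γⱼ the true variant–outcome
effect, θ the causal effect of exposure on outcome, and αⱼ a direct
(horizontally pleiotropic) effect that is zero for a valid instrument.
Observed effects γ̂ⱼ, Γ̂ⱼ are treated as independent Gaussians around
the truth with known standard errors — the two-sample assumption
(non-overlapping study samples) makes the exposure- and outcome-side
noise independent. Instruments are assumed mutually independent (LD
r² < 0.01 is enforced at selection); no LD-aware covariance is modelled
anywhere.

## Estimators and numerical choices

**Wald ratio / IVW.** The per-variant ratio SE is first-order delta
method, σ_Yj/|γ̂ⱼ|, ignoring exposure-side noise (NOME approximation).
This is deliberate: it is the convention of the standard two-sample MR
toolchain and it reproduces the packaged single-instrument confidence
interval exactly. A second-order correction is not offered in this
version; with the packaged instruments (F ranging from 13 to over 300)
the difference is far below display precision. The multiplicative
random-effects SE multiplies the fixed-effect SE by max(1, √(Q/(J−1)));
the floor at 1 means heterogeneity can only widen intervals. IVW,
median and mode p-values use the normal reference; MR-Egger uses t with
J−2 degrees of freedom — matching the conventions of the methods'
source implementations.

**Cochran's Q** always uses fixed-effect weights wⱼ = 1/se(β̂ⱼ)², the
standard definition, regardless of which IVW model is reported.

**Weighted median.** Cumulative standardized weights pⱼ =
(Sⱼ − wⱼ/2)/S_J over the ratio-sorted instruments, linear interpolation
at p = 0.5; ties are resolved by a stable sort. The SE is a parametric
bootstrap (default 1000 replicates): each β̂ⱼ is redrawn from
N(β̂ⱼ, se(β̂ⱼ)) with weights held fixed, and the SE is the standard
deviation of the recomputed medians. Whether the original analyses used
bootstrap or formula SEs for median/mode is not documented; the
bootstrap is standardized on here because it applies identically to
both estimators. Bootstrap seeds are explicit arguments and part of the
run config.

**Weighted mode.** Weighted Gaussian KDE over the ratios with bandwidth
h = φ·0.9·min(sd, IQR/1.34)·J^(−1/5) (modified Silverman; φ defaults
to 1). The argmax is located on a 1024-point grid spanning the ratios
±3h, then refined with bounded scalar minimization within two grid
steps; a degenerate bandwidth (all ratios identical) returns the common
value. The bootstrap SE recomputes the bandwidth per replicate.

**MR-Egger.** Instruments are oriented so γ̂ⱼ > 0 before the weighted
regression (weights 1/σ_Yj²) — the intercept is only meaningful under a
fixed orientation convention. Coefficients come from the 2×2 normal
equations; the covariance uses a residual variance factor floored at 1,
so an over-tight fit cannot shrink SEs below the homoskedastic model.
Collinear designs (all γ̂ equal after orientation) are rejected.

**MR-PRESSO.** The observed statistic is the outcome-precision-weighted
residual sum of squares about leave-one-out IVW predictions. The null
is simulated parametrically (default 1000 draws, fully vectorized):
γ̂ⱼ* ~ N(γ̂ⱼ, σ_Xj), Γ̂ⱼ* ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σ_Yj). Empirical p-values use
(k+1)/(n_sim+1), so the smallest reportable global p is 1/(n_sim+1) and
the smallest Bonferroni-adjusted per-variant p is J/(n_sim+1) — choose
n_sim accordingly when J is large. The distortion summary
(outlier-corrected IVW and percent change) is reported but has no
external reference value to validate against. A strong outlier biases
the leave-one-out predictions of its neighbours, so collateral flags on
clean variants can occur; the planted-outlier tests therefore assert
detection of the true outlier, not exclusivity.

## Harmonization

Records are joined on rsID (the packaged tables are rsID-keyed);
chromosome/position disagreement warns but never drops. Alignment tries
exact allele match, swapped match (negating the outcome beta and
complementing its frequency), then strand-complement versions of both
for non-palindromic pairs. Palindromic variants default to `drop_all` —
the paper-faithful choice, since the packaged European selection
excluded its two palindromic candidates outright — with
`drop_ambiguous` (MAF within 0.08 of 0.5, i.e. MAF > 0.42, is
unresolvable) and `keep_infer_by_eaf` (orient by frequency-side
agreement) available. Frequency inference near MAF 0.5 is logged as
unreliable. EAF disagreement between cohorts is logged, never a drop
reason: the packaged tables themselves show cohort-to-cohort EAF
spreads of ~0.01 for the same variant.

## Instrument selection

Thresholds default to p < 5×10⁻⁸, single-variant F = (β/se)² > 10, and
greedy LD pruning at r² < 0.01 in ascending-p order (ties broken by
rsID so the result is order-independent). LD is always an input table;
absent and cross-chromosome pairs count as r² = 0. Interactive
phenome-scan screening is replaced by explicit exclusion/protection
lists shipped as `PLEIOTROPY_PRESETS`, because web lookups are not
reproducible. Per-analysis threshold overrides are plain config: the
packaged East Asian caffeine instrument (p = 2.42×10⁻⁴, F = 13.5) was
selected under a relaxed p threshold with the F bound retained, and the
config accommodates exactly that.

Heterogeneity-driven pruning removes, at each step, the non-protected
instrument with the largest Q contribution wⱼ(β̂ⱼ − β̂_IVW)², refits,
and stops when the Q test's p ≥ α (default 0.05), a removal budget is
hit, or fewer than three instruments would remain. Greedy removal is
one reasonable operationalization of "exclude variants responsible for
significant heterogeneity"; because the published robust sets are
shipped as fixtures, disagreement between the greedy trace and the
published choice on borderline data affects nothing downstream. Q
decreases strictly at every step (tested).

## Synthetic data

The generator emits summary statistics directly from the linear model
above — no individual-level genotypes — with independent exposure and
outcome noise (non-overlapping samples by construction). Defaults:
γ ~ N(0, 0.1) truncated to |γ| ≥ 0.05, σ_X = 0.003, σ_Y = 0.01. The
truncation makes every instrument clear F > 10 deterministically; the
scales sit in the range of the packaged per-allele effects (0.01–0.35)
and their SEs. Pleiotropy options: balanced (mean-zero αⱼ, InSIDE
satisfied), directional, and correlated (InSIDE-violating). Directional
and correlated direct effects are applied in the orientation of the
exposure-increasing allele (αⱼ carries sign(γⱼ)): a one-sided pathway
effect is one-sided relative to the allele that raises the exposure,
and without this coupling a symmetric-γ simulation would turn nominally
directional pleiotropy into balanced pleiotropy after Egger's
orientation step. Presets mirror the dimensions of the packaged
analyses (J = 7, 22, 2, 1 with matching SE scales).

What the generator does **not** emulate: LD between instruments,
winner's curse in instrument discovery, sample overlap, binary/logistic
outcome scales, and allele-frequency–dependent effect sizes. Passing
calibration tests on this generator therefore demonstrates estimator
correctness under the stated model, not robustness to those real-data
complications.

Simulation sizes used in the test suite (500 replicates at J = 50 for
IVW coverage/bias; 200 replicates at J = 10 with 500 null draws for
MR-PRESSO detection; 60–300 replicates elsewhere) were chosen so
binomial noise sits well inside the asserted bands.

## Known limitations

- Exposure-side noise is ignored in ratio SEs (NOME); weak-instrument
  settings (F near 10 with many instruments) will undercover slightly.
- No proxy-variant substitution when an instrument is missing from the
  outcome GWAS, and no Steiger directionality filtering.
- MR-PRESSO's distortion test is reported without a validated reference.
- The packaged p-values are stored exactly as printed in the source
  tables; one (rs671) is internally inconsistent with its printed
  beta/SE pair, which `pvalue_consistency_check` will surface — the
  discrepancy is upstream of this package and left intact.
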