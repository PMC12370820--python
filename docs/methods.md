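# Methods

This note documents the models, parameter choices and numerical
behaviour of `iceegnorm`, and what the synthetic-data validation does and
does not demonstrate.

## Signal processing

The unit of work is a 70 s referential multichannel segment in µV.
Segment selection scans candidate onsets on a 1 s grid and returns the
earliest 70 s window whose every point is at least two hours from the
nearest edge of any annotated ictal interval; infeasible recordings raise
an explicit error rather than returning a degraded window.

Channel screening is a documented heuristic stand-in for visual review,
with three configurable rules: peak-to-peak range below 1 µV ("flat"),
robust z-score of the per-channel SD above 5 (median/MAD-based,
"amplitude outlier"), and mains power (±1 Hz around 50 and 60 Hz) more
than 3× the flanking (±2–5 Hz) spectral level ("line noise"). These
defaults are deliberately conservative; they are not a validated artefact
detector and real data will need site-specific review on top.

The filter is a zero-phase Butterworth band-pass, 0.5–80 Hz. The order
defaults to 6: applied forward-backward this attenuates a 95 Hz tone by
more than 20 dB at fs = 512 Hz while keeping the 10 Hz passband gain
within 1%, and its in-band droop at 75 Hz is smaller than a 4th-order
design's. Note that any causal-prototype low-pass with an 80 Hz corner
noticeably attenuates the top of the γ band (≈3 dB two-pass at 75 Hz);
since RBP is a within-contact ratio of log powers this depresses γ
uniformly across contacts and does not disturb cross-subject modelling,
but absolute γ power should not be read off the filtered signal.

Resampling to 200 Hz uses polyphase FIR resampling (anti-alias included).
Welch PSDs use 2 s Hann windows with 1 s overlap and density scaling; the
2 s window fixes the 0.5 Hz grid. Band power is the rectangle-rule sum of
density × bin width over bins whose centre lies in the half-open interval
[low, high), with excluded sub-intervals removed by the same rule — so
the 4 Hz bin belongs to θ, not δ, and no edge is double-counted. On a
flat unit density this yields exactly 3 µV² for δ and 37.5 µV² for γ
(47.5 Hz span minus two 5 Hz exclusions).

RBP divides the five log10 band powers by their sum. This is only a
convex weighting when all five logs share one sign; for µV-scale clinical
signals band powers are well above 1 µV² and the logs are positive, in
which regime larger band power means a larger RBP component. Mixed-sign
logs raise an error with guidance to rescale units rather than silently
producing non-convex weights. Whether "average band power" is divided by
bandwidth before the log is immaterial to any fixed band's comparisons
across contacts once L1 normalisation is applied uniformly; the
integrated (non-divided) convention is used and logged.

## Localisation and the normative table

Contacts are assigned to the region owning the nearest grey-matter voxel
centre (Euclidean, mm), excluded beyond 5 mm. Ties break to the lowest
region id, then lowest voxel index — determinism matters more than the
(measure-zero) tie itself. Voxel centres, not surfaces, define distance.
The module assumes caller-consistent coordinates (template or native) and
performs no registration.

Within a subject, contacts in the same region are averaged per band
(means of unit-sum vectors remain unit-sum). Pallidum, thalamus and
accumbens are excluded bilaterally (82 → 76 regions on the standard-size
atlas). Mirroring collapses homologous left/right regions (76 → 38);
a bilaterally implanted subject contributes one row per mirrored region,
combined by the per-band arithmetic mean by default. The mean is chosen
for symmetry and consistency with contact averaging; left- or
right-priority selection is available and the choice is recorded in the
table header. Re-mirroring a mirrored table is an error, not a no-op.

## The mixed model

Per band, RBP rows follow

    y_i = x_i' β + u_h(i) + ε_i,   u_h ~ N(0, σ²_u),  ε_i ~ N(0, σ²_e)

with hospital h as the grouping factor and fixed effects drawn from
{age, sex} (age in raw years, uncentred; sex coded 0 = female, 1 = male).
An age×sex interaction is implemented but excluded from the default
candidate set. Assumptions worth stating: linear age trends (no quadratic
terms), homoscedastic residuals shared across hospitals, and hospital
effects exchangeable with a common variance.

Estimation profiles the (RE)ML criterion down to λ = σ²_u/σ²_e. For fixed
λ the marginal covariance is block-diagonal and the Woodbury identity
gives closed-form GLS coefficients, the profiled σ̂²_e and the
log-determinants from per-group sufficient statistics, so one likelihood
evaluation costs O(H·p²). λ is minimised by a coarse log-spaced grid
(λ = 0 and 10⁻⁸…10⁶) followed by bounded Brent refinement to 10⁻⁸ on the
log10 scale, with the λ = 0 boundary always compared explicitly. REML
supplies the reported coefficients and variance components; ML refits
supply AIC, BIC (k = p + 2 parameters) and likelihood-ratio tests.
Best linear unbiased predictions of the hospital offsets are
û_h = λ·Σ r_h / (1 + λ n_h).

A fit is flagged singular when λ̂ < 10⁻⁴ or only one hospital is present.
Under a true σ²_u = 0 the boundary estimate λ̂ = 0 occurs with asymptotic
probability 1/2 (the boundary-MLE half-mass result), so roughly half of
null-variance replicates are flagged — users should treat the flag as
"variance indistinguishable from zero here", not as a fault.

ICC = σ²_u/(σ²_u + σ²_e). Marginal R² is var(x'β̂)/(var(x'β̂) + σ²_u +
σ²_e) — the denominator includes the residual variance, so values are not
additive across models with different fixed effects.

Profile confidence intervals profile the ML deviance over the remaining
coefficients and both variance components (an offset refit without the
profiled column), cutting at the χ²₁ quantile by Brent root-finding
within ±10 Wald SEs; if the profile fails to bracket (flat likelihood),
the Wald interval is substituted with a logged notice. In simulations at
study scale (15 hospitals, ~500 subjects) coverage of the 95% interval
runs at ≈ 93–95% — the mild deficit is the usual finite-cluster effect of
plug-in variance components and affects Wald intervals equally.

Model selection fits all four candidates, and declares the metrics in
agreement when the AIC-best and BIC-best model coincide with the unique
largest model whose every term has a CI excluding zero and whose
single-term LRTs reject at α = 0.05. When metrics split, the simplest
contending model is retained and the decision trace records the
tie-break. Selection CIs default to profiled; the per-ROI regional maps
default to Wald intervals (one profile per ROI × band is affordable but
unnecessary — at regional sample sizes the two agree to a few percent),
configurable either way.

Regional maps fit the age model per mirrored ROI, retain singular fits
(flagged), mark ROIs under a configurable minimum (default 10 rows) as
unfitted with a reason, and order output by sample size.

## Deviation scoring

An out-of-sample subject has no hospital offset estimate, so prediction
is population-level (offset at its prior mean, zero) and the score is the
residual divided by the model's residual SD — "deviation from the
regional regression line". Optionally the denominator inflates to
√(σ²_u + σ²_e), acknowledging the unknown hospital offset. Under the
generating model with small hospital variance, held-out scores are close
to standard normal; with large hospital variance the residual-only score
over-disperses (SD > 1), which is documented and tested directionally.
Singular-fit ROIs are scored with the raw residual only; ROIs absent from
the map are marked unscorable. Scores carry no claim about seizure-onset
localisation — they quantify distance from a normative trend, nothing
more.

## Synthetic data: what it emulates, and what it does not

`simulate_cohort` draws RBP tables from exactly the random-intercept
model above, independently per band (bands are modelled separately
downstream, so simulated per-band values are not constrained to sum
to 1). Defaults encode the study conditions: 15 hospitals × 34 subjects
(~500), ages uniform on 5–65, equal sex split, per-band intercepts
(0.35, 0.22, 0.18, 0.15, 0.10) and age slopes (−6.1, −0.8, +4.1, +2.9,
−0.2) × 10⁻⁴ per year, σ_e = 0.05 and σ_u = 0.02 RBP units (ICC ≈ 0.14,
inside the 5–30% range such cohorts exhibit). Implantation sparsity is
independent per ROI with configurable probabilities.

`simulate_recording` plants spectral content with a closed-form oracle:
white noise spectrally shaped to 1/f^χ (χ = 1 by default) plus one
fixed-amplitude sinusoid per band, scaled so the analytic band powers hit
the requested relative targets, with per-channel random phase and ±0.4 Hz
frequency jitter. The jitter keeps channels mutually incoherent —
realistic, and necessary for the common average reference not to inject
large cross-channel interference into single-frequency content. Total
in-band power defaults to 2500 µV² (≈50 µV RMS), keeping log band powers
positive.

`simulate_parcellation` builds hemisphere-paired voxel blobs on a jittered
lattice, named with standard cortical/subcortical base names so that the
bilateral subcortical exclusions and the 82 → 76 → 38 arithmetic apply
verbatim. It is a synthetic stand-in: coordinates carry no anatomical
meaning.

Passing tests on these generators shows the pipeline recovers what it
models — linear age trends, Gaussian hospital offsets, stationary planted
spectra. Real icEEG adds what the generators deliberately omit:
epileptiform transients, sleep architecture, non-Gaussian site effects,
age-dependent residual variance, spatially correlated implantations and
non-sinusoidal oscillations. Results on synthetic data bound
implementation correctness, not clinical validity.

## Problem sizes used in validation

The test suite and the acceptance script run simulation studies at fixed
sizes chosen to make Monte-Carlo error small relative to the tested
tolerances: 200 replicates for slope recovery and CI coverage at each of
ICC 0.05 and 0.30, 1000 null replicates for LRT calibration, 100
replicates per scenario for model selection, 25 matched replicate pairs
for the SE-versus-n comparison, and three 40-channel seeds for the
planted-spectrum ordering check. Fixed seeds make every run reproducible;
the acceptance script derives its seed streams from a single `--seed`.
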