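# Methods

This note documents the models, parameter choices and numerical behaviour
of each analysis stage, and what the synthetic-data generators do and do
not emulate.

## Synthetic cohorts

The generators are first-class, tested code: their defaults define the
study conditions under which every downstream stage is validated.

**Microdialysate time course** (`gen_metabolomics_timecourse`). Paired
burn/control samples per subject per 30-min fraction (−30 to 180 min, 8
fractions). Feature baselines are log-normal (median 10⁴, GSD e);
intensities carry multiplicative log-normal noise with unit mean and CV
`noise_cv` (default 0.2, a typical untargeted-UPLC-MS biological CV —
the instrument papers do not pin a value, so this is a conventional
choice). Planted features are multiplied, in burn samples only, by an
increase-then-plateau profile: 1 at the pre-injury fraction, linear rise
over three fractions to `effect_size` (default 3), constant thereafter.
All draws come from one `numpy` Generator in a documented order, so one
integer seed reproduces a cohort byte-identically through CSV.

**Lipidomics cohort** (`gen_lipidomics_cohort`). Burn/control biopsy pairs
with per-sample tissue weights (Gaussian, default 10 ± 2 mg, reflected at
zero); intensities scale with weight so the normalisation step has
something to undo. A pooled QC — the arithmetic mean of all biological
samples times instrument noise (CV 0.05) — is injected after every
`qc_every` (default 5) biological samples. Planted fold changes multiply
burn samples.

**Calcium traces** (`gen_calcium_traces`). Four cell classes: *responder*
(all drug windows + KCl), *capsaicin-only*, *KCl-only*, *dead* (nothing,
flat through the depolarising pulse). Transients have instantaneous rise
and mono-exponential decay (τ = 25 s), amplitude ~ N(0.3, 0.05) ratio
units truncated at 5σ of the additive Gaussian trace noise (SD 0.01), and
an onset lag uniform on [0, 6] s after window start. Sampling every 2 s.

**Heat-ramp cohort** (`gen_heat_ramp_cohort`). A 30-s resting hold at
32 °C (no heat-evoked signal) followed by a linear 32→55 °C ramp over
230 s. Each cell's threshold is drawn from a Gaussian mixture whose
default means are the four population peaks (33.9, 39.8, 44.4, 52 °C),
SD 1.5 °C, equal weights. The noiseless heat-evoked signal is built
directly in Arrhenius coordinates: log₁₀ signal is piecewise linear in
x = 1000/T_K with sub-threshold slope 2 per unit x and supra-threshold
slope 5× steeper, continuous at the cell's threshold, starting from a
2 × 10⁻² ratio-unit floor at 32 °C.

What the generators do **not** emulate: chromatographic peak shape and
retention drift, isotope envelopes, missing values, between-batch effects,
photobleaching and focus drift in imaging, dye saturation, and
heat-ramp nonlinearity. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated noise models, not robustness to
every artefact of real acquisitions.

## Canonical variates analysis

CVA is fitted on non-QC samples after column mean-centring. The design is
cell-means coding of condition × fraction (16 cells for the default time
course). Because features far exceed samples, the data are first reduced
by SVD to at most *n − g* dimensions (*g* = design cells), the largest
rank for which the within scatter stays positive definite; the
generalised eigenproblem *B a = λ W a* is solved in that score space with
`scipy.linalg.eigh`, and eigenvectors are back-projected through the
loadings to feature-space canonical weights. Requests for a larger rank
raise (over-parameterisation). When a direction has essentially zero
residual variance (a perfectly discriminating feature), a ridge of
10⁻¹⁰ · tr(W)/r is added to keep the factorisation defined. The sign of
each component is fixed so the burn − control contrast at the final
fraction is non-negative. Ranking is by |weight|, ties broken by feature
id, and the top-fraction shortlist takes the first ⌈f·n⌉ entries.

*Scaling.* The default is mean-centring only, so weights retain
intensity-scale meaning. With multiplicative (CV-proportional) noise,
however, raw-scale weights track baseline intensity rather than
discriminative content: on the planted-recovery benchmark (10 features of
2× effect among 200, 8 subjects) centring-only recovers 0/10 while
unit-variance scaling (`scale=True`) recovers 9/10. Discriminant analysis
of heteroscedastic MS intensities should therefore autoscale, and the
recovery tests do; the centring-only default is kept for weight
interpretability on variance-stabilised inputs.

## Lipidomics pipeline

The order is fixed and recorded in the run report: weight normalisation →
QC CV filter → median scaling → glog → autoscaling → Welch/Holm.

* QC CV uses the sample SD (ddof = 1); a feature with QC mean 0 is
  discarded (CV undefined).
* Median scaling multiplies each sample so its median equals the *median
  of per-sample biological medians*. This target (rather than the median
  of all pooled entries) makes the step exactly invariant to per-sample
  scale factors, which is the property the step exists to provide.
* glog λ defaults to the smallest positive intensity after weight
  normalisation; λ ≤ 0 is rejected. As λ → 0, g(x) → log₂ x for x > 0.
* Autoscaling centres and unit-variance-scales each feature (ddof = 1);
  post-condition mean 0 / variance 1 is asserted to 10⁻¹⁰ in tests.
* Welch t uses the Welch–Satterthwaite df per feature
  (`scipy.stats.ttest_ind(equal_var=False)`); identical groups are
  reported as t = 0, p = 1. Holm adjustment comes from
  `statsmodels.multipletests`. Fold changes are computed on the
  weight-normalised (pre-transform) scale and reported as log₂.
* Adduct offsets: +1.007276 Da (M+H), +22.989218 Da (M+Na), −1.007276 Da
  (M−H). Reference monoisotopic masses are computed from molecular
  formulas via `pyteomics.mass` at import time; 18:0 LPC (C₂₆H₅₄NO₇P) is
  523.36379 Da. A match requires |Δ| ≤ 0.05 Da; the "promising" flag
  additionally requires |Δ| < 35 ppm (the observed 524.3943 matches
  18:0 LPC M+H at +0.0232 Da ≈ 44 ppm: matched but not flagged).

## Calcium response calling

The baseline is the 30 s immediately before a window, clipped at the end
of any earlier window, and needs ≥ 10 samples (the recordings do not
define a baseline length; 30 s is a conventional choice exposed as a
parameter). A response requires strictly amplitude > 3σ_b *and* a first
3σ-crossing inside [start, end + lag]; the default lag of 10 s absorbs
perfusion dead time. AUC is the baseline-subtracted trapezoid over the
same interval, reported for responders and non-responders alike, negative
area not clipped. A flat trace with σ_b = 0 is flagged degenerate and not
a responder.

The 3σ rule has an irreducible false-positive rate on pure-noise traces —
about 10 % per 30-s window at 2-s sampling with a 15-sample baseline
(measured by simulation; stable across seeds to < 2 percentage points at
n = 2000). Consequently the viability gate retains exactly the non-dead
cells only on cohort draws without a noise excursion crossing 3σ in the
KCl window; cohort-level counts should be read with that base rate in
mind, exactly as with the original manual procedure.

## Heat thresholds

The Arrhenius ordinate is log₁₀(R − μ_b + ε) with μ_b the mean of the
pre-ramp hold and ε = 10⁻³ σ_b (floored at 10⁻¹²) to keep the log
defined; values below ε are clipped. When no hold exists the first five
ramp samples serve as baseline — biased high by the sub-threshold signal,
so recordings should include a hold. The breakpoint search is exhaustive
over interior grid points with ≥ 5 points per segment, each side fitted by
independent OLS; the threshold is the analytic intersection of the two
extrapolated lines converted back from 1000/T_K. Parallel lines or an
intersection outside the recorded ramp are not accepted. The
"accelerating" gate requires two-segment SSE < 0.7 × single-line SSE and a
supra/sub slope-magnitude ratio > 1.5 (both configurable; the source
procedure gives only the qualitative word). Multiplying a trace by a
positive constant shifts both intercepts equally and leaves the threshold
unchanged. On the default synthetic cohort the gate rejects cells whose
thresholds sit within ~2 °C of the ramp ends (one segment too short or
too noise-dominated to certify acceleration); among accepted cells the
median |error| is ≈ 0.3 °C.

## Threshold mixture decomposition

The histogram (1 °C bins spanning at least 32–55 °C) is fitted by bounded
least squares with a sum of K Gaussian curves (amplitude, mean, SD per
component), multi-started from quantile-, peak- and random-seeded
initialisations. Component weights are amplitude × SD, normalised. A
component pinned at the SD lower bound (0.3 °C) with non-trivial mass
marks the fit degenerate and excludes that K. K is the smallest candidate
for which adding a component fails a sequential F-test at α = 0.05; the
F denominator is the pure-error variance of the richest candidate rather
than the next model's own SSE (the latter under-rejects while both models
still show lack of fit, occasionally collapsing to K = 1 with
catastrophic means). BIC per candidate is reported alongside. On 400-cell
draws at the default population (separations ≥ 3.9 SD) this selects K = 4
on roughly 80–90 % of draws; on the remainder a fifth component is
admitted, with the extreme component means essentially unchanged (the
highest fitted mean stays within 0.5 °C of its population value across a
20-seed battery). An EM fit on the raw thresholds (`em_mixture`) is
provided as a cross-check and agrees with the histogram fit on
well-separated mixtures to ≈ 0.3 °C in the means.

The *cumulative threshold* of a pooled population is not uniquely defined
by the source material; both plausible readings are implemented — the
mean of a single-Gaussian fit to the pooled histogram (`pooled-fit`) and
the mixture-weighted mean of component means (`weighted-mean`) — and they
agree within ~1 °C on near-symmetric mixtures. A rate-of-rise Arrhenius
ordinate (instead of amplitude) is deliberately not implemented; the
amplitude ordinate is the documented choice.

## Contingency statistics

The 2×2 two-sided Fisher test delegates to `scipy.stats.fisher_exact`
(point-probability convention, the one used by mainstream environments;
mid-p and doubling conventions differ and are not offered). The
Freeman–Halton r×2 test enumerates all tables with the observed margins
(feasible for r ≤ 4 and totals into the thousands; the 3×2 with total
1531 enumerates ~10⁵ tables in well under a second) and sums probabilities
≤ the observed with 1 + 10⁻⁷ relative slack for float ties; beyond the
enumeration budget a Monte-Carlo estimate over margin-preserving tables is
returned with its standard error. Exact agreement with R's `fisher.test`
was verified on 2×2, 3×2 and 4×2 tables. Percentages in reports use
round-half-even at two decimals by default.

## Problem sizes

The test suite runs cohorts of 150–1000 cells, 200-feature tables with 8
subjects, 200 permutations for the CVA null, and 1000-replicate
simulations for FWER and ANOVA calibration — sizes at which every
targeted property is already stable; larger cohorts change none of the
qualitative conclusions and scale linearly.
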