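# Methods

## Cosinor regression

Each (variable, condition) series is modeled as

    y_i = M + A·cos(ω t_i − φ) + ε_i,    ω = 2π/τ,  τ = 24 h fixed,
    ε_i ~ N(0, σ²) i.i.d.

The period is never estimated: the experimental design (7 samples over one
light–dark cycle) cannot resolve period, and the scientific question is the
presence and phase of a 24-h rhythm, not its length.

Estimation uses the exact linear reparameterization
y = M + βc·cos(ωt) + βs·sin(ωt) with βc = A·cosφ, βs = A·sinφ. OLS on the
three-column design gives the global least-squares optimum (no starting
values, no convergence failures), from which A = √(βc² + βs²) and the peak
time = (τ/2π)·atan2(βs, βc) mod τ. Fits are rejected up front when fewer
than 3 distinct time points or 4 observations are available, rather than
returning a rank-deficient result.

The acrophase is parameterized as a **peak hour in [0, 24)** throughout;
radians are available via a single conversion function. This avoids the
sign/units ambiguity that plagues cosinor reimplementations.

Standard errors: residual variance s² = RSS/(n − 3); Cov(β) = s²(XᵀX)⁻¹;
then the delta method gives

    Var(A)  = (βc²·Var βc + βs²·Var βs + 2βcβs·Cov) / A²
    Var(φ)  = (βs²·Var βc + βc²·Var βs − 2βcβs·Cov) / A⁴

with SE(peak h) = (τ/2π)·SE(φ). The test suite verifies that these equal the
Jacobian-based standard errors of a direct nonlinear least-squares fit in
(M, A, φ). At A numerically 0 (tolerance 1e-12) the acrophase is flagged
undefined and the noise/signal ratio is +∞.

By default the cosinor is fitted to individual animal values (larger
residual df); fitting to per-ZT means is available via `fit_on=zt_means` in
the configuration, since the original protocol does not record which was
used.

## Dual rhythmicity criterion

A series is rhythmic iff (a) one-way ANOVA across its time points gives
P < α (default 0.05) and (b) SE(A)/A < 0.3. Both gates are strict
inequalities. The conjunction makes the rule strictly more conservative than
ANOVA alone, which the acceptance suite verifies on null (A = 0) data: the
empirical rhythm-declaration rate stays at or below α. The source protocol's
wording ("only if either … and …") is grammatically ambiguous; the
conjunctive reading is implemented because it matches the stated
noise/signal-ratio principle, and the disjunctive reading was rejected.

## ANOVA, SNK letters, pointwise tests

The one-way ANOVA is the classical fixed-effects decomposition
(`scipy.stats.f_oneway` behind the module surface). If all observations are
identical, F is undefined and p = 1 is returned with a warning.

SNK: level means are sorted descending (ties broken by ZT for deterministic
output). Every ordered stretch of p means is tested with the studentized
range, q_obs = (max − min)/√(MS_within/ñ) against q(α, p, df_within), where
ñ is the harmonic mean of the two cell sizes compared (Kramer adjustment;
irrelevant for balanced designs). The standard non-testing rule applies: a
stretch inside an accepted (non-significant) stretch is never tested.
Homogeneous subsets are the maximal sorted intervals containing no
significant pair; letters a, b, c… are assigned to subsets in order of
descending mean. Quantiles of the studentized range come from
`scipy.stats.studentized_range`, validated against classical printed tables
at α = 0.05 to two decimals.

Condition differences at a single ZT use Welch's unequal-variance t-test by
default (`per_timepoint_test=student_t` switches to the pooled-variance
test); the original figures' asterisks do not name their test, so neither
variant is claimed as "the" original.

## qPCR quantification

Efficiencies are fractions e ∈ [0, 1]; amplification base is (1 + e). The
Pfaffl ratio is (1+E_t)^(Ct_target,cal − Ct_target,s) /
(1+E_r)^(Ct_ref,cal − Ct_ref,s); the comparative method is 2^(−ΔΔCt) and
equals Pfaffl at e = 1 exactly. The pipeline default is Pfaffl; both are
exposed because the source protocol cites both without saying which produced
its figures. QC gates: efficiency within [0.85, 1.00] closed, standard-curve
R² strictly greater than 0.985 (absent R² passes). Technical triplicates are
averaged on the Ct scale before ratios. The calibrator is the mean Ct of a
caller-designated sample group (typically control at the matching ZT), so
the calibrator group's own mean ratio is 1.

## Synthetic generator

Observations are simulated as mesor + amplitude·cos(2π(t − peak)/24) + ε,
ε ~ N(0, σ), on the grid ZT 0, 4, 8, 12, 16, 20, 24 (the 24-h point is the
repeated dawn sample, kept as a distinct observation and a distinct ANOVA
level). Stress effects compose multiplicatively: a mesor factor, an
amplitude factor (0 = rhythm abolished), and a phase displacement in hours.

The noise is additive homoscedastic Gaussian — exactly the cosinor
regression assumption — so estimator tests are exact; real concentration
data are right-skewed and often heteroscedastic, which the generator does
not emulate (a lognormal option is a noted extension, and negative values
are not truncated by default to keep the Gaussian model exact; a
clamp-at-zero switch exists). A green test therefore establishes correctness
of the estimators and decision rules under their own assumptions, not
robustness to real-data pathologies.

The reference scenario assigns each variable the published group means as
control/stress mesors and the published peak ZTs as acrophases (e.g. plasma
cortisol 29.01 → 58.53 ng/mL; *pepck*-like expression peaking ZT0 in control
and ZT16 under stress). No per-animal raw data were ever deposited, so
amplitudes are plausible settings — roughly 30–40% of the mesor for rhythmic
variables — and noise SDs about half the amplitude, sized so that a
14-animal design detects the rhythms reliably while the blunted series fail
the criterion. These were chosen once from the printed SEM magnitudes and
are not calibrated to any test outcome. Group sizes follow the design:
n = 8 per ZT for metabolites/enzymes, n = 4 for mRNA variables.

## Rhythm comparison

Grand means pool all observations (identical to the mean of per-ZT means
for balanced designs). The phase shift is the minimal signed circular
displacement, in (−12, +12]: negative = advance, positive = delay, exactly
±12 h resolves to +12 (antiphase). The worked anchor for the sign
convention: a peak moving ZT0 → ZT16 is an 8-h advance. Classification
tolerance defaults to 1 h — a quarter of the 4-h sampling interval, below
which the design cannot resolve displacement. Alongside the cosinor-based
shift, the shift between argmax-of-ZT-means peaks is reported
(`phase_shift_argmax_h`) because published peak times are usually read from
the sampled maxima, not the fitted acrophase. No formal test for acrophase
difference is attempted: with only fitted phases and no deposited raw data
there is nothing to calibrate one against.

## Numerical choices and degenerate inputs

* Strict inequalities at every gate (p < α, ratio < 0.3, R² > 0.985).
* ANOVA with zero total variance → p = 1 + warning, not an exception.
* SNK with zero within-cell variance → every unequal pair significant.
* Identical samples in the pointwise test → p = 1.
* Zero-amplitude cosinor → amplitude 0, acrophase NaN/flagged, ratio +∞,
  never rhythmic.
* Mean change with a zero control mean → NaN, flagged rather than raised.
* All randomness flows through a single `numpy.random.Generator`; the same
  seed reproduces the full pipeline byte-for-byte.

## Known limitations

* Single-component, fixed-period cosinor only: no multi-harmonic fits, no
  period scanning, no population-mean cosinor hierarchy.
* No two-way ANOVA (condition × time interaction); conditions are analyzed
  separately, mirroring the original design.
* The synthetic generator produces independent Gaussian noise; no
  autocorrelation, no mechanistic clock dynamics.
* SNK is used for fidelity to the original protocol despite its known
  liberal familywise error control relative to Tukey's HSD.
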