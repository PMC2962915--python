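# Methods

## Model and assumptions

The package implements a three-species competition model for
active-site-directed chemical modification. Free enzyme E binds the
modification reagent (DTNB, Ellman's reagent) reversibly with
dissociation constant K_DTNB; the noncovalent E·DTNB complex then reacts
irreversibly with first-order rate constant j, releasing the
chromophoric thionitrobenzoate (TNB) anion and inactivating the enzyme.
A protecting ligand Co binds the same site with dissociation constant
Kd, and the E·Co complex is unreactive.

Assumptions:

* binding equilibria are rapid relative to the covalent step, so the
  three species stay at their equilibrium proportions throughout and
  the observed inactivation is pseudo-first-order;
* exactly one reactive cysteine per subunit, fully inactivating when
  modified (1:1 stoichiometry of TNB release to inactivation);
* a single ligand binding mode competing directly with the reagent.
  When this fails — e.g. a ligand with an additional, nonproductive
  occupancy mode — the protection-derived Kd reports overall site
  occupancy, not productive binding alone. That is a feature of the
  method, not of this implementation, but it shapes interpretation;
* reagent and ligand are in large excess over enzyme, so their free
  concentrations equal their total concentrations.

Rate laws (all concentrations molar internally):

    k    = j [DTNB] / (K_DTNB + [DTNB])
    k_Co = j [DTNB] / (K_DTNB (1 + [Co]/Kd) + [DTNB])

k_max, the protection-line intercept's reciprocal, is defined as the
first expression evaluated at the working [DTNB]: the only definition
consistent with the zero-ligand limit of k_Co. No reagent-independent
inactivation term is modelled.

## Estimation procedure

**Stage 1 — rate constants.** Activity-mode courses are fitted by
unweighted linear regression of ln(activity) on time (the classical
procedure for these data); k is the negated slope and se_k the slope's
standard error. Nonpositive activity values (possible under additive
noise) are dropped and counted, never clamped. A slope significantly
positive (beyond 2 SE) is reported as k = 0 with a `no_inactivation`
flag. Absorbance-mode traces are fitted to A(t) = A_inf·(1 − e^{−kt})
by Levenberg–Marquardt least squares, co-estimating A_inf by default
(robust to pipetting error in the thiol concentration); with A_inf held
at the Beer–Lambert value ε·ℓ·[SH]₀ the fit reduces to log-linear
regression and supports stoichiometry checks. R² is computed on the
fitted scale in each mode and is diagnostic only — it never gates
downstream fits.

**Stage 2 — binding parameters.** The saturation fit regresses 1/k on
1/[DTNB] (unweighted OLS): j = 1/intercept, K_DTNB = slope/intercept,
with standard errors by the delta method using the full regression
covariance. A nonlinear fit of the hyperbola is available and agrees
with the linearisation exactly on noiseless data; the linearisation is
the default for fidelity to the established procedure, despite its
known heteroscedasticity under noise. The protection fit regresses
1/k_Co on [Co] — the linearisation the model actually predicts — and
converts the slope to Kd = (1/j)(K_DTNB/[DTNB])/slope. se_Kd combines
the slope SE with se_j and se_K_DTNB in quadrature, treating them as
independent (only marginal uncertainties are available from stage 1); a
parametric bootstrap (default 500 resamples perturbing all inputs at
their SEs) is provided as a cross-check and agrees with the delta
method within ±50% on default synthetic data.

**Decision rules and degenerate inputs.** A saturation fit with
nonpositive ordinate intercept is an error (the data show no
saturation); a zero/negative slope yields K_DTNB = 0 flagged
degenerate. A protection-line slope not exceeding twice its SE yields
the explicit non-binding sentinel (Kd = ∞, represented exactly so the
analytic protection line has slope exactly 0) rather than a huge
unstable estimate; this rule is this package's own convention. Fewer
than 3 distinct concentration levels, mixed [DTNB] within a protection
series, or mismatched variants are usage errors.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| DTNB saturation grid | µM | 50, 100, 200, 300, 400, 600 | the original design; spans below and near K_DTNB for a conditioned reciprocal fit |
| working [DTNB] (protection) | µM | 200 | the original fixed protection condition |
| coenzyme grid | ×Kd | 0, 0.25, 0.5, 1, 2, 4 | brackets Kd; zero level pins the intercept against k_max |
| activity sampling | — | 12 points over 3 half-lives | keeps the log-linear fit well conditioned without sampling deep noise-dominated tails |
| activity noise | fraction | 0.02 | typical relative error of a manual enzymatic assay |
| absorbance noise | AU | 0.002 | typical photometric error of a bench spectrophotometer |
| ε(TNB, 412 nm) | mM⁻¹cm⁻¹ | 13.6 | standard literature value |
| path length | cm | 1.0 | standard cuvette (configurable) |

All concentrations are stored in molar internally; µM (reagent) and mM
(coenzyme) appear only at interfaces (CSV columns, catalog, reports).
This removes the silent unit-mismatch hazard in the K_DTNB/[DTNB] ratio.
Stoichiometry calculations take a user-supplied subunit molar
concentration rather than assuming a molecular mass. Temperature is
carried as metadata only; it never enters the model.

## What the synthetic data emulate — and what they do not

The generator reproduces the statistical structure the analysis
assumes: exponential decays (or exponential-rise absorbance traces)
at the model-predicted rates under the study's concentration designs,
with multiplicative Gaussian noise on activity (assay error scales with
signal) and additive Gaussian noise on absorbance (photometric error).
Per-series seeds derive from the master seed by stable hashing of the
series identity, so adding a series to a study never perturbs another's
draws. Replicate count defaults to 1 per condition and is configurable.

Not emulated: baseline drift, lamp flicker, mixing dead time, enzyme
denaturation over the incubation, pipetting error in the concentration
grids, or any departure from the single-site competition model.
Passing tests therefore demonstrate that the estimators invert the
assumed model correctly and are stable under idealised measurement
noise — not that the model is adequate for any particular real enzyme,
which only the internal consistency checks on real data (mode
agreement, intercept consistency, linearity of the reciprocal plots)
can support.

## Numerical choices

* Noiseless end-to-end recovery is exact to ~1e-9 relative because
  log-linear regression on an exact exponential and OLS on exactly
  affine reciprocals are exact inversions; tests assert this.
* curve_fit initialisation: absorbance fits start at (max(A), 1/t_end);
  nonlinear saturation fits start from the linearised estimates.
* Mode-agreement checks use the ratio of the two rate estimates with a
  delta-method SE; the default acceptance band 1 ± 2·(combined relative
  SE) carries a 1e-9 relative floor so noiseless fits, which agree to
  rounding error with zero reported SE, pass.
* Comparison-table ratios and fold changes are rounded to 2 significant
  figures by default (`sig_figs=None` disables rounding).
* Pipeline outputs contain no timestamps; a fixed configuration and
  seed reproduce every result file byte-for-byte, and the run manifest
  (resolved config + hash + seed + version) suffices to regenerate them.

## Problem sizes

Default study: 5 variants × (6 saturation + 3×6 protection) courses of
12 points each, fitted in well under a second. Stochastic checks use
200 seeded replicates for recovery/SE-calibration tests, 100 pairs for
the mode-agreement calibration, and 500 bootstrap resamples — sizes at
which the Monte-Carlo error of the checked summaries is comfortably
below the asserted bands.

## Known limitations

* Unweighted regression on reciprocal-transformed data is
  heteroscedastic under noise; the nonlinear alternatives are offered
  but are deliberately not the default.
* Error propagation assumes independence between the protection-line
  slope and the stage-1 baseline parameters; the bootstrap cross-check
  relaxes this only partially (it still treats the reported SEs as
  correct).
* No global multi-series likelihood: each series is fitted alone, so
  information is not shared across conditions.
* Outlier-robust regression, drift correction and multi-site
  modification are out of scope.
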