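# Methods

## Model and assumptions

The package models the time course of the isotopically exchangeable
fraction of water-soluble Cu added to soil (`E_add`, a fraction of the
dose) as the product of a diffusion survival factor and the complement of
two fast loss channels:

```
E_add(t) = S(x) · [1 − Y1 − Y2],        x = N · e^(K/T) · t
S(x)     = exp(x) · erfc(√x)
Y1       = B · t^(C/t) / (10^(pK°−pH) + 1)
Y2       = F · (C_org/100) · t^(G/t)
```

Assumptions inherited from the underlying chemistry:

* the pH channel is proportional to the CuOH⁺ fraction of dissolved Cu
  (two-species partition governed by the first hydrolysis constant pK°);
  temperature effects on this fast channel are neglected;
* occlusion is linear in total organic carbon;
* diffusion into micro/mesopores follows the plane-sheet, limited-volume
  solution, whose exact lability decline is `1 − S(x)`; the diffusion
  coefficient is Arrhenius in temperature, giving the composite
  `K = −Ea/R` (kelvin) and pre-factor `N` (per day). Only the composites
  are identifiable; the underlying `D0, Ea, α, l` are deliberately not
  modelled separately;
* moisture, microbial activity and plant uptake are out of scope, and the
  model applies to water-soluble Cu additions only (not sludges or organic
  fertilizers);
* for outdoor aging, `T` is the arithmetic mean temperature of the aging
  period (`Y2`'s temperature response is near-linear over 253–323 K, which
  justifies averaging).

An equivalent additive reading is `E_add = 1 − Y1 − Y2 − Y3` with
`Y3 = (1 − Y1 − Y2)(1 − S(x))`; the implementation verifies both forms
agree to 1e-12 relative. One printed form of the diffusion equation has an
inconsistent denominator (`1 − Y2 − Y3`); the full-model expression fixes
the intended form, `Y3/(1 − Y1 − Y2)`, and that is what is implemented.

## Parameters

| name | meaning | unit | default |
|------|---------|------|---------|
| B | precipitation/nucleation coefficient | – | 1.14 |
| C | fast-channel kinetic scale in `t^(C/t)` | d | 0 |
| N | diffusion pre-factor `D0/(α²l²)` | d⁻¹ | 214.91 |
| F | occlusion coefficient | – | 2.85 |
| G | occlusion kinetic scale in `t^(G/t)` | d | 0 |
| K | Arrhenius composite `−Ea/R` | K | −4330 |
| pK° | first hydrolysis constant of Cu | – | 7.7 |

Defaults are the calibrated long-term fit; `K = −4330` corresponds to an
activation energy of 36 kJ/mol with R = 8.314 J mol⁻¹ K⁻¹, and pK° = 7.7
is the bulk-solution hydrolysis constant. When pK° is freed (bounded to
[3, 10]) soil data pull it to ≈ 6.65 with little change in fit quality.

All times are internally in **days**; field ages given in years convert at
365 d/y (leap-day precision is far below model error).

## Numerical choices

* `S(x)` is evaluated as `erfcx(√x)` (the exponentially scaled
  complementary error function), never as a literal `exp(x)·erfc(√x)`
  product, which overflows for x ≳ 700. Field soils reach x ≈ 2, but
  property tests and parameter exploration reach x = 1e8 and beyond. The
  tests cross-check `erfcx` against adaptive quadrature of the shifted
  erfc integral to 1e-9 relative over x ∈ [1e-8, 1e4].
* `t^(C/t)` is computed as `exp((C/t)·ln t)`. At `t = 0` the model returns
  `E_add = 1` exactly (nothing has aged); for `C > 0` the kinetic factor's
  t→0⁺ limit of 0 is used if the factor itself is requested at t = 0.
  With the calibrated `C = G = 0` the factor is identically 1.
* The bracket `1 − Y1 − Y2` can go negative for high-pH, high-organic
  soils under the calibrated coefficients (e.g. pH 7.5, 23 % C_org); it is
  clamped to [0, 1], the result flagged, and a warning logged. `E_add` is
  a fraction and negative predictions are physically meaningless.
* Fitting is bounded nonlinear least squares (scipy's trust-region
  reflective) with `B, C, N, F, G ≥ 0`, `K ≤ 0`, `pK° ∈ [3, 10]`;
  tolerances `xtol = ftol = gtol = 1e-10`, Jacobian-based variable
  scaling. Because the objective is nonconvex in `N`, each fit runs a
  seeded multi-start (default 10 starts: the caller's initial point plus
  draws with `N` log-uniform on [1e-2, 1e4], `B, F` uniform on [0, 3],
  `C, G` uniform on [0, 10]); the best objective wins and per-start
  objectives are reported so basin structure is visible.
* R² is `1 − SSres/SStot` about the observation mean, pooled over
  observations; RMSE uses denominator `n` (not `n − p`). Trend anchors
  enter the fitting objective as weighted pseudo-observations but are
  excluded from R²/RMSE so fit statistics are comparable across anchor
  choices. Anchors could alternatively be read as hard constraints; the
  pseudo-observation reading is the default design here because it
  degrades gracefully when anchors conflict with data.
* Isotope dilution: the natural ⁶³Cu/⁶⁵Cu ratio defaults to 2.2435
  (69.15/30.85 atom %) and is overridable per measurement, since the
  solution ratio may be measured per soil. Measured ratios are assumed
  final (no mass-bias or interference correction). Added-E fractions
  outside [0, 1] are flagged but not clamped at the measurement layer —
  clamping is a prediction concern and raw values matter for QC.

## Synthetic data: what it emulates and what it does not

`generate_soils` draws pH, organic carbon and temperature independently
and uniformly over the incubation study's ranges (pH 2.98–7.52 in 0.01 M
CaCl₂, C_org 0.41–23.32 % w/w, T 278–298 K) and times log-uniformly over
1–30000 days, so that the √t and log-like diffusion regimes are both
populated. Observation noise is additive Gaussian on the fraction scale
(default sd 0.05), clipped to [0, 1] with clip events counted; an additive
error model is consistent with the calibration residual scale (RMSE ≈ 0.11
on fractions). Real soils differ in ways the generator does not attempt:
pH and organic carbon are correlated in nature, outdoor temperatures vary
seasonally rather than being a single mean, moisture and microbial
activity perturb long outdoor incubations, and measurement error is not
homoscedastic. Passing recovery tests therefore demonstrate that the
estimator is consistent and well-identified under the model's own
assumptions — not that field calibrations will reach the same precision.

The original long-term calibration table is not redistributable, so the
calibration checks run on `longterm_study_surrogate`: a synthetic stand-in
reproducing that study's *design* (19 soils over the property ranges, each
observed at 7–360 days, trend anchors at 3600 and 7200 days, noise sd
0.02) with targets generated from the model itself. The 20 field soils,
which are printed in full, ship verbatim as `field_soils_fixture` with a
SHA-256 transcription pin.

## Problem sizes

Test and acceptance runs use 19–200 soils, 5 recovery replicates and 8–10
multi-start initializations; a full fit takes well under a second, chosen
so the whole suite stays interactive while leaving recovery error an order
of magnitude inside its asserted bounds.

## Known limitations

* The pH channel's mechanistic basis (CuOH⁺ formation) is inferred from
  fitting behaviour and analogy to other metals, not from spectroscopy.
* With `B` fixed at 0 the hydrolysis constant is absent from the model and
  `pK°` is unidentifiable; the fitter warns in that configuration.
* High total-Cu field contaminations (well above the EC10 dosing the model
  was calibrated for) stretch the model's dose-independence assumption;
  the embedded field set includes such soils and they carry most of the
  validation error.
* No uncertainty quantification on fitted parameters (point estimates
  with convergence diagnostics only).
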