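# Methods

## Scope and model

`lutedose` implements region- and voxel-level internal dosimetry for
therapies with 177Lu-labelled radiopharmaceuticals (somatostatin-receptor
and PSMA ligands) following the MIRD schema: the mean absorbed dose to a
target region is

    D(r_T) = Σ_{r_S} Ã(r_S) · S(r_T ← r_S),

where Ã is the time-integrated activity (TIA) of a source region and
S(r_T ← r_S) the mean absorbed dose per unit TIA. The integration period is
infinity by default; finite horizons are supported for cycle-limited
questions. Canonical units are hours, MBq, gram, mGy and mJ, matching the
units of the packaged reference tables.

Two 177Lu-specific simplifications carry most of the computation:

* **Local energy deposition (LED).** 177Lu electrons have sub-millimetre
  ranges in soft tissue, so for self-dose the electron absorbed fraction is
  ≈1 and the photon fraction ≈0, giving S ≈ Δ_e/m. For convex soft-tissue
  regions of roughly 2–300 g this tracks published phantom S-values to
  within about 1–2% (the packaged diagnostics show mass×S/Δ_e of 1.01 for
  kidney and 1.04 for liver; red marrow, at 0.57, is the deliberate
  counter-example — its electrons escape the marrow micro-structure, so
  LED must not be used there).
* **Self-dose mass scaling.** S_pat ≈ (m_ref/m_pat)·S_ref, valid only for
  source = target; cross-dose records are never scaled.

## Radionuclide data

Three compilations are packaged (Olinda/HPS, ICRP 107, NuDat2), each with
the 6.647 d half-life and the mean electron/photon energy per decay. The
keV→(mJ per MBq·h) conversion uses the exact SI elementary charge
(1.602176634e-16 J/keV) and 3.6e9 decays per MBq·h. Published tables round
the keV and mJ columns independently from a more precise common source, so
converting a rounded keV entry can land one unit off in the fourth
significant figure of the printed mJ value; tests therefore allow the
propagated half-ulp input rounding (±0.05 keV ≈ ±2.9e-5 mJ MBq⁻¹h⁻¹).

## Activity quantification

* SPECT: Q_sp = C_cal/A_cal from a large-phantom acquisition; recovery
  coefficients R(v) measured on sphere inserts correct the partial-volume
  effect; VOI activity is C/(Q_sp·R(v)). Recovery curves are interpolated
  piecewise-linearly in log-volume (recovery varies smoothly over decades
  of volume) and clamped, with a flag, outside their support.
* Planar: conjugate-view geometric mean with broad-beam attenuation
  e^(μL/2); default μ_eff = 0.12 cm⁻¹ for the 208 keV photopeak,
  overridable. The 177Lu source self-attenuation factor is near unity and
  omitted. Background correction is plain rate subtraction of user-chosen
  background ROIs (no thickness rescaling — a documented simplification).
  TEW scatter correction requires explicit window widths; they are
  acquisition settings, not physics, and no default is sensible.
* Hybrid planar–SPECT: the planar TAC supplies the shape, one SPECT point
  the amplitude; anchors between samples use log-linear interpolation,
  exact for exponential washout.
* Dead time: a measured true→observed response curve is inverted by
  monotone interpolation. No paralyzable/non-paralyzable model is fitted,
  and observed rates outside the characterised range are refused rather
  than extrapolated.

## Time-integrated activity

Trapezoidal integration assumes a linear rise from (0,0) to the first
sample (instantaneous-uptake geometry) and adds a tail per policy: none,
A_last/λ_phys, or A_last/λ_fit from the last two samples. Note that the
physical-decay tail deliberately overestimates whenever the effective
washout is faster than physical decay (for a TAC with λ_eff = 0.01/h
sampled to 168 h it overshoots the closed form by ~25%, versus ~0.5% for
the last-two extrapolation); it is the conservative choice when the late
washout rate cannot be estimated.

Exponential fits (mono-, bi-, mono-with-uptake) use nonlinear least
squares with multi-start initialisation from log-linear segment estimates
plus seeded log-normal jitter, so results are bit-reproducible. The TIA is
the analytic integral of the fitted model; its uncertainty comes from
first-order propagation of the parameter covariance. `auto` selection uses
AICc counting the model parameters; models with no residual degrees of
freedom receive an infinite correction, so automatic selection of a
bi-exponential needs ≥6 samples — with 4–5 samples request it explicitly.
The early wash-in spike is intentionally not modelled: its area is small
and chasing it destabilises the washout-rate estimate.

Single-time-point TIA back-extrapolates a mono-exponential at the
population mean rate λ̄ through the measurement, TIA = A·e^(λ̄t)/λ̄. Its
relative uncertainty is evaluated two-sided at λ̄(1±CV) and the larger
deviation taken. This reproduces the published timing behaviour — 25.9% at
24 h, 10.3% at 96 h for λ̄ = 0.013/h, CV = 27% — where first-order
propagation does not, and it makes explicit that the uncertainty is
minimised near t = 1/λ̄ (≈77 h). The published 192 h figure (60%) is not
exactly reproducible by this rule (it gives ~55%), most likely because the
original evaluation sampled the full population histogram; the 192 h case
is therefore checked only for order of magnitude.

## Organ procedures

* **Kidneys.** Scheme 1 fits each kidney's activity TAC (mono-exponential,
  ≥3 samples at cycle 1), mass-scales the reference S-value, and doses each
  kidney with its own TIA and own-mass S-value; the mass-weighted mean of
  the two doses is then algebraically identical to applying the
  combined-mass S-value to the summed TIA, which resolves the ambiguity in
  how "the (mass-weighted) mean" combines the sides. Scheme 2 converts the
  recovery-corrected concentration to a dose rate Δ_e·[A]/ρ (ρ = 1.05
  g/cm³) and integrates a mono-exponential fit of the rate. On uniform
  synthetic kidneys the schemes agree to the kidney LED ratio, 1.01.
  Follow-up cycles back-extrapolate a single measurement with the cycle-1
  effective half-life; this is recorded as an assumption because
  intra-patient variability of up to a factor three has been reported.
  `kidney_scheme2` takes optional kidney volumes for the mass weighting
  (equal weights otherwise) — the concentration route otherwise never sees
  an organ size.
* **Red marrow / blood.** Blood-based self term
  Ã_RM = [Ã_BL]·RMBLR·m_RM,ref (RMBLR default 1), dosed with the
  reference marrow S-value; image-based cross terms (bone, high-uptake
  organs, remainder) are user-supplied (tia, S) pairs since no published
  numeric cross S-values are packaged. Blood dose uses the LED blood value
  85.3 Gy/(GBq·h/mL) plus a total-body photon term 0.00185 Gy/(GBq·h)
  scaled by M^(−2/3).
* **Glands.** Self-dose from a mass-scaled reference S-value where one
  exists (salivary, pituitary) or LED (lacrimal, 1.4 g default); a
  (low, mid, high) mass range returns dose bounds, since for these small
  regions the mass assumption dominates the uncertainty budget.
* **Extravasation.** Uniform activity in the infiltrated volume, removed
  at λ_phys + λ_bio, dosed by LED. 7.4 GBq in 100 cm³ without clearance
  gives 1.45e3 Gy at unit density (1.38e3 at 1.05 g/cm³); a 2 h lymphatic
  clearance half-life divides that by ≈81.
* **Voxels.** LED dose-rate maps Δ_e·[A]_k/ρ_k with uniform soft-tissue
  density unless a density map is given. Voxel-wise mono-exponential
  integration uses log-linear least squares; voxels whose rates do not
  decrease fall back to trapezoid-plus-physical-tail and are counted in
  the diagnostics. DVHs are cumulative over the mask, start at 1 and are
  non-increasing by construction.

## Radiobiology

BED = D·(1 + D/(α/β)·λ/(λ+μ)) for mono-exponential washout; fractionated
treatments sum per-cycle BEDs under the recorded assumption that cycle
intervals are long against the effective half-life. No default α/β or
repair half-life is shipped — published kidney BED limits are cited
thresholds, not computations, and inventing radiobiology constants would
be worse than requiring them. EQD2 = BED/(1+2/(α/β)).

## Synthetic fixtures

Generators return ground truth next to the degraded observable: TACs with
known closed-form TIA and multiplicative truncated-Gaussian noise
(count-derived activities have roughly constant CV); log-normal population
decay constants parameterised to an arithmetic mean and CV (positive,
right-skewed, like observed washout-rate histograms); sphere phantoms
blurred with an activity-conserving Gaussian as the resolution surrogate;
and conjugate-view slab projections satisfying the geometric-mean identity
exactly. They emulate the arithmetic structure of the measurement chain,
not its physics — no projector, scatter, dead time or anatomy — so passing
closed-loop tests demonstrates correct estimator algebra and calibration
logic, not clinical accuracy. Population-level clinical dose ranges (e.g.
kidney 0.54–1.00 Gy/GBq) depend on real pharmacokinetic variability and
are out of scope.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`). The test suite uses desk-scale problems:
500-replicate Monte-Carlo for fit bias/coverage, 10⁴ draws for population
moments, ≤96³ phantom grids; the whole suite runs in well under a minute
on one CPU. The acceptance script's two quantities are deterministic
worked examples and use no sampling.

## Known limitations

* No tomographic reconstruction, attenuation-map generation, registration
  or segmentation; images enter as arrays with voxel-size metadata.
* Cross-dose is supported only through user-supplied S-value records; no
  photon transport is performed.
* The LED sphere model carries the documented ≤2% bias for 2–300 g; a
  user correction table (log-mass interpolated) can remove it, but no
  correction values are bundled because none are published in tabular
  form, and Olinda v2.1 sphere values are excluded from defaults as
  inconsistent with the other sources.
* BED assumes mono-exponential washout; the general double-integral
  equieffective dose is out of scope.
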