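# Methods

This note records the model conventions, numerical choices, and known
limitations of cestkit. Everything quantitative stated here is computed by
the test suite or the example scripts; nothing is quoted from elsewhere.

## Signal model

A z-spectrum is the normalized saturated water signal `Mz/M0` versus
saturation offset `w` in ppm relative to water. The fitted model is

```
Mz(w) = 1 - v - L_water(w-h) - L_amide(w-h) - L_noe(w-h) - SL_mt(w-h)
```

with three area-normalized Lorentzian pools and one super-Lorentzian MT
pool. The vertical term `v` absorbs normalization error from a noisy
reference image: observed data behave as `(1-v)` times the ideal spectrum,
so fitted amplitudes scale by `(1-v)` and both data and amplitudes are
renormalized by `1/(1-v)` after fitting. The synthetic generator applies
the same convention in reverse (observed = `(1-v) ×` renormalized model),
which makes renormalization exactly invertible in closure tests. The
horizontal term `h` absorbs residual B0 error after voxelwise correction.

Reported **peak heights** are renormalized lineshape values at each pool
centre: `2A/(πΓ)` for Lorentzians and `A_SL` for MT (see next section).

## Super-Lorentzian conventions

The MT lineshape is the orientation integral

```
g(Δ) = ∫₀^{π/2} sinθ √(2/π) · T2b/|3cos²θ−1| · exp(−2 (Δ·T2b/(3cos²θ−1))²) dθ
```

with `Δ` converted to angular frequency (ppm → Hz → ×2π rad/s) and `T2b`
in seconds. This unit convention gives the lineshape its physical
several-hundred-ppm extent for `T2b` in the 1–50 µs fit range.

**Amplitude convention.** `g` carries units of seconds and a center value
of order 10⁻⁵ s, so a raw-amplitude parameterization could not reach
realistic MT depths (~0.2 of `M0`) within the published amplitude bounds
[0.001, 1]. The lineshape is therefore *peak-normalized*: divided by its
spline-patched value at the centre, so the patched curve equals `A_SL` at
the MT centre frequency. Two consequences: the amplitude bound [0.001, 1]
reads directly as a fraction of `M0`, and the "MT peak height" and the
amplitude parameter coincide by construction.

**Pole patch.** `g` diverges at its centre. Within ±20 ppm of the MT
centre the analytic curve is replaced by a cubic spline through anchor
evaluations at ±{20, 22.5, 25, 30, 40} ppm, symmetrized so the patch is
exactly even about the centre. Outside the window the analytic curve is
used; the two agree at the window edge to better than 10⁻⁹ relative.

**Quadrature.** The orientation integrand develops a sharp spike at the
magic angle `θ_m = acos(1/√3)` where `3cos²θ−1` changes sign. A single
512-point Gauss–Legendre panel on [0, π/2] leaves relative errors up to
~10⁻³ at `T2b = 1 µs` near the ±21 ppm window edge, so the rule is split
into two 256-point panels meeting at `θ_m` (same total cost). Measured
worst-case disagreement with adaptive quadrature is ~2 × 10⁻¹⁰ over
`T2b ∈ [1, 50] µs`, `|Δ| ∈ [21, 300]` ppm.

**Cached table.** Voxelwise fitting uses a precomputed bicubic interpolant
of the normalized patched shape on a (log T2b) × (|Δ|) grid
(`SuperLorentzianTable`). Worst-case interpolation error is < 10⁻⁴
(at the patch-edge derivative kink for large T2b), negligible against the
10⁻³ closure tolerances; single-spectrum fits default to the exact
evaluator.

## Fitting

Bounded trust-region-reflective least squares (`scipy.optimize.least_squares`),
all points weighted equally, finite-difference Jacobian, `ftol = xtol =
gtol = 10⁻¹⁰`, at most 2000 function evaluations. Default starting values
and bounds follow the published protocol table; pool centres are pinned by
near-degenerate bounds (water 0 ± 10⁻⁴ ppm, amide 3.5 ± 10⁻³, NOE −3.5 ±
10⁻³, MT −1.27 ± 10⁻⁵ ppm) rather than hard-coded, preserving their status
as bounded parameters. Voxelwise fits are independent, so iteration order
cannot affect results; a degenerate flat spectrum is rejected rather than
fitted.

**MT centre estimation** fits the reduced model {ω0_SL ∈ [−4, 4] ppm, T2b,
A_SL, v} to data strictly outside ±15 ppm (ten offsets in the protocol
schedule), multistarting over ω0 ∈ {−2, 0, +2} ppm, and reports the median
across voxels together with the full distribution. `h` is not floated in
the reduced fit: B0 correction precedes it, and the outer points carry no
leverage on a sub-ppm shift. Downstream fits keep the centre pinned at the
protocol constant −1.27 ppm unless explicitly overridden.

## WASABI B0 mapping and correction

The WASABI signal model is the Rabi-oscillation form

```
S(f) = | c − d · sin²(arctan(γ̄B1/(f−fδ))) · sin²(π·tp·√((γ̄B1)² + (f−fδ)²)) |
```

with all frequencies in Hz. The envelope factor is computed as
`(γ̄B1)²/((γ̄B1)² + (f−fδ)²)`, which handles the on-resonance limit
exactly. Fits are bounded (δ ∈ ±1 ppm, B1 within ±50 % of nominal,
c, d ∈ [0, 2]) and multistart over δ ∈ {−0.8, −0.4, 0, 0.4, 0.8} ppm to
avoid oscillation-aliasing local minima. Only δ feeds the pipeline; B1, c,
d, and the residual go to a QC table.

**Correction.** Per voxel, the spectrum over |w| ≤ 7.5 ppm is cubic-spline
interpolated onto a 1-Hz grid covering the dense ±5 ppm region (plus
padding), shifted by −δ, and resampled at the nominal inner offsets with a
cubic read-off of the grid (nearest- or linear-sample read-off aliases by
up to half a grid step at the steep water slope). Offsets at |w| ≥ 5.5 ppm
keep their measured values: the shift (≤ ~0.5 ppm) is far below their
spacing, so nearest-sample assignment is the identity there. The reference
image is never modified; voxels without a valid B0 estimate pass through
and are flagged. The residual roundtrip error is limited by cubic-spline
reconstruction of the water line from 0.25-ppm samples, measured at
≤ 7.3 × 10⁻⁴ for |δ| ≤ 0.4 ppm across all phantom regions and shift phases.

## MTR asymmetry

`MTRasym(ω) = Mz(−ω) − Mz(+ω)` on B0-corrected, reference-normalized
spectra, *without* `1/(1−v)` renormalization (asymmetry is a data metric,
not a fit metric). Off-grid evaluation uses the same cubic spline as B0
correction. The single-offset variant reports 3.5 ppm; the mean-of-three
variant averages 3.25/3.5/3.75 ppm and demonstrably reduces variance under
noise.

## Synthetic phantom

The generator emulates a 64 × 63 single-slice prostate acquisition:
elliptical prostate with posterior peripheral zone (PZ) and anterior
transition zone (TZ), two lateral obturator-internus muscle blobs, an
optional TZ tumor, a low-order-polynomial B0 field (default peak 0.3 ppm,
mimicking smooth shim residuals), and additive zero-mean Gaussian noise on
the normalized signal (default σ = 0.005). Gaussian rather than Rician
noise is justified at the magnitude SNR of prostate ROI data. TZ and
TZ-tumor peak heights follow published prostate medians (amide
0.113/0.102, NOE 0.109/0.096, MT 0.222/0.260, i.e. an MT tumor contrast of
+0.038); PZ and muscle values are this package's own plausible settings,
with muscle given the broadest water line (2.0 ppm FWHM) because its T2 is
shorter than prostate tissue, and the largest semisolid MT fraction.
Voxelwise noise is not a measured quantity; σ = 0.005 is chosen so
ROI-level test–retest CVs land in a realistic range and is not claimed as
ground truth.

The two-session study replicates the test–retest design: two scans per
session differing only by noise, session-2 pool amplitudes multiplied by
independent draws of `1 + N(0, cv)` (default cv = 0.10). The repeatability
validation uses five subjects with six ROIs each (left/right PZ, TZ,
muscle), a flat B0 field (B0 mapping and correction are validated
separately; disabling them isolates noise and between-session variation),
and ROI-averaged fits — the same granularity as in vivo analysis.

What passing phantom tests do *not* show: robustness to motion, Rician
noise at low SNR, partial-volume mixing at region boundaries, B1
inhomogeneity, or anatomy beyond the stylized geometry.

## Repeatability statistics

Bland–Altman: bias = mean(m1 − m2); 95 % limits of agreement = bias ±
1.96 × SD(differences) with the n−1 sample SD; percentage LOA relative to
the grand mean. The CV is the within-subject test–retest convention,
`(SD(diff)/√2) / grand mean`; a per-pair alternative is available behind a
flag. Percentages are flagged undefined when the grand mean is zero.
Pairings: intrasession = scan 1 vs scan 2 within each session;
intersession = scan 1 vs scan 1 and scan 2 vs scan 2 across sessions. ROIs
are pooled across tissue types; per-tissue breakdowns can be produced by
pre-filtering the long-format table.

Inter-reader agreement uses the two-way random-effects,
absolute-agreement, single-measure ICC from the mean-squares
decomposition, cross-checked against pingouin's ICC(A,1). Sample estimates
are clamped to [−1, 1] (pure-noise matrices can stray below −1); zero
total variance returns NaN. Contrast between ROI voxel populations uses
the two-sided tie-corrected Mann–Whitney U test (exact for small samples
without ties).

## Problem sizes used in validation

Full-geometry validation fits all ~1270 in-mask voxels of the 64 × 63
phantom at 65 offsets, noiseless and at σ = 0.005; MT-centre estimation
uses the same grid; WASABI recovery uses 100 noisy replicates at σ = 0.01;
the repeatability study uses 5 subjects × 2 sessions × 2 scans × 6 ROIs.
Unit tests use smaller grids (12–32 px) where geometry is incidental.

## Known limitations

* The super-Lorentzian amplitude convention is a choice; tools using
  area-normalized or raw-integral conventions will report different `A_SL`
  for the same tissue (heights at the centre remain comparable).
* The Lorentzian/super-Lorentzian decomposition is phenomenological — no
  Bloch–McConnell exchange modelling, no B1 or T1 correction of CEST
  amplitudes (AREX), and no five-or-more-pool variants (amine, hydroxyl).
* B0 correction resamples to the nominal offsets before fitting; keeping
  the 1-Hz grid through the fit is a plausible alternative reading of the
  protocol and would change results only at the interpolation-error level.
* The acquired ordering of the offset schedule is not modelled; offsets are
  stored outermost-first and all computations are order-independent.
* DICOM ingestion, pulse-waveform synthesis, SAR accounting, and
  interactive ROI drawing are out of scope; masks are inputs.
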