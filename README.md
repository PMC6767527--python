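# cestkit

Post-processing for multipool **chemical exchange saturation transfer (CEST)
MRI** of the prostate at 3.0 T, built as an importable Python library with a
thin command-line layer.

CEST imaging saturates labile protons (amide groups of mobile proteins,
aliphatic protons coupled through the nuclear Overhauser effect, the
semisolid macromolecular pool) at their resonance offsets and reads out the
transferred saturation as a dip in the water signal. Plotting the normalized
water signal `Mz/M0` against saturation offset gives the **z-spectrum**;
decomposing it into pools yields metabolically weighted contrast that is
being explored as an adjunct to multiparametric prostate MRI. This package
implements the full post-processing chain needed to do that reproducibly,
and a synthetic phantom generator so every stage can be validated without a
scanner.

## The model

Each z-spectrum is fitted with a four-pool model

```
Mz(w) = 1 - v - L_water(w-h) - L_amide(w-h) - L_noe(w-h) - SL_mt(w-h)
```

* `L_i` — area-normalized Lorentzians, `L(w) = A (Γ/2π) / ((w-w0)² + (Γ/2)²)`,
  for direct water saturation (0 ppm), the amide pool (+3.5 ppm), and the
  NOE pool (−3.5 ppm); the peak height at the centre is `2A/(πΓ)`.
* `SL_mt` — the super-Lorentzian lineshape of the semisolid MT pool
  (orientation integral over `θ` of Gaussian-broadened responses), centred
  at −1.27 ppm, with the divergent pole region within ±20 ppm of the centre
  replaced by a symmetric cubic-spline patch.
* `h`, `v` — whole-fit frequency and vertical offsets; after fitting, data
  and pool amplitudes are renormalized by `1/(1-v)`.

Fitting is bounded trust-region least squares with the published starting
values and box bounds. Around the fit sit: **WASABI** B0 mapping (a 5-ms
off-resonant block pulse whose Rabi-oscillation pattern encodes the water
shift δ per voxel), voxelwise B0 correction by 1-Hz interpolation and
shifting, **MTRasym** `= Mz(−ω) − Mz(+ω)` at 3.5 ppm, and Bland–Altman
test–retest statistics (bias, 95 % limits of agreement, coefficient of
variation, inter-reader ICC, Mann–Whitney U contrast tests).

## Worked example

`examples/02_forward_model_and_fit.py` synthesizes a transition-zone-like
spectrum on the 65-offset protocol schedule and fits it back:

```
pool    truth    fitted
amide   0.1130   0.1130
noe     0.1090   0.1090
mt      0.2220   0.2220
water   0.3410   0.3410
h = +0.00003 ppm, v = +0.00000, rss = 6.17e-14, converged = True
```

The columns are peak heights in fractions of `M0`: the amide column says
the amide pool removes 11.3 % of the water signal at +3.5 ppm, and noiseless
closure recovers every height to well under the 10⁻³ validation tolerance.
The other examples cover protocol arithmetic (`01`), B0 mapping and
correction (`03`, roundtrip error ≈ 7 × 10⁻⁴), and a simulated two-session
repeatability study (`04`, intersession CV > intrasession CV for every
metric).

A thin CLI mirrors the pipeline stages:

```bash
cestkit simulate --seed 3 --out-dir phantom
cestkit wasabi phantom/wasabi.nii.gz --offsets phantom/wasabi_offsets.csv --out-dir b0
cestkit correct phantom/cest.nii.gz --offsets phantom/cest_offsets.csv --b0-map b0/b0_map_ppm.nii.gz
cestkit fit corrected_out/cest_corrected.nii.gz --offsets corrected_out/cest_offsets.csv
```

## Layout

```
src/cestkit/        constants, lineshapes, volume containers, phantom,
                    wasabi, fitting, asymmetry, repeatability, io, pipeline, cli
examples/           one narrative script per capability
tests/              unit + property + end-to-end suites
docs/methods.md     model conventions, numerical choices, limitations
```
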