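"""WASABI B0 mapping and voxelwise spectrum correction on a small phantom.

Simulates a phantom with a smooth +/-0.3 ppm B0 field, fits the WASABI
Rabi-oscillation model per voxel, corrects the z-spectra by 1-Hz
interpolation and shifting, and prints the field-recovery and roundtrip
errors.
"""

import numpy as np

from cestkit import (
    PhantomConfig,
    build_protocol_offset_schedule,
    correct_b0,
    fit_b0_map,
    forward_zspectrum,
    make_phantom,
    region_masks,
    simulate_scan,
)

schedule = build_protocol_offset_schedule()
truth = make_phantom(PhantomConfig(shape=(24, 24), noise_sigma=0.0, b0_amplitude_ppm=0.3), seed=5)
zvol, wvol = simulate_scan(truth, schedule, scan_seed=1)

b0map, qc = fit_b0_map(wvol)
field_err = np.abs(b0map.delta_b0_ppm - truth.b0_map_ppm)[truth.mask]
print(f"WASABI fit on {len(qc)} voxels; max |recovered - true B0| = {field_err.max():.2e} ppm")

corrected = correct_b0(zvol, b0map)
offsets = schedule.as_array()
inner = np.abs(offsets) <= 5.0
worst = 0.0
for name, mask in region_masks(truth).items():
    expected = forward_zspectrum(truth.region_params[name], offsets)
    for iy, ix in np.argwhere(mask):
        worst = max(worst, np.max(np.abs(corrected.signal[iy, ix][inner] - expected[inner])))
print(f"shift-then-correct roundtrip: max |corrected - unshifted truth| = {worst:.2e}")

# The corrected spectra match the unshifted ground truth to <1e-3 across the
# dense +/-5 ppm region, which is what downstream fitting and MTRasym assume.
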