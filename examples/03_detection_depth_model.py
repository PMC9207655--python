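"""Detection-limit model: how deep can a single cell be seen?

Calibrates the single-cell yield so that the NIR system just detects a
cell at 3.5-mm depth with the compact 0.3-mm probe (the flow-phantom
anchor), then predicts maximum detection depths across separations,
checks robustness to +-50% cell brightness, and verifies the laser-safety
arithmetic for spreading the beam over a 3-mm spot.
"""

import difcsim as d
from difcsim import contrast as C
from difcsim import jacobian as J

volume = d.VoxelVolume()
config = d.MCConfig(n_photons=200_000, seed=3)

maps = {s: J.sensitivity_map("780", s, volume, config) for s in (0.3, 1.0, 3.0)}
model = C.calibrate_eta_cell(maps[0.3], C.DetectionModel(), 3.5)
print(f"calibrated eta_cell = {model.eta_cell:.1f} (arb. yield units)")
print(f"detection floor     = {model.snr_floor_db:.1f} dB (peak >= 5x noise)\n")

curves = {s: C.contrast_curve(m, model) for s, m in maps.items()}
for s, c in curves.items():
    depth = C.max_detection_depth(c, model)
    print(f"SDS {s} mm: maximum detection depth = {depth} mm")

bright = C.brightness_perturbation_sweep(model, curves, factors=(0.5, 1.5))
print(f"\n+-50% brightness moves the depth by at most "
      f"{bright.delta_mm.abs().max():.2f} mm")

irr, ok = C.irradiance_check(20.0, 3.0)
print(f"20 mW over a 3-mm spot: {irr:.0f} mW/cm^2 "
      f"({'within' if ok else 'exceeds'} the 300 mW/cm^2 IEC skin limit)")
# Larger separations extend the reach beyond the compact probe's depth;
# brightness uncertainty shifts the limit by up to ~1 mm, and the 3-mm
# illumination spot keeps the exposure within the IEC limit.
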