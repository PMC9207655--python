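# difcsim

Monte Carlo modeling toolkit for **diffuse fluorescence flow cytometry**
(DiFC): detecting single fluorescently labeled cells moving through blood
vessels a few millimeters under the skin, using a pair of surface fiber
probes and diffusely scattered light.

The package exists to answer a probe-design question.  DiFC works in mice,
where target vessels are under a millimeter deep.  Suitable human vessels
(wrist/forearm) are 2–4 mm deep, and both the cell signal and its contrast
against tissue autofluorescence collapse with depth.  `difcsim` quantifies
that collapse and the design levers against it — laser wavelength
(488/640/780 nm) and source–detector separation (SDS) — and simulates the
full measurement including the peak-detection pipeline.

## What it computes

**Photon transport.**  Weighted-packet voxel Monte Carlo in a homogeneous
50 × 50 × 50 mm tissue cube (0.25-mm voxels, Henyey–Greenstein scattering
with g = 0.9, n = 1.37, Fresnel surface, 5-ns time gate), yielding fluence
Green's functions G(r_j, r_s) per launched photon.  Closed-form diffusion
theory (infinite medium and extrapolated-boundary semi-infinite) is built
in as an independent validation oracle.

**Sensitivity (Jacobian) maps.**  Under the first-order Born
approximation the detected fluorescence perturbation from voxel j is

    W(r_j; r_s, r_d) = G_ex(r_j, r_s) · G_em(r_d, r_j) · dV ,

with the emission Green's function obtained by one adjoint run launched
from the detector (reciprocity).  Midline depth profiles of W across SDS
and wavelength reproduce the classic trade-off: separating the fibers
pushes the depth of maximum sensitivity deeper while the absolute
sensitivity falls by orders of magnitude.

**Detection limit.**  A cell is a sub-voxel point of yield η_cell on the
probe midline; autofluorescence is a homogeneous yield η_af per voxel.
With instrument noise σ = 0.2 % of the background level and a 5×-noise
threshold (SNR floor 20 log₁₀ 5 = 13.9 dB), the peak-to-noise ratio

    SNR(d) = 20 log₁₀ [ η_cell W(midline, d) / (0.002 · η_af Σ W) ]

is gain-free (PMT gain cancels between peak and background).  η_cell is
never measured directly; it is calibrated so the NIR system just detects
a cell at 3.5-mm depth with the compact 0.3-mm probe — the flow-phantom
anchor — after which the model predicts maximum detection depths for
every other configuration, their sensitivity to ±50 % errors in μa, μs
and cell brightness, and the IEC skin-exposure arithmetic.

**Synthetic experiments.**  A flow-phantom generator emulates microspheres
(10³/ml, 50 µl/min, 0.254-mm tubing → ≈16.4 mm/s) crossing two probes,
producing gain-matched two-channel traces with ground truth; the analysis
pipeline applies 5-s moving-median background subtraction, 1-min MAD noise
estimation, 5×-noise peak candidates, and forward/reverse two-probe
matching on transit time, amplitude and width.

## Worked example

```python
import difcsim as d
from difcsim import jacobian as J, contrast as C

volume = d.VoxelVolume()                       # 50-mm cube, 0.25-mm voxels
config = d.MCConfig(n_photons=200_000, seed=3) # desk-scale budget

maps = {s: J.sensitivity_map("780", s, volume, config) for s in (0.3, 1.0, 3.0)}
model = C.calibrate_eta_cell(maps[0.3], C.DetectionModel(), 3.5)
for s, m in maps.items():
    depth = C.max_detection_depth(C.contrast_curve(m, model), model)
    print(f"SDS {s} mm: maximum detection depth = {depth} mm")
```

prints (exact values depend on the photon budget and seed):

```
SDS 0.3 mm: maximum detection depth = 3.375 mm
SDS 1.0 mm: maximum detection depth = 3.625 mm
SDS 3.0 mm: maximum detection depth = 3.875 mm
```

i.e. once the NIR model is anchored to the phantom result at the compact
probe, moving to millimeter-scale separations extends the reach toward the
2–4-mm depths of human wrist vessels.  The `examples/` directory holds one
short script per capability (transport validation, depth profiles,
detection-depth model, synthetic two-probe run); each prints its numbers
with a line on what they mean.  A thin CLI (`difc fluence | jacobian |
contrast | simulate | detect | reproduce`) wraps the same functions for
shell use, and `difc reproduce` writes the full CSV report bundle.

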