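# Methods

This note documents the models, numerical choices and limitations behind
`difcsim`, in the order the computation flows: photon transport → Born
sensitivity → detection limit → synthetic traces → detection pipeline.

## Photon transport

**Medium and grid.**  A homogeneous cube, default 50 mm per side with
0.25-mm isotropic voxels (200³).  z = 0 is the illuminated surface, z
increases into the tissue, x runs along the source–detector axis, y along
the vessel/flow axis.  Voxel i spans [iΔ, (i+1)Δ) (half-open, 0-based);
positions are in mm from the cube corner.  Optical-property presets
(absorption μa, scattering μs in mm⁻¹; anisotropy g = 0.9; index n = 1.37)
represent human arm tissue at the three DiFC laser lines:

| preset | μa (mm⁻¹) | μs (mm⁻¹) |
|--------|-----------|-----------|
| 488    | 0.05      | 25        |
| 640    | 0.025     | 10        |
| 780    | 0.002     | 7         |

Excitation and emission share one property set per wavelength: the
fluorophore red shift is small against the uncertainty of literature
properties.

**Transport scheme.**  Weighted packets: exponential scattering steps of
mean 1/μs, continuous absorption weighting e^(−μa·ℓ) along the path,
Henyey–Greenstein deflection each scattering event.  The fluence estimator
is the exact path-length integral of the decaying weight per voxel,
∫ w dl = (w₀ − w₁)/μa, normalized by (launched photons × voxel volume) to
mm⁻² per photon.  Packet termination: escape through the top surface after
an unpolarized Fresnel test (n = 1.37 against air; total internal
reflection beyond ≈46.9°), absorbing side and bottom faces (the cube is
large enough that side losses are negligible at the depths studied), a
5-ns time-of-flight gate, and Russian roulette below weight 10⁻⁴ with
survival probability 0.1 (kills and boosts are folded into the absorbed
tally so absorbed + escaped + in-flight equals launched weight to
floating-point precision — asserted at 10⁻⁶ relative).  The source is a
pencil beam normal to the surface at the fiber position; fiber numerical
aperture and the instrument's 8-fiber collection ring are idealized to a
point source and point detector.  No specular launch loss is applied (the
fiber is modeled in contact with the medium).

**RNG and determinism.**  Each photon draws from its own xorshift64 stream
seeded by a splitmix64 mix of (run seed, photon index), so tallies are
independent of execution order and bit-identical across repeat runs.

**Validation.**  The engine is checked against closed-form diffusion
theory (infinite medium: e^(−μeff·r)/(4πDr) with D = 1/(3(μa+μs(1−g))))
at five transport mean free paths for all three presets; agreement is
within a few percent, comfortably inside the 15 % acceptance band.  The
oracle runs use an "infinite" geometry mode (no boundaries, tallies only
inside the grid), a raised roulette threshold (10⁻²) and, at 780 nm, a
10-ns gate — the closed-form oracle is continuous-wave, and at
μa = 0.002 mm⁻¹ a 5-ns gate would truncate a visible share of the CW
fluence.  The semi-infinite production geometry keeps the 5-ns default,
where escape dominates termination.

## Born sensitivity maps

W(r_j) = G_ex(r_j, r_s) · G_em_adjoint(r_j) · dV, with the emission
Green's function computed by a single forward run launched from the
detector (reciprocity).  The Ω_j integral is realized as the voxel product
times dV (single-voxel quadrature), matching the voxelized Green's
functions.  Probe pairs sit on the top-face center ± SDS/2 along x; since
the homogeneous cube is mirror-symmetric about that center, sweeps reuse
the source-launched field's exact x-flip as the detector field (a
statistically equivalent, cost-halving shortcut; reciprocity tests compute
both fields independently).  The adjoint identity itself is validated on a
10³-voxel medium against brute-force forward runs — emission launched
isotropically from probe voxels and tallied at the detector voxel — within
3× the combined MC standard error; the isotropic source/detector pair is
the setting in which voxel-fluence reciprocity is exact.

**Midline profiles.**  Depth profiles are read along the vertical voxel
column under the source–detector midpoint; when the midpoint falls on a
voxel boundary (it always does for a centered pair) the two adjacent
columns are averaged per axis, avoiding a half-voxel bias.  Report range
0–5 mm; ties in depth-of-maximum break toward the shallower voxel.
Profile collections are normalized by their single global maximum, which
the simulations place at the (0.3-mm SDS, 488-nm) combination.

## Detection-limit model

Peak = η_cell · W(midline, d) for a sub-voxel point cell in the voxel
containing depth d; background = η_af · ΣW for homogeneous
autofluorescence; noise is additive zero-mean Gaussian with
σ = noise_fraction (0.2 %) × background, constant over a trace (the
fraction is the instrument's measured characteristic; Gaussianity is this
package's declared choice).  The background level itself is set by the
gain-matching convention at baseline_fraction (10 %) of full scale; every
detectability statement is invariant to that choice and to PMT gain.  The
floor is threshold_multiple (5) × noise, i.e. 20 log₁₀ 5 ≈ 13.98 dB
(printed as 13.9).  Maximum detection depth is the deepest voxel-center
depth whose SNR clears the floor — all reported depths are multiples of
0.25 mm.

**Calibration.**  η_cell and η_af are not published quantities; the model
anchors η_cell by bisection (0.1 % relative) so the 780-nm, 0.3-mm-SDS
configuration detects a cell at 3.5-mm depth (the NIR phantom result).
The 3.5-mm target is mapped to the *nearest* voxel center, 3.375 mm (ties
break shallow).  The half-open containing-voxel alternative (3.625 mm) was
rejected: calibration places the anchor voxel exactly on the detection
floor, and with that convention the 3-mm-SDS baseline crossing also landed
within ~0.05 dB of the floor, so quantized detection depths flipped a full
voxel under Monte Carlo noise at any affordable budget.  The
nearest-center convention keeps ~0.5-dB margins at the working points and
makes reported depths budget-stable.  An overall rescaling of W cancels
between peak and noise, so the calibrated η_cell is invariant to the
Jacobian's arbitrary normalization (tested); only the ratio η_cell/η_af
matters.

**Sweeps.**  The SDS grid {0.3, 1, 2, 3, 5, 6, 12} mm covers every
separation named in the study.  SDS selection for deep cells uses the
gain- and η-free proxy W(midline, d)/ΣW; at 780 nm the 2-mm separation
maximizes it for a 3-mm-deep cell and has the best median over 2–4 mm —
the 1-mm separation is within ~4 %, so sweep budgets give the 1- and 2-mm
maps the most photons.  Robustness sweeps rebuild the Green's functions
with μa and μs independently scaled (3×3 grid by default; the ±50 %
corners for reports) while the calibrated model is held fixed; brightness
robustness rescales η_cell without MC reruns (Born linearity: exactly
20 log₁₀ 2 ≈ 6.0206 dB per doubling).  In this model the worst
optical-property corner (μa×1.5, μs×0.5 at 3-mm SDS) shifts the
continuous floor crossing by ~0.6 mm; voxel quantization reports that as
0.5 mm for most seeds and occasionally 0.75 mm — the quantity sits at the
boundary of the half-voxel comparison tolerance.

**Extended source.**  The IEC variant spreads the excitation over a
hexagonally packed grid of ≥37 pencil-beam positions covering the spot
(photons cycled round-robin, budget rounded to a multiple of the point
count so weights are exactly equal); irradiance arithmetic checks
power/(π(d/2)²) against the 300 mW/cm² NIR skin limit.

## Synthetic flow phantom

Defaults are the reference experiment: 10³ microspheres/ml at 50 µl/min
through 0.254-mm-ID tubing → Poisson arrivals at 50 min⁻¹ and a mean speed
of ≈16.4 mm/s; vessel depths 0.75–4 mm; two probes 3 mm apart along the
flow; 2-kHz sampling; 60-s traces.  Sampling rate, tubing ID and probe
spacing are package defaults (config-exposed), not reported instrument
values.  A particle's pulse is the sensitivity map sampled along the flow
line at the vessel depth, time-scaled by the flow speed, so deeper vessels
give lower and wider pulses whose maxima agree with the detection-limit
model by construction.  Channels are background + pulses + Gaussian noise
under the same gain-matching convention; probe 2 sees each event delayed
by separation/speed.  Particle brightness is deterministic by default; an
optional log-normal spread (CV 25 %) is off by default.  Ground truth
(arrival times, per-probe amplitudes, true SNR) travels with the trace.

Not emulated: pulsatile flow, motion and photoplethysmography artifacts,
cell clusters, depth-dependent background structure.  Passing pipeline
tests on these traces therefore demonstrates algorithmic correctness under
the stated noise model, not robustness to in-vivo artifacts.

## Detection pipeline

5-s centered moving-median subtraction (windows truncate at edges; median
is robust to sub-second pulses); local noise as moving MAD × 1.4826 over a
1-min window (a plain moving SD is a config switch); a 20-ms moving-average
pre-filter; one candidate per maximal contiguous excursion above 5× the
local noise, summarized at its maximum with FWHM width by linear
interpolation; candidates touching a trace boundary are flagged and
excluded from rate statistics.  Matching is greedy one-to-one in time
order: |transit| within [0.25×, 4×] of separation/speed, amplitude and
width ratios within 3×, ambiguity resolved by the smallest transit
deviation from the prior; the transit sign sets forward/reverse.  The
matching tolerances and the pre-filter width are declared defaults (the
instrument's exact values are not public), all exposed in
`PipelineParams`.

Because the noise estimate is taken on the unsmoothed subtracted signal
while thresholding acts on the pre-filtered one, the effective threshold
on smoothed noise is far above 5σ and event-free traces produce
essentially zero false alarms — consistent with the reported rate of
≤0.01/min.  The 1-min noise window varies slowly, so by default it is
evaluated every 25th sample and linearly interpolated (`decimation=1`
recovers the exact per-sample estimate; the two agree within ~2 %).

## Problem sizes

The reference simulation protocol is 10⁸ photons per Green's function.
The package's tests run at 2.5×10⁵–8×10⁵ photons per Green's function
(the 1- and 2-mm NIR separations get the larger budgets because their
3-mm-depth ranking is the closest call), and `scripts/acceptance.py` at
3.5×10⁵–1.4×10⁶; at these budgets the midline statistics that drive every
reported quantity have ~1–3 % Monte Carlo error.  Oracle comparisons use
smaller dedicated runs sized to keep shell-averaged errors well inside
their acceptance bands.  False-alarm characterization uses 600 one-minute
noise-only traces.

## Known limitations

Homogeneous tissue (no skin layering, no vessel-localized hemoglobin
absorption); point source/detector idealization of the fiber probe; one
property set for excitation and emission; CW only (no lifetime, no
polarization); forward model only (no tomographic inversion); detection
depths quantized to the 0.25-mm grid, so threshold-crossing quantities
carry an irreducible half-voxel granularity.
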