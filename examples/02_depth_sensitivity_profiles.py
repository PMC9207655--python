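"""How source-detector separation shapes depth sensitivity.

Builds adjoint Born sensitivity maps at 780 nm for a compact probe
(0.3-mm SDS) and a separated pair (3-mm SDS), then prints where each is
most sensitive and how fast sensitivity decays with depth.  Larger
separations probe deeper but collect far less light overall.
"""

import difcsim as d
from difcsim import jacobian as J

volume = d.VoxelVolume()
config = d.MCConfig(n_photons=150_000, seed=2)

for sds in (0.3, 3.0):
    smap = J.sensitivity_map("780", sds, volume, config)
    prof = J.midline_depth_profile(smap)
    dmax = J.depth_of_max_sensitivity(prof)
    print(f"SDS {sds} mm:")
    print(f"  depth of maximum sensitivity : {dmax:.3f} mm")
    print(f"  midline maximum (arb. units) : {prof.values.max():.3e}")
    at3 = prof.values[12]  # voxel containing 3-mm depth
    print(f"  sensitivity at 3 mm depth    : {at3:.3e}"
          f"  ({at3 / prof.values.max():.2e} of its own max)")
# The compact probe is overwhelmingly sensitive to the first millimeter;
# the separated pair trades absolute signal for a deeper sensitivity
# maximum - the design lever for reaching 2-4-mm human vessels.
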