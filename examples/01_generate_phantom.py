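"""Generate a synthetic phase-contrast acquisition of a gothic-arch aorta.

Builds an arch centerline with a sharp localized curvature peak, lofts a
tapering lumen surface, attaches a mass-conserving parabolic velocity
field, and voxelizes it at 2 mm / 20 cardiac frames with 5%-of-VENC
Gaussian noise — the resolution regime of pediatric 4D-flow scans.
"""

import numpy as np

from aortaflow.phantom import (
    AcquisitionSpec,
    CenterlineSpec,
    FlowProfileKind,
    RadiusProfileSpec,
    TemporalWaveform,
    VelocityModel,
    default_bounding_box,
    make_centerline,
    make_surface,
    voxelize,
)

# A kink of 0.11 /mm bends on a 9 mm radius: an 8 mm lumen would fold
# there, so the tube is kept at 7 mm (sharper kinks need narrower vessels)
spec = CenterlineSpec(
    kind="gothic_arch", length=190.0, arch_radius=14.0,
    gothic_kink_curvature=0.11, point_spacing=1.0,
)
centerline = make_centerline(spec)
radius = RadiusProfileSpec(base_radius=7.0, taper_rate=0.008)
surface = make_surface(centerline, radius)
velocity = VelocityModel(centerline, radius, flow_rate_l_min=3.6,
                         profile=FlowProfileKind("poiseuille"))

acq = AcquisitionSpec(voxel_spacing=2.0, n_frames=20, venc=150.0,
                      noise_sd_fraction=0.05, seed=7)
field = voxelize(velocity, acq, TemporalWaveform.raised_cosine(20),
                 default_bounding_box(centerline, 8.0))

peak_speed = np.linalg.norm(field.frame(7), axis=-1).max()
print(f"centerline: {len(centerline.points)} points, {centerline.length:.0f} mm")
print(f"surface: {len(surface.vertices)} vertices, watertight={surface.is_watertight}")
print(f"field: {field.n_frames} frames on a {field.grid_shape} grid at {field.spacing} mm")
print(f"peak sampled speed at systole: {peak_speed:.2f} m/s (VENC {acq.venc/100:.2f} m/s)")
# The peak speed stays below VENC, so the synthetic scan is alias-free;
# background voxels carry pure Gaussian noise, as static tissue does.
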