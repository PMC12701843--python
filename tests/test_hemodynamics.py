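"""Conduit-function metrics: flow, SAW pressure drop, comparators."""

import math

import numpy as np
import pytest

from aortaflow.geometry import RegionLandmarks, partition_regions
from aortaflow.hemodynamics import (
    AxialProfile,
    PlaneOutsideLumenError,
    circular_cross_section,
    delta_pd,
    detect_peak_systole,
    flow_rate,
    pd_profile,
    peak_pd,
    region_hemodynamics,
    sample_cross_section,
    saw_pd,
    simplified_bernoulli,
    viscous_dissipation,
    voxel_lumen_mask,
    wall_shear_stress,
)
from aortaflow.phantom import (
    CenterlineSpec,
    FlowProfileKind,
    RadiusProfileSpec,
    VelocityModel,
    make_centerline,
    make_landmarks,
    make_surface,
)
from conftest import TubeBundle, flow_for_mean_speed

MID = np.array([0.0, 0.0, 60.0])
EZ = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# sampling and flow rate
# ---------------------------------------------------------------------------

def test_sample_cross_section_plug_alignment(plug_tube):
    cs = sample_cross_section(plug_tube.velocity, MID, EZ, plug_tube.surface, 0.5)
    v = cs.velocities[cs.lumen_mask]
    assert np.allclose(v[:, 2], 1.0, atol=1e-9)
    assert np.allclose(v[:, :2], 0.0, atol=1e-12)


def test_sample_cross_section_area_converges(poiseuille_tube):
    a1 = sample_cross_section(
        poiseuille_tube.velocity, MID, EZ, poiseuille_tube.surface, 1.0
    ).area_mm2
    a2 = sample_cross_section(
        poiseuille_tube.velocity, MID, EZ, poiseuille_tube.surface, 0.5
    ).area_mm2
    assert abs(a2 - a1) / a2 < 0.01


def test_sample_cross_section_outside_rejected(poiseuille_tube):
    with pytest.raises(PlaneOutsideLumenError):
        sample_cross_section(
            poiseuille_tube.velocity, [0, 0, -50.0], EZ, poiseuille_tube.surface, 1.0
        )


@pytest.mark.parametrize(
    "profile, v_mean, expected_q",
    [("plug", 1.0, 18.85), ("poiseuille", 0.5, 9.42)],
)
def test_flow_rate_closed_forms(profile, v_mean, expected_q):
    tube = TubeBundle(v_mean=v_mean, profile=profile)
    cs = circular_cross_section(tube.velocity, MID, EZ, 10.0, 0.25)
    assert flow_rate(cs) == pytest.approx(expected_q, rel=0.003)


def test_flow_rate_antisymmetric_under_normal_flip(poiseuille_tube):
    cs = circular_cross_section(poiseuille_tube.velocity, MID, EZ, 10.0, 0.5)
    assert flow_rate(cs.reversed()) == pytest.approx(-flow_rate(cs))


# ---------------------------------------------------------------------------
# peak systole
# ---------------------------------------------------------------------------

def test_detect_peak_systole_raised_cosine(poiseuille_tube):
    fld = poiseuille_tube.field(voxel_spacing=2.0, n_frames=20)
    assert detect_peak_systole(fld) == 7


def test_detect_peak_systole_single_frame(poiseuille_field):
    assert detect_peak_systole(poiseuille_field) == 0


def test_detect_peak_systole_tie_returns_earliest():
    from aortaflow.phantom import VelocityField4D

    data = np.zeros((12, 4, 4, 4, 3), dtype=np.float32)
    data[5, ..., 2] = 1.0
    data[9, ..., 2] = 1.0
    fld = VelocityField4D(data, 2.0, np.zeros(3), np.arange(12.0))
    assert detect_peak_systole(fld) == 5


def test_detect_peak_systole_all_zero_errors():
    from aortaflow.phantom import VelocityField4D

    fld = VelocityField4D(
        np.zeros((3, 4, 4, 4, 3), dtype=np.float32), 2.0, np.zeros(3), np.arange(3.0)
    )
    with pytest.raises(ValueError):
        detect_peak_systole(fld)


# ---------------------------------------------------------------------------
# SAW pressure drop
# ---------------------------------------------------------------------------

def test_saw_plug_closed_form(plug_tube):
    """Plug at 1 m/s: PD_A = rho v^2 / 2 = 530 Pa = 3.98 mm Hg."""
    cs = circular_cross_section(plug_tube.velocity, MID, EZ, 10.0, 0.25)
    assert saw_pd(cs, rho=1060.0) == pytest.approx(3.98, rel=0.02)


def test_saw_poiseuille_closed_form(poiseuille_tube):
    """Parabolic at mean 0.5 m/s: PD_A = rho V^2 = 265 Pa = 1.99 mm Hg."""
    cs = circular_cross_section(poiseuille_tube.velocity, MID, EZ, 10.0, 0.25)
    assert saw_pd(cs, rho=1060.0) == pytest.approx(1.99, rel=0.02)


def test_saw_scales_quadratically(poiseuille_tube):
    cs = circular_cross_section(poiseuille_tube.velocity, MID, EZ, 10.0, 0.5)
    scaled = circular_cross_section(
        lambda p: 3.0 * poiseuille_tube.velocity(p), MID, EZ, 10.0, 0.5
    )
    assert saw_pd(scaled) == pytest.approx(9.0 * saw_pd(cs), rel=1e-9)


def test_saw_undefined_below_flow_threshold(poiseuille_tube):
    cs = circular_cross_section(
        lambda p: 1e-4 * poiseuille_tube.velocity(p), MID, EZ, 10.0, 0.5
    )
    assert math.isnan(saw_pd(cs, q_min_l_min=0.1))


# ---------------------------------------------------------------------------
# Simplified Bernoulli
# ---------------------------------------------------------------------------

def test_bernoulli_exact_and_clinical(plug_tube):
    cs = circular_cross_section(plug_tube.velocity, MID, EZ, 10.0, 0.25)
    assert simplified_bernoulli(cs) == pytest.approx(3.98, abs=0.01)
    assert simplified_bernoulli(cs, clinical_coefficient=True) == pytest.approx(4.0)


def test_bernoulli_twice_saw_on_parabolic(poiseuille_tube):
    """The factor-2 overestimation: peak-velocity Bernoulli vs full-profile
    SAW on parabolic flow."""
    cs = circular_cross_section(poiseuille_tube.velocity, MID, EZ, 10.0, 0.25)
    assert simplified_bernoulli(cs) / saw_pd(cs) == pytest.approx(2.0, abs=0.02)


@pytest.mark.parametrize("profile,kw", [
    ("plug", {}),
    ("poiseuille", {}),
    ("skewed", {"skew_eccentricity": 0.6}),
])
def test_bernoulli_dominates_saw(profile, kw):
    """Exact-mode Bernoulli >= SAW for any profile; equality only for plug."""
    tube = TubeBundle(v_mean=0.5, profile=profile)
    if kw:
        tube.velocity = VelocityModel(
            tube.centerline, tube.radius_spec, tube.flow_l_min,
            FlowProfileKind(profile, **kw),
        )
    cs = circular_cross_section(tube.velocity, MID, EZ, 10.0, 0.25)
    b, s = simplified_bernoulli(cs), saw_pd(cs)
    if profile == "plug":
        assert b == pytest.approx(s, rel=1e-6)
    else:
        assert b > s * 1.5


# ---------------------------------------------------------------------------
# axial profile, delta and peak
# ---------------------------------------------------------------------------

def test_pd_profile_constant_on_straight_tube(poiseuille_tube):
    stations = poiseuille_tube.centerline.resample(4.0)
    prof = pd_profile(
        poiseuille_tube.velocity, stations, poiseuille_tube.surface, in_plane_step=0.5
    )
    pd = prof.pd_a_mmhg[np.isfinite(prof.pd_a_mmhg)]
    assert (pd.max() - pd.min()) / pd.mean() < 0.02
    q = prof.q_l_min[np.isfinite(prof.q_l_min)]
    assert np.allclose(q, poiseuille_tube.flow_l_min, rtol=0.02)


def test_pd_profile_rises_through_taper():
    cl = make_centerline(CenterlineSpec(kind="straight", length=160.0, point_spacing=2.0))

    def radius(s):
        s = np.asarray(s, float)
        t = np.clip((s - 40.0) / 80.0, 0, 1)
        return 10.0 - 3.0 * (0.5 - 0.5 * np.cos(math.pi * t))

    surf = make_surface(cl, radius)
    vel = VelocityModel(cl, radius, flow_for_mean_speed(0.4, 10.0))
    prof = pd_profile(vel, cl.resample(4.0), surf, in_plane_step=0.5)
    inside = (prof.s >= 40.0) & (prof.s <= 120.0)
    pd = prof.pd_a_mmhg[inside]
    assert np.all(np.diff(pd[np.isfinite(pd)]) > -1e-6)


def _flat_profile(values, s=None):
    values = np.asarray(values, dtype=float)
    s = np.linspace(0, 200, len(values)) if s is None else s
    return AxialProfile(
        s=s, q_l_min=np.full_like(values, 5.0), pd_a_mmhg=values,
        v_max=np.ones_like(values), frame=0,
    )


def _partition_200():
    from aortaflow.geometry import Centerline

    pts = np.zeros((101, 3))
    pts[:, 2] = np.linspace(0, 200, 101)
    cl = Centerline.from_points(pts)
    return partition_regions(cl, RegionLandmarks(0, 50, 90, 140, 200))


def test_delta_pd_modes():
    part = _partition_200()
    flat = _flat_profile(np.full(101, 2.0))
    assert delta_pd(flat, part, "TA") == 0.0
    assert delta_pd(flat, part, "TA", mode="max_minus_start") == 0.0

    rising = _flat_profile(np.linspace(0, 4, 101))  # 2 mm Hg over TA_DA1 (90 mm span)
    d = delta_pd(rising, part, "TA_DA1")
    assert d == pytest.approx(
        rising.pd_a_mmhg[69] - rising.pd_a_mmhg[25]
    )  # stations at s=138 and 50
    assert delta_pd(rising, part, "TA_DA1", mode="max_minus_start") == pytest.approx(d)

    falling = _flat_profile(np.linspace(4, 0, 101))
    assert delta_pd(falling, part, "AA") < 0  # aneurysm-like decline
    assert delta_pd(falling, part, "AA", mode="max_minus_start") == 0.0


def test_peak_pd_location_and_tie_rule():
    part = _partition_200()
    vals = np.zeros(101)
    vals[35] = 3.0  # s = 70, inside TA
    prof = _flat_profile(vals)
    peak, loc = peak_pd(prof, part, "TA")
    assert peak == 3.0 and loc == pytest.approx(70.0)
    flat = _flat_profile(np.full(101, 1.5))
    _, loc = peak_pd(flat, part, "DA1")
    assert loc == pytest.approx(90.0)  # most proximal on ties


def test_region_errors_when_no_defined_stations():
    part = _partition_200()
    vals = np.full(101, np.nan)
    vals[:20] = 1.0  # only AA defined
    prof = _flat_profile(vals)
    with pytest.raises(ValueError, match="DA2"):
        delta_pd(prof, part, "DA2")


# ---------------------------------------------------------------------------
# wall shear stress
# ---------------------------------------------------------------------------

def test_wss_poiseuille_closed_form(poiseuille_tube, poiseuille_field):
    """Poiseuille wall shear 4 mu V / R = 0.8 Pa at mu = 4 mPa s."""
    wm = wall_shear_stress(
        poiseuille_field.interpolator(0), poiseuille_tube.surface,
        mu=0.004, wall_step=0.5,
    )
    z = poiseuille_tube.surface.vertices[:, 2]
    interior = wm.valid & (np.abs(z - 60.0) < 40.0)
    assert interior.sum() > 1000
    assert np.nanmean(wm.wss_pa[interior]) == pytest.approx(0.8, rel=0.15)


def test_wss_linear_in_viscosity(poiseuille_tube):
    wm1 = wall_shear_stress(poiseuille_tube.velocity, poiseuille_tube.surface,
                            mu=0.004, wall_step=0.5)
    wm2 = wall_shear_stress(poiseuille_tube.velocity, poiseuille_tube.surface,
                            mu=0.008, wall_step=0.5)
    sel = wm1.valid & wm2.valid
    assert np.allclose(wm2.wss_pa[sel], 2.0 * wm1.wss_pa[sel], rtol=1e-9)


# ---------------------------------------------------------------------------
# viscous dissipation
# ---------------------------------------------------------------------------

def test_vd_poiseuille_q_dp_identity(poiseuille_tube, poiseuille_field):
    """Integrated dissipation equals 8 pi mu V^2 L for Poiseuille flow."""
    mask = voxel_lumen_mask(poiseuille_field, poiseuille_tube.surface)
    _, vd = viscous_dissipation(
        poiseuille_field.frame(0), mask, mu=0.004, voxel_spacing=1.0
    )
    expected = 8 * math.pi * 0.004 * 0.5**2 * 0.12  # L = 0.12 m
    assert vd == pytest.approx(expected, rel=0.20)


def test_vd_zero_for_rigid_translation():
    v = np.zeros((8, 8, 8, 3))
    v[..., 0] = 0.7
    mask = np.ones((8, 8, 8), dtype=bool)
    phi, vd = viscous_dissipation(v, mask, voxel_spacing=1.0)
    assert np.allclose(phi, 0.0)
    assert vd == 0.0


def test_vd_quadratic_scaling(poiseuille_field, poiseuille_tube):
    mask = voxel_lumen_mask(poiseuille_field, poiseuille_tube.surface)
    _, vd1 = viscous_dissipation(poiseuille_field.frame(0), mask, voxel_spacing=1.0)
    _, vd2 = viscous_dissipation(2.0 * poiseuille_field.frame(0), mask, voxel_spacing=1.0)
    assert vd2 == pytest.approx(4.0 * vd1, rel=1e-6)


def test_vd_rejects_thin_lumen():
    v = np.zeros((10, 10, 10, 3))
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask[:, :, 4:6] = True  # 2 voxels across
    with pytest.raises(ValueError, match="thinner"):
        viscous_dissipation(v, mask, voxel_spacing=1.0)


# ---------------------------------------------------------------------------
# regional summary
# ---------------------------------------------------------------------------

def test_region_hemodynamics_uniform_flow():
    part = _partition_200()
    prof = _flat_profile(np.full(101, 2.0))

    class S:
        bsa = 1.0

    rh = region_hemodynamics(prof, part, subject=S())
    for name in ("AA", "TA", "DA1", "DA2", "TA_DA1"):
        assert rh.regions[name]["q_mean_per_bsa"] == pytest.approx(5.0)
        assert rh.regions[name]["delta_pd_mmhg"] == 0.0


def test_region_hemodynamics_combined_segment_definition():
    part = _partition_200()
    prof = _flat_profile(np.linspace(0, 4, 101))
    rh = region_hemodynamics(prof, part)
    expect = prof.pd_a_mmhg[69] - prof.pd_a_mmhg[25]
    assert rh.regions["TA_DA1"]["delta_pd_mmhg"] == pytest.approx(expect)
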