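"""Phantom generator: centerlines, surfaces, analytic fields, voxelization."""

import math
import warnings

import numpy as np
import pytest

from aortaflow.geometry import menger_curvature
from aortaflow.phantom import (
    AcquisitionSpec,
    CenterlineSpec,
    FlowProfileKind,
    RadiusProfileSpec,
    SubjectRecord,
    TemporalWaveform,
    VelocityModel,
    analytic_curvature,
    default_bounding_box,
    ground_truth_manifest,
    make_centerline,
    make_cohort,
    make_landmarks,
    make_surface,
    voxelize,
)
from aortaflow.cohort_stats import compare_groups
from conftest import TubeBundle, flow_for_mean_speed


# ---------------------------------------------------------------------------
# centerlines
# ---------------------------------------------------------------------------

def test_straight_centerline_collinear():
    cl = make_centerline(CenterlineSpec(kind="straight", length=100.0, point_spacing=1.0))
    assert len(cl.points) == 101
    # collinear: zero curvature everywhere
    assert np.all(analytic_curvature(CenterlineSpec(kind="straight", length=100.0), cl.s) == 0)
    chords = cl.points[-1] - cl.points[0]
    assert np.linalg.norm(chords) == pytest.approx(100.0)


def test_arch_curvature_is_inverse_radius():
    spec = CenterlineSpec(kind="arch", length=200.0, arch_radius=12.5)
    assert analytic_curvature(spec, np.array([100.0]))[0] == pytest.approx(0.08)
    cl = make_centerline(spec)
    # tangent continuity: consecutive tangents never turn faster than the
    # arc's own rate (kappa x spacing = 0.08 rad), i.e. no extra kinks
    dots = np.einsum("ij,ij->i", cl.tangents[:-1], cl.tangents[1:])
    assert dots.min() > math.cos(0.08 * spec.point_spacing) - 1e-4


def test_gothic_arch_peak_curvature():
    """The localized kink reaches the specified peak, at the scale of
    angular reconstructed arches (~0.22 /mm)."""
    spec = CenterlineSpec(
        kind="gothic_arch", length=200.0, arch_radius=20.0, gothic_kink_curvature=0.22
    )
    s = np.linspace(0, 200, 4001)
    assert analytic_curvature(spec, s).max() == pytest.approx(0.22, rel=1e-6)


def test_centerline_spec_validation():
    with pytest.raises(ValueError):
        CenterlineSpec(kind="straight", length=-1.0)
    with pytest.raises(ValueError):
        CenterlineSpec(kind="arch", length=100.0, arch_radius=-5.0)
    with pytest.raises(ValueError):
        CenterlineSpec(kind="gothic_arch", length=200.0, arch_radius=20.0,
                       gothic_kink_curvature=0.01)  # below base arch curvature


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def test_surface_straight_tube_rings(poiseuille_tube):
    mesh = poiseuille_tube.surface
    assert mesh.is_watertight
    ring = mesh.vertices[: 64]
    assert np.allclose(np.linalg.norm(ring[:, :2], axis=1), 10.0, atol=1e-6)


def test_surface_stenosis_and_aneurysm_extremes():
    cl = make_centerline(CenterlineSpec(kind="straight", length=120.0, point_spacing=2.0))
    sten = make_surface(cl, RadiusProfileSpec(10.0, stenoses=((60.0, 0.5, 20.0),)))
    radii = np.linalg.norm(sten.vertices[:-2][:, :2], axis=1)
    assert radii.min() == pytest.approx(5.0, rel=1e-6)
    aneu = make_surface(cl, RadiusProfileSpec(10.0, aneurysms=((60.0, 0.5, 20.0),)))
    radii = np.linalg.norm(aneu.vertices[:-2][:, :2], axis=1)
    assert radii.max() == pytest.approx(15.0, rel=1e-6)


def test_surface_rejects_self_intersecting_loft():
    spec = CenterlineSpec(kind="arch", length=200.0, arch_radius=10.0)
    cl = make_centerline(spec)
    with pytest.raises(ValueError, match="self-intersecting"):
        make_surface(cl, RadiusProfileSpec(base_radius=12.0))


def test_radius_profile_must_stay_positive():
    with pytest.raises(ValueError):
        RadiusProfileSpec(base_radius=5.0, taper_rate=0.1)(np.array([80.0]))


# ---------------------------------------------------------------------------
# analytic velocity
# ---------------------------------------------------------------------------

def test_flow_for_unit_plug_speed():
    # V = 1 m/s in r = 10 mm tube -> Q = pi R^2 V = 18.85 L/min
    assert flow_for_mean_speed(1.0, 10.0) == pytest.approx(18.85, abs=0.005)


def test_poiseuille_apex_twice_mean(poiseuille_tube):
    v = poiseuille_tube.velocity(np.array([[0.0, 0.0, 60.0]]))
    assert v[0, 2] == pytest.approx(1.0, rel=1e-6)  # 2 x 0.5 m/s


def test_velocity_zero_outside_lumen(poiseuille_tube):
    v, mask = poiseuille_tube.velocity(
        np.array([[0, 10.5, 60.0], [0, 5.0, 60.0]]), return_mask=True
    )
    assert not mask[0] and mask[1]
    assert np.all(v[0] == 0.0)


def test_continuity_speed_doubles_when_area_halves():
    cl = make_centerline(CenterlineSpec(kind="straight", length=200.0, point_spacing=2.0))
    r0 = 10.0

    def radius(s):
        s = np.asarray(s, float)
        t = np.clip((s - 50.0) / 100.0, 0, 1)
        return r0 * (1.0 - t * (1.0 - 1.0 / math.sqrt(2.0)))  # area halves

    vel = VelocityModel(cl, radius, flow_for_mean_speed(0.5, r0))
    assert vel.mean_speed(np.array([180.0]))[0] == pytest.approx(1.0, rel=1e-6)


def test_mass_conservation_by_section_integration(poiseuille_tube):
    """Riemann-sum flux through perpendicular planes equals Q to < 0.5%."""
    from aortaflow.hemodynamics import circular_cross_section, flow_rate

    for z in (20.0, 60.0, 100.0):
        cs = circular_cross_section(
            poiseuille_tube.velocity, [0, 0, z], [0, 0, 1], 10.0, in_plane_step=0.2
        )
        assert flow_rate(cs) == pytest.approx(poiseuille_tube.flow_l_min, rel=0.005)


def test_skewed_profile_preserves_flow_and_shifts_apex():
    from aortaflow.hemodynamics import circular_cross_section, flow_rate

    spec = CenterlineSpec(kind="arch", length=200.0, arch_radius=20.0)
    cl = make_centerline(spec)
    q = flow_for_mean_speed(0.5, 8.0)
    skew = VelocityModel(cl, RadiusProfileSpec(8.0), q,
                         FlowProfileKind("skewed", skew_eccentricity=0.5))
    apex_pt = cl.interpolate(np.array([100.0]))[0]  # arch apex
    tangent = cl.tangents[np.argmin(np.abs(cl.s - 100.0))]
    cs = circular_cross_section(skew, apex_pt, tangent, 8.0, in_plane_step=0.2)
    assert flow_rate(cs) == pytest.approx(q, rel=0.005)
    speeds = np.linalg.norm(cs.velocities, axis=1)
    apex_sample = cs.points[np.argmax(speeds)]
    assert np.linalg.norm(apex_sample - apex_pt) > 0.5  # apex off-axis


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def test_voxelize_noise_free_equals_analytic(poiseuille_tube, poiseuille_field):
    centers = poiseuille_field.voxel_centers()
    expected = poiseuille_tube.velocity(centers).reshape(
        *poiseuille_field.grid_shape, 3
    )
    assert np.allclose(poiseuille_field.frame(0), expected, atol=1e-6)


def test_voxelize_seed_determinism(poiseuille_tube):
    a = poiseuille_tube.field(voxel_spacing=2.0, noise_sd_fraction=0.05, seed=7)
    b = poiseuille_tube.field(voxel_spacing=2.0, noise_sd_fraction=0.05, seed=7)
    assert np.array_equal(a.data, b.data)
    c = poiseuille_tube.field(voxel_spacing=2.0, noise_sd_fraction=0.05, seed=8)
    assert not np.array_equal(a.data, c.data)


def test_voxelize_noise_sd_calibration(poiseuille_tube):
    """Empirical background noise sd = noise_sd_fraction x VENC within 2%."""
    acq = AcquisitionSpec(voxel_spacing=2.0, n_frames=1,
                          noise_sd_fraction=0.05, venc=150.0, seed=1)
    bbox = default_bounding_box(poiseuille_tube.centerline, 10.0, margin=30.0)
    fld = voxelize(poiseuille_tube.velocity, acq,
                   TemporalWaveform.raised_cosine(1), bbox)
    centers = fld.voxel_centers()
    r = np.linalg.norm(centers[:, :2], axis=1)
    background = (r > 12.0).reshape(fld.grid_shape)
    vals = fld.frame(0)[background]
    assert vals.size >= 1e5
    assert vals.std() == pytest.approx(0.075, rel=0.02)  # 5% of 150 cm/s, in m/s


def test_voxelize_warns_above_venc():
    tube = TubeBundle(v_mean=1.0)  # apex 2.0 m/s > VENC 1.5 m/s
    with pytest.warns(UserWarning, match="VENC"):
        tube.field(voxel_spacing=2.0)


def test_waveform_contract():
    wf = TemporalWaveform.raised_cosine(20, peak_frame=7)
    assert wf.scale_factors.max() == 1.0
    assert wf.peak_frame == 7
    assert np.all(wf.scale_factors >= 0)
    with pytest.raises(ValueError):
        TemporalWaveform(frame_times=np.arange(3.0), scale_factors=np.array([0.5, 0.9, 0.7]))


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def test_landmark_fractions_scale_with_length():
    cl = make_centerline(CenterlineSpec(kind="straight", length=200.0, point_spacing=2.0))
    lm = make_landmarks(cl, (0, 0.25, 0.45, 0.7, 1.0))
    assert lm.aortic_valve == 0.0
    assert lm.brachiocephalic == pytest.approx(50.0)
    assert lm.diaphragm == pytest.approx(200.0)


def test_landmarks_reject_degenerate_fractions():
    cl = make_centerline(CenterlineSpec(kind="straight", length=200.0, point_spacing=2.0))
    with pytest.raises(ValueError):
        make_landmarks(cl, (0, 0.45, 0.45, 0.7, 1.0))


# ---------------------------------------------------------------------------
# ground-truth manifest
# ---------------------------------------------------------------------------

def test_manifest_closed_forms():
    spec = CenterlineSpec(kind="straight", length=100.0, point_spacing=2.0)
    rad = RadiusProfileSpec(base_radius=10.0)
    man = ground_truth_manifest(spec, rad, flow_for_mean_speed(0.5, 10.0))
    assert np.allclose(man["diameter_mm"], 20.0)
    # Poiseuille: PD_A = rho V^2 = 1060 * 0.25 Pa = 1.988 mm Hg
    assert np.allclose(man["pd_a_mmhg"], 1060 * 0.25 / 133.322, rtol=1e-6)
    assert man["shape_factor"] == 2.0


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def test_cohort_cardiac_output_within_3se():
    subs = make_cohort({"control": 78}, seed=5)
    q_mean = np.mean([s.flow_rate_peak_l_min for s in subs])
    wf = TemporalWaveform.raised_cosine()
    co = q_mean * wf.mean
    se = 0.8 / math.sqrt(78)
    assert abs(co - 3.7) < 3 * se


def test_cohort_bsa_consistent_with_mosteller():
    subs = make_cohort({"hlhs_child": 5}, seed=2)
    from aortaflow.geometry import bsa_mosteller

    for s in subs:
        assert s.record.bsa == pytest.approx(
            bsa_mosteller(s.record.height, s.record.weight)
        )


def test_cohort_imposed_taper_shifts_delta_pd():
    """The HLHS-child group's steeper transition taper shifts the
    ground-truth TA+DA1 pressure-drop increment upward vs controls."""
    subs = make_cohort({"control": 40, "hlhs_child": 40}, seed=3)
    ctrl = [s.ground_truth["TA_DA1"]["delta_pd_mmhg"]
            for s in subs if s.record.group == "control"]
    child = [s.ground_truth["TA_DA1"]["delta_pd_mmhg"]
             for s in subs if s.record.group == "hlhs_child"]
    assert np.mean(child) > np.mean(ctrl) + 0.5


def test_cohort_null_calibration():
    """Identical group specs: downstream test rejects at ~alpha."""
    from aortaflow.phantom import DEFAULT_GROUP_EFFECTS, GroupSpec

    effects = {
        "a": DEFAULT_GROUP_EFFECTS["control"],
        "b": GroupSpec(name="b"),  # same defaults as control
    }
    rejections = 0
    n_rep = 60
    for seed in range(n_rep):
        subs = make_cohort({"a": 15, "b": 15}, group_effects=effects, seed=seed)
        x = [s.ground_truth["TA_DA1"]["delta_pd_mmhg"]
             for s in subs if s.record.group == "a"]
        y = [s.ground_truth["TA_DA1"]["delta_pd_mmhg"]
             for s in subs if s.record.group == "b"]
        rejections += compare_groups(x, y).p_value < 0.05
    # alpha = 0.05: expect ~3/60; allow up to ~4 SE
    assert rejections <= 12


def test_cohort_rejects_bad_inputs():
    with pytest.raises(ValueError):
        make_cohort({"control": 0})
    with pytest.raises(ValueError):
        make_cohort({"unknown_group": 3})


def test_cohort_subject_builds_phantom():
    subs = make_cohort({"control": 1}, seed=11)
    cl, surface, vel, field = subs[0].build(
        AcquisitionSpec(voxel_spacing=2.5, n_frames=1, noise_sd_fraction=0.0)
    )
    assert surface.is_watertight
    assert field.grid_shape[0] > 4
    # field magnitudes physiologic: peak speed between 0.2 and 3 m/s
    peak = np.linalg.norm(field.frame(0), axis=-1).max()
    assert 0.2 < peak < 3.0


def test_subject_record_validation():
    with pytest.raises(ValueError):
        SubjectRecord(id="x", group="control", age=8.0, sex="F",
                      height=-1.0, weight=25.0)
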