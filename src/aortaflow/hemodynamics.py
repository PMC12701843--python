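"""Conduit-function metrics from a measured velocity field.

The central quantity is the advective pressure drop PD_A, computed by the
simplified advective work-energy relative pressure (SAW) formulation: at a
vessel cross-section with unit normal n (proximal-to-distal),

    PD_A = rho / (2 Q) * integral over the lumen of |v|^2 (v . n) dA,

with Q the flow rate through the same section.  PD_A is the pressure
difference needed to create the observed flow momentum from rest, and is
an upper bound on the energy the flow can dissipate downstream.  Because
it weights the full velocity profile by its own flux, it corrects the
Simplified Bernoulli estimate (which collapses the profile to its peak
velocity); for a parabolic profile the exact-mode Bernoulli value is
exactly twice PD_A.

Also provided: flow rate, peak-systole detection (frame of maximal
lumen-integrated momentum), regional peak PD_A and increments dPD_A, and
the gradient-based comparator metrics wall shear stress and viscous
dissipation, which PD_A is designed to be more robust than.

Internally SI units are used; mm Hg and L/min appear only at reporting
boundaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import shapely
import trimesh

from .geometry import (
    Centerline,
    RegionPartition,
    _plane_basis,
    cross_section_contour,
)
from .containment import points_in_mesh, voxel_lumen_mask

__all__ = [
    "RHO_BLOOD",
    "MU_BLOOD",
    "PA_PER_MMHG",
    "CrossSectionSample",
    "AxialProfile",
    "RegionHemodynamics",
    "WallMetrics",
    "sample_cross_section",
    "circular_cross_section",
    "flow_rate",
    "detect_peak_systole",
    "saw_pd",
    "pd_profile",
    "delta_pd",
    "peak_pd",
    "simplified_bernoulli",
    "wall_shear_stress",
    "viscous_dissipation",
    "region_hemodynamics",
    "voxel_lumen_mask",
]

#: Standard blood density (kg/m^3) and dynamic viscosity (Pa s).
RHO_BLOOD = 1060.0
MU_BLOOD = 0.004
PA_PER_MMHG = 133.322

#: Stations whose |Q| falls below this fraction of the profile maximum are
#: flagged undefined (the 1/Q prefactor of SAW is singular at low flow).
Q_MIN_FRACTION = 0.05


class PlaneOutsideLumenError(ValueError):
    """The sampling plane does not cut an enclosing lumen contour."""


@dataclass
class CrossSectionSample:
    """In-plane velocity samples at one cross-section.

    ``points`` are 3-D sample positions (mm) on the plane through
    ``plane_point`` with unit ``normal`` (proximal-to-distal);
    ``velocities`` in m/s; ``lumen_mask`` marks samples inside the lumen
    contour; ``dA`` is the in-plane element area (mm^2).
    """

    plane_point: np.ndarray
    normal: np.ndarray
    points: np.ndarray  # (M, 3) mm
    velocities: np.ndarray  # (M, 3) m/s
    lumen_mask: np.ndarray  # (M,) bool
    dA: float  # mm^2

    @property
    def area_mm2(self) -> float:
        return float(self.lumen_mask.sum() * self.dA)

    @property
    def n_lumen(self) -> int:
        return int(self.lumen_mask.sum())

    def reversed(self) -> "CrossSectionSample":
        """Same sample with the flow-direction normal flipped."""
        return CrossSectionSample(
            plane_point=self.plane_point,
            normal=-self.normal,
            points=self.points,
            velocities=self.velocities,
            lumen_mask=self.lumen_mask,
            dA=self.dA,
        )


def sample_cross_section(
    velocity_fn: Callable[[np.ndarray], np.ndarray],
    plane_point: np.ndarray,
    normal: np.ndarray,
    surface: trimesh.Trimesh,
    in_plane_step: float = 1.0,
) -> CrossSectionSample:
    """Sample velocities on a regular in-plane grid over the lumen contour.

    ``velocity_fn`` maps (M, 3) positions in mm to (M, 3) velocities in
    m/s (an analytic model or a trilinear field interpolator).  The lumen
    mask comes from a point-in-contour test against the closed surface
    section enclosing the centerline point.
    """
    if in_plane_step <= 0:
        raise ValueError("in_plane_step must be positive")
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    poly = cross_section_contour(surface, plane_point, normal)
    if poly is None:
        raise PlaneOutsideLumenError(
            "plane does not intersect the lumen in an enclosing contour"
        )
    u, w = _plane_basis(normal)
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx + in_plane_step / 2, maxx, in_plane_step)
    ys = np.arange(miny + in_plane_step / 2, maxy, in_plane_step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    mask = shapely.contains_xy(poly, gx, gy)
    pts3 = (
        np.asarray(plane_point, dtype=float)
        + gx[:, None] * u
        + gy[:, None] * w
    )
    vel = np.asarray(velocity_fn(pts3), dtype=float)
    return CrossSectionSample(
        plane_point=np.asarray(plane_point, dtype=float),
        normal=normal,
        points=pts3,
        velocities=vel,
        lumen_mask=mask,
        dA=in_plane_step**2,
    )


def circular_cross_section(
    velocity_fn: Callable[[np.ndarray], np.ndarray],
    center: np.ndarray,
    normal: np.ndarray,
    radius: float,
    in_plane_step: float = 0.25,
) -> CrossSectionSample:
    """Cross-section sample with an ideal circular lumen mask (no mesh).

    Useful for closed-form checks where the lumen boundary is known
    exactly.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    u, w = _plane_basis(normal)
    half = np.arange(in_plane_step / 2, radius + in_plane_step, in_plane_step)
    coords = np.concatenate([-half[::-1], half])
    gx, gy = np.meshgrid(coords, coords, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    mask = gx**2 + gy**2 <= radius**2
    pts3 = np.asarray(center, dtype=float) + gx[:, None] * u + gy[:, None] * w
    vel = np.asarray(velocity_fn(pts3), dtype=float)
    return CrossSectionSample(
        plane_point=np.asarray(center, dtype=float),
        normal=normal,
        points=pts3,
        velocities=vel,
        lumen_mask=mask,
        dA=in_plane_step**2,
    )


def flow_rate(cs: CrossSectionSample) -> float:
    """Flow rate through the section in L/min (positive proximal-to-distal)."""
    vn = cs.velocities[cs.lumen_mask] @ cs.normal  # m/s
    q_si = float(np.sum(vn) * cs.dA * 1e-6)  # m^3/s
    return q_si * 60000.0


def _flow_rate_si(cs: CrossSectionSample) -> float:
    return flow_rate(cs) / 60000.0


def saw_pd(
    cs: CrossSectionSample,
    rho: float = RHO_BLOOD,
    q_min_l_min: float | None = None,
) -> float:
    """Advective pressure drop (SAW formulation) at one station, in mm Hg.

    ``PD_A = rho / (2 Q) * sum |v|^2 (v . n) dA`` over lumen samples, with
    Q the flow rate through the same sample.  Stations whose |Q| falls
    below ``q_min_l_min`` are undefined (NaN) rather than letting the 1/Q
    prefactor blow up.
    """
    q_si = _flow_rate_si(cs)
    if q_min_l_min is not None and abs(q_si) * 60000.0 < q_min_l_min:
        return float("nan")
    if abs(q_si) < 1e-15:
        return float("nan")
    v = cs.velocities[cs.lumen_mask]
    vn = v @ cs.normal
    flux = float(np.sum(np.einsum("ij,ij->i", v, v) * vn) * cs.dA * 1e-6)
    pd_pa = rho / (2.0 * q_si) * flux
    return pd_pa / PA_PER_MMHG


def simplified_bernoulli(
    cs: CrossSectionSample,
    rho: float = RHO_BLOOD,
    clinical_coefficient: bool = False,
) -> float:
    """Simplified Bernoulli pressure difference from peak velocity (mm Hg).

    Exact mode: ``rho * v_max^2 / 2`` converted to mm Hg.  Clinical mode:
    the bedside ``4 * v_max^2`` with v_max in m/s, which absorbs rho/2 and
    the unit conversion into the coefficient 4.
    """
    v = cs.velocities[cs.lumen_mask]
    if len(v) == 0:
        raise ValueError("empty cross-section sample")
    v_max = float(np.linalg.norm(v, axis=1).max())
    if clinical_coefficient:
        return 4.0 * v_max**2
    return rho * v_max**2 / 2.0 / PA_PER_MMHG


def detect_peak_systole(field, lumen_mask: np.ndarray | None = None,
                        rho: float = RHO_BLOOD) -> int:
    """Frame of maximal lumen-integrated momentum magnitude.

    The statistic is ``sum rho |v| dV`` over lumen voxels — a scalar
    momentum proxy that cannot self-cancel around the arch, where the flow
    direction reverses spatially.  Ties return the earliest frame.
    """
    data = field.data  # (nt, nx, ny, nz, 3)
    speed = np.linalg.norm(data, axis=-1)
    if lumen_mask is not None:
        speed = speed * lumen_mask[None, ...]
    totals = speed.reshape(field.n_frames, -1).sum(axis=1) * rho * field.voxel_volume_m3
    if np.all(totals == 0):
        raise ValueError("velocity field is identically zero; no systole to detect")
    return int(np.argmax(totals))


@dataclass
class AxialProfile:
    """Per-station hemodynamic traces along the centerline at one frame."""

    s: np.ndarray  # mm
    q_l_min: np.ndarray  # flow rate, L/min
    pd_a_mmhg: np.ndarray  # advective pressure drop, NaN where undefined
    v_max: np.ndarray  # peak sampled speed, m/s
    frame: int
    rho: float = RHO_BLOOD
    n_undefined: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_mm": self.s,
                "q_l_min": self.q_l_min,
                "pd_a_mmhg": self.pd_a_mmhg,
                "v_max_m_s": self.v_max,
            }
        )


def pd_profile(
    velocity_fn: Callable[[np.ndarray], np.ndarray],
    centerline: Centerline,
    surface: trimesh.Trimesh,
    frame: int = 0,
    rho: float = RHO_BLOOD,
    in_plane_step: float = 1.0,
    q_min_fraction: float = Q_MIN_FRACTION,
) -> AxialProfile:
    """Advective pressure drop and flow rate at every centerline station.

    ``velocity_fn`` is evaluated on each perpendicular cross-section.
    Stations where sampling fails, or whose |Q| is below
    ``q_min_fraction`` of the profile's maximum |Q|, are carried as
    missing.  If more than 20% of stations end up undefined a warning is
    recorded.
    """
    n = len(centerline.points)
    q = np.full(n, np.nan)
    pd_a = np.full(n, np.nan)
    v_max = np.full(n, np.nan)
    samples: list[CrossSectionSample | None] = [None] * n
    for i, (p, t) in enumerate(zip(centerline.points, centerline.tangents)):
        try:
            cs = sample_cross_section(velocity_fn, p, t, surface, in_plane_step)
        except PlaneOutsideLumenError:
            continue
        samples[i] = cs
        q[i] = flow_rate(cs)
        v = cs.velocities[cs.lumen_mask]
        if len(v):
            v_max[i] = np.linalg.norm(v, axis=1).max()

    q_abs_max = np.nanmax(np.abs(q)) if np.any(np.isfinite(q)) else 0.0
    q_min = q_min_fraction * q_abs_max
    for i, cs in enumerate(samples):
        if cs is None:
            continue
        if abs(q[i]) < q_min or q_abs_max == 0.0:
            continue  # leave PD undefined at low-flow stations
        pd_a[i] = saw_pd(cs, rho=rho)

    n_undef = int(np.sum(~np.isfinite(pd_a)))
    if n_undef > 0.2 * n:
        warnings.warn(
            f"{n_undef}/{n} stations have undefined PD_A", stacklevel=2
        )
    return AxialProfile(
        s=centerline.s.copy(), q_l_min=q, pd_a_mmhg=pd_a, v_max=v_max,
        frame=frame, rho=rho, n_undefined=n_undef,
    )


def _region_defined(profile: AxialProfile, bounds: tuple[float, float],
                    closed_hi: bool) -> np.ndarray:
    lo, hi = bounds
    m = (profile.s >= lo) & ((profile.s <= hi) if closed_hi else (profile.s < hi))
    return np.where(m & np.isfinite(profile.pd_a_mmhg))[0]


def _region_indices(profile: AxialProfile, partition: RegionPartition,
                    region: str) -> np.ndarray:
    m = partition.mask(profile.s, region)
    idx = np.where(m & np.isfinite(profile.pd_a_mmhg))[0]
    if not m.any():
        raise ValueError(f"region {region} contains no stations")
    if len(idx) == 0:
        raise ValueError(f"region {region} has no defined PD_A stations")
    return idx


def delta_pd(
    profile: AxialProfile,
    partition: RegionPartition,
    region: str,
    mode: str = "end_minus_start",
) -> float:
    """PD_A increment across a region (mm Hg).

    ``end_minus_start`` (default): distal-most minus proximal-most defined
    station — can be negative, e.g. across an aneurysmal segment.
    ``max_minus_start``: region maximum minus the proximal value, always
    >= 0.  The nearest defined station stands in for an undefined bound.
    """
    if mode not in ("end_minus_start", "max_minus_start"):
        raise ValueError(f"unknown delta_pd mode: {mode!r}")
    idx = _region_indices(profile, partition, region)
    pd_a = profile.pd_a_mmhg
    start = pd_a[idx[0]]
    if mode == "end_minus_start":
        return float(pd_a[idx[-1]] - start)
    return float(np.max(pd_a[idx]) - start)


def peak_pd(
    profile: AxialProfile,
    partition: RegionPartition,
    region: str,
) -> tuple[float, float]:
    """Maximum PD_A in a region and its arc-length location (mm).

    Ties resolve to the most proximal station.
    """
    idx = _region_indices(profile, partition, region)
    vals = profile.pd_a_mmhg[idx]
    k = idx[int(np.argmax(vals))]  # argmax returns the first (proximal) tie
    return float(profile.pd_a_mmhg[k]), float(profile.s[k])


# ---------------------------------------------------------------------------
# Comparator metrics
# ---------------------------------------------------------------------------

@dataclass
class WallMetrics:
    """Wall shear stress per surface vertex and a validity mask."""

    wss_pa: np.ndarray  # (n_vertices,), NaN where flagged
    valid: np.ndarray  # (n_vertices,) bool
    mu: float
    wall_step: float  # mm


def wall_shear_stress(
    velocity_fn: Callable[[np.ndarray], np.ndarray],
    surface: trimesh.Trimesh,
    mu: float = MU_BLOOD,
    wall_step: float = 1.0,
) -> WallMetrics:
    """Wall shear stress magnitude at each surface vertex (Pa).

    Velocity is sampled at inward-normal offsets {h, 2h} from each vertex;
    with the no-slip condition v(wall) = 0, the wall-normal derivative of
    the wall-tangential velocity is estimated by the second-order one-sided
    difference ``(4 v(h) - v(2h)) / (2h)`` and WSS = mu x its magnitude.
    Vertices whose offset points leave the lumen are flagged invalid.
    """
    if wall_step <= 0:
        raise ValueError("wall_step must be positive")
    verts = surface.vertices
    inward = -surface.vertex_normals  # trimesh normals point outward
    p1 = verts + inward * wall_step
    p2 = verts + inward * 2.0 * wall_step
    ok = points_in_mesh(
        surface, np.vstack([p1, p2]), bin_width=wall_step / 2.0
    )
    valid = ok[: len(verts)] & ok[len(verts):]
    v1 = np.asarray(velocity_fn(p1), dtype=float)
    v2 = np.asarray(velocity_fn(p2), dtype=float)
    # project out the wall-normal component to keep the tangential part
    n = inward
    v1t = v1 - (np.einsum("ij,ij->i", v1, n))[:, None] * n
    v2t = v2 - (np.einsum("ij,ij->i", v2, n))[:, None] * n
    h_m = wall_step / 1000.0
    dvdn = (4.0 * v1t - v2t) / (2.0 * h_m)
    wss = mu * np.linalg.norm(dvdn, axis=1)
    wss[~valid] = np.nan
    return WallMetrics(wss_pa=wss, valid=valid, mu=mu, wall_step=wall_step)


def viscous_dissipation(
    velocity: np.ndarray,
    lumen_mask: np.ndarray,
    mu: float = MU_BLOOD,
    voxel_spacing: float = 2.0,
) -> tuple[np.ndarray, float]:
    """Viscous dissipation rate density Phi (W/m^3) and its lumen integral (W).

    The strain-rate tensor ``e_ij = (d_i v_j + d_j v_i) / 2`` is estimated
    by central differences on the voxel grid, using the velocity array as
    acquired: at the lumen edge the difference stencil reaches one voxel
    outside, where voxelized data is (noise around) zero at the wall —
    encoding the no-slip condition one-sidedly — and continues smoothly
    across open flow boundaries.  ``Phi = 2 mu sum_ij e_ij^2``; the
    integrated dissipation sums Phi over lumen voxels times the voxel
    volume.  Like any gradient-based metric this inherits the noise of
    every voxel in the stencil, which is precisely why the advective
    pressure drop is preferred as the headline inefficiency measure.
    """
    velocity = np.asarray(velocity, dtype=float)
    if velocity.ndim != 4 or velocity.shape[-1] != 3:
        raise ValueError("velocity must have shape (nx, ny, nz, 3)")
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    if lumen_mask.shape != velocity.shape[:3]:
        raise ValueError("lumen_mask must match the voxel grid")
    spans = [int(m.sum()) for m in (
        lumen_mask.any(axis=(1, 2)), lumen_mask.any(axis=(0, 2)),
        lumen_mask.any(axis=(0, 1)),
    )]
    if min(spans) < 3:
        raise ValueError(
            "lumen thinner than 3 voxels in at least one direction; "
            "use a finer phantom grid"
        )
    h_m = voxel_spacing / 1000.0
    grads = np.stack(np.gradient(velocity, h_m, axis=(0, 1, 2)), axis=0)  # (3, nx, ny, nz, 3): d_i v_j
    e = 0.5 * (grads + np.transpose(grads, (4, 1, 2, 3, 0)))
    phi = 2.0 * mu * np.sum(e**2, axis=(0, 4))  # W/m^3
    integrated = float(phi[lumen_mask].sum() * h_m**3)
    return phi, integrated


# ---------------------------------------------------------------------------
# Regional summaries
# ---------------------------------------------------------------------------

@dataclass
class RegionHemodynamics:
    """Per-region conduit-function scalars (one subject, one frame)."""

    regions: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.regions).T


def region_hemodynamics(
    profile: AxialProfile,
    partition: RegionPartition,
    subject=None,
) -> RegionHemodynamics:
    """Regional summaries: mean Q/BSA, peak PD_A (+ location), dPD_A.

    Computed for AA, TA, DA1, DA2 and the combined TA_DA1 transition; both
    dPD_A modes are reported, with ``end_minus_start`` the headline value.
    """
    out: dict[str, dict[str, float]] = {}
    for name in partition.names:
        m = partition.mask(profile.s, name)
        if not m.any():
            raise ValueError(f"region {name} contains no stations")
        q = profile.q_l_min[m]
        q = q[np.isfinite(q)]
        peak, loc = peak_pd(profile, partition, name)
        row = {
            "q_mean_l_min": float(q.mean()) if len(q) else float("nan"),
            "pd_a_peak_mmhg": peak,
            "pd_a_peak_s_mm": loc,
            "delta_pd_mmhg": delta_pd(profile, partition, name),
            "delta_pd_max_minus_start_mmhg": delta_pd(
                profile, partition, name, mode="max_minus_start"
            ),
        }
        if subject is not None and getattr(subject, "bsa", None):
            row["q_mean_per_bsa"] = row["q_mean_l_min"] / subject.bsa
        out[name] = row
    return RegionHemodynamics(regions=out)
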