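"""Synthetic phase-contrast phantoms with analytic ground truth.

Patient 4D-flow MRI cannot be redistributed, so every downstream stage is
exercised on phantoms: parametric centerlines (straight tube, rounded
arch, "gothic" arch with a sharp localized curvature peak), lofted tubular
surfaces with tapers / stenoses / aneurysms, mass-conserving analytic
velocity fields (plug, Poiseuille, skewed), and their voxelization onto a
regular grid at acquisition-realistic resolution (~2 mm isotropic voxels,
~20 cardiac frames, VENC 120-150 cm/s) with additive Gaussian velocity
noise.

Every phantom carries a ground-truth manifest (analytic diameter,
curvature, flow rate and advective pressure drop per station) that
downstream tests compare against.

Units: millimetres for geometry, m/s for velocity, L/min for flow rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator
from scipy.spatial import cKDTree
import trimesh

from .geometry import (
    Centerline,
    RegionLandmarks,
    bsa_mosteller,
)

__all__ = [
    "CenterlineSpec",
    "RadiusProfileSpec",
    "AcquisitionSpec",
    "TemporalWaveform",
    "FlowProfileKind",
    "SubjectRecord",
    "VelocityField4D",
    "VelocityModel",
    "CohortSubject",
    "GroupSpec",
    "DEFAULT_GROUP_EFFECTS",
    "make_centerline",
    "analytic_curvature",
    "make_surface",
    "analytic_velocity",
    "voxelize",
    "default_bounding_box",
    "make_landmarks",
    "make_cohort",
    "ground_truth_manifest",
    "RHO_BLOOD",
]

#: Density of blood (kg/m^3), the standard literature value.
RHO_BLOOD = 1060.0

_PA_PER_MMHG = 133.322


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CenterlineSpec:
    """Parametric centerline archetype.

    ``kind`` is one of ``straight`` (a line), ``arch`` (two straight limbs
    joined by a half-turn circular arc of radius ``arch_radius``, tangent
    continuous) or ``gothic_arch`` (an arch with a localized raised-cosine
    curvature bump at the apex whose analytic peak equals
    ``gothic_kink_curvature``, emulating angular reconstructed arches).
    """

    kind: str = "straight"
    length: float = 200.0  # mm
    arch_radius: float | None = None  # mm
    gothic_kink_curvature: float | None = None  # 1/mm
    gothic_kink_width: float = 10.0  # mm
    point_spacing: float = 1.0  # mm

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "arch", "gothic_arch"):
            raise ValueError(f"unknown centerline kind: {self.kind!r}")
        if self.length <= 0 or self.point_spacing <= 0:
            raise ValueError("length and point_spacing must be positive")
        if self.kind != "straight":
            if self.arch_radius is None or self.arch_radius <= 0:
                raise ValueError("arch kinds require arch_radius > 0")
            if math.pi * self.arch_radius >= self.length:
                raise ValueError("arch arc longer than total length")
        if self.kind == "gothic_arch":
            k = self.gothic_kink_curvature
            if k is None or k <= 0:
                raise ValueError("gothic_arch requires gothic_kink_curvature > 0")
            if k < 1.0 / self.arch_radius:
                raise ValueError(
                    "gothic kink curvature must exceed the base arch curvature"
                )


@dataclass(frozen=True)
class RadiusProfileSpec:
    """Lumen radius along arc length: base radius, linear taper, local lesions.

    Stenoses multiply the radius by ``1 - depth_fraction`` at their center;
    aneurysms by ``1 + amplitude_fraction``; both with raised-cosine
    support of the given width.
    """

    base_radius: float  # mm
    taper_rate: float = 0.0  # mm radius lost per mm arc length
    stenoses: tuple[tuple[float, float, float], ...] = ()  # (center_s, depth, width)
    aneurysms: tuple[tuple[float, float, float], ...] = ()  # (center_s, amp, width)

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        for _, depth, width in self.stenoses:
            if not (0.0 <= depth < 1.0) or width <= 0:
                raise ValueError("stenosis depth must be in [0, 1), width > 0")
        for _, amp, width in self.aneurysms:
            if amp < 0 or width <= 0:
                raise ValueError("aneurysm amplitude must be >= 0, width > 0")

    def __call__(self, s: np.ndarray) -> np.ndarray:
        """Radius r(s) in mm."""
        s = np.asarray(s, dtype=float)
        r = self.base_radius - self.taper_rate * s
        factor = np.ones_like(s)
        for center, depth, width in self.stenoses:
            factor *= 1.0 - depth * _raised_cosine_bump(s, center, width)
        for center, amp, width in self.aneurysms:
            factor *= 1.0 + amp * _raised_cosine_bump(s, center, width)
        r = r * factor
        if np.any(r <= 0):
            raise ValueError("radius profile must stay positive everywhere")
        return r


def _raised_cosine_bump(s: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-peak raised-cosine bump with support ``[center - w/2, center + w/2]``."""
    x = (np.asarray(s, dtype=float) - center) / (width / 2.0)
    out = np.zeros_like(x)
    inside = np.abs(x) < 1.0
    out[inside] = 0.5 * (1.0 + np.cos(math.pi * x[inside]))
    return out


@dataclass(frozen=True)
class AcquisitionSpec:
    """Emulated phase-contrast acquisition parameters."""

    voxel_spacing: float = 2.0  # mm, isotropic
    n_frames: int = 20  # per cardiac cycle
    venc: float = 150.0  # cm/s
    noise_sd_fraction: float = 0.05  # sd of Gaussian velocity noise / VENC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")


@dataclass(frozen=True)
class TemporalWaveform:
    """Per-frame flow scaling over the cardiac cycle (peak systole = 1)."""

    frame_times: np.ndarray  # ms
    scale_factors: np.ndarray  # dimensionless, max = 1, all >= 0

    def __post_init__(self) -> None:
        sf = np.asarray(self.scale_factors, dtype=float)
        if len(sf) != len(self.frame_times):
            raise ValueError("frame_times and scale_factors must align")
        if sf.min() < 0 or not math.isclose(sf.max(), 1.0, rel_tol=1e-9):
            raise ValueError("scale factors must be >= 0 with max exactly 1")

    @property
    def mean(self) -> float:
        """Cycle-mean scale factor (peak flow = mean flow / this)."""
        return float(np.mean(self.scale_factors))

    @property
    def peak_frame(self) -> int:
        return int(np.argmax(self.scale_factors))

    @classmethod
    def raised_cosine(
        cls,
        n_frames: int = 20,
        peak_frame: int = 7,
        rr_interval_ms: float = 750.0,
    ) -> "TemporalWaveform":
        """Unimodal systolic pulse: raised cosine over frames
        ``[0, 2 * peak_frame]``, zero in the diastolic remainder."""
        t = np.arange(n_frames) * rr_interval_ms / n_frames
        f = np.arange(n_frames, dtype=float)
        sf = np.zeros(n_frames)
        if peak_frame >= n_frames:  # short cycles keep the ~35% systolic peak
            peak_frame = max(1, int(round(0.35 * n_frames)))
        if n_frames == 1:
            sf[0] = 1.0
        else:
            width = 2 * peak_frame
            inside = f <= width
            sf[inside] = 0.5 * (1.0 - np.cos(math.pi * f[inside] / peak_frame))
            sf[peak_frame] = 1.0
        return cls(frame_times=t, scale_factors=sf)


@dataclass(frozen=True)
class FlowProfileKind:
    """Cross-sectional velocity profile shape.

    ``plug`` — uniform speed; ``poiseuille`` — parabolic, apex 2x mean;
    ``skewed`` — parabolic with apex displaced toward the inner-curvature
    direction by ``skew_eccentricity x radius`` (flux preserving), as seen
    downstream of curved segments.
    """

    kind: str = "poiseuille"
    skew_eccentricity: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("plug", "poiseuille", "skewed"):
            raise ValueError(f"unknown flow profile kind: {self.kind!r}")
        if not (0.0 <= self.skew_eccentricity < 1.0):
            raise ValueError("skew_eccentricity must lie in [0, 1)")

    @property
    def shape_factor(self) -> float:
        """alpha = <v^3> / V^3 over the section; the advective pressure drop
        of a profile is rho * alpha * V^2 / 2 at mean speed V."""
        if self.kind == "plug":
            return 1.0
        if self.kind == "poiseuille":
            return 2.0
        return 2.0 + 0.6 * self.skew_eccentricity**2


@dataclass(frozen=True)
class SubjectRecord:
    """Subject metadata for body-size indexing and cohort bookkeeping."""

    id: str
    group: str  # control | hlhs_child | hlhs_adolescent
    age: float  # years
    sex: str
    height: float  # m
    weight: float  # kg
    bsa: float | None = None  # m^2; derived by Mosteller if omitted
    heart_rate: float = 80.0  # bpm

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        if self.bsa is None:
            object.__setattr__(self, "bsa", bsa_mosteller(self.height, self.weight))
        elif self.bsa <= 0:
            raise ValueError("bsa must be positive")


# ---------------------------------------------------------------------------
# Centerline construction
# ---------------------------------------------------------------------------

def _curvature_function(spec: CenterlineSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic planar curvature kappa(s) for a centerline spec."""
    L = spec.length
    if spec.kind == "straight":
        return lambda s: np.zeros_like(np.asarray(s, dtype=float))
    R = spec.arch_radius
    arc_len = math.pi * R
    limb = (L - arc_len) / 2.0
    lo, hi = limb, limb + arc_len

    def base(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.where((s >= lo) & (s <= hi), 1.0 / R, 0.0)

    if spec.kind == "arch":
        return base

    apex = limb + arc_len / 2.0
    extra = spec.gothic_kink_curvature - 1.0 / R
    width = spec.gothic_kink_width

    def gothic(s: np.ndarray) -> np.ndarray:
        return base(s) + extra * _raised_cosine_bump(np.asarray(s, float), apex, width)

    return gothic


def analytic_curvature(spec: CenterlineSpec, s: np.ndarray) -> np.ndarray:
    """Ground-truth curvature (1/mm) at arc lengths ``s``."""
    return _curvature_function(spec)(s)


def make_centerline(spec: CenterlineSpec) -> Centerline:
    """Build the centerline by integrating its planar curvature profile.

    The curve starts at the origin heading +z and turns toward +x within
    the x-z plane; an arch therefore ascends, turns through half a circle
    and descends, like a sagittal aortic silhouette.
    """
    n_out = int(round(spec.length / spec.point_spacing))
    s_out = np.linspace(0.0, spec.length, n_out + 1)
    if spec.kind == "straight":
        pts = np.zeros((n_out + 1, 3))
        pts[:, 2] = s_out
        return Centerline.from_points(pts)

    kappa = _curvature_function(spec)
    ds = min(spec.point_spacing, 1.0) / 20.0
    s_fine = np.arange(0.0, spec.length + ds / 2, ds)
    theta = cumulative_trapezoid(kappa(s_fine), s_fine, initial=0.0)
    x = cumulative_trapezoid(np.sin(theta), s_fine, initial=0.0)
    z = cumulative_trapezoid(np.cos(theta), s_fine, initial=0.0)
    pts = np.zeros((n_out + 1, 3))
    pts[:, 0] = np.interp(s_out, s_fine, x)
    pts[:, 2] = np.interp(s_out, s_fine, z)
    return Centerline.from_points(pts)


# ---------------------------------------------------------------------------
# Surface construction
# ---------------------------------------------------------------------------

def _transport_frames(centerline: Centerline) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transported in-plane frames (e1, e2) along the centerline,
    minimizing twist so lofted rings do not spiral."""
    t = centerline.tangents
    n = len(t)
    e1 = np.zeros((n, 3))
    helper = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(t[0], helper)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1[0] = np.cross(t[0], helper)
    e1[0] /= np.linalg.norm(e1[0])
    for i in range(1, n):
        v = e1[i - 1] - np.dot(e1[i - 1], t[i]) * t[i]
        nv = np.linalg.norm(v)
        if nv < 1e-12:  # pathological kink; restart the frame
            h = helper if abs(np.dot(t[i], helper)) < 0.9 else np.array([1.0, 0.0, 0.0])
            v = np.cross(t[i], h)
            nv = np.linalg.norm(v)
        e1[i] = v / nv
    e2 = np.cross(t, e1)
    return e1, e2


def make_surface(
    centerline: Centerline,
    radius: RadiusProfileSpec | Callable[[np.ndarray], np.ndarray] | np.ndarray,
    n_circumferential: int = 32,
) -> trimesh.Trimesh:
    """Loft a watertight triangulated tube around the centerline.

    Each ring lies in the plane perpendicular to the local tangent.  Ends
    are capped with triangle fans so the mesh is watertight.  Lofts whose
    adjacent rings would cross (local radius exceeding the local radius of
    curvature) are rejected.
    """
    if n_circumferential < 3:
        raise ValueError("need at least 3 circumferential vertices")
    if callable(radius):
        r = np.asarray(radius(centerline.s), dtype=float)
    else:
        r = np.asarray(radius, dtype=float)
        if r.shape != centerline.s.shape:
            raise ValueError("radius array must align with centerline stations")
    if np.any(r <= 0):
        raise ValueError("radius must be positive at every station")

    from .geometry import _menger_profile  # local to avoid polluting public API

    kappa = _menger_profile(centerline.points)
    if np.any(r * kappa >= 0.999):
        raise ValueError(
            "self-intersecting loft: radius exceeds local radius of curvature"
        )

    e1, e2 = _transport_frames(centerline)
    phi = np.linspace(0.0, 2.0 * math.pi, n_circumferential, endpoint=False)
    cosp, sinp = np.cos(phi), np.sin(phi)
    n_st = len(centerline.points)
    rings = (
        centerline.points[:, None, :]
        + r[:, None, None] * (cosp[None, :, None] * e1[:, None, :] + sinp[None, :, None] * e2[:, None, :])
    )
    vertices = rings.reshape(-1, 3)

    faces = []
    m = n_circumferential
    for i in range(n_st - 1):
        base0, base1 = i * m, (i + 1) * m
        for j in range(m):
            j1 = (j + 1) % m
            faces.append([base0 + j, base1 + j, base1 + j1])
            faces.append([base0 + j, base1 + j1, base0 + j1])
    # end caps (fans around the ring centroids)
    c0 = len(vertices)
    c1 = c0 + 1
    vertices = np.vstack([vertices, centerline.points[0], centerline.points[-1]])
    for j in range(m):
        j1 = (j + 1) % m
        faces.append([c0, j1, j])
        base = (n_st - 1) * m
        faces.append([c1, base + j, base + j1])

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:  # consistent outward-facing winding
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# Analytic velocity
# ---------------------------------------------------------------------------

class VelocityModel:
    """Mass-conserving analytic velocity field around a centerline.

    Velocity is aligned with the local centerline tangent; the
    cross-sectional mean speed at arc length s is ``V(s) = Q / A(s)``, so
    flux through any perpendicular section equals the specified flow rate.
    Points outside the lumen evaluate to zero velocity.
    """

    def __init__(
        self,
        centerline: Centerline,
        radius: RadiusProfileSpec | Callable[[np.ndarray], np.ndarray],
        flow_rate_l_min: float,
        profile: FlowProfileKind | None = None,
        fine_spacing: float = 0.5,
    ) -> None:
        if flow_rate_l_min <= 0:
            raise ValueError("flow rate must be positive")
        self.profile = profile or FlowProfileKind()
        self.flow_rate_l_min = float(flow_rate_l_min)
        self.q_si = flow_rate_l_min / 60000.0  # m^3/s
        self.centerline = centerline
        self.radius = radius

        fine = centerline.resample(fine_spacing)
        self._fine = fine
        self._tree = cKDTree(fine.points)
        self._r = np.asarray(radius(fine.s), dtype=float)  # mm
        # mean speed V(s) = Q / A(s); radius mm -> m
        self._v_mean = self.q_si / (math.pi * (self._r / 1000.0) ** 2)
        # inner-curvature direction for the skewed profile
        dT = np.gradient(fine.tangents, fine.s, axis=0)
        norms = np.linalg.norm(dT, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            inner = np.where(norms > 1e-6, dT / np.maximum(norms, 1e-300), 0.0)
        self._inner = inner

    def mean_speed(self, s: np.ndarray) -> np.ndarray:
        """V(s) = Q / A(s) in m/s."""
        s = np.asarray(s, dtype=float)
        r_m = np.asarray(self.radius(s), dtype=float) / 1000.0
        return self.q_si / (math.pi * r_m**2)

    def __call__(
        self, points: np.ndarray, return_mask: bool = False
    ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self._tree.query(points)
        c = self._fine.points[idx]
        t = self._fine.tangents[idx]
        d = points - c
        axial = np.einsum("ij,ij->i", d, t)
        radial = d - axial[:, None] * t
        rr = np.linalg.norm(radial, axis=1)
        r_here = self._r[idx]
        inside = rr <= r_here * (1.0 + 1e-9)
        r_hat = np.where(r_here > 0, rr / r_here, 0.0)

        kind = self.profile.kind
        if kind == "plug":
            mult = np.ones_like(r_hat)
        else:
            mult = 2.0 * (1.0 - np.minimum(r_hat, 1.0) ** 2)
            if kind == "skewed" and self.profile.skew_eccentricity > 0:
                with np.errstate(invalid="ignore", divide="ignore"):
                    cos_phi = np.where(
                        rr > 1e-12,
                        np.einsum("ij,ij->i", radial, self._inner[idx]) / np.maximum(rr, 1e-300),
                        0.0,
                    )
                mult = mult * (1.0 + self.profile.skew_eccentricity * r_hat * cos_phi)
        speed = self._v_mean[idx] * mult
        v = np.where(inside[:, None], speed[:, None] * t, 0.0)
        if return_mask:
            return v, inside
        return v


def analytic_velocity(
    centerline: Centerline,
    radius: RadiusProfileSpec | Callable[[np.ndarray], np.ndarray],
    flow_rate_l_min: float,
    profile: FlowProfileKind | None = None,
) -> VelocityModel:
    """Convenience constructor for :class:`VelocityModel`."""
    return VelocityModel(centerline, radius, flow_rate_l_min, profile)


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

@dataclass
class VelocityField4D:
    """Three-component velocity on a regular voxel grid over cardiac frames.

    ``data`` has shape (n_frames, nx, ny, nz, 3) in m/s; ``origin`` is the
    position (mm) of the center of voxel (0, 0, 0); voxel-center sampling,
    0-based indices, right-handed axes.
    """

    data: np.ndarray
    spacing: float  # mm, isotropic
    origin: np.ndarray  # (3,) mm
    frame_times: np.ndarray  # ms

    def __post_init__(self) -> None:
        if self.data.ndim != 5 or self.data.shape[-1] != 3:
            raise ValueError("data must have shape (nt, nx, ny, nz, 3)")
        if len(self.frame_times) != self.data.shape[0]:
            raise ValueError("frame_times must match the number of frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:4]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing * np.arange(self.data.shape[1 + k])
            for k in range(3)
        )

    def voxel_centers(self) -> np.ndarray:
        ax = self.axes()
        grid = np.meshgrid(*ax, indexing="ij")
        return np.stack([g.ravel() for g in grid], axis=1)

    def frame(self, i: int) -> np.ndarray:
        return self.data[i]

    def interpolator(self, frame: int) -> RegularGridInterpolator:
        """Trilinear interpolator of the 3-vector field of one frame;
        evaluates to zero outside the grid."""
        return RegularGridInterpolator(
            self.axes(),
            self.data[frame],
            method="linear",
            bounds_error=False,
            fill_value=0.0,
        )

    @property
    def voxel_volume_m3(self) -> float:
        return (self.spacing / 1000.0) ** 3


def voxelize(
    velocity_fn: Callable[[np.ndarray], np.ndarray],
    acq: AcquisitionSpec,
    waveform: TemporalWaveform | None = None,
    bounding_box: tuple[np.ndarray, np.ndarray] | None = None,
) -> VelocityField4D:
    """Sample an analytic velocity field onto an acquisition grid.

    Velocities are evaluated at voxel centers, scaled per frame by the
    temporal waveform, and perturbed by i.i.d. Gaussian noise of sd
    ``noise_sd_fraction x VENC`` on each component, inside and outside the
    lumen (static tissue carries noise only).  Reproducible from
    ``acq.seed``.  A warning (not an error) is raised if the noise-free
    peak speed exceeds VENC, since aliasing is not simulated.
    """
    if waveform is None:
        waveform = TemporalWaveform.raised_cosine(n_frames=acq.n_frames)
    if len(waveform.scale_factors) != acq.n_frames:
        raise ValueError("waveform length must equal acq.n_frames")
    if bounding_box is None:
        raise ValueError("bounding_box is required (min_corner, max_corner) in mm")
    lo = np.asarray(bounding_box[0], dtype=float)
    hi = np.asarray(bounding_box[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("bounding box must have positive extent")

    h = acq.voxel_spacing
    shape = np.maximum(np.ceil((hi - lo) / h).astype(int), 1)
    origin = lo + h / 2.0
    axes = [origin[k] + h * np.arange(shape[k]) for k in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grid], axis=1)
    v0 = np.asarray(velocity_fn(pts), dtype=float).reshape(*shape, 3)

    venc_ms = acq.venc / 100.0  # cm/s -> m/s
    peak = np.abs(v0).max()
    if peak > venc_ms:
        warnings.warn(
            f"noise-free speed component {peak:.3f} m/s exceeds VENC "
            f"{venc_ms:.3f} m/s; aliasing is not simulated",
            stacklevel=2,
        )

    rng = np.random.default_rng(acq.seed)
    data = np.empty((acq.n_frames, *shape, 3), dtype=np.float32)
    noise_sd = acq.noise_sd_fraction * venc_ms
    for t, scale in enumerate(waveform.scale_factors):
        frame = v0 * scale
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        data[t] = frame.astype(np.float32)
    return VelocityField4D(
        data=data,
        spacing=h,
        origin=origin,
        frame_times=np.asarray(waveform.frame_times, dtype=float),
    )


def default_bounding_box(
    centerline: Centerline,
    max_radius: float,
    margin: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned box enclosing the lumen with a margin (mm)."""
    pad = max_radius + margin
    return centerline.points.min(axis=0) - pad, centerline.points.max(axis=0) + pad


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

#: Default landmark arc-length fractions delimiting AA / TA / DA1 / DA2.
DEFAULT_LANDMARK_FRACTIONS = (0.0, 0.25, 0.45, 0.70, 1.0)


def make_landmarks(
    centerline: Centerline,
    fractions: Sequence[float] = DEFAULT_LANDMARK_FRACTIONS,
) -> RegionLandmarks:
    """Place the five anatomic landmarks at arc-length fractions."""
    f = np.asarray(fractions, dtype=float)
    if len(f) != 5:
        raise ValueError("exactly 5 landmark fractions required")
    if f[0] < 0 or f[-1] > 1 or not np.all(np.diff(f) > 0):
        raise ValueError("fractions must be strictly increasing within [0, 1]")
    s = f * centerline.length
    return RegionLandmarks(*s)


# ---------------------------------------------------------------------------
# Ground-truth manifest
# ---------------------------------------------------------------------------

def ground_truth_manifest(
    spec: CenterlineSpec,
    radius: RadiusProfileSpec | Callable[[np.ndarray], np.ndarray],
    flow_rate_l_min: float,
    profile: FlowProfileKind | None = None,
    rho: float = RHO_BLOOD,
    station_spacing: float = 2.0,
) -> dict:
    """Analytic per-station ground truth for a phantom.

    Emits arc length, diameter, curvature, flow rate and the advective
    pressure drop ``PD_A(s) = rho * alpha * V(s)^2 / 2`` (mm Hg), where
    ``alpha`` is the profile shape factor and ``V = Q/A``.
    """
    profile = profile or FlowProfileKind()
    n = int(round(spec.length / station_spacing))
    s = np.linspace(0.0, spec.length, n + 1)
    r = np.asarray(radius(s), dtype=float)
    q_si = flow_rate_l_min / 60000.0
    v_mean = q_si / (math.pi * (r / 1000.0) ** 2)
    pd_mmhg = rho * profile.shape_factor * v_mean**2 / 2.0 / _PA_PER_MMHG
    return {
        "s_mm": s.tolist(),
        "diameter_mm": (2.0 * r).tolist(),
        "curvature_per_mm": analytic_curvature(spec, s).tolist(),
        "flow_rate_l_min": flow_rate_l_min,
        "mean_speed_m_s": v_mean.tolist(),
        "pd_a_mmhg": pd_mmhg.tolist(),
        "profile": profile.kind,
        "shape_factor": profile.shape_factor,
        "rho_kg_m3": rho,
    }


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Distributions (mean, sd) defining one study group.

    Anthropometrics follow the study-group characteristics (cardiac output
    in L/min, BMI in kg/m^2, height in m); vessel size is parameterised by
    the height-indexed ascending-aorta diameter (mm/m^2.7); conduit
    inefficiency is imposed by drawing a target advective pressure-drop
    increment (mm Hg) for each segment span, realised geometrically as a
    taper.
    """

    name: str
    cardiac_output: tuple[float, float] = (3.7, 0.8)  # L/min
    height: tuple[float, float] = (1.25, 0.07)  # m
    bmi: tuple[float, float] = (16.4, 2.0)  # kg/m^2
    age: tuple[float, float] = (7.6, 1.0)  # years
    heart_rate: tuple[float, float] = (84.2, 10.2)  # bpm
    aa_diameter_per_h27: tuple[float, float] = (9.23, 1.27)  # mm/m^2.7
    delta_pd_aa: tuple[float, float] = (-0.08, 1.41)  # mm Hg across AA
    delta_pd_ta_da1: tuple[float, float] = (1.0, 1.2)  # mm Hg across TA+DA1
    delta_pd_da2: tuple[float, float] = (2.31, 1.03)  # mm Hg across DA2
    gothic_fraction: float = 0.0  # probability of a gothic arch
    gothic_kappa: tuple[float, float] = (0.22, 0.05)  # 1/mm
    male_fraction: float = 0.5


#: Default study conditions: a healthy control group, an HLHS child group and
#: an HLHS adolescent group with the cohort-characteristic magnitudes.
DEFAULT_GROUP_EFFECTS: dict[str, GroupSpec] = {
    "control": GroupSpec(name="control"),
    "hlhs_child": GroupSpec(
        name="hlhs_child",
        cardiac_output=(2.7, 0.7),
        height=(1.27, 0.08),
        bmi=(16.1, 1.6),
        age=(8.0, 1.7),
        heart_rate=(84.2, 6.4),
        aa_diameter_per_h27=(10.73, 4.45),
        delta_pd_aa=(0.75, 0.86),
        delta_pd_ta_da1=(2.3, 1.4),
        delta_pd_da2=(2.26, 1.11),
        gothic_fraction=0.3,
        male_fraction=0.8,
    ),
    "hlhs_adolescent": GroupSpec(
        name="hlhs_adolescent",
        cardiac_output=(6.8, 2.8),
        height=(1.68, 0.09),
        bmi=(22.7, 4.9),
        age=(15.1, 1.9),
        heart_rate=(72.8, 4.8),
        aa_diameter_per_h27=(8.42, 3.91),
        delta_pd_aa=(-1.63, 2.32),
        delta_pd_ta_da1=(4.0, 1.7),
        delta_pd_da2=(1.83, 1.58),
        gothic_fraction=0.4,
        gothic_kappa=(0.22, 0.09),
        male_fraction=0.57,
    ),
}


@dataclass
class CohortSubject:
    """One synthetic subject: metadata, phantom specs, and ground truth."""

    record: SubjectRecord
    centerline_spec: CenterlineSpec
    radius_knots: tuple[np.ndarray, np.ndarray]  # (s stations mm, radius mm)
    flow_rate_peak_l_min: float
    profile: FlowProfileKind
    landmark_fractions: tuple[float, ...]
    ground_truth: dict  # per-region metrics

    def radius_function(self) -> Callable[[np.ndarray], np.ndarray]:
        interp = PchipInterpolator(*self.radius_knots)

        def r(s: np.ndarray) -> np.ndarray:
            return interp(np.clip(np.asarray(s, float), self.radius_knots[0][0], self.radius_knots[0][-1]))

        return r

    def build(self, acq: AcquisitionSpec | None = None):
        """Realise the phantom: centerline, surface, velocity model and
        (optionally) a voxelized field."""
        cl = make_centerline(self.centerline_spec)
        radius = self.radius_function()
        surface = make_surface(cl, radius)
        vel = VelocityModel(cl, radius, self.flow_rate_peak_l_min, self.profile)
        field = None
        if acq is not None:
            bbox = default_bounding_box(cl, float(np.max(self.radius_knots[1])))
            field = voxelize(vel, acq, TemporalWaveform.raised_cosine(acq.n_frames), bbox)
        return cl, surface, vel, field


def _draw_truncated(rng, mean, sd, lo=-np.inf, hi=np.inf, max_tries=200):
    if not (lo < mean < hi) and sd == 0:
        raise ValueError("distribution incompatible with physical bounds")
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise ValueError(
        f"distribution N({mean}, {sd}) produces non-physical draws within ({lo}, {hi})"
    )


def make_cohort(
    n_per_group: dict[str, int],
    group_effects: dict[str, GroupSpec] | None = None,
    seed: int = 0,
    waveform: TemporalWaveform | None = None,
    station_spacing: float = 2.0,
) -> list[CohortSubject]:
    """Generate a synthetic cohort with analytic per-region ground truth.

    For each subject, anthropometrics and cardiac output are drawn from
    the group distributions; the ascending-aorta radius follows the drawn
    height-indexed diameter; per-segment target pressure-drop increments
    are realised by solving ``V_end^2 = V_start^2 + 2 dP / (rho alpha)``
    for the distal mean speed and hence the distal radius.  The returned
    subjects carry the phantom specs (so the full voxel pipeline can be
    run on any of them) and the analytic ground-truth regional metrics.
    """
    effects = group_effects or DEFAULT_GROUP_EFFECTS
    for g, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"n_per_group[{g!r}] must be >= 1")
        if g not in effects:
            raise ValueError(f"no GroupSpec for group {g!r}")
    waveform = waveform or TemporalWaveform.raised_cosine()
    rng = np.random.default_rng(seed)
    fractions = DEFAULT_LANDMARK_FRACTIONS
    subjects: list[CohortSubject] = []

    for group, n in n_per_group.items():
        gs = effects[group]
        for i in range(n):
            rec_id = f"{group}_{i:03d}"
            height = _draw_truncated(rng, *gs.height, lo=0.5, hi=2.2)
            bmi = _draw_truncated(rng, *gs.bmi, lo=10.0, hi=45.0)
            weight = bmi * height**2
            age = _draw_truncated(rng, *gs.age, lo=0.5, hi=25.0)
            hr = _draw_truncated(rng, *gs.heart_rate, lo=35.0, hi=180.0)
            sex = "M" if rng.random() < gs.male_fraction else "F"
            co = _draw_truncated(rng, *gs.cardiac_output, lo=0.5, hi=15.0)
            record = SubjectRecord(
                id=rec_id, group=group, age=age, sex=sex,
                height=height, weight=weight, heart_rate=hr,
            )

            # geometry: aortic length scales with height; arch radius spans
            # the TA fraction of that length
            length = 145.0 * height  # mm
            d27 = _draw_truncated(rng, *gs.aa_diameter_per_h27, lo=3.0, hi=25.0)
            r_aa = d27 * height**2.7 / 2.0  # mm
            arch_radius = 0.22 * length / math.pi
            if rng.random() < gs.gothic_fraction:
                gk = _draw_truncated(rng, *gs.gothic_kappa,
                                     lo=1.0 / arch_radius + 1e-3, hi=1.0)
                cl_spec = CenterlineSpec(
                    kind="gothic_arch", length=length, arch_radius=arch_radius,
                    gothic_kink_curvature=gk,
                )
            else:
                cl_spec = CenterlineSpec(
                    kind="arch", length=length, arch_radius=arch_radius
                )

            profile = FlowProfileKind("poiseuille")
            alpha = profile.shape_factor
            q_peak = co / waveform.mean  # peak-systole flow, L/min
            q_si = q_peak / 60000.0
            v_aa = q_si / (math.pi * (r_aa / 1000.0) ** 2)

            def v2_after(v2_start: float, dpd_mmhg: float) -> float:
                v2 = v2_start + 2.0 * dpd_mmhg * _PA_PER_MMHG / (RHO_BLOOD * alpha)
                return max(v2, 0.04 * v2_start)  # floor: radius at most ~2.2x

            dpd_aa = _draw_truncated(rng, *gs.delta_pd_aa, lo=-15.0, hi=15.0)
            dpd_tada1 = _draw_truncated(rng, *gs.delta_pd_ta_da1, lo=-15.0, hi=15.0)
            dpd_da2 = _draw_truncated(rng, *gs.delta_pd_da2, lo=-15.0, hi=15.0)

            v2 = [v_aa**2]
            v2.append(v2_after(v2[-1], dpd_aa))          # end of AA
            v2.append(v2_after(v2[-1], 0.4 * dpd_tada1))  # end of TA
            v2.append(v2_after(v2[-2], dpd_tada1))        # end of DA1
            v2.append(v2_after(v2[-1], dpd_da2))          # end of DA2
            radii = [
                1000.0 * math.sqrt(q_si / (math.pi * math.sqrt(x))) for x in v2
            ]
            knots_s = np.asarray(fractions) * length
            knots_r = np.asarray(radii)

            subj = CohortSubject(
                record=record,
                centerline_spec=cl_spec,
                radius_knots=(knots_s, knots_r),
                flow_rate_peak_l_min=q_peak,
                profile=profile,
                landmark_fractions=fractions,
                ground_truth={},
            )
            subj.ground_truth = _cohort_ground_truth(
                subj, alpha, q_peak, record, station_spacing
            )
            subjects.append(subj)
    return subjects


def _cohort_ground_truth(
    subj: CohortSubject,
    alpha: float,
    q_peak_l_min: float,
    record: SubjectRecord,
    station_spacing: float,
) -> dict:
    """Analytic per-region metrics for a cohort subject."""
    length = subj.centerline_spec.length
    n = int(round(length / station_spacing))
    s = np.linspace(0.0, length, n + 1)
    r = subj.radius_function()(s)
    q_si = q_peak_l_min / 60000.0
    v = q_si / (math.pi * (r / 1000.0) ** 2)
    pd = RHO_BLOOD * alpha * v**2 / 2.0 / _PA_PER_MMHG
    kappa = analytic_curvature(subj.centerline_spec, s)
    bounds = np.asarray(subj.landmark_fractions) * length
    regions = {
        "AA": (bounds[0], bounds[1]),
        "TA": (bounds[1], bounds[2]),
        "DA1": (bounds[2], bounds[3]),
        "DA2": (bounds[3], bounds[4]),
        "TA_DA1": (bounds[1], bounds[3]),
    }
    gt: dict[str, dict[str, float]] = {}
    for name, (lo, hi) in regions.items():
        m = (s >= lo) & ((s <= hi) if hi >= bounds[4] - 1e-9 else (s < hi))
        idx = np.where(m)[0]
        gt[name] = {
            "diameter_mean_mm": float((2 * r[m]).mean()),
            "diameter_mean_per_height_2p7": float(
                (2 * r[m]).mean() / record.height**2.7
            ),
            "curvature_peak_per_mm": float(kappa[m].max()),
            "flow_rate_per_bsa": float(q_peak_l_min / record.bsa),
            "pd_a_peak_mmhg": float(pd[m].max()),
            "delta_pd_mmhg": float(pd[idx[-1]] - pd[idx[0]]),
        }
    return gt
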