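"""Shared phantom fixtures.

All fixtures are generated programmatically; the straight-tube bundle is
session-scoped because meshing and voxelization dominate test runtime.
"""

import math

import numpy as np
import pytest

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


def flow_for_mean_speed(v_mean: float, radius_mm: float) -> float:
    """Flow rate (L/min) giving cross-sectional mean speed v_mean (m/s)."""
    return math.pi * (radius_mm / 1000.0) ** 2 * v_mean * 60000.0


class TubeBundle:
    """A straight tube phantom with its analytic Poiseuille field."""

    def __init__(self, radius=10.0, length=120.0, v_mean=0.5, profile="poiseuille"):
        self.radius = radius
        self.length = length
        self.v_mean = v_mean
        self.spec = CenterlineSpec(kind="straight", length=length, point_spacing=2.0)
        self.centerline = make_centerline(self.spec)
        self.radius_spec = RadiusProfileSpec(base_radius=radius)
        self.surface = make_surface(self.centerline, self.radius_spec,
                                    n_circumferential=64)
        self.flow_l_min = flow_for_mean_speed(v_mean, radius)
        self.velocity = VelocityModel(
            self.centerline, self.radius_spec, self.flow_l_min,
            FlowProfileKind(profile),
        )

    def field(self, voxel_spacing=1.0, noise_sd_fraction=0.0, seed=0, n_frames=1):
        acq = AcquisitionSpec(
            voxel_spacing=voxel_spacing, n_frames=n_frames,
            noise_sd_fraction=noise_sd_fraction, seed=seed,
        )
        wf = TemporalWaveform.raised_cosine(n_frames)
        bbox = default_bounding_box(self.centerline, self.radius)
        return voxelize(self.velocity, acq, wf, bbox)


@pytest.fixture(scope="session")
def poiseuille_tube():
    """r = 10 mm straight tube, parabolic profile, mean speed 0.5 m/s."""
    return TubeBundle()


@pytest.fixture(scope="session")
def plug_tube():
    """r = 10 mm straight tube, plug profile, mean speed 1.0 m/s."""
    return TubeBundle(v_mean=1.0, profile="plug")


@pytest.fixture(scope="session")
def poiseuille_field(poiseuille_tube):
    """Noise-free voxelization of the Poiseuille tube at 1 mm."""
    return poiseuille_tube.field(voxel_spacing=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
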