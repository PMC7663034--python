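"""Shared fixtures: analytic shapes and seeded synthetic cohorts."""

import numpy as np
import pytest

from gmnodule import NoduleContour, extract_feature_table, generate_cohort
from gmnodule.synthetic import ShapeSpec, generate_shape


def circle_contour(r=50.0, center=(64.0, 64.0), n=400):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return NoduleContour(
        np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
    )


def ellipse_contour(a=60.0, b=30.0, center=(150.0, 150.0), n=600):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return NoduleContour(
        np.column_stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)])
    )


@pytest.fixture
def disk():
    return circle_contour()


@pytest.fixture
def rectangle():
    """Axis-aligned 40 x 20 rectangle."""
    return NoduleContour([(0.0, 0.0), (40.0, 0.0), (40.0, 20.0), (0.0, 20.0)])


@pytest.fixture
def ellipse():
    return ellipse_contour()


def random_shape(seed, spiculated=None):
    """One seeded random synthetic contour (mixed smooth/irregular)."""
    rng = np.random.default_rng(seed)
    if spiculated is None:
        spiculated = bool(rng.integers(0, 2))
    a = rng.uniform(20, 55)
    b = a * rng.uniform(0.5, 1.4)
    spec = ShapeSpec(
        class_label=int(spiculated),
        base_semi_axes=(a, b),
        rotation_deg=rng.uniform(-80, 80),
        spicule_amplitude=rng.uniform(0.05, 0.2) if spiculated else 0.0,
        spicule_count=int(rng.integers(5, 13)),
        lobulation_amplitude=rng.uniform(0.0, 0.08) if spiculated else 0.0,
        canvas=(256, 256),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return generate_shape(spec)[1]


@pytest.fixture(scope="session")
def random_shapes_50():
    return [random_shape(1000 + i) for i in range(50)]


@pytest.fixture(scope="session")
def cohort_table_200():
    """Feature table of the default 200-per-class synthetic cohort."""
    return extract_feature_table(generate_cohort(200, seed=7))
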