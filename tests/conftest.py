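"""Shared fixtures: analytic chains and small phantoms.

Everything is generated programmatically; no data files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrepmap import mrep, phantom
from mrepmap.core_io import Volume3D

ELLIPSOID_AXES = (25.0, 20.0, 30.0)


def ellipsoid_radial(axes=ELLIPSOID_AXES):
    a, b, c = axes

    def radial(theta, phi):
        st, ct = np.sin(theta), np.cos(theta)
        return 1.0 / np.sqrt((st * np.cos(phi) / a) ** 2
                             + (st * np.sin(phi) / b) ** 2 + (ct / c) ** 2)

    return radial


def bumpy_radial(seed=42, amplitude=0.02, axes=ELLIPSOID_AXES):
    """Ellipsoid with a smooth low-order radial perturbation."""
    rng = np.random.default_rng(seed)
    c1, c2, c3 = rng.normal(size=3)
    base = ellipsoid_radial(axes)

    def radial(theta, phi):
        bump = amplitude * (c1 * np.sin(2 * theta) * np.cos(2 * phi)
                            + c2 * np.cos(3 * theta)
                            + c3 * np.sin(theta) * np.sin(phi))
        return base(theta, phi) * (1.0 + bump)

    return radial


@pytest.fixture(scope="session")
def ellipsoid_chain() -> mrep.MRepChain:
    return mrep.chain_from_radial([0.0, 0.0, 0.0], ellipsoid_radial())


@pytest.fixture(scope="session")
def bumpy_chain() -> mrep.MRepChain:
    return mrep.chain_from_radial([0.0, 0.0, 0.0], bumpy_radial())


@pytest.fixture(scope="session")
def small_grid() -> Volume3D:
    """A 1 x 1 x 3 mm grid that covers the ellipsoid chain."""
    return Volume3D(np.zeros((70, 60, 26)), (1.0, 1.0, 3.0),
                    (-34.5, -29.5, -37.5))


@pytest.fixture(scope="session")
def quiet_pair():
    """A deterministic phantom pair with no setup shift (shared across
    tests that only need one realistic case)."""
    spec = phantom.PhantomSpec(seed=7, translation_mm=(0.0, 0.0, 0.0))
    pct, tct, contours, truth = phantom.generate_pair(spec)
    return spec, pct, tct, contours, truth


def interior_points(chain: mrep.MRepChain, n: int, seed: int = 0,
                    shrink: float = 0.95) -> np.ndarray:
    """Random points strictly inside a chain's surface (rejection
    sampling against the interpolated surface radius)."""
    rng = np.random.default_rng(seed)
    pts = []
    center = chain.hubs.mean(axis=0)
    rmax = np.linalg.norm(chain.tips.reshape(-1, 3) - center, axis=1).max()
    while len(pts) < n:
        q = center + rng.uniform(-rmax, rmax, size=3)
        ijk, ok = mrep.image_to_model_batch(q[None], chain)
        if ok[0] and ijk[0, 2] <= shrink:
            pts.append(q)
    return np.array(pts)
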