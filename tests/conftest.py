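"""Shared fixtures: small landmark configurations and synthetic populations."""

import numpy as np
import pytest

from otolith import LandmarkConfiguration, PopulationSpec, generate_population


def make_config(points, specimen_id="test", block="bony"):
    pts = np.asarray(points, dtype=float)
    k = pts.shape[0]
    return LandmarkConfiguration(
        specimen_id=specimen_id,
        points=pts,
        labels=[f"P{i}" for i in range(k)],
        roles=["single"] * k,
        curve_ids=[None] * k,
        blocks=[block] * k,
    )


def random_rotation(rng):
    """Uniform-ish proper rotation from a random matrix's QR factor."""
    Q, R = np.linalg.qr(rng.normal(size=(3, 3)))
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@pytest.fixture(scope="session")
def default_population():
    """One default synthetic population (12 specimens, meshes included)."""
    return generate_population(PopulationSpec(seed=11))


@pytest.fixture(scope="session")
def landmark_population():
    """Landmarks-only population for statistics tests."""
    return generate_population(PopulationSpec(seed=7, generate_meshes=False))
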