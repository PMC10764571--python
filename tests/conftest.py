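import dataclasses

import numpy as np
import pytest

import bilayer_turing as bt
from bilayer_turing.config import config_from_dict


@pytest.fixture
def rng():
    return np.random.default_rng(20240103)


@pytest.fixture
def fig2a_bilayer():
    """Two identical Schnakenberg layers, A = B = I, bulk below threshold."""
    return config_from_dict({"preset": "fig2a"}).bilayer


@pytest.fixture
def fig2b_bilayer():
    return config_from_dict({"preset": "fig2b"}).bilayer


@pytest.fixture
def fig2a_small(fig2a_bilayer):
    """fig2a kinetics on a short domain for affordable simulation."""
    return dataclasses.replace(fig2a_bilayer, geometry=bt.Geometry1D1D(100.0))


@pytest.fixture
def chemotaxis_bulk_layer():
    """Three-species chemotaxis bulk with the reference bulk kinetics and the
    strong-sensitivity overrides (chi=120, d_u=d_c=25)."""
    kin = bt.make_preset(
        "pseudo_linear_bulk",
        r0=0.2, a0=3.0, a1=8.0, b=2.0, a2=7.0,
        b0=0.75, c1=0.5, c2=1.5, d=1.0, cstar=0.25,
    )
    return bt.LayerModel(kin, (25.0, 35.0, 25.0), bt.ChemotaxisSpec(chi=120.0))


def random_bilayer_1d1d(rng, n=2, m=2, stable_layers=True):
    """A random small bilayer with positive diagonal diffusion, linear
    kinetics built from random (optionally Hurwitz-stable) Jacobians."""

    def random_kinetics(dim):
        while True:
            J = rng.normal(size=(dim, dim))
            if not stable_layers or np.max(np.linalg.eigvals(J).real) < -0.05:
                break
        return bt.KineticsModel(
            dim, {}, lambda w, J=J: J @ np.asarray(w, float),
            lambda w, J=J: J.copy(), "random_linear",
            tuple(f"x{i}" for i in range(dim)), np.zeros(dim),
        )

    surface = bt.LayerModel(random_kinetics(n), tuple(rng.uniform(0.2, 3.0, n)))
    bulk = bt.LayerModel(random_kinetics(m), tuple(rng.uniform(0.2, 3.0, m)))
    A = rng.uniform(-0.5, 1.5, (n, n))
    B = rng.uniform(-0.5, 1.5, (n, n))
    return bt.BilayerModel(surface, bulk, A, B, bt.Geometry1D1D(100.0))
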