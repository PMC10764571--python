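"""Reaction kinetics presets with analytic Jacobians.

Each preset returns a :class:`KineticsModel` bundling the reaction rate
function ``f(u)`` of a single layer, its analytic Jacobian, and the parameter
record.  The presets are the standard pattern-formation kinetics used for
bilayer (epidermis/dermis-like) Turing analysis:

``schnakenberg``
    Activator-depleted substrate model ``f = s(a - u + u^2 v)``,
    ``g = s(b - u^2 v)`` with ``0 < a < b``, ``s > 0``.
``pseudo_linear_surface`` / ``pseudo_linear_bulk``
    Piecewise-linear (clipped) autocatalytic kinetics in the style of
    Kondo-Asai, with a clip ``phi(z) = max(0, min(z, M))`` guaranteeing
    bounded rates and positivity of solutions.  The bulk variant carries a
    third species, chemotactic cells with logistic growth
    ``r(c) = r0 c (c* - c)``.
``keller_segel_linear``
    Minimal chemoattractant/cell pair ``f(u, c) = a c - b u``,
    ``r(c) = c(c* - c)``.
``jp_family``
    One-parameter family of linear(ised) kinetics with Jacobian
    ``[[1, -1], [p, 1 - p]]`` whose critical inhibitor diffusion
    ``1 + p + 2 sqrt(p)`` is concave in ``p``.
``gierer_meinhardt``
    Classical activator-inhibitor model, provided for convenience.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "KineticsModel",
    "ClipFunction",
    "KineticsError",
    "EquilibriumNotFound",
    "make_preset",
    "find_equilibrium",
    "schnakenberg",
    "pseudo_linear_surface",
    "pseudo_linear_bulk",
    "keller_segel_linear",
    "jp_family",
    "gierer_meinhardt",
    "PRESETS",
]


class KineticsError(ValueError):
    """Invalid preset name or parameter."""


class EquilibriumNotFound(RuntimeError):
    """Newton iteration for a kinetic equilibrium failed."""


@dataclass(frozen=True)
class ClipFunction:
    """Piecewise-linear clip ``phi(z) = max(0, min(z, M))``.

    Acts as the identity on ``(0, M)``; its derivative is 1 there and 0
    outside.  ``M`` is chosen large enough that the kinetics behave linearly
    around the equilibrium.
    """

    M: float

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise KineticsError(f"clip cap M must be positive, got {self.M}")

    def __call__(self, z):
        return np.clip(z, 0.0, self.M)

    def derivative(self, z, warn: bool = False):
        """Derivative of the clip; optionally warn when evaluated off the
        linear branch (the Jacobian is then one-sided)."""
        z = np.asarray(z, dtype=float)
        on_branch = (z > 0.0) & (z < self.M)
        if warn and not np.all(on_branch):
            warnings.warn(
                "Jacobian of clipped kinetics evaluated at a clipped point; "
                "linearisation is one-sided there.",
                RuntimeWarning,
                stacklevel=2,
            )
        return np.where(on_branch, 1.0, 0.0)


@dataclass(frozen=True)
class KineticsModel:
    """A reaction kinetics: rates, analytic Jacobian and parameters.

    Attributes
    ----------
    n_species:
        Number of interacting species.
    params:
        Named real parameters of the preset.
    rates:
        Map from a state vector of length ``n_species`` to the reaction
        rate vector.
    jacobian:
        Map from a state vector to the ``n x n`` Jacobian of ``rates``.
    label:
        Preset identifier.
    species:
        Species names, used to address diffusion coefficients (``d_u`` etc.).
    equilibrium_hint:
        A state near (or at) a homogeneous equilibrium, used to seed Newton.
    """

    n_species: int
    params: Mapping[str, float]
    rates: Callable[[np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    label: str
    species: tuple[str, ...]
    equilibrium_hint: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.species) != self.n_species:
            raise KineticsError(
                f"{self.label}: species names {self.species} inconsistent "
                f"with n_species={self.n_species}"
            )


def _require(params: Mapping[str, float], preset: str, **conditions) -> None:
    for key, ok in conditions.items():
        if not ok:
            raise KineticsError(
                f"preset {preset!r}: parameter {key!r}={params.get(key)} "
                "missing or out of range"
            )


def schnakenberg(a: float, b: float, s: float = 1.0) -> KineticsModel:
    """Schnakenberg kinetics ``f = s(a - u + u^2 v)``, ``g = s(b - u^2 v)``.

    The unique positive equilibrium is ``u* = a + b``, ``v* = b / (a + b)^2``.
    """
    params = {"a": a, "b": b, "s": s}
    _require(params, "schnakenberg", a=0 < a, b=a < b, s=s > 0)

    def rates(w: np.ndarray) -> np.ndarray:
        u, v = w
        return np.array([s * (a - u + u * u * v), s * (b - u * u * v)])

    def jacobian(w: np.ndarray) -> np.ndarray:
        u, v = w
        return np.array(
            [[s * (-1.0 + 2.0 * u * v), s * u * u], [-2.0 * s * u * v, -s * u * u]]
        )

    ustar = a + b
    hint = np.array([ustar, b / ustar**2])
    return KineticsModel(2, params, rates, jacobian, "schnakenberg", ("u", "v"), hint)


def _pseudo_linear_equilibrium(
    a0: float, a1: float, b: float, a2: float, b0: float, c1: float, d: float, c2: float
) -> np.ndarray:
    # On the linear branch (phi = identity) the equilibrium solves
    #   (a2 - a1) u + b v = a0,   -d u + (c2 - c1) v = b0.
    A = np.array([[a2 - a1, b], [-d, c2 - c1]])
    rhs = np.array([a0, b0])
    if abs(np.linalg.det(A)) < 1e-14:
        raise KineticsError(
            "pseudo_linear: linear-branch equilibrium system is singular"
        )
    return np.linalg.solve(A, rhs)


def pseudo_linear_surface(
    a0: float,
    a1: float,
    b: float,
    a2: float,
    b0: float,
    c1: float,
    d: float,
    c2: float,
    M: float | None = None,
) -> KineticsModel:
    """Clipped pseudo-linear surface kinetics.

    ``f = phi(a0 + a1 u - b v) - a2 u``, ``g = phi(b0 + c1 v + d u) - c2 v``
    with autocatalytic feedback through ``a1 u`` and ``c1 v``.  The default
    clip cap is ten times the largest linear-branch equilibrium image, so the
    kinetics are exactly linear near the equilibrium.
    """
    params = {"a0": a0, "a1": a1, "b": b, "a2": a2, "b0": b0, "c1": c1, "d": d, "c2": c2}
    conditions = {k: v >= 0 for k, v in params.items()}
    conditions["a2"] = a2 > 0
    conditions["c2"] = c2 > 0
    _require(params, "pseudo_linear_surface", **conditions)
    ueq = _pseudo_linear_equilibrium(a0, a1, b, a2, b0, c1, d, c2)
    if M is None:
        M = 10.0 * float(max(a2 * ueq[0], c2 * ueq[1]))
    phi = ClipFunction(M)
    params = {**params, "M": phi.M}

    def args(w):
        u, v = w
        return a0 + a1 * u - b * v, b0 + c1 * v + d * u

    def rates(w: np.ndarray) -> np.ndarray:
        u, v = w
        z1, z2 = args(w)
        return np.array([phi(z1) - a2 * u, phi(z2) - c2 * v])

    def jacobian(w: np.ndarray) -> np.ndarray:
        z1, z2 = args(w)
        p1 = float(phi.derivative(z1, warn=True))
        p2 = float(phi.derivative(z2, warn=True))
        return np.array([[a1 * p1 - a2, -b * p1], [d * p2, c1 * p2 - c2]])

    return KineticsModel(
        2, params, rates, jacobian, "pseudo_linear_surface", ("u", "v"), ueq
    )


def pseudo_linear_bulk(
    r0: float,
    a0: float,
    a1: float,
    b: float,
    a2: float,
    b0: float,
    c1: float,
    c2: float,
    d: float,
    cstar: float,
    M: float | None = None,
) -> KineticsModel:
    """Clipped pseudo-linear bulk kinetics with chemotactic cells.

    Species ``(u, v, c)``: the signalling molecules are produced by the cells
    without feedback, ``f = phi(a0 + a1 c - b v) - a2 u``,
    ``g = phi(b0 + (c1 + d) c) - c2 v``, and the cells grow logistically,
    ``r = r0 c (c* - c)``.
    """
    params = {
        "r0": r0, "a0": a0, "a1": a1, "b": b, "a2": a2,
        "b0": b0, "c1": c1, "c2": c2, "d": d, "cstar": cstar,
    }
    conditions = {k: v >= 0 for k, v in params.items()}
    conditions.update(r0=r0 > 0, a2=a2 > 0, c2=c2 > 0, cstar=cstar > 0)
    _require(params, "pseudo_linear_bulk", **conditions)
    vstar = (b0 + (c1 + d) * cstar) / c2
    ustar = (a0 + a1 * cstar - b * vstar) / a2
    if M is None:
        M = 10.0 * float(max(a2 * ustar, c2 * vstar))
    phi = ClipFunction(M)
    params = {**params, "M": phi.M}
    hint = np.array([ustar, vstar, cstar])

    def rates(w: np.ndarray) -> np.ndarray:
        u, v, c = w
        z1 = a0 + a1 * c - b * v
        z2 = b0 + (c1 + d) * c
        return np.array(
            [phi(z1) - a2 * u, phi(z2) - c2 * v, r0 * c * (cstar - c)]
        )

    def jacobian(w: np.ndarray) -> np.ndarray:
        u, v, c = w
        z1 = a0 + a1 * c - b * v
        z2 = b0 + (c1 + d) * c
        p1 = float(phi.derivative(z1, warn=True))
        p2 = float(phi.derivative(z2, warn=True))
        return np.array(
            [
                [-a2, -b * p1, a1 * p1],
                [0.0, -c2, (c1 + d) * p2],
                [0.0, 0.0, r0 * (cstar - 2.0 * c)],
            ]
        )

    return KineticsModel(
        3, params, rates, jacobian, "pseudo_linear_bulk", ("u", "v", "c"), hint
    )


def keller_segel_linear(a: float, b: float, cstar: float) -> KineticsModel:
    """Linear Keller-Segel pair: ``f(u, c) = a c - b u``, ``r(c) = c(c* - c)``."""
    params = {"a": a, "b": b, "cstar": cstar}
    _require(params, "keller_segel_linear", a=a > 0, b=b > 0, cstar=cstar > 0)

    def rates(w: np.ndarray) -> np.ndarray:
        u, c = w
        return np.array([a * c - b * u, c * (cstar - c)])

    def jacobian(w: np.ndarray) -> np.ndarray:
        u, c = w
        return np.array([[-b, a], [0.0, cstar - 2.0 * c]])

    hint = np.array([a * cstar / b, cstar])
    return KineticsModel(
        2, params, rates, jacobian, "keller_segel_linear", ("u", "c"), hint
    )


def jp_family(p: float) -> KineticsModel:
    """Linearised kinetics with Jacobian ``[[1, -1], [p, 1 - p]]`` at (0, 0).

    The critical inhibitor diffusion of this family, ``1 + p + 2 sqrt(p)``,
    is concave in ``p``, which makes pairs of members a canonical example of
    stabilisation by strong inter-layer coupling.
    """
    params = {"p": p}
    _require(params, "jp_family", p=p > 0)
    J = np.array([[1.0, -1.0], [p, 1.0 - p]])

    def rates(w: np.ndarray) -> np.ndarray:
        return J @ np.asarray(w, dtype=float)

    def jacobian(w: np.ndarray) -> np.ndarray:
        return J.copy()

    return KineticsModel(
        2, params, rates, jacobian, "jp_family", ("u", "v"), np.zeros(2)
    )


def gierer_meinhardt(a: float, b: float) -> KineticsModel:
    """Gierer-Meinhardt kinetics ``f = a - b u + u^2 / v``, ``g = u^2 - v``."""
    params = {"a": a, "b": b}
    _require(params, "gierer_meinhardt", a=a >= 0, b=b > 0)

    def rates(w: np.ndarray) -> np.ndarray:
        u, v = w
        return np.array([a - b * u + u * u / v, u * u - v])

    def jacobian(w: np.ndarray) -> np.ndarray:
        u, v = w
        return np.array([[-b + 2.0 * u / v, -(u * u) / (v * v)], [2.0 * u, -1.0]])

    ustar = (a + 1.0) / b
    hint = np.array([ustar, ustar**2])
    return KineticsModel(
        2, params, rates, jacobian, "gierer_meinhardt", ("u", "v"), hint
    )


PRESETS: dict[str, Callable[..., KineticsModel]] = {
    "schnakenberg": schnakenberg,
    "pseudo_linear_surface": pseudo_linear_surface,
    "pseudo_linear_bulk": pseudo_linear_bulk,
    "keller_segel_linear": keller_segel_linear,
    "jp_family": jp_family,
    "gierer_meinhardt": gierer_meinhardt,
}


def make_preset(name: str, **params: float) -> KineticsModel:
    """Build a kinetics preset by name.

    Raises
    ------
    KineticsError
        For an unknown preset name, or a missing/out-of-range parameter
        (the message names the offending key).
    """
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KineticsError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    try:
        return factory(**params)
    except TypeError as exc:
        raise KineticsError(f"preset {name!r}: {exc}") from None


def find_equilibrium(
    model: KineticsModel,
    guess: np.ndarray | None = None,
    *,
    rtol: float = 1e-12,
    max_iter: int = 100,
) -> np.ndarray:
    """Newton solve of ``rates(w) = 0`` with the analytic Jacobian.

    Returns ``w`` with ``||rates(w)|| <= rtol * (1 + ||w||)``.

    Raises
    ------
    EquilibriumNotFound
        On a singular Jacobian at an iterate or non-convergence.
    """
    if guess is None:
        if model.equilibrium_hint is None:
            raise EquilibriumNotFound(f"{model.label}: no guess and no hint")
        guess = model.equilibrium_hint
    w = np.array(guess, dtype=float)
    for _ in range(max_iter):
        r = model.rates(w)
        if np.linalg.norm(r) <= rtol * (1.0 + np.linalg.norm(w)):
            return w
        J = model.jacobian(w)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise EquilibriumNotFound(
                f"{model.label}: singular Jacobian at iterate {w}"
            ) from exc
        w = w + step
    raise EquilibriumNotFound(
        f"{model.label}: Newton did not converge in {max_iter} iterations "
        f"(residual {np.linalg.norm(model.rates(w)):.3e})"
    )
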