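"""Homogeneous equilibria of the coupled bilayer system.

In the 1D-1D geometry the coupled equilibrium solves the algebraic system

    f_S(u_S*) + eta A (u_B*~ - u_S*) = 0,
    f_B(u_B*) + eta B~ (u_S*~ - u_B*) = 0,

and may be *asymmetric* (u_S* != u_B*~) and eta-dependent.  In the 1D-2D
geometry the interface condition forces a shared equilibrium, independent of
eta, with f_S(u_S*) = 0, f_B(u_B*) = 0 and u_S* equal to the first n bulk
components.

The solver continues the branch rooted at the uncoupled (eta = 0) equilibria
by an adaptive Newton continuation in eta; no global root enumeration is
attempted, since existence and uniqueness away from eta = 0 cannot be
guaranteed in general.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import find_equilibrium
from .models import BilayerModel, Geometry1D2D

__all__ = [
    "EquilibriumState",
    "EquilibriumError",
    "coupled_equilibrium",
    "equilibrium_sensitivity",
    "equilibrium_curve",
]

_RTOL = 1e-12


class EquilibriumError(RuntimeError):
    """Continuation or shared-root failure."""


@dataclass(frozen=True)
class EquilibriumState:
    """Homogeneous equilibrium pair of the coupled system."""

    u_S: np.ndarray
    u_B: np.ndarray
    eta: float
    residual: float

    @property
    def u_B_tilde(self) -> np.ndarray:
        return self.u_B[: len(self.u_S)]


def _coupled_residual(
    bilayer: BilayerModel, eta: float, u_S: np.ndarray, u_B: np.ndarray
) -> np.ndarray:
    rS = bilayer.surface.kinetics.rates(u_S) + eta * bilayer.A @ (
        u_B[: bilayer.n] - u_S
    )
    rB = bilayer.bulk.kinetics.rates(u_B) + eta * bilayer.B_tilde @ (
        bilayer.pad_to_bulk(u_S) - u_B
    )
    return np.concatenate([rS, rB])


def _coupled_jacobian(
    bilayer: BilayerModel, eta: float, u_S: np.ndarray, u_B: np.ndarray
) -> np.ndarray:
    n, m = bilayer.n, bilayer.m
    J = np.zeros((n + m, n + m))
    J[:n, :n] = bilayer.surface.kinetics.jacobian(u_S) - eta * bilayer.A
    J[:n, n : n + n] = eta * bilayer.A
    Bt = bilayer.B_tilde
    J[n:, :n] = eta * Bt[:, :n]
    J[n:, n:] = bilayer.bulk.kinetics.jacobian(u_B) - eta * Bt
    return J


def _newton(bilayer, eta, w0, max_iter=50):
    n = bilayer.n
    w = np.array(w0, dtype=float)
    # the exchange term eta*A*(u_B - u_S) contributes round-off ~ eps*eta*|A|
    # to the residual, so the attainable tolerance grows with eta
    eps = np.finfo(float).eps
    coupling_scale = eta * (np.abs(bilayer.A).max() + np.abs(bilayer.B).max())
    for _ in range(max_iter):
        r = _coupled_residual(bilayer, eta, w[:n], w[n:])
        tol = (_RTOL + 100.0 * eps * coupling_scale) * (1.0 + np.linalg.norm(w))
        if np.linalg.norm(r, np.inf) <= tol:
            return w
        J = _coupled_jacobian(bilayer, eta, w[:n], w[n:])
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise EquilibriumError(
                f"singular Jacobian in coupled Newton at eta={eta}"
            ) from exc
        w = w + step
    raise EquilibriumError(f"coupled Newton did not converge at eta={eta}")


def _uncoupled_state(bilayer: BilayerModel) -> np.ndarray:
    u_S0 = find_equilibrium(bilayer.surface.kinetics)
    u_B0 = find_equilibrium(bilayer.bulk.kinetics)
    return np.concatenate([u_S0, u_B0])


def coupled_equilibrium(
    bilayer: BilayerModel,
    eta: float,
    start: EquilibriumState | None = None,
    *,
    step0: float = 1e-3,
    max_step: float = 1.0,
) -> EquilibriumState:
    """Equilibrium of the coupled system at coupling strength ``eta``.

    For the 1D-1D geometry the branch is continued in eta from the uncoupled
    equilibria (or from ``start``) with an adaptive step: the step starts at
    ``step0``, doubles after each successful Newton solve (capped at
    ``max_step`` or a quarter of the current eta, whichever is larger), and
    halves on failure.  For the 1D-2D geometry the two layers must share a
    root; a mismatch beyond 1e-10 raises :class:`EquilibriumError`.
    """
    n = bilayer.n
    if isinstance(bilayer.geometry, Geometry1D2D):
        u_S0 = find_equilibrium(bilayer.surface.kinetics)
        u_B0 = find_equilibrium(bilayer.bulk.kinetics)
        mismatch = float(
            np.linalg.norm(bilayer.surface.kinetics.rates(u_S0))
            + np.linalg.norm(bilayer.bulk.kinetics.rates(u_B0))
            + np.linalg.norm(u_S0 - u_B0[:n], np.inf)
        )
        if mismatch > 1e-10:
            raise EquilibriumError(
                "1D-2D geometry requires a shared homogeneous equilibrium; "
                f"layer roots differ by {mismatch:.3e}"
            )
        res = float(
            np.linalg.norm(
                np.concatenate(
                    [bilayer.surface.kinetics.rates(u_S0), bilayer.bulk.kinetics.rates(u_B0)]
                ),
                np.inf,
            )
        )
        return EquilibriumState(u_S0, u_B0, float(eta), res)

    if start is None:
        w = _uncoupled_state(bilayer)
        eta_cur = 0.0
    else:
        w = np.concatenate([start.u_S, start.u_B])
        eta_cur = start.eta

    step = min(step0, abs(eta - eta_cur)) if eta != eta_cur else 0.0
    direction = 1.0 if eta >= eta_cur else -1.0
    while abs(eta - eta_cur) > 0:
        step = min(step, abs(eta - eta_cur))
        if step <= 0:
            step = min(step0, abs(eta - eta_cur))
        trial = eta_cur + direction * step
        try:
            w = _newton(bilayer, trial, w)
        except EquilibriumError:
            if step < 1e-10:
                raise
            step *= 0.5
            continue
        eta_cur = trial
        step = min(2.0 * step, max(max_step, 0.25 * abs(eta_cur)))

    w = _newton(bilayer, eta, w)
    res = float(
        np.linalg.norm(_coupled_residual(bilayer, eta, w[:n], w[n:]), np.inf)
    )
    return EquilibriumState(w[:n], w[n:], float(eta), res)


def equilibrium_curve(
    bilayer: BilayerModel, etas: np.ndarray
) -> list[EquilibriumState]:
    """Equilibria along an increasing eta grid, each continued from the last."""
    out: list[EquilibriumState] = []
    prev: EquilibriumState | None = None
    for eta in etas:
        prev = coupled_equilibrium(bilayer, float(eta), start=prev)
        out.append(prev)
    return out


def equilibrium_sensitivity(
    bilayer: BilayerModel,
) -> tuple[np.ndarray, np.ndarray]:
    """First-order eta-sensitivity of the equilibrium branch at eta = 0.

    Returns ``(u_S*'(0), u_B*'(0))`` where

        u_S*'(0) = J_S^-1 A (u_S*(0) - u_B*~(0)),
        u_B*'(0) = J_B^-1 B~ (u_B*(0) - u_S*~(0)),

    with the Jacobians of the uncoupled kinetics at their own equilibria.
    Both vanish when the uncoupled layers share their equilibrium.
    """
    u_S0 = find_equilibrium(bilayer.surface.kinetics)
    u_B0 = find_equilibrium(bilayer.bulk.kinetics)
    J_S = bilayer.surface.kinetics.jacobian(u_S0)
    J_B = bilayer.bulk.kinetics.jacobian(u_B0)
    try:
        dS = np.linalg.solve(J_S, bilayer.A @ (u_S0 - u_B0[: bilayer.n]))
        dB = np.linalg.solve(
            J_B, bilayer.B_tilde @ (u_B0 - bilayer.pad_to_bulk(u_S0))
        )
    except np.linalg.LinAlgError as exc:
        raise EquilibriumError("singular kinetics Jacobian at eta=0") from exc
    return dS, dB
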