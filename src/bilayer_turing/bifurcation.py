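"""Critical bifurcation parameters of the coupled bilayer system.

The Turing bifurcation at coupling strength eta is characterised by the two
marginal conditions

    a0(eta, w*, xi_c, delta_c) = 0,   d a0 / d xi (eta, w*, xi_c, delta_c) = 0,

where a0 is the dispersion determinant at zero growth rate and delta is the
bifurcation parameter (any diffusion coefficient, or the chemotactic
sensitivity).  This module provides

* the classical single-layer critical diffusion (closed form for two-species
  reaction-diffusion, numerical onset search otherwise, e.g. chemotaxis),
* Newton solution and eta-continuation of the coupled marginal curve
  delta_c(eta),
* the weak-coupling tangent delta_c'(0) from the comatrix formulas,
  including the asymmetric-equilibria contribution,
* the strong-coupling (eta -> infinity) reduced system and its asymptotic
  critical parameter, with the midpoint-convexity criterion deciding whether
  strong coupling can stabilise or create patterns,
* the eta-band in which the homogeneous mode q = 0 itself is unstable, and
* instability-region rasters over an (eta, delta) grid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .equilibria import (
    EquilibriumState,
    coupled_equilibrium,
    equilibrium_sensitivity,
)
from .kinetics import KineticsModel, find_equilibrium
from .linear_stability import (
    build_linearization,
    comatrix,
    make_a0,
    matrix_entire_functions,
    mode_scan,
)
from .models import BilayerModel, Geometry1D2D, LayerModel

__all__ = [
    "CriticalPoint",
    "InstabilityRegion",
    "BifurcationError",
    "NoTuringInstability",
    "layer_critical_diffusion",
    "critical_point",
    "marginal_curve",
    "weak_coupling_slope",
    "strong_coupling_limit",
    "average_kinetics",
    "midpoint_convexity_verdict",
    "homogeneous_mode_band",
    "instability_region",
]

# default xi window for branch searches; the onset xi of every system
# considered here lies well inside it
_XI_GRID = np.geomspace(1e-4, 1e2, 64)


class BifurcationError(RuntimeError):
    """Newton/continuation failure or degenerate transversality."""


class NoTuringInstability(BifurcationError):
    """The layer admits no classical diffusion-driven instability."""


@dataclass(frozen=True)
class CriticalPoint:
    """One point of the marginal curve: a0 = 0 and da0/dxi = 0."""

    xi_c: float
    delta_c: float
    eta: float
    branch_id: int = 0
    branches: tuple[tuple[float, float], ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class InstabilityRegion:
    """Boolean raster of mode-scan instability over an (eta, delta) grid."""

    eta_grid: np.ndarray
    delta_grid: np.ndarray
    unstable: np.ndarray  # shape (len(eta_grid), len(delta_grid))
    valid: np.ndarray
    mode_L: float
    q_max: int


# ---------------------------------------------------------------------------
# Single-layer critical diffusion
# ---------------------------------------------------------------------------


def _two_species_closed_form(
    J: np.ndarray, d_fixed: float, delta_index: int
) -> tuple[float, float]:
    """Classical critical inhibitor diffusion for a two-species system.

    With the delta-species as inhibitor and the other (activator) species
    diffusing at the fixed rate ``d_fixed``:

        delta_c / d = ((sqrt(det J) + sqrt(-f_v g_u)) / f_u)^2,
        xi_c * d    = (delta_c/d * f_u + g_v) / (2 delta_c/d).
    """
    i = 1 - delta_index  # activator slot
    j = delta_index
    f_u, f_v = J[i, i], J[i, j]
    g_u, g_v = J[j, i], J[j, j]
    tr, det = f_u + g_v, f_u * g_v - f_v * g_u
    if det <= 0:
        raise NoTuringInstability(
            f"equilibrium has det J = {det:.4g} <= 0; no Turing pair"
        )
    if tr >= 0:
        warnings.warn(
            f"equilibrium is not strictly stable to homogeneous perturbations "
            f"(tr J = {tr:.4g} >= 0); the critical-diffusion closed form is "
            "still evaluated",
            RuntimeWarning,
            stacklevel=3,
        )
    if f_u <= 0:
        raise NoTuringInstability(
            f"no classical two-species Turing instability: f_u={f_u:.4g} <= 0"
        )
    if -f_v * g_u < 0:
        raise NoTuringInstability(
            f"cross terms have the wrong sign: -f_v g_u = {-f_v * g_u:.4g} < 0"
        )
    dtilde = ((np.sqrt(det) + np.sqrt(-f_v * g_u)) / f_u) ** 2
    delta_c = d_fixed * dtilde
    xi_c = (dtilde * f_u + g_v) / (2.0 * dtilde) / d_fixed
    return float(delta_c), float(xi_c)


def _min_det_over_xi(layer: LayerModel, eq: np.ndarray) -> tuple[float, float]:
    J = layer.kinetics.jacobian(eq)
    D = layer.diffusion_matrix(eq)

    def det_at(xi: float) -> float:
        return float(np.linalg.det(xi * D - J))

    vals = np.array([det_at(x) for x in _XI_GRID])
    i = int(np.argmin(vals))
    lo = _XI_GRID[max(i - 1, 0)]
    hi = _XI_GRID[min(i + 1, len(_XI_GRID) - 1)]
    res = minimize_scalar(det_at, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    if res.fun < vals[i]:
        return float(res.fun), float(res.x)
    return float(vals[i]), float(_XI_GRID[i])


def layer_critical_diffusion(
    layer: LayerModel,
    delta_name: str,
    *,
    window: tuple[float, float] = (1e-3, 1e6),
) -> tuple[float, float]:
    """Critical value of one diffusion parameter of a single layer.

    ``delta_name`` is the species name whose diffusion coefficient is the
    bifurcation parameter (or ``"chi"`` for the chemotactic sensitivity).
    Returns ``(delta_c, xi_c)``.

    Two-species pure reaction-diffusion layers use the classical closed
    form; layers with three or more species, or with chemotaxis, locate the
    smallest parameter value at which ``min_xi det(xi D - J)`` touches zero,
    by bracketing on a geometric grid and bisection to relative tolerance
    1e-6.
    """
    eq = find_equilibrium(layer.kinetics)
    J = layer.kinetics.jacobian(eq)
    if np.max(np.linalg.eigvals(J).real) >= 0:
        warnings.warn(
            "layer equilibrium is not strictly stable without diffusion; "
            "the marginal onset is still located",
            RuntimeWarning,
            stacklevel=2,
        )

    if delta_name != "chi":
        idx = layer.kinetics.species.index(delta_name)

    if (
        layer.n_species == 2
        and layer.chemotaxis is None
        and delta_name != "chi"
    ):
        d_fixed = layer.diffusivities[1 - idx]
        return _two_species_closed_form(J, d_fixed, idx)

    def phi(delta: float) -> float:
        if delta_name == "chi":
            import dataclasses

            lay = dataclasses.replace(
                layer,
                chemotaxis=dataclasses.replace(layer.chemotaxis, chi=delta),
            )
        else:
            lay = layer.replace_diffusivity(idx, delta)
        return _min_det_over_xi(lay, eq)[0]

    deltas = np.geomspace(window[0], window[1], 130)
    signs = None
    prev_d, prev_v = deltas[0], phi(deltas[0])
    bracket = None
    for d in deltas[1:]:
        v = phi(d)
        if prev_v == 0.0 or prev_v * v < 0:
            bracket = (prev_d, d)
            break
        prev_d, prev_v = d, v
    if bracket is None:
        raise NoTuringInstability(
            f"no onset of marginal instability for {delta_name!r} in "
            f"window {window}"
        )
    delta_c = brentq(phi, *bracket, rtol=1e-8)
    if delta_name == "chi":
        import dataclasses

        lay = dataclasses.replace(
            layer, chemotaxis=dataclasses.replace(layer.chemotaxis, chi=delta_c)
        )
    else:
        lay = layer.replace_diffusivity(idx, delta_c)
    xi_c = _min_det_over_xi(lay, eq)[1]
    return float(delta_c), float(xi_c)


# ---------------------------------------------------------------------------
# Coupled critical point and continuation
# ---------------------------------------------------------------------------


def _driving_layer(bilayer: BilayerModel, delta_name: str) -> str:
    if delta_name.endswith("S") and delta_name.startswith("d_"):
        return "surface"
    return "bulk"


def _layer_species_name(delta_name: str) -> str:
    if delta_name in ("chi",):
        return "chi"
    if delta_name == "d_c":
        return "c"
    return delta_name[2:-1]


def _newton_2d(a0, xi0, delta0, *, tol=1e-10, max_iter=60):
    xi, delta = float(xi0), float(delta0)

    def G(x, d):
        hx = 1e-6 * (1.0 + x)
        g0 = a0(x, d)
        g1 = (a0(x + hx, d) - a0(max(x - hx, 0.0), d)) / (x + hx - max(x - hx, 0.0))
        return np.array([g0, g1])

    for _ in range(max_iter):
        g = G(xi, delta)
        hx = 1e-6 * (1.0 + xi)
        hd = 1e-6 * (1.0 + abs(delta))
        Jx = (G(xi + hx, delta) - G(xi - hx, delta)) / (2 * hx) if xi > hx else (
            G(xi + hx, delta) - g
        ) / hx
        Jd = (G(xi, delta + hd) - G(xi, delta - hd)) / (2 * hd)
        Jac = np.column_stack([Jx, Jd])
        try:
            step = np.linalg.solve(Jac, -g)
        except np.linalg.LinAlgError as exc:
            raise BifurcationError(
                "singular Jacobian in critical-point Newton "
                "(possible transversality failure)"
            ) from exc
        # damp steps that would leave the admissible quadrant
        lam = 1.0
        while xi + lam * step[0] <= 0 or delta + lam * step[1] <= 0:
            lam *= 0.5
            if lam < 1e-8:
                raise BifurcationError("critical-point Newton left xi, delta > 0")
        xi += lam * step[0]
        delta += lam * step[1]
        if max(abs(step[0]) / (1.0 + xi), abs(step[1]) / (1.0 + abs(delta))) < tol:
            return xi, delta
    raise BifurcationError("critical-point Newton did not converge")


def critical_point(
    bilayer: BilayerModel,
    eta: float,
    delta_name: str,
    *,
    start: tuple[float, float] | None = None,
    equilibrium: EquilibriumState | None = None,
    enumerate_branches: bool = True,
) -> CriticalPoint:
    """Solve the marginal system (a0, da0/dxi) = 0 in (xi, delta) at one eta.

    Warm-started from the classical critical values of the driving layer (or
    from ``start``).  When several xi-stationary branches of a0 exist, Newton
    is run from each and the branch with the smallest delta (the global
    marginal onset) is returned; all branches are recorded.
    """
    if equilibrium is None:
        equilibrium = coupled_equilibrium(bilayer, eta)
    a0 = make_a0(bilayer, equilibrium, eta, delta_name)
    if start is None:
        layer: LayerModel = getattr(bilayer, _driving_layer(bilayer, delta_name))
        start = layer_critical_diffusion(layer, _layer_species_name(delta_name))[::-1]
        # layer_critical_diffusion returns (delta, xi); start is (xi, delta)
    xi0, delta0 = start
    xi_c, delta_c = _newton_2d(a0, xi0, delta0)
    branches = [(xi_c, delta_c)]
    if enumerate_branches:
        # stationary points of a0(., delta_c): sign changes of the xi-derivative
        h = 1e-6
        grads = []
        for x in _XI_GRID:
            hx = h * (1.0 + x)
            grads.append((a0(x + hx, delta_c) - a0(x, delta_c)) / hx)
        grads = np.array(grads)
        for i in range(len(grads) - 1):
            if grads[i] * grads[i + 1] < 0:
                xg = float(np.sqrt(_XI_GRID[i] * _XI_GRID[i + 1]))
                if any(abs(xg - b[0]) < 0.3 * (1 + b[0]) for b in branches):
                    continue
                try:
                    xb, db = _newton_2d(a0, xg, delta_c)
                except BifurcationError:
                    continue
                if db > 0 and not any(
                    abs(xb - b[0]) < 1e-4 * (1 + b[0])
                    and abs(db - b[1]) < 1e-4 * (1 + b[1])
                    for b in branches
                ):
                    branches.append((xb, db))
    branches.sort(key=lambda b: b[1])
    xi_c, delta_c = branches[0]
    return CriticalPoint(
        xi_c=float(xi_c),
        delta_c=float(delta_c),
        eta=float(eta),
        branch_id=0,
        branches=tuple(branches),
    )


def marginal_curve(
    bilayer: BilayerModel,
    delta_name: str,
    eta_stop: float,
    *,
    eta_values: np.ndarray | None = None,
    step0: float = 1e-2,
) -> list[CriticalPoint]:
    """Continue the marginal curve delta_c(eta) from eta = 0 to ``eta_stop``.

    Natural continuation in eta with an adaptive step (doubling on success up
    to a quarter of the current eta, halving on Newton failure), each point
    warm-started from the previous one.  ``eta_values`` forces additional
    sample points.
    """
    targets = set() if eta_values is None else {float(e) for e in eta_values}
    targets.add(float(eta_stop))
    points: list[CriticalPoint] = []
    eq = coupled_equilibrium(bilayer, 0.0)
    cp = critical_point(bilayer, 0.0, delta_name, equilibrium=eq,
                        enumerate_branches=False)
    points.append(cp)
    eta_cur, step = 0.0, step0
    pending = sorted(t for t in targets if t > 0)
    while pending:
        nxt = min(eta_cur + step, pending[0])
        try:
            eq = coupled_equilibrium(bilayer, nxt, start=eq)
            cp = critical_point(
                bilayer,
                nxt,
                delta_name,
                start=(cp.xi_c, cp.delta_c),
                equilibrium=eq,
                enumerate_branches=False,
            )
        except BifurcationError:
            if step < 1e-8:
                raise
            step *= 0.5
            continue
        eta_cur = nxt
        points.append(cp)
        if eta_cur >= pending[0] - 1e-14:
            pending.pop(0)
        step = min(2.0 * step, max(1.0, 0.25 * eta_cur))
    return points


# ---------------------------------------------------------------------------
# Weak-coupling tangent
# ---------------------------------------------------------------------------


def _det_grad_wrt_state(layer: LayerModel, eq: np.ndarray, xi: float) -> np.ndarray:
    """Gradient of det(xi D(u) - J(u)) in the equilibrium components."""
    grad = np.zeros(len(eq))
    for i in range(len(eq)):
        h = 1e-6 * (1.0 + abs(eq[i]))
        up, dn = eq.copy(), eq.copy()
        up[i] += h
        dn[i] -= h
        dp = np.linalg.det(xi * layer.diffusion_matrix(up) - layer.kinetics.jacobian(up))
        dm = np.linalg.det(xi * layer.diffusion_matrix(dn) - layer.kinetics.jacobian(dn))
        grad[i] = (dp - dm) / (2 * h)
    return grad


def weak_coupling_slope(
    bilayer: BilayerModel, case: str, delta_name: str
) -> float:
    """Tangent delta_c'(0) of the marginal curve at zero coupling.

    ``case`` selects the comatrix formula:

    * ``surface_1d1d``: -(co(P0).A + u_S*'(0) . grad |P0|) / d_delta |P0|
    * ``bulk_1d1d``: the same with (W0, B~, u_B*'(0)), W0 = xi D_B - J_B
    * ``surface_1d2d``: -co(P0).A / d_delta |P0| (shared equilibrium)
    * ``bulk_1d2d``: -co(W0).(B~ F2(H, R0)) / d_delta |W0|,
      W0 = D_B F1(H, R0)

    All quantities are evaluated at the uncoupled critical point
    (w*(0), xi_c(0), delta_c(0)) of the driving layer.
    """
    if case not in ("surface_1d1d", "bulk_1d1d", "surface_1d2d", "bulk_1d2d"):
        raise ValueError(f"unknown case {case!r}")
    surface_driven = case.startswith("surface")
    layer = bilayer.surface if surface_driven else bilayer.bulk
    species = _layer_species_name(delta_name)
    delta_c, xi_c = layer_critical_diffusion(layer, species)
    eq = find_equilibrium(layer.kinetics)

    def layer_at(delta: float) -> LayerModel:
        import dataclasses

        if species == "chi":
            return dataclasses.replace(
                layer, chemotaxis=dataclasses.replace(layer.chemotaxis, chi=delta)
            )
        return layer.replace_diffusivity(layer.kinetics.species.index(species), delta)

    lay_c = layer_at(delta_c)
    J = lay_c.kinetics.jacobian(eq)
    D = lay_c.diffusion_matrix(eq)
    exchange = bilayer.A if surface_driven else bilayer.B_tilde

    if case == "bulk_1d2d":
        if not isinstance(bilayer.geometry, Geometry1D2D):
            raise BifurcationError("bulk_1d2d case requires a 1D-2D geometry")
        H = bilayer.geometry.H

        def W0_at(delta: float) -> np.ndarray:
            lay = layer_at(delta)
            Dl = lay.diffusion_matrix(eq)
            Q0 = xi_c * Dl - lay.kinetics.jacobian(eq)
            R0 = np.linalg.solve(Dl, Q0)
            F1 = matrix_entire_functions(H, R0)[0]
            return Dl @ F1

        Q0 = xi_c * D - J
        R0 = np.linalg.solve(D, Q0)
        F1, F2, _ = matrix_entire_functions(H, R0)
        W0 = D @ F1
        numerator = float(np.sum(comatrix(W0) * (exchange @ F2)))
        hd = 1e-6 * (1.0 + delta_c)
        d_delta = (
            np.linalg.det(W0_at(delta_c + hd)) - np.linalg.det(W0_at(delta_c - hd))
        ) / (2 * hd)
    else:
        P0 = xi_c * D - J
        numerator = float(np.sum(comatrix(P0) * exchange))
        hd = 1e-6 * (1.0 + delta_c)
        lay_p, lay_m = layer_at(delta_c + hd), layer_at(delta_c - hd)
        d_delta = (
            np.linalg.det(xi_c * lay_p.diffusion_matrix(eq) - J)
            - np.linalg.det(xi_c * lay_m.diffusion_matrix(eq) - J)
        ) / (2 * hd)
        if case in ("surface_1d1d", "bulk_1d1d"):
            dS, dB = equilibrium_sensitivity(bilayer)
            sens = dS if surface_driven else dB
            if np.linalg.norm(sens) > 0:
                grad = _det_grad_wrt_state(lay_c, eq, xi_c)
                numerator += float(sens @ grad)

    if abs(d_delta) < 1e-14:
        raise BifurcationError(
            "degenerate transversality: d(det)/d(delta) vanishes at the "
            "critical point"
        )
    return -numerator / d_delta


# ---------------------------------------------------------------------------
# Strong coupling
# ---------------------------------------------------------------------------


def average_kinetics(
    f_S: KineticsModel, f_B: KineticsModel, label: str = "average"
) -> KineticsModel:
    """Kinetics with rates (f_S + f_B)/2 (layers must have equal species)."""
    if f_S.n_species != f_B.n_species:
        raise BifurcationError("averaging requires equally many species")

    def rates(w):
        return 0.5 * (f_S.rates(w) + f_B.rates(w))

    def jacobian(w):
        return 0.5 * (f_S.jacobian(w) + f_B.jacobian(w))

    hint = None
    if f_S.equilibrium_hint is not None:
        hint = np.asarray(f_S.equilibrium_hint, dtype=float)
    return KineticsModel(
        f_S.n_species,
        {"surface": dict(f_S.params), "bulk": dict(f_B.params)},
        rates,
        jacobian,
        label,
        f_S.species,
        hint,
    )


def strong_coupling_limit(
    bilayer: BilayerModel,
) -> tuple[KineticsModel, np.ndarray, float | None]:
    """Reduced single-layer system of the strong-coupling (eta >> 1) limit.

    With m = n and A + B having a spectrum in the closed right half plane,
    surface and bulk concentrations collapse onto their average u, governed
    by

        (A^-1 + B^-1) du/dt = A^-1 f_S(u) + B^-1 f_B(u)
                              + div((A^-1 D_S + B^-1 D_B) grad u).

    Returns ``(reduced kinetics, reduced diffusion matrix, delta_c_inf)``.
    ``delta_c_inf`` is the asymptotic critical surface-inhibitor diffusion
    ``2 delta_c[(f_S+f_B)/2] - d_vB`` for two-species systems with A = B and
    equal activator diffusivities; it is None (no finite critical value)
    when the averaged kinetics admit no Turing instability, e.g. for a
    mass-conserving pair f_S = -f_B whose reduced equation is a pure
    diffusion equation.
    """
    n, m = bilayer.n, bilayer.m
    if n != m:
        raise BifurcationError("strong-coupling reduction requires m = n")
    A, B = bilayer.A, bilayer.B
    if abs(np.linalg.det(A)) < 1e-14 or abs(np.linalg.det(B)) < 1e-14:
        raise BifurcationError("exchange matrices must be invertible")
    if np.min(np.linalg.eigvals(A + B).real) < 0:
        raise BifurcationError("A + B must have eigenvalues with Re >= 0")
    Ai, Bi = np.linalg.inv(A), np.linalg.inv(B)
    Mc = np.linalg.inv(Ai + Bi)
    fS, fB = bilayer.surface.kinetics, bilayer.bulk.kinetics

    def rates(w):
        return Mc @ (Ai @ fS.rates(w) + Bi @ fB.rates(w))

    def jacobian(w):
        return Mc @ (Ai @ fS.jacobian(w) + Bi @ fB.jacobian(w))

    hint = fS.equilibrium_hint
    reduced = KineticsModel(
        n,
        {"surface": dict(fS.params), "bulk": dict(fB.params)},
        rates,
        jacobian,
        "strong_coupling_reduced",
        fS.species,
        hint,
    )
    eq_guess = hint if hint is not None else np.ones(n)
    D_red = Mc @ (
        Ai @ bilayer.surface.diffusion_matrix(eq_guess)
        + Bi @ bilayer.bulk.diffusion_matrix(eq_guess)
    )

    delta_c_inf: float | None = None
    if (
        n == 2
        and bilayer.surface.chemotaxis is None
        and bilayer.bulk.chemotaxis is None
        and np.allclose(A, B)
        and np.isclose(bilayer.surface.diffusivities[0], bilayer.bulk.diffusivities[0])
    ):
        avg = average_kinetics(fS, fB)
        d_u = bilayer.surface.diffusivities[0]
        avg_layer = LayerModel(avg, (d_u, 1.0))
        from .kinetics import EquilibriumNotFound

        try:
            dc_avg, _ = layer_critical_diffusion(avg_layer, avg.species[1])
        except (NoTuringInstability, EquilibriumNotFound):
            delta_c_inf = None
        else:
            delta_c_inf = 2.0 * dc_avg - bilayer.bulk.diffusivities[1]
    return reduced, D_red, delta_c_inf


def midpoint_convexity_verdict(
    f_S: KineticsModel, f_B: KineticsModel, d_u: float = 1.0, *, tol: float = 1e-9
) -> str:
    """Compare delta_c[(f_S+f_B)/2] with the mean of the layer values.

    * ``strong_coupling_can_stabilize``: the average exceeds the mean, so two
      independently patterning layers can be driven homogeneous by strong
      coupling.
    * ``strong_coupling_can_pattern``: the average lies below the mean, so
      two independently non-patterning layers can pattern under strong
      coupling.
    * ``neither``: equality (e.g. identical kinetics).
    """
    dc_S, _ = layer_critical_diffusion(LayerModel(f_S, (d_u, 1.0)), f_S.species[1])
    dc_B, _ = layer_critical_diffusion(LayerModel(f_B, (d_u, 1.0)), f_B.species[1])
    avg = average_kinetics(f_S, f_B)
    dc_avg, _ = layer_critical_diffusion(LayerModel(avg, (d_u, 1.0)), avg.species[1])
    mean = 0.5 * (dc_S + dc_B)
    if dc_avg > mean + tol:
        return "strong_coupling_can_stabilize"
    if dc_avg < mean - tol:
        return "strong_coupling_can_pattern"
    return "neither"


# ---------------------------------------------------------------------------
# Homogeneous (q = 0) mode band
# ---------------------------------------------------------------------------


def homogeneous_mode_band(
    J: np.ndarray, alpha: float, beta: float
) -> tuple[tuple[float, float, float], np.ndarray]:
    """Eta-interval where the homogeneous mode of two identical coupled
    layers with A = B = diag(alpha, beta) is unstable.

    The mode is unstable for eta strictly between the real roots of

        4 alpha beta eta^2 - 2 (alpha g_v + beta f_u) eta + det J,

    when those exist.  Returns ``(coefficients, roots)`` with ``roots`` empty
    when the quadratic has no real root (the mode then stays stable for all
    eta, J itself being stable).
    """
    J = np.asarray(J, dtype=float)
    f_u, g_v = J[0, 0], J[1, 1]
    detJ = float(np.linalg.det(J))
    c2 = 4.0 * alpha * beta
    c1 = -2.0 * (alpha * g_v + beta * f_u)
    c0 = detJ
    coeffs = (c2, c1, c0)
    if c2 == 0.0:
        if c1 == 0.0:
            return coeffs, np.array([])
        root = -c0 / c1
        return coeffs, (np.array([root]) if root > 0 else np.array([]))
    disc = c1 * c1 - 4.0 * c2 * c0
    if disc <= 0:
        return coeffs, np.array([])
    r = np.sort(np.roots([c2, c1, c0]).real)
    return coeffs, r


# ---------------------------------------------------------------------------
# Instability region raster
# ---------------------------------------------------------------------------


def instability_region(
    bilayer: BilayerModel,
    eta_grid: np.ndarray,
    delta_grid: np.ndarray,
    delta_name: str,
    L: float,
    q_max: int,
) -> InstabilityRegion:
    """Mode-scan verdicts over an (eta, delta) grid.

    The equilibrium is recomputed (by continuation) at each eta; diffusion
    overrides do not shift it, so one equilibrium serves a whole delta
    column.  Cells where the equilibrium continuation fails are marked
    invalid, not unstable.
    """
    eta_grid = np.asarray(eta_grid, dtype=float)
    delta_grid = np.asarray(delta_grid, dtype=float)
    unstable = np.zeros((len(eta_grid), len(delta_grid)), dtype=bool)
    valid = np.ones_like(unstable)
    eq = None
    for i, eta in enumerate(eta_grid):
        try:
            eq = coupled_equilibrium(bilayer, float(eta), start=eq)
        except Exception:
            valid[i, :] = False
            eq = None
            continue
        for j, delta in enumerate(delta_grid):
            bl = bilayer.with_param(delta_name, float(delta))
            lin = build_linearization(bl, eq, eta)
            unstable[i, j] = bool(mode_scan(lin, L, q_max))
    return InstabilityRegion(eta_grid, delta_grid, unstable, valid, L, q_max)
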