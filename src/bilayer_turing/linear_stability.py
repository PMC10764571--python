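"""Dispersion matrices, dispersion polynomials and per-mode stability.

Linearising the coupled bilayer system about a homogeneous equilibrium and
expanding in cosine modes cos(k_q x), k_q = q pi / L, the perturbation of
mode xi = k_q^2 satisfies a kernel condition on the matrix

    M(lambda, xi) = [[lambda I + P0, 0], [0, lambda I + Q0]] + eta E   (1D-1D)

with P0 = xi D_S - J_S, Q0 = xi D_B - J_B and an exchange block E.  In the
1D-1D geometry det(M) is a polynomial of degree n + m in lambda, so each
mode can be classified by the Routh-Hurwitz criterion.  In the 1D-2D
geometry the bulk block is replaced by the transcendental matrix
W0 = D_B F1(H, R0), R0 = D_B^{-1} Q0, where F1 and the companion functions
F2, F2~ are entire matrix functions defined by power series (never through a
matrix square root, which need not exist - R0 is nilpotent at a two-species
critical point).  Stability claims in the 1D-2D geometry are therefore
limited to the marginal (lambda = 0) level.

xi is treated as a continuous variable throughout the analytics; the mode
scan is the only discrete-xi surface.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import EquilibriumState
from .models import BilayerModel, Geometry1D2D, ModelError

__all__ = [
    "BilayerLinearization",
    "LinearStabilityError",
    "build_linearization",
    "char_poly_1d1d",
    "mode_matrix_1d1d",
    "routh_hurwitz_stable",
    "mode_scan",
    "matrix_entire_functions",
    "comatrix",
    "dispersion_determinant",
    "make_a0",
    "a0_and_grad",
]


class LinearStabilityError(RuntimeError):
    """Assembly or series-convergence failure."""


@dataclass(frozen=True)
class BilayerLinearization:
    """All matrices of the linearised bilayer system at one equilibrium."""

    J_S: np.ndarray
    J_B: np.ndarray
    D_S: np.ndarray
    D_B: np.ndarray
    A: np.ndarray
    B: np.ndarray
    eta: float
    geometry: object
    equilibrium: EquilibriumState

    @property
    def n(self) -> int:
        return self.J_S.shape[0]

    @property
    def m(self) -> int:
        return self.J_B.shape[0]

    @property
    def B_tilde(self) -> np.ndarray:
        Bt = np.zeros((self.m, self.m))
        Bt[: self.n, : self.n] = self.B
        return Bt

    def P0(self, xi: float) -> np.ndarray:
        return xi * self.D_S - self.J_S

    def Q0(self, xi: float) -> np.ndarray:
        return xi * self.D_B - self.J_B

    def coupling_E(self) -> np.ndarray:
        """Exchange block of the 1D-1D dispersion matrix."""
        n, m = self.n, self.m
        E = np.zeros((n + m, n + m))
        E[:n, :n] = self.A
        E[:n, n : 2 * n] = -self.A
        Bt = self.B_tilde
        E[n:, :n] = -Bt[:, :n]
        E[n:, n:] = Bt
        return E


def build_linearization(
    bilayer: BilayerModel,
    equilibrium: EquilibriumState,
    eta: float | None = None,
    *,
    residual_tol: float = 1e-8,
) -> BilayerLinearization:
    """Evaluate all linearisation matrices at ``equilibrium``.

    Checks that the equilibrium satisfies the coupled equilibrium relations
    and that both diffusion matrices have spectra in the open right half
    plane (the positive definiteness assumption of the model).
    """
    if eta is None:
        eta = equilibrium.eta
    if bilayer.n > bilayer.m:
        raise ModelError("surface cannot have more species than the bulk")
    scale = 1.0 + np.linalg.norm(np.concatenate([equilibrium.u_S, equilibrium.u_B]))
    if equilibrium.residual > residual_tol * scale:
        raise LinearStabilityError(
            f"equilibrium residual {equilibrium.residual:.3e} too large"
        )
    D_S = bilayer.surface.diffusion_matrix(equilibrium.u_S)
    D_B = bilayer.bulk.diffusion_matrix(equilibrium.u_B)
    for name, D in (("D_S", D_S), ("D_B", D_B)):
        if np.min(np.linalg.eigvals(D).real) <= 0:
            raise LinearStabilityError(
                f"{name} is not positive (semi)definite at the equilibrium"
            )
    return BilayerLinearization(
        J_S=bilayer.surface.kinetics.jacobian(equilibrium.u_S),
        J_B=bilayer.bulk.kinetics.jacobian(equilibrium.u_B),
        D_S=D_S,
        D_B=D_B,
        A=bilayer.A,
        B=bilayer.B,
        eta=float(eta),
        geometry=bilayer.geometry,
        equilibrium=equilibrium,
    )


# ---------------------------------------------------------------------------
# 1D-1D dispersion polynomial and Routh-Hurwitz classification
# ---------------------------------------------------------------------------


def mode_matrix_1d1d(lin: BilayerLinearization, xi: float) -> np.ndarray:
    """System matrix C(xi) with det(M) = det(lambda I + C); the temporal
    eigenvalues of the mode are the eigenvalues of -C."""
    n, m = lin.n, lin.m
    C = np.zeros((n + m, n + m))
    C[:n, :n] = lin.P0(xi)
    C[n:, n:] = lin.Q0(xi)
    return C + lin.eta * lin.coupling_E()


def char_poly_1d1d(lin: BilayerLinearization, xi: float) -> np.ndarray:
    """Coefficients (leading first, monic) of det(M) as a polynomial in lambda.

    Computed by evaluating det(lambda I + C) at n+m+1 Chebyshev-spaced
    lambda samples and solving the interpolation system; this keeps the
    construction independent of any eigenvalue solver.
    """
    if getattr(lin.geometry, "kind", None) == "1d2d":
        raise LinearStabilityError("char_poly_1d1d requires the 1D-1D geometry")
    C = mode_matrix_1d1d(lin, xi)
    deg = C.shape[0]
    radius = 1.0 + np.linalg.norm(C, 2)
    nodes = radius * np.cos(np.pi * (2 * np.arange(deg + 1) + 1) / (2 * (deg + 1)))
    dets = np.array([np.linalg.det(lam * np.eye(deg) + C) for lam in nodes])
    V = np.vander(nodes, deg + 1)  # columns lam^deg ... lam^0
    coeffs = np.linalg.solve(V, dets)
    # det(lambda I + C) is monic by construction; normalise away round-off
    return coeffs / coeffs[0]


def routh_hurwitz_stable(coeffs: np.ndarray, tau: float | None = None) -> bool:
    """True iff all roots of the polynomial have strictly negative real part.

    Decided by the Hurwitz determinants.  Marginal cases (any determinant or
    coefficient within ``tau`` of zero, default ``1e-10 max|coeff|``) are
    reported unstable, so instability regions come out closed.
    """
    a = np.asarray(coeffs, dtype=float)
    if a.ndim != 1 or a.size < 1 or a[0] == 0.0:
        raise ValueError("polynomial must have a nonzero leading coefficient")
    if tau is None:
        tau = 1e-10 * float(np.max(np.abs(a)))
    if a[0] < 0:
        a = -a
    deg = a.size - 1
    if deg == 0:
        return True
    if np.any(a <= tau):  # necessary condition
        return False
    H = np.zeros((deg, deg))
    for i in range(deg):
        for j in range(deg):
            k = 2 * (j + 1) - (i + 1)
            if 0 <= k <= deg:
                H[i, j] = a[k]
    for size in range(1, deg + 1):
        if np.linalg.det(H[:size, :size]) <= tau:
            return False
    return True


def mode_scan(
    lin: BilayerLinearization, L: float, q_max: int
) -> list[int]:
    """Unstable mode indices q in 0..q_max for modes k_q = q pi / L."""
    unstable = []
    for q in range(q_max + 1):
        xi = (q * np.pi / L) ** 2
        if not routh_hurwitz_stable(char_poly_1d1d(lin, xi)):
            unstable.append(q)
    return unstable


# ---------------------------------------------------------------------------
# Matrix entire functions for the 1D-2D bulk factor
# ---------------------------------------------------------------------------


def _scalar_F(H: float, z: complex) -> tuple[complex, complex, complex]:
    x = H * np.sqrt(z + 0j)
    if abs(x) < 1e-6:
        x2 = x * x
        f1 = (x2 / H) * (1.0 + x2 / 6.0)
        f2 = 1.0 + x2 / 2.0 + x2 * x2 / 24.0
        f2t = 1.0 + x2 / 3.0
    else:
        f1 = np.sqrt(z + 0j) * np.sinh(x)
        f2 = np.cosh(x)
        f2t = (np.sinh(x) + x * np.cosh(x)) / (2.0 * x)
    return f1, f2, f2t


def matrix_entire_functions(
    H: float, R: np.ndarray, *, rtol: float = 1e-12, max_terms: int = 400
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The entire matrix functions of the 1D-2D bulk dispersion factor.

        F1(H, R)  = sum_{k>=1} H^(2k-1) / (2k-1)! R^k   ( = sqrt(R) sinh(H sqrt(R)) )
        F2(H, R)  = sum_{k>=0} H^(2k)   / (2k)!   R^k   ( = cosh(H sqrt(R)) )
        F2~(H, R) = sum_{k>=0} (k+1)/(2k+1) H^(2k)/(2k)! R^k

    Returns ``(F1, F2, F2~)``.  No matrix square root is ever formed: for a
    small argument the series is summed directly (it terminates exactly for
    nilpotent R), and for a large argument the functions are evaluated
    through the eigendecomposition with the scalar closed forms, falling
    back to an extended-precision series when R is too ill conditioned to
    diagonalise.
    """
    if H <= 0:
        raise ValueError(f"depth H must be positive, got {H}")
    R = np.asarray(R, dtype=float)
    mdim = R.shape[0]
    x2 = H * H * np.linalg.norm(R, 2)

    if x2 <= 100.0:
        return _series_F(H, R, rtol=rtol, max_terms=max_terms, dtype=float)

    # large argument: try diagonalisation
    w, V = np.linalg.eig(R)
    cond = np.linalg.cond(V)
    if cond < 1e8:
        f1 = np.array([_scalar_F(H, z)[0] for z in w])
        f2 = np.array([_scalar_F(H, z)[1] for z in w])
        f2t = np.array([_scalar_F(H, z)[2] for z in w])
        Vinv = np.linalg.inv(V)
        out = []
        for f in (f1, f2, f2t):
            F = (V * f) @ Vinv
            out.append(F.real if np.isrealobj(R) else F)
        return tuple(out)  # type: ignore[return-value]

    return _series_F(H, R, rtol=rtol, max_terms=max_terms, dtype=np.longdouble)


def _series_F(H, R, *, rtol, max_terms, dtype):
    mdim = R.shape[0]
    R = R.astype(dtype)
    I = np.eye(mdim, dtype=dtype)
    F1 = np.zeros_like(I)
    F2 = I.copy()
    F2t = I.copy()
    Rk = I.copy()  # R^k
    coef = np.ones((), dtype=dtype)  # H^(2k) / (2k)!
    max_term = 0.0
    for k in range(1, max_terms + 1):
        Rk = Rk @ R
        coef = coef * (H * H) / ((2 * k - 1) * (2 * k))
        t2 = coef * Rk
        t1 = ((2 * k) / H) * t2  # H^(2k-1)/(2k-1)! R^k
        t2t = ((k + 1) / (2 * k + 1)) * t2
        F1 += t1
        F2 += t2
        F2t += t2t
        tn = float(np.max(np.abs(t1))) + float(np.max(np.abs(t2)))
        max_term = max(max_term, tn)
        norms = float(np.max(np.abs(F1))) + float(np.max(np.abs(F2)))
        if tn <= rtol * max(norms, 1e-300):
            # accumulated cancellation estimate
            eps = float(np.finfo(dtype).eps)
            if max_term * eps > rtol * max(norms, 1e-300):
                raise LinearStabilityError(
                    "matrix entire-function series suffered catastrophic "
                    "cancellation; rescale the argument"
                )
            return (
                F1.astype(float),
                F2.astype(float),
                F2t.astype(float),
            )
    raise LinearStabilityError(
        f"matrix entire-function series not converged in {max_terms} terms"
    )


# ---------------------------------------------------------------------------
# Comatrix (cofactor matrix) and Jacobi's formula
# ---------------------------------------------------------------------------


def comatrix(Amat: np.ndarray) -> np.ndarray:
    """Cofactor matrix: d/dh det(A + h B)|_0 = co(A) . B = Tr(co(A)^T B)."""
    A = np.asarray(Amat, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("comatrix requires a square matrix")
    nd = A.shape[0]
    if nd == 1:
        return np.ones((1, 1))
    C = np.empty_like(A)
    for i in range(nd):
        for j in range(nd):
            minor = np.delete(np.delete(A, i, axis=0), j, axis=1)
            C[i, j] = (-1) ** (i + j) * np.linalg.det(minor)
    return C


# ---------------------------------------------------------------------------
# Marginal (lambda = 0) determinant a0 for both geometries
# ---------------------------------------------------------------------------


def dispersion_determinant(lin: BilayerLinearization, xi: float) -> float:
    """a0(xi) = det(M) at lambda = 0 for the geometry of ``lin``."""
    n, m = lin.n, lin.m
    if getattr(lin.geometry, "kind", None) == "1d2d":
        H = lin.geometry.H
        Q0 = lin.Q0(xi)
        R0 = np.linalg.solve(lin.D_B, Q0)
        F1, F2, _ = matrix_entire_functions(H, R0)
        W0 = lin.D_B @ F1
        M = np.zeros((n + m, n + m))
        M[:n, :n] = lin.P0(xi) + lin.eta * lin.A
        M[:n, n:] = -lin.eta * lin.A @ F2[:n, :]
        Bt = lin.B_tilde
        M[n:, :n] = -lin.eta * Bt[:, :n]
        M[n:, n:] = W0 + lin.eta * Bt @ F2
        return float(np.linalg.det(M))
    return float(np.linalg.det(mode_matrix_1d1d(lin, xi)))


def make_a0(
    bilayer: BilayerModel,
    equilibrium: EquilibriumState,
    eta: float,
    delta_name: str | None = None,
):
    """Closure ``a0(xi, delta)`` with the named parameter overridden.

    ``delta`` may be omitted (or the name be None) to evaluate at the
    model's current parameters.  Diffusion parameters and the chemotactic
    sensitivity do not shift the equilibrium, so the same equilibrium state
    is reused across overrides.
    """

    def a0(xi: float, delta: float | None = None) -> float:
        bl = bilayer
        if delta is not None:
            if delta_name is None:
                raise ValueError("delta supplied but no delta_name bound")
            bl = bilayer.with_param(delta_name, delta)
        lin = build_linearization(bl, equilibrium, eta)
        return dispersion_determinant(lin, xi)

    return a0


def a0_and_grad(
    bilayer: BilayerModel,
    equilibrium: EquilibriumState,
    eta: float,
    xi: float,
    delta_name: str | None = None,
    delta_value: float | None = None,
) -> tuple[float, float]:
    """``(a0, da0/dxi)`` at one (xi, delta), gradient by central differences
    with step ``1e-6 (1 + xi)``."""
    a0 = make_a0(bilayer, equilibrium, eta, delta_name)
    h = 1e-6 * (1.0 + xi)
    val = a0(xi, delta_value)
    hi = a0(xi + h, delta_value)
    lo = a0(max(xi - h, 0.0), delta_value)
    width = xi + h - max(xi - h, 0.0)
    return val, (hi - lo) / width
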