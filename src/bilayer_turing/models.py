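"""Layer and bilayer model containers.

A :class:`LayerModel` is a reaction-cross-diffusion system: kinetics plus a
(cross-)diffusion matrix evaluated at a state.  Chemotaxis is encoded as a
state-dependent lower-left block of the diffusion matrix: with cells ``c``
attracted up gradients of ``k(u) = u_attr`` with sensitivity ``h(c) = chi c``,
the cell row of ``D`` reads ``(-h(c) grad k(u)^T, d_c)``.

A :class:`BilayerModel` couples a surface layer (n species) to a bulk layer
(m >= n species) through linear exchange of the first n bulk species, with
exchange matrices ``A`` (into the surface) and ``B`` (into the bulk), scaled
by a coupling strength ``eta`` supplied to the analysis operations.  The
geometry is either 1D-1D (two coupled lines of length L) or 1D-2D (a line
coupled to a rectangle of depth H through a Robin interface condition).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Union

import numpy as np

from .kinetics import KineticsModel

__all__ = [
    "ChemotaxisSpec",
    "LayerModel",
    "BilayerModel",
    "Geometry1D1D",
    "Geometry1D2D",
    "ModelError",
]


class ModelError(ValueError):
    """Inconsistent model specification."""


@dataclass(frozen=True)
class ChemotaxisSpec:
    """Chemotactic drift of the last species up gradients of one of the
    others: flux ``-h(c) grad k(u)`` with ``h(c) = chi c``, ``k(u) = u_attr``."""

    chi: float
    attractant: int = 0


@dataclass(frozen=True)
class Geometry1D1D:
    L: float

    @property
    def kind(self) -> str:
        return "1d1d"


@dataclass(frozen=True)
class Geometry1D2D:
    L: float
    H: float

    @property
    def kind(self) -> str:
        return "1d2d"


Geometry = Union[Geometry1D1D, Geometry1D2D]


@dataclass(frozen=True)
class LayerModel:
    """Kinetics plus a diffusion law.

    ``diffusivities`` holds one diagonal diffusion coefficient per species,
    in species order.  If ``chemotaxis`` is set, the last species is the cell
    population and the full cross-diffusion matrix gains the chemotaxis row.
    """

    kinetics: KineticsModel
    diffusivities: tuple[float, ...]
    chemotaxis: ChemotaxisSpec | None = None

    def __post_init__(self) -> None:
        if len(self.diffusivities) != self.kinetics.n_species:
            raise ModelError(
                f"layer {self.kinetics.label}: {len(self.diffusivities)} "
                f"diffusivities for {self.kinetics.n_species} species"
            )
        if self.chemotaxis is not None:
            if self.kinetics.n_species < 2:
                raise ModelError("chemotaxis requires at least two species")
            if not 0 <= self.chemotaxis.attractant < self.kinetics.n_species - 1:
                raise ModelError(
                    f"chemoattractant index {self.chemotaxis.attractant} out of range"
                )

    @property
    def n_species(self) -> int:
        return self.kinetics.n_species

    def diffusion_matrix(self, state: np.ndarray) -> np.ndarray:
        """Cross-diffusion matrix evaluated at ``state``."""
        D = np.diag(np.asarray(self.diffusivities, dtype=float))
        if self.chemotaxis is not None:
            c = float(np.asarray(state)[-1])
            D[-1, self.chemotaxis.attractant] = -self.chemotaxis.chi * c
        return D

    def replace_diffusivity(self, index: int, value: float) -> "LayerModel":
        d = list(self.diffusivities)
        d[index] = float(value)
        return dataclasses.replace(self, diffusivities=tuple(d))


@dataclass(frozen=True)
class BilayerModel:
    """Surface + bulk layers with linear inter-layer exchange.

    ``A`` and ``B`` are n x n exchange matrices (surface gain and bulk gain
    respectively); the coupling strength ``eta`` multiplies both and is
    passed to each analysis operation rather than stored here.
    """

    surface: LayerModel
    bulk: LayerModel
    A: np.ndarray
    B: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        n, m = self.n, self.m
        if n > m:
            raise ModelError(f"surface species n={n} exceeds bulk species m={m}")
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if A.shape != (n, n) or B.shape != (n, n):
            raise ModelError(
                f"exchange matrices must be {n}x{n}; got A{A.shape}, B{B.shape}"
            )
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    @property
    def n(self) -> int:
        return self.surface.n_species

    @property
    def m(self) -> int:
        return self.bulk.n_species

    @property
    def B_tilde(self) -> np.ndarray:
        """``B`` padded by zeros to m x m."""
        Bt = np.zeros((self.m, self.m))
        Bt[: self.n, : self.n] = self.B
        return Bt

    def pad_to_bulk(self, vec: np.ndarray) -> np.ndarray:
        """Surface vector extended by zeros to bulk dimension (u_S tilde)."""
        out = np.zeros(self.m)
        out[: self.n] = vec
        return out

    # -- named-parameter override hook --------------------------------------
    # Any diffusion coefficient or the chemotactic sensitivity can serve as
    # the bifurcation parameter; names follow d_<species><S|B>, d_c, chi.

    def parameter(self, name: str) -> float:
        layer, idx, attr = self._resolve(name)
        if attr == "chi":
            return getattr(self, layer).chemotaxis.chi
        return getattr(self, layer).diffusivities[idx]

    def with_param(self, name: str, value: float) -> "BilayerModel":
        """Copy of the model with one named scalar parameter overridden."""
        layer, idx, attr = self._resolve(name)
        lm: LayerModel = getattr(self, layer)
        if attr == "chi":
            lm = dataclasses.replace(
                lm, chemotaxis=dataclasses.replace(lm.chemotaxis, chi=float(value))
            )
        else:
            lm = lm.replace_diffusivity(idx, value)
        return dataclasses.replace(self, **{layer: lm})

    def _resolve(self, name: str) -> tuple[str, int, str]:
        if name == "chi":
            if self.bulk.chemotaxis is not None:
                return "bulk", -1, "chi"
            if self.surface.chemotaxis is not None:
                return "surface", -1, "chi"
            raise ModelError("no chemotaxis block to which 'chi' could refer")
        if name == "d_c":
            # cell diffusion of the chemotaxis layer
            if self.bulk.chemotaxis is not None:
                return "bulk", self.m - 1, "d"
            if self.surface.chemotaxis is not None:
                return "surface", self.n - 1, "d"
            raise ModelError("no chemotaxis block to which 'd_c' could refer")
        if name.startswith("d_") and name[-1] in ("S", "B"):
            layer = "surface" if name[-1] == "S" else "bulk"
            species = name[2:-1]
            lm: LayerModel = getattr(self, layer)
            if species in lm.kinetics.species:
                return layer, lm.kinetics.species.index(species), "d"
        raise ModelError(
            f"unknown parameter name {name!r} (expected d_<species>S, "
            "d_<species>B, d_c or chi)"
        )
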