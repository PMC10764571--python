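"""Declarative run configuration, figure presets and output writers.

One YAML document drives both the analytics and the simulator, so a single
preset describes prediction and verification.  Figure presets expand to the
parameter sets of the reference bilayer scenarios (two coupled Schnakenberg
lines, asymmetric Schnakenberg pairs, pseudo-linear/chemotaxis 1D-2D skins,
the J_p stabilisation pair) before user overrides are applied; expansion is
idempotent.

Matrices are given row-major; parameter names follow the transliterated
symbols (d_uS, d_vS, d_uB, d_vB, d_c, chi, alpha, beta, eta, a, b, s, H, L).
"""
from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .kinetics import make_preset
from .models import (
    BilayerModel,
    ChemotaxisSpec,
    Geometry1D1D,
    Geometry1D2D,
    LayerModel,
)
from .simulate import SimulationConfig

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "config_from_dict",
    "FIGURE_PRESETS",
    "figure_preset",
    "write_table",
]


class ConfigError(ValueError):
    """Schema violation; the message names the offending key path."""


_SCHNAK_1 = {"kinetics": "schnakenberg", "params": {"a": 0.2305, "b": 0.7695, "s": 1.0}}
_SCHNAK_2 = {"kinetics": "schnakenberg", "params": {"a": 0.2305, "b": 0.7695, "s": 2.0}}
_SCHNAK_B = {"kinetics": "schnakenberg", "params": {"a": 0.15, "b": 0.2, "s": 0.5}}
_PL_SURFACE = {
    "kinetics": "pseudo_linear_surface",
    "params": {"a0": 1.0, "a1": 2.0, "b": 2.0, "a2": 2.0,
               "b0": 0.25, "c1": 1.0, "d": 1.0, "c2": 2.0},
}
_PL_BULK = {
    "kinetics": "pseudo_linear_bulk",
    "params": {"r0": 0.2, "a0": 3.0, "a1": 8.0, "b": 2.0, "a2": 7.0,
               "b0": 0.75, "c1": 0.5, "c2": 1.5, "d": 1.0, "cstar": 0.25},
}

# Parameters are the reference scenarios' caption values.  The delta-species
# diffusivity in the driving layer is a placeholder that analyses override.
FIGURE_PRESETS: dict[str, dict] = {
    "fig2a": {
        "model": {
            "surface": {**_SCHNAK_1, "diffusivities": [1.0, 17.0]},
            "bulk": {**_SCHNAK_1, "diffusivities": [1.0, 15.0]},
            "A": [[1.0, 0.0], [0.0, 1.0]],
            "B": [[1.0, 0.0], [0.0, 1.0]],
        },
        "geometry": {"kind": "1d1d", "L": 1000.0},
        "analysis": {"delta_name": "d_vS", "eta": 0.0, "q_max": 1500},
    },
    "fig2b": {
        "model": {
            "surface": {**_SCHNAK_1, "diffusivities": [1.0, 17.0]},
            "bulk": {**_SCHNAK_1, "diffusivities": [1.0, 15.0]},
            "A": [[1.0, 0.0], [0.0, 30.0]],
            "B": [[1.0, 0.0], [0.0, 30.0]],
        },
        "geometry": {"kind": "1d1d", "L": 1000.0},
        "analysis": {"delta_name": "d_vS", "eta": 0.0, "q_max": 1500},
    },
    "fig3": {
        "model": {
            "surface": {**_SCHNAK_2, "diffusivities": [1.0, 17.0]},
            "bulk": {**_SCHNAK_B, "diffusivities": [1.0, 15.0]},
            "A": [[1.0, 0.0], [0.0, 1.0]],
            "B": [[1.0, 0.0], [0.0, 1.0]],
        },
        "geometry": {"kind": "1d1d", "L": 1000.0},
        "analysis": {"delta_name": "d_vS", "eta": 0.0, "q_max": 1500},
    },
    "fig4a": {
        "model": {
            "surface": {**_PL_SURFACE, "diffusivities": [1.0, 6.41]},
            "bulk": {**_PL_BULK, "diffusivities": [10.0, 6.0, 10.0],
                     "chemotaxis": {"chi": 50.0, "attractant": 0}},
            "A": [[1.0, 0.0], [0.0, 1.0]],
            "B": [[1.0, 0.0], [0.0, 1.0]],
        },
        "geometry": {"kind": "1d2d", "L": 50.0, "H": 50.0},
        "analysis": {"delta_name": "d_vB", "eta": 0.01, "q_max": 128},
        "simulation": {"N_x": 128, "N_y": 128, "t_final": 500.0},
    },
    "fig4b": {
        "model": {
            "surface": {**_PL_SURFACE, "diffusivities": [1.0, 2.91]},
            "bulk": {**_PL_BULK, "diffusivities": [10.0, 60.0, 10.0],
                     "chemotaxis": {"chi": 50.0, "attractant": 0}},
            "A": [[1.0, 0.0], [0.0, 1.0]],
            "B": [[1.0, 0.0], [0.0, 1.0]],
        },
        "geometry": {"kind": "1d2d", "L": 50.0, "H": 50.0},
        "analysis": {"delta_name": "d_vB", "eta": 0.01, "q_max": 128},
        "simulation": {"N_x": 128, "N_y": 128, "t_final": 500.0},
    },
    "fig5": {
        "model": {
            "surface": {**_PL_SURFACE, "diffusivities": [1.0, 2.91]},
            "bulk": {**_PL_BULK, "diffusivities": [25.0, 35.0, 25.0],
                     "chemotaxis": {"chi": 120.0, "attractant": 0}},
            "A": [[1.0, 0.0], [0.0, 1.0]],
            "B": [[1.0, 0.0], [0.0, 180.0]],
        },
        "geometry": {"kind": "1d2d", "L": 50.0, "H": 50.0},
        "analysis": {"delta_name": "d_vB", "eta": 0.01, "q_max": 512},
        "simulation": {"N_x": 512, "N_y": 512},
    },
    "fig6a": {
        "model": {
            "surface": {**_SCHNAK_1, "diffusivities": [1.0, 17.0]},
            "bulk": {**_SCHNAK_1, "diffusivities": [1.0, 15.0]},
            "A": [[1.0, 0.0], [0.0, 1.0]],
            "B": [[1.0, 0.0], [0.0, 1.0]],
        },
        "geometry": {"kind": "1d1d", "L": 1000.0},
        "analysis": {"delta_name": "d_vS", "eta": 1000.0, "q_max": 1500},
    },
    "fig6b": {
        "model": {
            "surface": {"kinetics": "jp_family", "params": {"p": 200.0},
                        "diffusivities": [1.0, 230.0]},
            "bulk": {"kinetics": "jp_family", "params": {"p": 2.0},
                     "diffusivities": [1.0, 10.0]},
            "A": [[1.0, 0.0], [0.0, 1.0]],
            "B": [[1.0, 0.0], [0.0, 1.0]],
        },
        "geometry": {"kind": "1d1d", "L": 1000.0},
        "analysis": {"delta_name": "d_vS", "eta": 0.0, "q_max": 1500},
    },
    "fig7": {
        "model": {
            "surface": {**_SCHNAK_2, "diffusivities": [1.0, 17.0]},
            "bulk": {**_SCHNAK_2, "diffusivities": [1.0, 1.0]},
            "A": [[1.0, 0.0], [0.0, 40.0]],
            "B": [[1.0, 0.0], [0.0, 40.0]],
        },
        "geometry": {"kind": "1d1d", "L": 1000.0},
        "analysis": {"delta_name": "d_vS", "eta": 0.0, "q_max": 1500},
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def figure_preset(name: str) -> dict:
    """The fully expanded configuration dictionary of one figure preset."""
    try:
        return copy.deepcopy(FIGURE_PRESETS[name])
    except KeyError:
        raise ConfigError(
            f"preset: unknown figure preset {name!r}; "
            f"available: {sorted(FIGURE_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration: raw mapping plus constructed objects."""

    raw: dict
    bilayer: BilayerModel
    analysis: dict
    simulation: SimulationConfig
    seed: int

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=float).encode()
        ).hexdigest()[:16]


def _get(d: dict, path: str, default=None, required=False):
    cur: Any = d
    for part in path.split("."):
        if not isinstance(cur, dict) or part not in cur:
            if required:
                raise ConfigError(f"missing required key {path!r}")
            return default
        cur = cur[part]
    return cur


def _build_layer(spec: dict, path: str) -> LayerModel:
    if "kinetics" not in spec:
        raise ConfigError(f"{path}.kinetics is required")
    try:
        kin = make_preset(spec["kinetics"], **spec.get("params", {}))
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    diff = spec.get("diffusivities")
    if diff is None or len(diff) != kin.n_species:
        raise ConfigError(
            f"{path}.diffusivities must list {kin.n_species} coefficients"
        )
    chemo = None
    if spec.get("chemotaxis"):
        cspec = spec["chemotaxis"]
        if "chi" not in cspec:
            raise ConfigError(f"{path}.chemotaxis.chi is required")
        chemo = ChemotaxisSpec(
            chi=float(cspec["chi"]), attractant=int(cspec.get("attractant", 0))
        )
    return LayerModel(kin, tuple(float(d) for d in diff), chemo)


def config_from_dict(data: dict) -> RunConfig:
    """Validate and resolve a configuration mapping (presets first)."""
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    data = copy.deepcopy(data)
    preset = data.pop("preset", None)
    if preset is not None:
        data = _deep_merge(figure_preset(preset), data)
        data["preset_expanded_from"] = preset

    model = _get(data, "model", required=True)
    surface = _build_layer(_get(model, "surface", required=True), "model.surface")
    bulk = _build_layer(_get(model, "bulk", required=True), "model.bulk")
    n = surface.n_species
    A = np.asarray(_get(model, "A", np.eye(n).tolist()), dtype=float)
    B = np.asarray(_get(model, "B", np.eye(n).tolist()), dtype=float)

    geo = _get(data, "geometry", required=True)
    kind = geo.get("kind")
    if kind == "1d1d":
        geometry = Geometry1D1D(L=float(geo.get("L", 1000.0)))
    elif kind == "1d2d":
        if "H" not in geo:
            raise ConfigError("geometry.H is required for the 1d2d geometry")
        geometry = Geometry1D2D(L=float(geo.get("L", 100.0)), H=float(geo["H"]))
    else:
        raise ConfigError(f"geometry.kind must be 1d1d or 1d2d, got {kind!r}")

    try:
        bilayer = BilayerModel(surface, bulk, A, B, geometry)
    except Exception as exc:
        raise ConfigError(f"model: {exc}") from exc

    analysis = dict(_get(data, "analysis", {}))
    seed = int(_get(data, "seed", 0))
    sim_raw = dict(_get(data, "simulation", {}))
    sim_raw.setdefault("seed", seed)
    try:
        simulation = SimulationConfig(**sim_raw)
    except TypeError as exc:
        raise ConfigError(f"simulation: {exc}") from exc
    return RunConfig(
        raw=data, bilayer=bilayer, analysis=analysis, simulation=simulation, seed=seed
    )


def load_config(path: str | Path) -> RunConfig:
    """Load, expand and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file {path} does not exist")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    return config_from_dict(data or {})


def write_table(
    path: str | Path,
    header: list[str],
    rows: np.ndarray,
    *,
    config_hash: str = "",
    seed: int | None = None,
) -> None:
    """Columnar CSV with a provenance comment block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = f"# config_hash={config_hash} seed={seed}\n"
    with open(path, "w") as fh:
        fh.write(meta)
        fh.write(",".join(header) + "\n")
        for row in np.atleast_2d(rows):
            fh.write(",".join(f"{v:.12g}" for v in row) + "\n")
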