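"""Calibration of the basal-synthesis endpoints used for hybridization runs.

The coefficient ``C`` (basal synthesis of the core factor) moves the system
through the spot -> labyrinth -> inverted-spot sequence: low ``C`` yields
sparse pigmented spots on a light background, high ``C`` a mostly pigmented
field with light spots, and intermediate ``C`` labyrinths.  The two "pure
species" endpoints used by the hybrid (metaball / gradient) runs are chosen
by sweeping ``C`` and picking the values whose pigmented-area fraction is
closest to configurable dark/light targets.  The module-level defaults were
produced by :func:`calibrate_c_endpoints` with its default arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import DiffusionParams, KineticParams
from .mesh import make_grid_mesh
from .simulate import binarize_field, simulate

__all__ = ["CEndpoints", "calibrate_c_endpoints", "C_DARK_SPOTS", "C_LIGHT_SPOTS"]

# Defaults from calibrate_c_endpoints(seed=1): pigmented fractions ~0.06 / ~0.88.
C_DARK_SPOTS = -0.04
C_LIGHT_SPOTS = 0.32


@dataclass
class CEndpoints:
    c_dark: float
    c_light: float
    sweep: list[tuple[float, float | None]]  # (C, pigmented fraction or None if flat)


def calibrate_c_endpoints(
    base: KineticParams | None = None,
    diff: DiffusionParams | None = None,
    c_grid: np.ndarray | None = None,
    target_dark: float = 0.1,
    target_light: float = 0.9,
    grid_size: int = 64,
    seed: int = 1,
) -> CEndpoints:
    """Sweep ``C`` on a periodic grid and pick spot-regime endpoints.

    A value of ``C`` is considered pattern-forming when the auto threshold is
    defined (non-flat field).  Among pattern-forming values, the endpoint for
    dark spots minimizes ``|fraction - target_dark|`` and the light-spot
    endpoint minimizes ``|fraction - target_light|``.
    """
    base = base or KineticParams()
    if c_grid is None:
        c_grid = np.round(np.arange(-0.08, 0.40001, 0.02), 4)
    mesh = make_grid_mesh(grid_size, grid_size, periodic=True)
    sweep: list[tuple[float, float | None]] = []
    for c in c_grid:
        try:
            state = simulate(mesh, base.with_C(float(c)), diff, seed=seed)
            frac = float(binarize_field(state).mean())
        except (ValueError, FloatingPointError):
            frac = None
        sweep.append((float(c), frac))
    formed = [(c, f) for c, f in sweep if f is not None]
    if not formed:
        raise RuntimeError("no pattern-forming C value in the sweep")
    c_dark = min(formed, key=lambda cf: abs(cf[1] - target_dark))[0]
    c_light = min(formed, key=lambda cf: abs(cf[1] - target_light))[0]
    if c_dark == c_light:
        raise RuntimeError("calibration collapsed to a single endpoint; widen the sweep")
    return CEndpoints(c_dark=c_dark, c_light=c_light, sweep=sweep)
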