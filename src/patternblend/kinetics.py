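"""Reaction kinetics of the two-factor activator/inhibitor system.

The model is a linear two-factor reaction-diffusion system with saturating
synthesis.  Factor ``u`` (the "core" pigmentation factor) is produced at rate
``A*u - B*v + C`` — self-activation, inhibition by ``v`` and a basal offset —
and degraded at rate ``D*u``; the inhibitor ``v`` is produced at ``E*u - F``
and degraded at ``G*v``.  Both synthesis terms are clamped to ``[0, synUmax]``
and ``[0, synVmax]`` respectively, which bounds the dynamics and lets a linear
system produce stable Turing patterns.  With the default constants the
uniform interior steady state is stable in a well-mixed system
(``tr J = -0.01``, ``det J = 0.005``) and Turing-unstable once ``Dv >> Du``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "KineticParams",
    "DiffusionParams",
    "reaction",
    "clipped_fixed_points",
    "stable_clipped_fixed_point",
]


@dataclass(frozen=True)
class KineticParams:
    """Reaction coefficients; defaults are the standard pattern-forming set.

    ``C`` is the basal synthesis offset of ``u``; it is the knob used to move
    between dark-spot, labyrinth and light-spot regimes and therefore has no
    single canonical value (default 0 = mid-regime).
    """

    A: float = 0.08
    B: float = 0.08
    C: float = 0.0
    D: float = 0.03
    E: float = 0.1
    F: float = 0.12
    G: float = 0.06
    synUmax: float = 0.23
    synVmax: float = 0.5
    R: float = 80.0

    def __post_init__(self) -> None:
        if self.synUmax <= 0 or self.synVmax <= 0:
            raise ValueError("synthesis caps must be positive")
        if self.R <= 0:
            raise ValueError("reaction rate multiplier R must be positive")

    def with_C(self, c: float) -> "KineticParams":
        return replace(self, C=float(c))

    def as_arrays(self, n: int) -> dict[str, np.ndarray]:
        """Broadcast every coefficient to a length-``n`` array."""
        return {f.name: np.full(n, getattr(self, f.name)) for f in fields(self)}


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion coefficients; patterns need long-range inhibition Dv >> Du.

    Zero diffusion is allowed (well-mixed / per-cell dynamics, used to probe
    the reaction fixed points); negative coefficients are not.
    """

    Du: float = 0.5
    Dv: float = 10.0

    def __post_init__(self) -> None:
        if self.Du < 0 or self.Dv < 0:
            raise ValueError("diffusion coefficients must be non-negative")


def reaction(u, v, p, *, clip_variant: bool = True):
    """Evaluate the reaction terms ``f`` and ``g``.

    Synthesis terms are clipped to their admissible ranges *before* the decay
    terms are subtracted.  Accepts scalars or arrays for ``u``/``v``; ``p`` may
    be a :class:`KineticParams` or a dict of per-cell coefficient arrays (as
    produced by :func:`patternblend.fields.parameter_field`).

    Returns ``(f, g)`` with ``f = clip(A*u-B*v+C) - D*u`` and
    ``g = clip(E*u-F) - G*v``.
    """
    if isinstance(p, KineticParams):
        A, B, C, D = p.A, p.B, p.C, p.D
        E, F, G = p.E, p.F, p.G
        su_max, sv_max = p.synUmax, p.synVmax
    else:
        A, B, C, D = p["A"], p["B"], p["C"], p["D"]
        E, F, G = p["E"], p["F"], p["G"]
        su_max, sv_max = p["synUmax"], p["synVmax"]
    syn_u = A * u - B * v + C
    syn_v = E * u - F
    if clip_variant:
        syn_u = np.clip(syn_u, 0.0, su_max)
        syn_v = np.clip(syn_v, 0.0, sv_max)
    return syn_u - D * u, syn_v - G * v


def clipped_fixed_points(p: KineticParams) -> list[tuple[float, float, bool]]:
    """Enumerate fixed points of the clipped kinetics.

    Each synthesis term can sit in one of three regimes: clipped at 0, linear,
    or clipped at its cap.  For each of the nine regime combinations the
    resulting (at most linear) 2x2 system is solved and the solution kept only
    if it is consistent with the assumed regimes.  Returns a list of
    ``(u*, v*, stable)`` where stability is judged from the Jacobian of the
    regime the fixed point sits in (marginal regimes count as unstable).
    """
    out: list[tuple[float, float, bool]] = []
    tol = 1e-12
    for ru in (0, 1, 2):  # u-synthesis regime: low clip, linear, high clip
        for rv in (0, 1, 2):
            # f = syn_u - D u = 0 ; g = syn_v - G v = 0
            # Regime 0: syn = 0, regime 2: syn = cap, regime 1: linear.
            # Build linear system M [u v]^T = b.
            if ru == 0:
                mu = (-p.D, 0.0)
                bu = 0.0
            elif ru == 2:
                mu = (-p.D, 0.0)
                bu = -p.synUmax
            else:
                mu = (p.A - p.D, -p.B)
                bu = -p.C
            if rv == 0:
                mv = (0.0, -p.G)
                bv = 0.0
            elif rv == 2:
                mv = (0.0, -p.G)
                bv = -p.synVmax
            else:
                mv = (p.E, -p.G)
                bv = p.F
            M = np.array([mu, mv])
            if abs(np.linalg.det(M)) < tol:
                continue
            u_star, v_star = np.linalg.solve(M, [bu, bv])
            syn_u = p.A * u_star - p.B * v_star + p.C
            syn_v = p.E * u_star - p.F
            ok_u = {0: syn_u <= tol, 1: -tol <= syn_u <= p.synUmax + tol, 2: syn_u >= p.synUmax - tol}[ru]
            ok_v = {0: syn_v <= tol, 1: -tol <= syn_v <= p.synVmax + tol, 2: syn_v >= p.synVmax - tol}[rv]
            if not (ok_u and ok_v):
                continue
            jac = np.array(
                [
                    [(p.A if ru == 1 else 0.0) - p.D, -p.B if ru == 1 else 0.0],
                    [p.E if rv == 1 else 0.0, -p.G],
                ]
            )
            stable = bool(np.all(np.real(np.linalg.eigvals(jac)) < 0))
            if not any(abs(u_star - u0) < 1e-9 and abs(v_star - v0) < 1e-9 for u0, v0, _ in out):
                out.append((float(u_star), float(v_star), stable))
    return out


def stable_clipped_fixed_point(p: KineticParams) -> tuple[float, float]:
    """The stable rest state of the well-mixed (diffusion-free) system.

    When several fixed points are stable the interior one (no active
    clipping) is preferred: it is the state whose Turing destabilization
    seeds patterns.  Raises ``ValueError`` when no clipped fixed point is
    linearly stable.
    """
    stable = [(u, v) for u, v, s in clipped_fixed_points(p) if s]
    if not stable:
        raise ValueError("no stable clipped fixed point for these parameters")
    for u, v in stable:
        if 0.0 < p.A * u - p.B * v + p.C < p.synUmax and 0.0 < p.E * u - p.F < p.synVmax:
            return u, v
    return stable[0]
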