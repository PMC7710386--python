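"""Synthetic data generators for every stage of the pipeline.

Each generator is deterministic per seed and emits objects in exactly the
schemas the analysis modules consume, so the whole pipeline is testable
without any external data.  Defaults emulate the scale of the study system:
~4,000 genera averaging ~4.5 species each, a labyrinthine-motif prevalence
of ~5%, genome scans with tens of thousands of biallelic sites in ~50
contiguous blocks, and spot/labyrinth pattern images from the calibrated
reaction-diffusion endpoints.

The "blending" dependency is injected at the genus level: when a genus
contains both dark-spotted and light-spotted species, each member species'
probability of carrying the labyrinthine motif is multiplied by
``blending_effect`` (1 = null).  This controls exactly the quantity the
collocation screen measures, without simulating hybrid speciation itself.
Admixture is injected as a frequency mixture p2' = (1-f) p2 + f p3, which
has analytic expectations at desk scale (no coalescent machinery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .calibrate import C_DARK_SPOTS, C_LIGHT_SPOTS
from .collocation import MOTIFS, AnnotationTable, build_annotation_table
from .kinetics import KineticParams
from .mesh import make_grid_mesh
from .simulate import binarize_field, field_to_grid, simulate
from .traitevo import RateModel, simulate_ctmc

__all__ = [
    "AnnotationGenConfig",
    "GenotypeGenConfig",
    "gen_annotation_table",
    "gen_trait_tree",
    "gen_genotypes",
    "gen_pattern_images",
    "DEFAULT_PREVALENCES",
]

# species-level motif prevalences; Maze at the ~5% abundance of the study
# system, spots and common fill/blotch motifs more frequent
DEFAULT_PREVALENCES = {
    "St-H": 0.10,
    "St-D": 0.08,
    "St-V": 0.12,
    "Maze": 0.05,
    "Sp-D": 0.10,
    "Sp-L": 0.08,
    "Eyes": 0.06,
    "Area": 0.15,
    "Sddl": 0.05,
    "Bltc": 0.12,
    "Mono": 0.20,
}


@dataclass
class AnnotationGenConfig:
    n_genera: int = 2000
    mean_species_per_genus: float = 4.5  # geometric (support >= 1)
    fixed_species_per_genus: int | None = None  # overrides the geometric draw
    prevalences: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    blending_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blending_effect < 0:
            raise ValueError("blending_effect must be >= 0")
        for m, p in self.prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {m} must be in (0, 1)")


@dataclass
class GenotypeGenConfig:
    n_sites: int = 20000
    n_blocks: int = 50
    divergence: float = 0.1  # Balding-Nichols drift parameter F per population
    admixture_f: float = 0.0  # P3 -> P2 fraction
    n_diagnostic: int = 10000
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.admixture_f < 1.0:
            raise ValueError("admixture fraction must be in [0, 1)")
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks")


def gen_annotation_table(cfg: AnnotationGenConfig) -> AnnotationTable:
    """Species-level annotation table with a controllable blending dependency.

    All motifs except Maze are drawn independently per species at the stated
    prevalences; the per-species Maze probability is multiplied by
    ``blending_effect`` (capped at 0.95) in genera that contain both a Sp-D
    and a Sp-L carrier.

    Note that even at ``blending_effect = 1`` the *genus-level* co-occurrence
    statistics are positively biased when genus sizes vary (a larger genus
    accumulates every motif), exactly as in real genus-level collocation;
    ``fixed_species_per_genus`` removes that heterogeneity for strict null
    calibrations.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    p_maze = cfg.prevalences["Maze"]
    for gi in range(cfg.n_genera):
        genus = f"Genus{gi:05d}"
        if cfg.fixed_species_per_genus is not None:
            n_sp = int(cfg.fixed_species_per_genus)
        else:
            n_sp = int(rng.geometric(1.0 / cfg.mean_species_per_genus))  # support >= 1
        flags = {
            m: rng.random(n_sp) < cfg.prevalences[m] for m in MOTIFS if m != "Maze"
        }
        boosted = flags["Sp-D"].any() and flags["Sp-L"].any()
        q = min(p_maze * (cfg.blending_effect if boosted else 1.0), 0.95)
        flags["Maze"] = rng.random(n_sp) < q
        for si in range(n_sp):
            rows.append(
                {
                    "species": f"{genus} sp{si + 1}",
                    "genus": genus,
                    "family": f"Family{gi // 8:04d}",
                    "order": f"Order{gi // 200:03d}",
                    **{m: int(flags[m][si]) for m in MOTIFS},
                }
            )
    df = pd.DataFrame(
        rows, columns=["species", "genus", "family", "order", *MOTIFS]
    )
    if df.empty:
        df = pd.DataFrame(columns=["species", "genus", "family", "order", *MOTIFS])
        return AnnotationTable(df)
    return build_annotation_table(df)


def gen_trait_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    model: RateModel | None = None,
    root_state: int = 0,
    seed: int = 0,
    max_attempts: int = 20,
) -> tuple[dendropy.Tree, dict[str, int]]:
    """Birth-death tree conditioned on ``n_tips`` with CTMC-evolved states.

    Retries on total extinction (possible when death_rate > 0) up to
    ``max_attempts`` before raising.
    """
    import random as _random

    from dendropy.model import birthdeath

    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    if model is None:
        model = RateModel.create("independent")
    last_err = None
    for attempt in range(max_attempts):
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate,
                death_rate,
                num_extant_tips=n_tips,
                rng=_random.Random(seed + 7919 * attempt),
            )
            break
        except Exception as err:  # dendropy raises on total extinction
            last_err = err
    else:
        raise RuntimeError(f"tree simulation failed after {max_attempts} attempts") from last_err
    for i, leaf in enumerate(tree.leaf_node_iter()):
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label=f"T{i + 1}")
    tips = simulate_ctmc(tree, model, root_state=root_state, seed=seed)
    return tree, tips


def gen_genotypes(cfg: GenotypeGenConfig) -> dict[str, pd.DataFrame]:
    """Frequency matrix and diagnostic genotypes with known ground truth.

    Returns ``{"freqs": ..., "diagnostic": ...}``.  Frequencies: per-site
    ancestral frequency U(0.05, 0.95), drifted independently per population
    under a Balding-Nichols model with parameter ``divergence``; the outgroup
    keeps frequency 0 (it defines the ancestral allele); admixture mixes P3
    into P2.  Diagnostic sites are fixed differences between two parental
    panels; individuals ``parent_a``, ``parent_b``, ``f1``, ``f2`` carry
    dosages 0, 2, 1 and {0,1,2} with probability {1/4, 1/2, 1/4}.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    anc = rng.uniform(0.05, 0.95, n)
    F = cfg.divergence
    a, b = anc * (1 - F) / F, (1 - anc) * (1 - F) / F
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    p3 = rng.beta(a, b)
    if cfg.admixture_f > 0:
        p2 = (1 - cfg.admixture_f) * p2 + cfg.admixture_f * p3
    blocks = np.repeat(np.arange(cfg.n_blocks), int(np.ceil(n / cfg.n_blocks)))[:n]
    freqs = pd.DataFrame(
        {"site": np.arange(n), "block": blocks, "p1": p1, "p2": p2, "p3": p3, "p4": 0.0}
    )

    nd = cfg.n_diagnostic
    dblocks = np.repeat(np.arange(cfg.n_blocks), int(np.ceil(nd / cfg.n_blocks)))[:nd]
    f2 = rng.choice([0, 1, 2], size=nd, p=[0.25, 0.5, 0.25]).astype(float)
    diag = pd.DataFrame(
        {
            "block": dblocks,
            "panel_a_freq": 0.0,
            "panel_b_freq": 1.0,
            "parent_a": 0.0,
            "parent_b": 2.0,
            "f1": 1.0,
            "f2": f2,
        }
    )
    if cfg.missing_rate > 0:
        for col in ("parent_a", "parent_b", "f1", "f2"):
            mask = rng.random(nd) < cfg.missing_rate
            diag.loc[mask, col] = np.nan
    return {"freqs": freqs, "diagnostic": diag}


def gen_pattern_images(
    kind: str,
    size: tuple[int, int] = (64, 64),
    seed: int = 0,
    base: KineticParams | None = None,
):
    """A simulated pattern image of the requested kind.

    ``kind`` is ``spots_dark``, ``spots_light`` or ``labyrinth`` (generated
    at the calibrated endpoint / mid-gradient basal-synthesis values).
    Returns ``(binary, gray, threshold)``: the boolean pigment image, the
    continuous core-factor field, and the threshold that separated them.
    """
    c_by_kind = {
        "spots_dark": C_DARK_SPOTS,
        "spots_light": C_LIGHT_SPOTS,
        "labyrinth": 0.5 * (C_DARK_SPOTS + C_LIGHT_SPOTS),
    }
    if kind not in c_by_kind:
        raise ValueError(f"unknown pattern kind {kind!r}")
    base = base or KineticParams()
    h, w = size
    mesh = make_grid_mesh(w, h, periodic=True)
    state = simulate(mesh, base.with_C(c_by_kind[kind]), seed=seed)
    lo, hi = np.percentile(state.u, [5.0, 95.0])
    thr = 0.5 * (lo + hi)
    binary = field_to_grid(mesh, binarize_field(state, thr))
    gray = field_to_grid(mesh, state.u)
    return binary, gray, thr
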