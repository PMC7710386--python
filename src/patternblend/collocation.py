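"""Genus-level phylogenetic collocation of color pattern motifs.

Species-level binary annotations (11 motif classes) are collapsed to
genus-level presence by logical OR; within-genus co-occurrence of two motifs
is then summarized in a 2x2 contingency table over genera and scored with six
association measures.  Restricting to genera with at least 2 species
(pairwise) or 3 species (triple) keeps singleton genera — where co-occurrence
is trivially confounded with single-species pleiotropy — out of the counts.

The six measures, for motifs A and B with observed genus counts ``O_ij``
(i, j = occurrence of A, B), marginals ``A_i``, ``B_j`` and expected counts
``E_ij = A_i B_j / N``:

    JI  = O11 / (O10 + O01 + O11)          (Jaccard index)
    SDC = 2 O11 / (A1 + B1)                (Sorensen-Dice coefficient)
    SSI = O11 / min(A1, B1)                (Simpson similarity index)
    LL  = 2 * sum_ij O_ij ln(O_ij / E_ij)  (log-likelihood ratio statistic)
    T   = (O11 - E11) / sqrt(O11)          (t score)
    Z   = (O11 - E11) / sqrt(E11)          (z score)

T and Z follow the corpus-linguistics convention with square-root
denominators; ``radicals=False`` switches to plain ``O11`` / ``E11``
denominators for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MOTIFS",
    "AnnotationTable",
    "GenusMotifTable",
    "ContingencyCounts",
    "AssociationScores",
    "read_annotations",
    "aggregate_to_genus",
    "pair_contingency",
    "triple_contingency",
    "association_measures",
    "association_screen",
]

MOTIFS = ["St-H", "St-D", "St-V", "Maze", "Sp-D", "Sp-L", "Eyes", "Area", "Sddl", "Bltc", "Mono"]
TAXONOMY_COLS = ["species", "genus", "family", "order"]


@dataclass
class AnnotationTable:
    """Species-level annotations: one row per species, 11 binary motif flags."""

    df: pd.DataFrame

    @property
    def n_species(self) -> int:
        return len(self.df)


@dataclass
class GenusMotifTable:
    """Genus-level motif presence (OR over member species) with species counts."""

    df: pd.DataFrame  # index: genus; columns: MOTIFS + n_species

    @property
    def n_genera(self) -> int:
        return len(self.df)


@dataclass
class ContingencyCounts:
    O11: int
    O10: int
    O01: int
    O00: int

    @property
    def N(self) -> int:
        return self.O11 + self.O10 + self.O01 + self.O00

    @property
    def A1(self) -> int:
        return self.O11 + self.O10

    @property
    def A0(self) -> int:
        return self.O01 + self.O00

    @property
    def B1(self) -> int:
        return self.O11 + self.O01

    @property
    def B0(self) -> int:
        return self.O10 + self.O00

    def expected(self) -> dict[str, float]:
        n = self.N
        return {
            "E11": self.A1 * self.B1 / n,
            "E10": self.A1 * self.B0 / n,
            "E01": self.A0 * self.B1 / n,
            "E00": self.A0 * self.B0 / n,
        }


@dataclass
class AssociationScores:
    JI: float
    SDC: float
    SSI: float
    LL: float
    T: float
    Z: float
    t_undefined: bool = False  # O11 = 0: T reported as 0 with this flag set


def read_annotations(path, column_map: dict[str, str] | None = None) -> AnnotationTable:
    """Read a species-level annotation TSV/CSV.

    Expects columns species, genus, family, order and the 11 motif flags (a
    ``column_map`` of ``{file column -> canonical name}`` adapts other
    headers).  Duplicate species rows (several images of one species) are
    collapsed by OR over flags.  Non-binary flag values are rejected.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TAXONOMY_COLS + MOTIFS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table is missing columns: {missing}")
    return build_annotation_table(df)


def build_annotation_table(df: pd.DataFrame) -> AnnotationTable:
    """Validate a raw dataframe and collapse duplicate species by OR."""
    df = df[TAXONOMY_COLS + MOTIFS].copy()
    flags = df[MOTIFS]
    if not flags.isin([0, 1]).all().all():
        bad = [c for c in MOTIFS if not flags[c].isin([0, 1]).all()]
        raise ValueError(f"non-binary motif flags in columns {bad}")
    if df["species"].isna().any() or df["genus"].isna().any():
        raise ValueError("every row needs a species and a genus")
    collapsed = df.groupby("species", sort=False).agg(
        {**{c: "first" for c in TAXONOMY_COLS[1:]}, **{m: "max" for m in MOTIFS}}
    )
    return AnnotationTable(collapsed.reset_index())


def aggregate_to_genus(t: AnnotationTable) -> GenusMotifTable:
    """Genus flag = OR over member species; n_species recorded per genus."""
    g = t.df.groupby("genus", sort=False)
    out = g[MOTIFS].max()
    out["n_species"] = g.size()
    return GenusMotifTable(out)


def _subset(g: GenusMotifTable, min_species: int) -> pd.DataFrame:
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    return g.df[g.df["n_species"] >= min_species]


def _check_motifs(*names: str) -> None:
    for m in names:
        if m not in MOTIFS:
            raise KeyError(f"unknown motif {m!r}")


def pair_contingency(
    g: GenusMotifTable, motifA: str, motifB: str, min_species: int = 2
) -> ContingencyCounts:
    """2x2 genus counts for a motif pair over genera with >= min_species."""
    _check_motifs(motifA, motifB)
    if motifA == motifB:
        raise ValueError("motifA and motifB must differ")
    sub = _subset(g, min_species)
    a = sub[motifA].to_numpy(dtype=bool)
    b = sub[motifB].to_numpy(dtype=bool)
    return ContingencyCounts(
        O11=int(np.sum(a & b)),
        O10=int(np.sum(a & ~b)),
        O01=int(np.sum(~a & b)),
        O00=int(np.sum(~a & ~b)),
    )


def triple_contingency(
    g: GenusMotifTable, pair: tuple[str, str], motifB: str, min_species: int = 3
) -> ContingencyCounts:
    """As pair_contingency with "motif A" = co-occurrence of both pair members."""
    a1, a2 = pair
    _check_motifs(a1, a2, motifB)
    if len({a1, a2, motifB}) != 3:
        raise ValueError("triple needs three distinct motifs")
    sub = _subset(g, min_species)
    a = sub[a1].to_numpy(dtype=bool) & sub[a2].to_numpy(dtype=bool)
    b = sub[motifB].to_numpy(dtype=bool)
    return ContingencyCounts(
        O11=int(np.sum(a & b)),
        O10=int(np.sum(a & ~b)),
        O01=int(np.sum(~a & b)),
        O00=int(np.sum(~a & ~b)),
    )


def association_measures(c: ContingencyCounts, radicals: bool = True) -> AssociationScores:
    """The six association measures of a 2x2 contingency table.

    LL terms with ``O_ij = 0`` contribute 0 (the x ln x -> 0 limit).  With
    ``O11 = 0`` the T score is undefined and reported as 0 with the
    ``t_undefined`` flag; ``E11 = 0`` (an empty margin) is an error.
    """
    if c.N <= 0:
        raise ValueError("empty contingency table (no genera pass the filter)")
    e = c.expected()
    if e["E11"] <= 0:
        raise ValueError("E11 = 0: a motif margin is empty")
    denom_union = c.O10 + c.O01 + c.O11
    ji = c.O11 / denom_union if denom_union else 0.0
    sdc = 2.0 * c.O11 / (c.A1 + c.B1) if (c.A1 + c.B1) else 0.0
    ssi = c.O11 / min(c.A1, c.B1) if min(c.A1, c.B1) else 0.0
    ll = 0.0
    for key, obs in (("E11", c.O11), ("E10", c.O10), ("E01", c.O01), ("E00", c.O00)):
        if obs > 0:
            ll += obs * math.log(obs / e[key])
    ll *= 2.0
    t_undef = c.O11 == 0
    t_den = (math.sqrt(c.O11) if radicals else c.O11) if c.O11 else 1.0
    t = 0.0 if t_undef else (c.O11 - e["E11"]) / t_den
    z = (c.O11 - e["E11"]) / (math.sqrt(e["E11"]) if radicals else e["E11"])
    return AssociationScores(JI=ji, SDC=sdc, SSI=ssi, LL=ll, T=t, Z=z, t_undefined=t_undef)


def association_screen(
    g: GenusMotifTable,
    mode: str = "pairwise",
    anchor: tuple[str, str] = ("Sp-D", "Sp-L"),
    min_species: int | None = None,
    radicals: bool = True,
) -> pd.DataFrame:
    """Score every motif pair (or every partner of an anchor pair) as tidy rows.

    ``pairwise`` scores all 55 unordered motif pairs over genera with at
    least 2 species; ``triple`` scores the co-occurrence of the anchor pair
    against each of the 9 remaining motifs over genera with at least 3
    species.  Returns a dataframe with one row per combination and the six
    measures as columns, sorted by Z descending.
    """
    if mode == "pairwise":
        ms = 2 if min_species is None else min_species
        rows = []
        for i, ma in enumerate(MOTIFS):
            for mb in MOTIFS[i + 1 :]:
                s = association_measures(pair_contingency(g, ma, mb, ms), radicals)
                rows.append({"motif_a": ma, "motif_b": mb, **s.__dict__})
    elif mode == "triple":
        ms = 3 if min_species is None else min_species
        rows = []
        for mb in MOTIFS:
            if mb in anchor:
                continue
            s = association_measures(triple_contingency(g, anchor, mb, ms), radicals)
            rows.append({"motif_a": "+".join(anchor), "motif_b": mb, **s.__dict__})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows).sort_values("Z", ascending=False, ignore_index=True)
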