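"""Introgression statistics on allele-frequency matrices.

Implements the frequency (population-level) form of the four-taxon
ABBA-BABA test.  For site s with derived-allele frequencies p1, p2, p3, p4
in (P1, P2, P3, Outgroup):

    p_ABBA(s) = (1-p1) p2 p3 (1-p4)
    p_BABA(s) = p1 (1-p2) p3 (1-p4)
    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)

Under incomplete lineage sorting alone D is symmetric around 0; an excess of
ABBA (D > 0) indicates gene flow between P2 and P3.  Significance comes from
a delete-one-block jackknife over contiguous genomic blocks (emulating the
5-Mb blocks of genome-scale analyses).  The trio-level D_min is the minimum
of |D| across the three possible topologies of a species trio against a
fixed outgroup — a conservative signal that is nonzero only if no tree
arrangement can explain the site patterns without gene flow.

Interclass heterozygosity — the fraction of ancestry-diagnostic sites at
which an individual carries one allele from each parental panel — separates
early-generation hybrids (~1 for an F1) from backcrossed or ancient mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DStatResult",
    "TrioDminResult",
    "patterson_d",
    "d_min",
    "holm_bonferroni",
    "interclass_heterozygosity",
    "assign_blocks",
    "read_freq_matrix",
]


@dataclass
class DStatResult:
    D: float
    z: float
    se: float
    n_blocks: int
    abba_sum: float
    baba_sum: float
    n_sites_used: int
    n_sites_dropped: int


@dataclass
class TrioDminResult:
    trio: tuple[str, str, str]
    outgroup: str
    topologies: list[tuple[str, str, str]]  # (P1, P2, P3) per arrangement
    d_values: list[float]
    z_values: list[float]
    d_min: float
    z_min: float  # z of the topology attaining the minimum |D|
    p_value: float  # two-sided normal p of z_min
    significant: bool | None = None  # set by a later multiple-testing step


def assign_blocks(positions: np.ndarray, block_size: float) -> np.ndarray:
    """Map genomic positions to contiguous block ids of ``block_size``."""
    positions = np.asarray(positions, dtype=float)
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    return (positions // block_size).astype(int)


def read_freq_matrix(path) -> pd.DataFrame:
    """Read a site x population frequency TSV with a ``block`` column."""
    df = pd.read_csv(path, sep="\t")
    if "block" not in df.columns:
        raise ValueError("frequency matrix needs a 'block' column")
    return df


def _abba_baba_sums(p1, p2, p3, p4):
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def patterson_d(
    fm: pd.DataFrame, pops: tuple[str, str, str, str] = ("p1", "p2", "p3", "p4")
) -> DStatResult:
    """Patterson's D with a delete-one-block jackknife z score.

    ``fm`` holds one row per biallelic site with a ``block`` column and
    derived-allele frequency columns named in ``pops`` (P1, P2, P3, Outgroup
    order).  Sites with any missing frequency are dropped and counted.
    Requires at least 2 blocks; raises on a zero denominator (no informative
    sites).
    """
    cols = ["block", *pops]
    missing = [c for c in cols if c not in fm.columns]
    if missing:
        raise ValueError(f"frequency matrix is missing columns: {missing}")
    sub = fm[cols].dropna()
    n_dropped = len(fm) - len(sub)
    p1, p2, p3, p4 = (sub[c].to_numpy(dtype=float) for c in pops)
    if np.any((np.stack([p1, p2, p3, p4]) < 0) | (np.stack([p1, p2, p3, p4]) > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    abba, baba = _abba_baba_sums(p1, p2, p3, p4)
    num, den = abba.sum() - baba.sum(), abba.sum() + baba.sum()
    if den <= 0:
        raise ValueError("no informative sites: ABBA + BABA = 0")
    d = num / den

    blocks = sub["block"].to_numpy()
    uniq = np.unique(blocks)
    if uniq.size < 2:
        raise ValueError("need at least 2 blocks for the jackknife")
    # delete-one-block pseudovalues
    abba_b = np.array([abba[blocks == b].sum() for b in uniq])
    baba_b = np.array([baba[blocks == b].sum() for b in uniq])
    num_del = num - (abba_b - baba_b)
    den_del = den - (abba_b + baba_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_del = np.where(den_del > 0, num_del / den_del, 0.0)
    m = uniq.size
    se = float(np.sqrt((m - 1) / m * np.sum((d_del - d_del.mean()) ** 2)))
    z = float(d / se) if se > 0 else (0.0 if d == 0 else np.inf * np.sign(d))
    return DStatResult(
        D=float(d),
        z=z,
        se=se,
        n_blocks=int(m),
        abba_sum=float(abba.sum()),
        baba_sum=float(baba.sum()),
        n_sites_used=len(sub),
        n_sites_dropped=int(n_dropped),
    )


def d_min(
    fm: pd.DataFrame, trio: tuple[str, str, str], outgroup: str
) -> TrioDminResult:
    """Minimum |D| over the three topologies of a trio (conservative signal).

    Evaluates D(A,B;C,O), D(A,C;B,O) and D(C,B;A,O) by column permutation;
    the reported p-value is the two-sided normal tail of the jackknife z of
    the topology attaining the minimum |D|.
    """
    a, b, c = trio
    topologies = [(a, b, c), (a, c, b), (c, b, a)]
    results = [patterson_d(fm, pops=(x, y, w, outgroup)) for x, y, w in topologies]
    ds = [r.D for r in results]
    zs = [r.z for r in results]
    k = int(np.argmin([abs(d) for d in ds]))
    z_min = zs[k]
    p = float(2 * stats.norm.sf(abs(z_min)))
    return TrioDminResult(
        trio=trio,
        outgroup=outgroup,
        topologies=topologies,
        d_values=ds,
        z_values=zs,
        d_min=abs(ds[k]),
        z_min=z_min,
        p_value=p,
    )


def holm_bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm procedure; returns a boolean reject decision per test."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("no p-values to adjust")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = pvals.size
    order = np.argsort(pvals)
    reject = np.zeros(n, dtype=bool)
    for rank, idx in enumerate(order):
        if pvals[idx] * (n - rank) <= alpha:
            reject[idx] = True
        else:
            break  # step-down: once one fails, all larger p fail
    return reject


def interclass_heterozygosity(
    dosages, blocks=None
) -> float | tuple[float, float]:
    """Fraction of callable diagnostic sites that are heterozygous.

    ``dosages`` are derived-allele dosages (0/1/2) of one individual at sites
    fixed for opposite alleles in the two parental panels; NaN marks
    uncallable sites.  With ``blocks`` given, also returns a delete-one-block
    jackknife standard error.
    """
    d = np.asarray(dosages, dtype=float)
    callable_mask = ~np.isnan(d)
    n = int(callable_mask.sum())
    if n == 0:
        raise ValueError("no callable diagnostic sites")
    het = float((d[callable_mask] == 1).mean())
    if blocks is None:
        return het
    blk = np.asarray(blocks)[callable_mask]
    uniq = np.unique(blk)
    if uniq.size < 2:
        raise ValueError("need at least 2 blocks for the jackknife")
    is_het = (d[callable_mask] == 1).astype(float)
    het_del = np.array([is_het[blk != b].mean() for b in uniq])
    m = uniq.size
    se = float(np.sqrt((m - 1) / m * np.sum((het_del - het_del.mean()) ** 2)))
    return het, se
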