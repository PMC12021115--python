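"""Outgroup f3 / f4 statistics with block-jackknife uncertainty, and the
f4-averaged breed distance network.

f3(X, Y; O) = mean over sites of (pX - pO)(pY - pO): shared genetic drift
of X and Y relative to the outgroup.  f4(P1, P2; P3, O) = mean of
(p1 - p2)(p3 - pO): treeness test, zero for an unadmixed quartet
((P1,P2),(P3,O)).  Uncertainty comes from a delete-one weighted jackknife
over contiguous physical blocks.  The network layer averages f4 over third
breeds: disf4(a, b) = sum_i f4(a, i; b, O) / n, symmetrized to
disedge(a, b) = (disf4(a, b) + disf4(b, a)) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, SampleMeta

BLOCK_SIZE_DEFAULT = 5_000_000


@dataclass
class FStatResult:
    """One f-statistic with jackknife uncertainty."""

    pops: tuple
    value: float
    se: float
    z: float
    n_sites: int
    n_blocks: int


def breed_frequencies(gm: GenotypeMatrix, meta: SampleMeta, column: str = "breed") -> pd.DataFrame:
    """Alternate-allele frequency per site per breed (NaN where uncalled)."""
    cols = {}
    for breed, sub in meta.table.groupby(column, sort=False):
        idx = [gm.samples.index(s) for s in sub["sample"] if s in gm.samples]
        d = gm.dosages[idx]
        called = d != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cols[breed] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return pd.DataFrame(cols)


def physical_blocks(
    positions: np.ndarray, chroms: np.ndarray, block_size: int = BLOCK_SIZE_DEFAULT
) -> np.ndarray:
    """Contiguous genomic block index per site (chromosome-aware)."""
    out = np.empty(len(positions), dtype=np.int64)
    next_block = 0
    for chrom in pd.unique(np.asarray(chroms)):
        m = np.asarray(chroms) == chrom
        local = (np.asarray(positions)[m] - 1) // block_size
        _, local = np.unique(local, return_inverse=True)
        out[m] = local + next_block
        next_block += local.max() + 1 if m.any() else 0
    return out


def block_jackknife(values: np.ndarray, blocks: np.ndarray) -> tuple[float, float, int]:
    """Delete-one weighted block jackknife of a mean.

    ``values`` are per-site contributions; ``blocks`` their block labels.
    Uses the weighted jackknife for unequal block sizes (Busing et al.
    1999); with equal blocks it reduces to the textbook delete-one formula.
    Returns (estimate, SE, n_blocks); SE is NaN with fewer than 2 blocks.
    """
    values = np.asarray(values, dtype=float)
    blocks = np.asarray(blocks)
    ok = ~np.isnan(values)
    values, blocks = values[ok], blocks[ok]
    n = len(values)
    if n == 0:
        raise ValueError("no usable sites")
    labels, inv = np.unique(blocks, return_inverse=True)
    g = len(labels)
    est = values.mean()
    if g < 2:
        return est, float("nan"), g
    m_j = np.bincount(inv).astype(float)
    sums = np.bincount(inv, weights=values)
    total = values.sum()
    theta_del = (total - sums) / (n - m_j)  # delete-block means
    h_j = n / m_j
    theta_dot = g * est - ((1.0 - m_j / n) * theta_del).sum()
    tau = h_j * est - (h_j - 1.0) * theta_del
    var = ((tau - theta_dot) ** 2 / (h_j - 1.0)).sum() / g
    return est, float(np.sqrt(var)), g


def _freq_product_stat(
    terms: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    pops: tuple,
    block_size: int,
) -> FStatResult:
    usable = ~np.isnan(terms)
    if usable.sum() == 0:
        raise ValueError("zero usable sites for f-statistic")
    blocks = physical_blocks(positions[usable], np.asarray(chroms)[usable], block_size)
    est, se, nb = block_jackknife(terms[usable], blocks)
    z = est / se if se and se > 0 else float("nan")
    return FStatResult(pops, float(est), float(se), float(z), int(usable.sum()), nb)


def outgroup_f3(
    freqs: pd.DataFrame,
    x: str,
    y: str,
    outgroup: str,
    positions: np.ndarray,
    chroms: np.ndarray,
    block_size: int = BLOCK_SIZE_DEFAULT,
) -> FStatResult:
    """f3(X, Y; O) with jackknife SE; complete-case over the three pops."""
    pX, pY, pO = (freqs[k].to_numpy() for k in (x, y, outgroup))
    terms = (pX - pO) * (pY - pO)
    return _freq_product_stat(terms, np.asarray(positions), chroms, (x, y, outgroup), block_size)


def f4(
    freqs: pd.DataFrame,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    positions: np.ndarray,
    chroms: np.ndarray,
    block_size: int = BLOCK_SIZE_DEFAULT,
) -> FStatResult:
    """f4(P1, P2; P3, O) with jackknife SE; complete-case over the quartet."""
    a, b, c, o = (freqs[k].to_numpy() for k in (p1, p2, p3, outgroup))
    terms = (a - b) * (c - o)
    return _freq_product_stat(terms, np.asarray(positions), chroms, (p1, p2, p3, outgroup), block_size)


def disf4_matrix(
    freqs: pd.DataFrame,
    breeds: list[str],
    outgroup: str,
    positions: np.ndarray,
    chroms: np.ndarray,
    exclude: list[str] | None = None,
    include_self_terms: bool = False,
    block_size: int = BLOCK_SIZE_DEFAULT,
) -> pd.DataFrame:
    """Directional f4 distance matrix disf4(a, b) over included breeds.

    disf4(a, b) averages f4(a, i; b, O) over third breeds i.  By default i
    runs over the included breeds excluding a and b (i = a contributes an
    exact zero and i = b a self-referential term); ``include_self_terms``
    restores the literal all-breeds average.  Breeds in ``exclude`` (e.g.
    those geographically adjacent to the Yakutian horse when building the
    pony network) are removed before any computation.
    """
    excl = set(exclude or [])
    inc = [b for b in breeds if b not in excl]
    if len(inc) < 3:
        raise ValueError("need at least 3 included breeds")
    mat = pd.DataFrame(np.nan, index=inc, columns=inc, dtype=float)
    for a in inc:
        for b in inc:
            if a == b:
                continue
            third = inc if include_self_terms else [i for i in inc if i not in (a, b)]
            if not third:
                raise ValueError("no third breeds to average over")
            vals = [
                f4(freqs, a, i, b, outgroup, positions, chroms, block_size).value
                for i in third
            ]
            mat.loc[a, b] = float(np.mean(vals))
    return mat


def disedge_network(directional: pd.DataFrame, n_bins: int = 5) -> pd.DataFrame:
    """Symmetrized edge table from a directional disf4 matrix.

    disedge(a, b) = (disf4(a, b) + disf4(b, a)) / 2.  Edges are ranked by
    shared drift (larger disedge = closer) and binned into ``n_bins``
    strength classes (1 = weakest ... n_bins = strongest) for rendering;
    the full table is always returned.
    """
    breeds = list(directional.index)
    rows = []
    for i, a in enumerate(breeds):
        for b in breeds[i + 1 :]:
            ab = directional.loc[a, b]
            ba = directional.loc[b, a]
            rows.append(
                {
                    "breed_a": a,
                    "breed_b": b,
                    "disf4_ab": float(ab),
                    "disf4_ba": float(ba),
                    "disedge": float((ab + ba) / 2.0),
                }
            )
    edges = pd.DataFrame(rows)
    if len(edges):
        ranks = edges["disedge"].rank(method="first")
        edges["strength_bin"] = (
            np.ceil(ranks / len(edges) * n_bins).astype(int).clip(1, n_bins)
        )
    else:
        edges["strength_bin"] = pd.Series(dtype=int)
    return edges
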