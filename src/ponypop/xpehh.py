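"""Cross-population extended haplotype homozygosity from first principles.

EHH at extension x is the probability that two haplotypes drawn without
replacement are identical over the stretch from the core site to x.  iHH
integrates EHH over physical distance (trapezoid), both directions from the
core, until EHH falls below a cutoff.  XP-EHH is ln(iHH_query / iHH_ref)
per core, standardized genome-wide; with ponies as the query population,
positive scores localize selection on the pony side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import assign_windows


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes for one population.

    ``haps`` is (n_haplotypes x n_sites) with alleles in {0,1};
    ``positions`` are bp, strictly increasing.
    """

    haps: np.ndarray
    positions: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haps.ndim != 2 or self.haps.shape[1] != len(self.positions):
            raise ValueError("haps must be (n_haplotypes x n_sites)")
        if not np.all((self.haps == 0) | (self.haps == 1)):
            raise ValueError("haplotype alleles must be 0/1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_hap(self) -> int:
        return self.haps.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]


@dataclass
class XPEHHParams:
    """Integration and scoring parameters (bp units)."""

    ehh_cutoff: float = 0.05
    max_extend: int = 1_000_000
    max_gap: int = 200_000
    min_core_maf: float = 0.05


def _ehh_of_groups(group_sizes: np.ndarray, n: int) -> float:
    return float((group_sizes * (group_sizes - 1)).sum() / (n * (n - 1)))


def ehh_curve(
    panel: HaplotypePanel, core_index: int, direction: int
) -> tuple[np.ndarray, np.ndarray]:
    """EHH at each site outward from the core (inclusive).

    ``direction`` is +1 (toward larger positions) or -1.  Haplotypes are
    grouped by identity over [core..x]; EHH(x) = sum_g C(n_g,2) / C(n,2).
    Monotone non-increasing in |x - core| since each step refines the
    partition.  Returns (site indices, EHH values), starting at the core.
    """
    n = panel.n_hap
    if n < 2:
        raise ValueError("EHH needs at least two haplotypes")
    if not (0 <= core_index < panel.n_sites):
        raise IndexError("core site out of range")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    idx = []
    vals = []
    groups = np.zeros(n, dtype=np.int64)  # all in one group before the core allele
    x = core_index
    while 0 <= x < panel.n_sites:
        # refine groups by the allele at x
        key = groups * 2 + panel.haps[:, x]
        _, groups = np.unique(key, return_inverse=True)
        sizes = np.bincount(groups)
        idx.append(x)
        vals.append(_ehh_of_groups(sizes, n))
        x += direction
    return np.asarray(idx), np.asarray(vals)


def ihh(
    panel: HaplotypePanel,
    core_index: int,
    params: XPEHHParams | None = None,
) -> tuple[float, bool]:
    """Integrated EHH (bp) around a core site.

    Trapezoidal integral of the EHH curve over physical position, each
    direction, until EHH < cutoff (the crossing segment is included) or the
    extension exceeds ``max_extend``; integration truncates at adjacent-site
    gaps above ``max_gap``.  Returns (iHH, truncated_flag); the flag marks
    cores whose curve never fell below the cutoff inside the allowed range.
    """
    params = params or XPEHHParams()
    pos = panel.positions
    total = 0.0
    truncated = False
    n = panel.n_hap
    for direction in (+1, -1):
        groups = np.zeros(n, dtype=np.int64)
        key = groups * 2 + panel.haps[:, core_index]
        _, groups = np.unique(key, return_inverse=True)
        prev_ehh = _ehh_of_groups(np.bincount(groups), n)
        if prev_ehh < params.ehh_cutoff:
            continue  # immediate stop: EHH already below cutoff at the core
        x = core_index
        stopped = False
        while True:
            nxt = x + direction
            if not (0 <= nxt < panel.n_sites):
                break
            gap = abs(int(pos[nxt]) - int(pos[x]))
            if gap > params.max_gap:
                stopped = True
                break
            if abs(int(pos[nxt]) - int(pos[core_index])) > params.max_extend:
                stopped = True
                break
            key = groups * 2 + panel.haps[:, nxt]
            _, groups = np.unique(key, return_inverse=True)
            e = _ehh_of_groups(np.bincount(groups), n)
            total += 0.5 * (prev_ehh + e) * gap
            prev_ehh = e
            x = nxt
            if e < params.ehh_cutoff:
                stopped = True
                break
        if not stopped and prev_ehh >= params.ehh_cutoff:
            truncated = True  # hit chromosome end above cutoff
    return total, truncated


def xpehh_scores(
    query: HaplotypePanel,
    ref: HaplotypePanel,
    params: XPEHHParams | None = None,
    chrom: str = "1",
) -> pd.DataFrame:
    """Raw and genome-standardized XP-EHH per core site.

    Cores are restricted to pooled MAF >= ``min_core_maf``.  Cores where
    either panel yields iHH = 0, or where either population is monomorphic
    over the whole extension (EHH stuck at 1 to the boundary in both
    panels' curves), are skipped with a reason.
    """
    params = params or XPEHHParams()
    if query.n_sites != ref.n_sites or np.any(query.positions != ref.positions):
        raise ValueError("query and ref panels must share the site set")
    pooled = np.vstack([query.haps, ref.haps])
    freq = pooled.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    rows = []
    for core in np.flatnonzero(maf >= params.min_core_maf):
        ihh_q, trunc_q = ihh(query, core, params)
        ihh_r, trunc_r = ihh(ref, core, params)
        if ihh_r <= 0.0 or ihh_q <= 0.0:
            rows.append(
                {"chrom": chrom, "pos": int(query.positions[core]), "core_index": core,
                 "raw": np.nan, "skipped": "zero_ihh"}
            )
            continue
        rows.append(
            {"chrom": chrom, "pos": int(query.positions[core]), "core_index": core,
             "raw": float(np.log(ihh_q / ihh_r)),
             "skipped": "truncated" if (trunc_q or trunc_r) else ""}
        )
    track = pd.DataFrame(rows, columns=["chrom", "pos", "core_index", "raw", "skipped"])
    raw = track["raw"]
    usable = raw.notna()
    mu = raw[usable].mean()
    sd = raw[usable].std(ddof=0)
    track["normalized"] = (raw - mu) / sd if usable.sum() >= 2 and sd > 0 else np.nan
    return track


def window_average(
    track: pd.DataFrame, window_size: int = 10_000
) -> pd.DataFrame:
    """Mean normalized XP-EHH of the cores falling in each window.

    Windows with no scored cores are absent (undefined).
    """
    t = track[track["normalized"].notna()].copy()
    t["w"] = assign_windows(t["pos"].to_numpy(), window_size)
    frames = []
    for chrom, sub in t.groupby("chrom", sort=False):
        g = sub.groupby("w", sort=True).agg(
            mean_xpehh=("normalized", "mean"), n_cores=("normalized", "size")
        ).reset_index()
        g.insert(0, "chrom", chrom)
        g["start"] = g["w"] * window_size
        g["end"] = (g["w"] + 1) * window_size
        frames.append(g[["chrom", "start", "end", "n_cores", "mean_xpehh"]])
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cores", "mean_xpehh"])
    return pd.concat(frames, ignore_index=True)


def panels_from_genotypes(gm, meta, query_pops, ref_pops, chrom=None):
    """Build query/ref HaplotypePanels from a phased GenotypeMatrix + metadata."""
    if gm.haplotypes is None:
        raise ValueError("phased haplotypes required for XP-EHH")
    if chrom is not None:
        keep = np.flatnonzero(gm.chroms == chrom)
        gm = gm.take_sites(keep)
    panels = []
    for pops, lab in ((query_pops, "query"), (ref_pops, "ref")):
        names = meta.samples_in(pops)
        sub = gm.take_samples(names)
        if np.any(sub.haplotypes < 0):
            raise ValueError("missing haplotype calls not supported in panels")
        panels.append(HaplotypePanel(sub.haplotypes, sub.positions, lab))
    return tuple(panels)
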