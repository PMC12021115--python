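"""Windowed differentiation and diversity statistics.

Weir & Cockerham (1984) two-population variance components give per-site
FST; windows combine them as ratio-of-sums.  Nucleotide diversity is the
unbiased per-site heterozygosity summed over a window and divided by the
window length in bp.  Also here: LD decay curves per breed and a
scanning-window runs-of-homozygosity caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, assign_windows, tile_windows

WINDOW_SIZE_DEFAULT = 10_000


def _pop_site_summaries(d: np.ndarray):
    """Per-site (n diploids called, alt frequency, observed het freq) for one pop."""
    called = d != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, d, 0).sum(axis=0)
    het = np.where(called, d == 1, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


def site_fst_components(
    d1: np.ndarray, d2: np.ndarray, min_n: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components per site for two populations.

    Returns (a, d, ok) where ``a`` is the among-population component,
    ``d = a + b + c`` the total, and ``ok`` flags sites with at least
    ``min_n`` called diploids in each population.  Per-site FST is a/d
    where d > 0.
    """
    n1, p1, h1 = _pop_site_summaries(d1)
    n2, p2, h2 = _pop_site_summaries(d2)
    ok = (n1 >= min_n) & (n2 >= min_n)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    tot = a + b + c
    a = np.where(ok, a, np.nan)
    tot = np.where(ok, tot, np.nan)
    return a, tot, ok


def windowed_fst(
    a: np.ndarray,
    d: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    window_size: int = WINDOW_SIZE_DEFAULT,
) -> pd.DataFrame:
    """Ratio-of-sums window FST: sum(a)/sum(a+b+c) over the sites of each window.

    Windows with no usable sites or non-positive total variance are NaN
    (excluded from quantile ranking downstream).  The per-window
    mean-of-ratios estimator is also reported for comparison.
    """
    win = assign_windows(positions, window_size)
    ok = ~np.isnan(a) & ~np.isnan(d)
    frames = []
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        tab = pd.DataFrame(
            {"w": win[m], "a": np.where(ok[m], a[m], 0.0), "d": np.where(ok[m], d[m], 0.0),
             "n": ok[m].astype(int)}
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            tab["ratio"] = np.where((tab["d"] > 0) & ok[m], tab["a"] / tab["d"], np.nan)
        g = tab.groupby("w", sort=True).agg(
            sum_a=("a", "sum"), sum_d=("d", "sum"), n_snps=("n", "sum"),
            mean_of_ratios=("ratio", "mean"),
        )
        g["fst"] = np.where(g["sum_d"] > 0, g["sum_a"] / g["sum_d"], np.nan)
        g.loc[g["n_snps"] == 0, "fst"] = np.nan
        g = g.reset_index()
        g.insert(0, "chrom", chrom)
        g["start"] = g["w"] * window_size
        g["end"] = (g["w"] + 1) * window_size
        frames.append(g[["chrom", "start", "end", "n_snps", "fst", "mean_of_ratios"]])
    return pd.concat(frames, ignore_index=True)


def windowed_pi(
    gm: GenotypeMatrix, window_size: int = WINDOW_SIZE_DEFAULT
) -> pd.DataFrame:
    """Nucleotide diversity per window, per bp.

    Per-site pi is c_ref*c_alt / C(n,2) over the n called chromosomes at the
    site; window theta_pi sums site pi and divides by the window length in
    bp.  Windows with sites but zero called chromosomes at all of them are
    flagged NaN; windows with no sites are 0 (monomorphic stretch).
    """
    d = gm.dosages
    called = d != MISSING
    n_chrom = 2 * called.sum(axis=0).astype(float)
    alt = np.where(called, d, 0).sum(axis=0).astype(float)
    ref = n_chrom - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pairs = n_chrom * (n_chrom - 1) / 2.0
        site_pi = np.where(pairs > 0, ref * alt / np.maximum(pairs, 1), np.nan)
    win = assign_windows(gm.positions, window_size)
    chroms = gm.chroms
    frames = []
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        tab = pd.DataFrame({"w": win[m], "pi": site_pi[m]})
        g = tab.groupby("w", sort=True).agg(
            pi_sum=("pi", lambda s: np.nan if s.isna().all() else s.sum(skipna=True)),
            n_snps=("pi", "size"),
        ).reset_index()
        g.insert(0, "chrom", chrom)
        g["start"] = g["w"] * window_size
        g["end"] = (g["w"] + 1) * window_size
        g["theta_pi"] = g["pi_sum"] / (g["end"] - g["start"])
        frames.append(g[["chrom", "start", "end", "n_snps", "theta_pi"]])
    return pd.concat(frames, ignore_index=True)


def pi_ratio(
    pi_a: pd.DataFrame, pi_b: pd.DataFrame, min_snps: int = 1
) -> pd.DataFrame:
    """Per-window ratio theta_pi_a / theta_pi_b on the shared window grid.

    Windows where the denominator is 0/NaN or either side has fewer than
    ``min_snps`` SNPs get NaN (excluded from ranking).
    """
    merged = pi_a.merge(
        pi_b, on=["chrom", "start", "end"], suffixes=("_a", "_b"), how="outer"
    )
    num = merged["theta_pi_a"]
    den = merged["theta_pi_b"]
    low = (merged["n_snps_a"].fillna(0) < min_snps) | (merged["n_snps_b"].fillna(0) < min_snps)
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["pi_ratio"] = np.where(
            (den > 0) & ~low & ~num.isna(), num / den, np.nan
        )
    return merged[["chrom", "start", "end", "n_snps_a", "n_snps_b",
                   "theta_pi_a", "theta_pi_b", "pi_ratio"]]


def window_table(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    window_size: int = WINDOW_SIZE_DEFAULT,
    label_a: str = "pony",
    label_b: str = "horse",
    min_pi_snps: int = 1,
) -> pd.DataFrame:
    """FST + per-group theta_pi + pi ratio on one window grid.

    ``gm_a`` and ``gm_b`` must share the variant table (same sites); group a
    is conventionally the pony side of the contrast.
    """
    a, d, _ = site_fst_components(gm_a.dosages, gm_b.dosages)
    fst = windowed_fst(a, d, gm_a.positions, gm_a.chroms, window_size)
    pa = windowed_pi(gm_a, window_size)
    pb = windowed_pi(gm_b, window_size)
    pr = pi_ratio(pa, pb, min_snps=min_pi_snps)
    out = fst.merge(pr, on=["chrom", "start", "end"], how="outer")
    out = out.rename(
        columns={
            "theta_pi_a": f"pi_{label_a}",
            "theta_pi_b": f"pi_{label_b}",
            "n_snps_a": f"n_snps_{label_a}",
            "n_snps_b": f"n_snps_{label_b}",
        }
    )
    return out


def ld_decay(
    gm: GenotypeMatrix,
    max_dist: int = 500_000,
    bin_width: int = 10_000,
    min_samples: int = 8,
) -> pd.DataFrame:
    """Mean dosage-correlation r^2 per physical-distance bin.

    All site pairs on the same chromosome within ``max_dist`` contribute;
    requires at least ``min_samples`` individuals (breeds below the minimum
    are the caller's responsibility to exclude).
    """
    if gm.n_samples < min_samples:
        raise ValueError(
            f"LD decay requires >= {min_samples} samples, got {gm.n_samples}"
        )
    d = gm.dosages.astype(float)
    d[gm.dosages == MISSING] = np.nan
    pos = gm.positions
    chroms = gm.chroms
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        dc = d[:, m]
        pc = pos[m]
        order = np.argsort(pc)
        dc, pc = dc[:, order], pc[order]
        # standardize ignoring NaN; pairwise complete-case r via masked dot
        for i in range(dc.shape[1]):
            far = np.searchsorted(pc, pc[i] + max_dist, side="right")
            for j in range(i + 1, far):
                dist = pc[j] - pc[i]
                if dist == 0 or dist > max_dist:
                    continue
                x, y = dc[:, i], dc[:, j]
                okm = ~np.isnan(x) & ~np.isnan(y)
                if okm.sum() < 2:
                    continue
                xv, yv = x[okm], y[okm]
                sx, sy = xv.std(), yv.std()
                if sx == 0 or sy == 0:
                    continue
                r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
                b = min(int((dist - 1) // bin_width), n_bins - 1)
                sums[b] += r * r
                counts[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "dist_low": np.arange(n_bins) * bin_width,
            "dist_high": (np.arange(n_bins) + 1) * bin_width,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


@dataclass
class ROHParams:
    """Scanning-window ROH parameters (PLINK --homozyg style).

    Lengths are bp.  A 50-SNP window is a hit when it contains at most
    ``max_het_per_window`` heterozygous and ``max_missing_per_window``
    missing calls; a homozygous SNP is in-ROH when the fraction of
    overlapping windows that are hits reaches ``hit_rate``.  Runs split at
    adjacent-SNP gaps above ``max_gap``; emitted segments must satisfy the
    length, SNP-count and density (kb per SNP) thresholds.
    """

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    hit_rate: float = 0.05
    min_length: int = 500_000
    min_snps: int = 50
    max_gap: int = 100_000
    max_kb_per_snp: float = 50.0


def roh_detect(gm: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Runs of homozygosity per sample.

    Returns a table (sample, chrom, start, end, n_snps, length_kb) with
    1-based inclusive start/end at the first/last SNP of each segment.
    """
    params = params or ROHParams()
    w = params.window_snps
    rows = []
    chroms = gm.chroms
    for chrom in pd.unique(chroms):
        m = np.flatnonzero(chroms == chrom)
        pos = gm.positions[m]
        order = np.argsort(pos)
        m, pos = m[order], pos[order]
        n_sites = len(m)
        if n_sites < w:
            continue
        for si, sample in enumerate(gm.samples):
            g = gm.dosages[si, m]
            het = (g == 1).astype(np.int32)
            mis = (g == MISSING).astype(np.int32)
            ch = np.concatenate([[0], np.cumsum(het)])
            cm = np.concatenate([[0], np.cumsum(mis)])
            n_win = n_sites - w + 1
            starts = np.arange(n_win)
            hits = (
                (ch[starts + w] - ch[starts] <= params.max_het_per_window)
                & (cm[starts + w] - cm[starts] <= params.max_missing_per_window)
            ).astype(np.int32)
            chits = np.concatenate([[0], np.cumsum(hits)])
            # windows overlapping SNP k start in [k-w+1, k] clipped to [0, n_win)
            k = np.arange(n_sites)
            lo = np.clip(k - w + 1, 0, n_win)
            hi = np.clip(k + 1, 0, n_win)
            n_over = np.maximum(hi - lo, 1)
            frac = (chits[hi] - chits[lo]) / n_over
            in_roh = (frac >= params.hit_rate) & (g == 0) | (frac >= params.hit_rate) & (g == 2)
            # maximal runs, split at large gaps
            idx = np.flatnonzero(in_roh)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(
                (np.diff(idx) > 1) | (np.diff(pos[idx]) > params.max_gap)
            )
            run_starts = np.concatenate([[0], breaks + 1])
            run_ends = np.concatenate([breaks, [idx.size - 1]])
            for rs, re in zip(run_starts, run_ends):
                first, last = idx[rs], idx[re]
                length = pos[last] - pos[first] + 1
                n_snps = re - rs + 1
                if length < params.min_length or n_snps < params.min_snps:
                    continue
                if (length / 1000.0) / n_snps > params.max_kb_per_snp:
                    continue
                rows.append(
                    {
                        "sample": sample,
                        "chrom": chrom,
                        "start": int(pos[first]),
                        "end": int(pos[last]),
                        "n_snps": int(n_snps),
                        "length_kb": float(length / 1000.0),
                    }
                )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_snps", "length_kb"]
    )
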