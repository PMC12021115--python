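"""Sweep calling from multi-metric window tracks, genotype-frequency
gradients across height groups, and interval-overlap testing.

Windows in the extreme tail (default top 1%) of each metric -- FST, pi
ratio and mean XP-EHH -- are merged into per-metric regions; a candidate
selective sweep is any region supported by at least two metrics.  The
overlap between two candidate sets (e.g. Eastern-pony and Western-pony
contrasts) is scored with an interval-wise Fisher exact test and a
length-preserving random-shuffle permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix, SampleMeta, merge_intervals


def quantile_cut(
    values: np.ndarray, q: float = 0.01, tail: str = "upper"
) -> tuple[float, np.ndarray]:
    """Empirical tail threshold and flag mask over defined values.

    ``q`` is the tail fraction (0.01 = top 1%).  The threshold is the
    (1-q) or q empirical quantile of the non-NaN values; flagging is by
    strict inequality, so ties at the threshold are not flagged.  NaN
    windows are never flagged.  ``q = 1`` flags every defined window.
    """
    values = np.asarray(values, dtype=float)
    defined = ~np.isnan(values)
    if defined.sum() == 0:
        raise ValueError("all windows undefined")
    if not (0 < q <= 1):
        raise ValueError("q must be in (0,1]")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if q == 1.0:
        thr = values[defined].min() if tail == "upper" else values[defined].max()
        return float(thr), defined.copy()
    vals = values[defined]
    if tail == "upper":
        thr = np.quantile(vals, 1.0 - q)
        flags = defined & (values > thr)
    else:
        thr = np.quantile(vals, q)
        flags = defined & (values < thr)
    return float(thr), flags


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    metrics: tuple
    peaks: dict = field(default_factory=dict)


def _flagged_regions(
    table: pd.DataFrame, flags: np.ndarray, merge_gap: int
) -> dict[str, np.ndarray]:
    """Merge flagged windows into per-chromosome interval arrays."""
    out: dict[str, list] = {}
    sub = table.loc[flags, ["chrom", "start", "end"]]
    for chrom, grp in sub.groupby("chrom", sort=False):
        out[chrom] = merge_intervals(grp[["start", "end"]].to_numpy(), gap=merge_gap)
    return {c: np.asarray(v) for c, v in out.items()}


def merge_close_snps(positions: np.ndarray, max_gap: int = 100) -> np.ndarray:
    """Merge flagged SNP positions closer than ``max_gap`` bp into intervals.

    Used for XP-EHH SNP-level flags in the overlap-analysis mode; returns
    0-based half-open intervals, each SNP contributing a 1-bp interval
    before merging.
    """
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    if pos.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.column_stack([pos - 1, pos])
    return merge_intervals(iv, gap=max_gap)


def call_candidates(
    window_table: pd.DataFrame,
    metrics: dict[str, str] | None = None,
    q: float = 0.01,
    merge_gap: int = 0,
) -> pd.DataFrame:
    """Candidate sweep regions supported by >= 2 metric tails.

    ``metrics`` maps a column of ``window_table`` to its relevant tail,
    default ``{"fst": "upper", "pi_ratio": "lower", "mean_xpehh": "upper"}``
    for a query-side (pony) sweep scan.  Per metric, flagged windows are
    merged (adjacent or within ``merge_gap``); candidates are the maximal
    intervals covered by at least two metric region-sets.  Output columns:
    chrom, start, end, n_metrics, metrics (comma list), and one peak value
    per metric over the candidate's windows.
    """
    if metrics is None:
        metrics = {"fst": "upper", "pi_ratio": "lower", "mean_xpehh": "upper"}
    region_sets: dict[str, dict[str, np.ndarray]] = {}
    for col, tail in metrics.items():
        vals = window_table[col].to_numpy(dtype=float)
        try:
            _, flags = quantile_cut(vals, q=q, tail=tail)
        except ValueError:
            continue  # metric entirely undefined
        region_sets[col] = _flagged_regions(window_table, flags, merge_gap)
    rows = []
    chroms = pd.unique(window_table["chrom"])
    for chrom in chroms:
        # sweep-line over region boundaries, counting metric coverage
        events = []
        for col, regs in region_sets.items():
            for s, e in regs.get(chrom, []):
                events.append((s, +1, col))
                events.append((e, -1, col))
        if not events:
            continue
        events.sort(key=lambda t: (t[0], -t[1]))
        open_metrics: dict[str, int] = {}
        cur_start = None
        prev_pos = None
        for pos, delta, col in events:
            covered = [m for m, c in open_metrics.items() if c > 0]
            if cur_start is not None and pos > prev_pos and len(covered) >= 2:
                rows.append((chrom, prev_pos, pos, tuple(sorted(covered))))
            open_metrics[col] = open_metrics.get(col, 0) + delta
            prev_pos = pos
            cur_start = pos
        # merge contiguous pieces with identical support later
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_metrics", "metrics"]
            + [f"peak_{m}" for m in metrics]
        )
    pieces = pd.DataFrame(rows, columns=["chrom", "start", "end", "support"])
    out_rows = []
    for chrom, grp in pieces.groupby("chrom", sort=False):
        iv = merge_intervals(grp[["start", "end"]].to_numpy())
        for s, e in iv:
            inside = grp[(grp["start"] < e) & (grp["end"] > s)]
            support = sorted({m for sup in inside["support"] for m in sup})
            wins = window_table[
                (window_table["chrom"] == chrom)
                & (window_table["start"] < e)
                & (window_table["end"] > s)
            ]
            rec = {
                "chrom": chrom,
                "start": int(s),
                "end": int(e),
                "n_metrics": len(support),
                "metrics": ",".join(support),
            }
            for col, tail in metrics.items():
                v = wins[col].dropna() if col in wins else pd.Series(dtype=float)
                if v.empty:
                    rec[f"peak_{col}"] = np.nan
                else:
                    rec[f"peak_{col}"] = float(v.max() if tail == "upper" else v.min())
            out_rows.append(rec)
    out = pd.DataFrame(out_rows)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def genotype_gradient(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    meta: SampleMeta,
    height_order: list[str],
) -> tuple[pd.DataFrame, bool | None]:
    """Genotype frequencies of a region's SNPs across ordered height groups.

    Returns a table of {0,1,2} genotype frequencies and the mean
    alternate-allele frequency per group, plus a monotonicity flag: True
    when the mean alternate-allele frequency is non-increasing or
    non-decreasing across the ordered groups (None with fewer than two
    non-empty groups).
    """
    pos0 = gm.positions - 1
    in_region = (gm.chroms == chrom) & (pos0 >= start) & (pos0 < end)
    if not in_region.any():
        raise ValueError("region contains no SNPs")
    sub = gm.take_sites(np.flatnonzero(in_region))
    rows = []
    freqs = []
    for group in height_order:
        names = [s for s in meta.samples_in(group, column="height_class") if s in sub.samples]
        if not names:
            continue
        g = sub.take_samples(names)
        d = g.dosages
        called = d != MISSING
        n_calls = called.sum()
        if n_calls == 0:
            continue
        rec = {"height_class": group, "n_samples": len(names)}
        for code in (0, 1, 2):
            rec[f"freq_geno_{code}"] = float((d[called] == code).sum() / n_calls)
        af = np.nanmean(np.where(called, d, np.nan)) / 2.0
        rec["alt_allele_freq"] = float(af)
        rows.append(rec)
        freqs.append(af)
    table = pd.DataFrame(rows)
    if len(freqs) < 2:
        return table, None
    diffs = np.diff(freqs)
    monotone = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    return table, monotone


@dataclass
class OverlapTestResult:
    n11: int
    n12: int
    n21: int
    n22: int
    odds_ratio: float
    fisher_p: float
    null_odds_ratios: np.ndarray | None = None
    empirical_p: float | None = None
    seed: int | None = None


def _as_interval_dict(intervals) -> dict[str, np.ndarray]:
    """Normalize (chrom, start, end) rows into merged per-chromosome arrays."""
    if isinstance(intervals, dict):
        return {c: merge_intervals(np.asarray(v)) for c, v in intervals.items()}
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    return {
        c: merge_intervals(g[["start", "end"]].to_numpy())
        for c, g in df.groupby("chrom", sort=False)
    }


def _count_overlaps(a: dict, b: dict) -> int:
    """Number of A-intervals overlapping at least one B-interval."""
    n = 0
    for chrom, iva in a.items():
        ivb = b.get(chrom)
        if ivb is None or len(ivb) == 0:
            continue
        starts, ends = ivb[:, 0], ivb[:, 1]
        for s, e in iva:
            j = np.searchsorted(starts, e, side="left")
            if j > 0 and np.any(ends[:j] > s):
                n += 1
    return n


def interval_fisher(set_a, set_b, genome_lengths: dict[str, int]) -> OverlapTestResult:
    """Interval-wise Fisher exact test of overlap between two interval sets.

    Each set is merged internally first.  n11 = A-intervals hitting >= 1
    B-interval; n12 = the rest of A; n21 = B-intervals hitting no
    A-interval; n22 estimates the remaining genomic "slots":
    round(L / (mean_len_A + mean_len_B)) - n11 - n12 - n21, floored at 0,
    with L the total genome length.  Odds ratio uses the Haldane 0.5
    correction when the table has a zero cell; p is two-sided.
    """
    a = _as_interval_dict(set_a)
    b = _as_interval_dict(set_b)
    na = sum(len(v) for v in a.values())
    nb = sum(len(v) for v in b.values())
    if na == 0 or nb == 0:
        raise ValueError("empty interval set")
    n11 = _count_overlaps(a, b)
    n12 = na - n11
    n21 = nb - _count_overlaps(b, a)
    L = sum(genome_lengths.values())
    mean_a = sum((v[:, 1] - v[:, 0]).sum() for v in a.values()) / na
    mean_b = sum((v[:, 1] - v[:, 0]).sum() for v in b.values()) / nb
    n22 = max(0, int(round(L / (mean_a + mean_b))) - n11 - n12 - n21)
    table = np.array([[n11, n12], [n21, n22]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        oddsr = ((n11 + 0.5) * (n22 + 0.5)) / ((n12 + 0.5) * (n21 + 0.5))
    else:
        oddsr = (n11 * n22) / (n12 * n21)
    return OverlapTestResult(n11, n12, n21, n22, float(oddsr), float(p))


def _shuffle_intervals(
    intervals: dict[str, np.ndarray],
    genome_lengths: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Re-place intervals uniformly at random, preserving each interval's
    length and chromosome, without overlap among the placed intervals."""
    out = {}
    for chrom, iv in intervals.items():
        L = genome_lengths[chrom]
        lengths = (iv[:, 1] - iv[:, 0]).astype(np.int64)
        free = L - lengths.sum()
        if free < 0:
            raise ValueError(f"intervals do not fit on chromosome {chrom}")
        lengths = rng.permutation(lengths)
        cuts = np.sort(rng.integers(0, free + 1, size=len(lengths)))
        starts = cuts + np.concatenate([[0], np.cumsum(lengths[:-1])])
        out[chrom] = np.column_stack([starts, starts + lengths])
    return out


def shuffle_overlap_null(
    set_a,
    set_b,
    genome_lengths: dict[str, int],
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> OverlapTestResult:
    """Permutation null for the interval-overlap odds ratio.

    Set A is re-placed uniformly at random ``n_shuffles`` times (lengths and
    chromosome assignments preserved, placements non-overlapping); the
    Fisher odds ratio is recomputed per replicate.  The empirical p-value is
    (1 + #{null OR >= observed OR}) / (n_shuffles + 1) -- never literal 0.
    """
    a = _as_interval_dict(set_a)
    b = _as_interval_dict(set_b)
    observed = interval_fisher(a, b, genome_lengths)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = _shuffle_intervals(a, genome_lengths, rng)
        null[k] = interval_fisher(shuffled, b, genome_lengths).odds_ratio
    emp_p = (1 + int((null >= observed.odds_ratio).sum())) / (n_shuffles + 1)
    observed.null_odds_ratios = null
    observed.empirical_p = float(emp_p)
    observed.seed = seed
    return observed
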