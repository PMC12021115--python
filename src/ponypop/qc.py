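"""Variant- and sample-level quality control.

Implements the standard resequencing QC ladder: GATK-style hard filters on
INFO annotations, sample/variant missingness and MAF thresholds,
Hardy-Weinberg exact testing, sliding-window LD pruning, and GRM-based
kinship exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


@dataclass
class HardFilterThresholds:
    """Clause thresholds of the hard-filter OR expression.

    A site fails if any of: QD < qd_min, MQ < mq_min, FS > fs_max,
    SOR > sor_max, MQRankSum < mqranksum_min, ReadPosRankSum <
    readposranksum_min, QUAL < qual_min.  Defaults are the conventional
    GATK germline SNP values.
    """

    qd_min: float = 2.0
    mq_min: float = 50.0
    fs_max: float = 60.0
    sor_max: float = 3.0
    mqranksum_min: float = -5.0
    readposranksum_min: float = -5.0
    qual_min: float = 30.0


@dataclass
class QCThresholds:
    """Genotype-level filtering thresholds.

    Rates and MAF are fractions in [0,1].  The per-sample missingness
    default 0.0008 transcribes the source protocol's ">0.08%" literally;
    it is likely intended as 8% and is configurable.
    """

    max_sample_missing_rate: float = 0.0008
    max_variant_missing_rate: float = 0.02
    min_maf: float = 0.01
    hwe_p_min: float = 1e-6
    prune_window: int = 50
    prune_step: int = 5
    prune_r2_max: float = 0.5

    def __post_init__(self) -> None:
        for name in ("max_sample_missing_rate", "max_variant_missing_rate", "min_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if not (self.prune_window >= self.prune_step >= 1):
            raise ValueError("require prune_window >= prune_step >= 1")


_CLAUSES = (
    ("QD", "QD", "lt", "qd_min"),
    ("MQ", "MQ", "lt", "mq_min"),
    ("FS", "FS", "gt", "fs_max"),
    ("SOR", "SOR", "gt", "sor_max"),
    ("MQRankSum", "MQRankSum", "lt", "mqranksum_min"),
    ("ReadPosRankSum", "ReadPosRankSum", "lt", "readposranksum_min"),
    ("QUAL", "qual", "lt", "qual_min"),
)


def apply_hard_filters(
    variants: pd.DataFrame, t: HardFilterThresholds | None = None
) -> pd.DataFrame:
    """Evaluate the hard-filter OR expression per site.

    Returns a frame aligned with ``variants`` carrying ``pass_`` (bool),
    ``reasons`` (comma-joined failed clauses), ``not_evaluated``
    (clauses whose annotation was absent) and ``errors`` (clauses whose
    annotation was non-numeric; such clauses do not trigger, the site is
    reported and the run continues).  Absent annotations never trigger
    their clause; all inequalities are strict.
    """
    t = t or HardFilterThresholds()
    n = len(variants)
    reasons = [[] for _ in range(n)]
    skipped = [[] for _ in range(n)]
    errors = [[] for _ in range(n)]
    for clause, col, op, attr in _CLAUSES:
        thr = getattr(t, attr)
        if col not in variants.columns:
            for lst in skipped:
                lst.append(clause)
            continue
        vals = variants[col]
        num = pd.to_numeric(vals, errors="coerce")
        bad = num.isna() & vals.notna()
        absent = vals.isna() if vals.dtype != object else num.isna() & ~bad
        trig = (num < thr) if op == "lt" else (num > thr)
        trig = trig.fillna(False).to_numpy()
        bad = bad.to_numpy()
        absent = num.isna().to_numpy() & ~bad
        for j in np.flatnonzero(trig):
            reasons[j].append(clause)
        for j in np.flatnonzero(absent):
            skipped[j].append(clause)
        for j in np.flatnonzero(bad):
            errors[j].append(clause)
    return pd.DataFrame(
        {
            "pass_": [not r for r in reasons],
            "reasons": [",".join(r) for r in reasons],
            "not_evaluated": [",".join(s) for s in skipped],
            "errors": [",".join(e) for e in errors],
        },
        index=variants.index,
    )


def missingness_maf_filter(
    gm: GenotypeMatrix, t: QCThresholds | None = None
) -> tuple[GenotypeMatrix, dict]:
    """Remove high-missingness samples, then high-missingness sites, then
    low-MAF sites (MAF recomputed on the retained samples).

    Order is fixed: sample filter first, site filters on the reduced
    matrix.  Raises if every sample is removed.
    """
    t = t or QCThresholds()
    d = gm.dosages
    miss = d == MISSING
    sample_rate = miss.mean(axis=1) if gm.n_sites else np.zeros(gm.n_samples)
    keep_samples = sample_rate <= t.max_sample_missing_rate
    if not keep_samples.any():
        raise ValueError("all samples removed by missingness filter")
    gm2 = gm.take_samples([s for s, k in zip(gm.samples, keep_samples) if k])

    miss2 = gm2.dosages == MISSING
    site_rate = miss2.mean(axis=0)
    keep_sites = site_rate <= t.max_variant_missing_rate
    af = gm2.allele_frequency()
    maf = np.minimum(af, 1.0 - af)
    keep_sites &= ~np.isnan(maf) & (maf >= t.min_maf)
    out = gm2.take_sites(np.flatnonzero(keep_sites))
    report = {
        "n_samples_in": gm.n_samples,
        "n_samples_removed": int((~keep_samples).sum()),
        "n_sites_in": gm.n_sites,
        "n_sites_missingness_removed": int((site_rate > t.max_variant_missing_rate).sum()),
        "n_sites_maf_removed": int(
            ((site_rate <= t.max_variant_missing_rate) & ~(
                ~np.isnan(maf) & (maf >= t.min_maf))).sum()
        ),
        "n_sites_out": out.n_sites,
    }
    return out, report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on the heterozygote count.

    Conditions on the allele counts: p-value is the summed probability of
    every heterozygote count (same parity, same allele totals) whose
    conditional probability does not exceed the observed one.  Monomorphic
    samples return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty sample")
    n_a = 2 * n_aa + n_Aa  # minor allele copies (relabel below)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    # unnormalized probabilities over het counts with the parity of `rare`;
    # P(h+2)/P(h) = 4 * hom_rare(h) * hom_common(h) / ((h+2)(h+1))
    het_max = rare
    common = 2 * n - rare
    probs = {}
    h = rare % 2
    p = 1.0
    probs[h] = p
    while h + 2 <= het_max:
        hom_r = (rare - h) // 2
        hom_c = (common - h) // 2
        p = p * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
        probs[h] = p
        if p > 1e280:  # rescale to avoid overflow; relative values only
            for k in probs:
                probs[k] /= p
            p = probs[h]
    total = sum(probs.values())
    obs = probs[n_Aa] if n_Aa in probs else 0.0
    if n_Aa not in probs:
        raise ValueError("heterozygote count inconsistent with allele totals")
    pval = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, pval)


def hwe_filter(gm: GenotypeMatrix, p_min: float = 1e-6) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop sites whose HWE exact p-value is below ``p_min``."""
    d = gm.dosages
    keep = np.ones(gm.n_sites, dtype=bool)
    for j in range(gm.n_sites):
        col = d[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        p = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        keep[j] = p >= p_min
    return gm.take_sites(np.flatnonzero(keep)), keep


def _dosage_r2(d: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages over samples called at both sites."""
    a, b = d[:, i], d[:, j]
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.5
) -> np.ndarray:
    """Sliding-window LD pruning; returns retained site indices.

    Within each window of ``window`` SNPs (advanced by ``step``), while any
    retained pair has r^2 > ``r2_max`` the pair with the highest r^2 is
    resolved by removing its lower-MAF member (tie: the later position).
    Windows are per chromosome; the procedure is deterministic.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    d = gm.dosages
    af = gm.allele_frequency()
    maf = np.minimum(af, 1.0 - af)
    keep = np.ones(gm.n_sites, dtype=bool)
    chroms = gm.chroms
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, max(len(idx) - 1, 1), step):
            win = idx[start : start + window]
            if len(win) < 2:
                continue
            active = [j for j in win if keep[j]]
            while True:
                best = None
                for x in range(len(active)):
                    for y in range(x + 1, len(active)):
                        r2 = _dosage_r2(d, active[x], active[y])
                        if r2 > r2_max and (best is None or r2 > best[0]):
                            best = (r2, active[x], active[y])
                if best is None:
                    break
                _, i, j = best
                if maf[i] < maf[j]:
                    drop = i
                elif maf[j] < maf[i]:
                    drop = j
                else:
                    drop = j  # tie: later position removed
                keep[drop] = False
                active.remove(drop)
            if start + window >= len(idx):
                break
    return np.flatnonzero(keep)


def grm_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """VanRaden-style genomic relationship matrix.

    g_jk = mean over sites (non-missing in both samples) of
    (x_j - 2p)(x_k - 2p) / (2p(1-p)), with p the sample allele frequency.
    Monomorphic sites are excluded.  Pairs with no shared sites get NaN.
    """
    d = gm.dosages.astype(float)
    called = gm.dosages != MISSING
    p = gm.allele_frequency()
    usable = ~np.isnan(p) & (p > 0) & (p < 1)
    d = d[:, usable]
    called = called[:, usable]
    p = p[usable]
    z = np.where(called, (d - 2 * p) / np.sqrt(2 * p * (1 - p)), 0.0)
    num = z @ z.T
    m = called.astype(float) @ called.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(m > 0, num / m, np.nan)


def grm_kinship_filter(
    gm: GenotypeMatrix, max_grm: float = 0.3
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy relatedness exclusion.

    While any off-diagonal GRM entry among retained samples exceeds
    ``max_grm``, the retained sample with the highest mean relatedness to
    all other retained samples (among those in a flagged pair) is removed.
    Returns (retained sample names, flagged pairs with their GRM values).
    """
    grm = grm_matrix(gm)
    n = gm.n_samples
    active = list(range(n))
    flagged_pairs = [
        (gm.samples[i], gm.samples[j], float(grm[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if not np.isnan(grm[i, j]) and grm[i, j] > max_grm
    ]
    while True:
        pairs = [
            (i, j)
            for ai, i in enumerate(active)
            for j in active[ai + 1 :]
            if not np.isnan(grm[i, j]) and grm[i, j] > max_grm
        ]
        if not pairs:
            break
        involved = sorted({k for p in pairs for k in p})
        mean_rel = {}
        for k in involved:
            others = [o for o in active if o != k and not np.isnan(grm[k, o])]
            mean_rel[k] = np.mean([grm[k, o] for o in others]) if others else -np.inf
        # remove the most-related; tie -> larger index
        drop = max(involved, key=lambda k: (mean_rel[k], k))
        active.remove(drop)
    return [gm.samples[i] for i in active], flagged_pairs
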