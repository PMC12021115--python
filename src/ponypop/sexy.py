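"""Genomic sex assignment, Y-chromosome haplotypes, and depth-based
gene-presence scoring.

Sex is called from sequencing-depth summaries: the primary signal is the
covered fraction of the Y chromosome (males exceed ~94%); the
corroborating indices are Rx (X per-bp rate over the mean autosomal rate;
~0.5 in males, ~1 in females) and Ry (Y reads over X+Y reads).  Disagreement
between primary and corroborating rules yields an explicit "ambiguous"
call rather than a forced sex.  The Y side filters the male-specific
region to hemizygous-consistent sites and counts distinct haplotypes; the
phylogeny side provides the p-distance matrix and a neighbor-joining tree
rooted on a named outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


@dataclass
class SexThresholds:
    """Decision thresholds for genomic sex calling.

    ``cov_y_male``: minimum Y covered fraction for the primary male rule.
    Ry bands follow the index's source convention (>= 0.075 male-consistent,
    <= 0.016 female-consistent); Rx bands are generous around the expected
    0.5 (male) and 1.0 (female).
    """

    cov_y_male: float = 0.94
    ry_male: float = 0.075
    ry_female: float = 0.016
    rx_male_max: float = 0.65
    rx_female_min: float = 0.85


def sex_indices(depth: pd.DataFrame, autosomes: list[str] | None = None) -> pd.DataFrame:
    """Per-sample depth indices from a (chrom, sample, total_reads,
    covered_bp, chrom_len) table.

    Returns covY (covered fraction of Y), X/Chr1 and Y/Chr1 per-bp depth
    ratios, Rx (X rate over mean autosomal rate) and Ry
    (reads_Y / (reads_X + reads_Y)).  All indices are invariant to a global
    rescaling of read counts.
    """
    need = {"chrom", "sample", "total_reads", "covered_bp", "chrom_len"}
    if not need <= set(depth.columns):
        raise ValueError(f"depth table must have columns {sorted(need)}")
    rows = []
    for sample, sub in depth.groupby("sample", sort=False):
        sub = sub.set_index("chrom")
        for c in ("1", "X", "Y"):
            if c not in sub.index:
                raise ValueError(f"sample {sample}: chromosome {c!r} missing from depth table")
        if autosomes is None:
            auto = [c for c in sub.index if c not in ("X", "Y")]
        else:
            auto = autosomes
        rate = sub["total_reads"] / sub["chrom_len"]
        auto_rate = rate.loc[auto].mean()
        if auto_rate <= 0:
            raise ValueError(f"sample {sample}: zero autosomal reads")
        reads_x = sub.loc["X", "total_reads"]
        reads_y = sub.loc["Y", "total_reads"]
        xy = reads_x + reads_y
        rows.append(
            {
                "sample": sample,
                "cov_y": sub.loc["Y", "covered_bp"] / sub.loc["Y", "chrom_len"],
                "x_over_chr1": rate.loc["X"] / rate.loc["1"],
                "y_over_chr1": rate.loc["Y"] / rate.loc["1"],
                "rx": rate.loc["X"] / auto_rate,
                "ry": reads_y / xy if xy > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def call_sex(
    indices: pd.DataFrame,
    thresholds: SexThresholds | None = None,
    recorded_sex: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Sex calls with rationale from depth indices.

    Primary rule: covY > threshold => male.  The Rx/Ry secondary rules must
    corroborate; any disagreement gives "ambiguous" with both rules named.
    When ``recorded_sex`` is given, a ``mismatch`` column reports calls that
    contradict the recorded value.
    """
    t = thresholds or SexThresholds()
    rows = []
    for _, r in indices.iterrows():
        primary_male = r["cov_y"] > t.cov_y_male
        ry_vote = (
            "male" if r["ry"] >= t.ry_male else "female" if r["ry"] <= t.ry_female else "unclear"
        )
        rx_vote = (
            "male" if r["rx"] <= t.rx_male_max
            else "female" if r["rx"] >= t.rx_female_min
            else "unclear"
        )
        if primary_male:
            if "female" in (ry_vote, rx_vote):
                call = "ambiguous"
                why = (
                    f"covY={r['cov_y']:.3f}>{t.cov_y_male} says male but "
                    f"Ry vote={ry_vote}, Rx vote={rx_vote}"
                )
            else:
                call = "male"
                why = f"covY={r['cov_y']:.3f}>{t.cov_y_male}; Ry/Rx consistent"
        else:
            if ry_vote == "female" and rx_vote == "female":
                call = "female"
                why = f"covY={r['cov_y']:.3f}<=threshold; Ry and Rx female-consistent"
            elif "male" in (ry_vote, rx_vote):
                call = "ambiguous"
                why = (
                    f"covY={r['cov_y']:.3f} below male threshold but "
                    f"Ry vote={ry_vote}, Rx vote={rx_vote}"
                )
            else:
                call = "ambiguous"
                why = f"no rule decisive (covY={r['cov_y']:.3f}, Ry={r['ry']:.4f}, Rx={r['rx']:.3f})"
        rec = dict(r)
        rec.update({"call": call, "rationale": why})
        if recorded_sex is not None:
            recorded = recorded_sex.get(r["sample"])
            rec["recorded_sex"] = recorded
            rec["mismatch"] = bool(
                recorded is not None and call in ("male", "female") and call != recorded
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def msy_filter(
    gm: GenotypeMatrix,
    males: list[str],
    max_variant_missing: float = 0.02,
    min_maf: float = 0.005,
    max_sample_missing: float = 0.0008,
    haplotype_mode: bool = True,
) -> tuple[GenotypeMatrix, dict]:
    """Filter Y-chromosome genotypes of male samples for haplotype analysis.

    Stages, each recorded in the attrition report: (1) restrict to males;
    drop every site with a heterozygous call in any male (hemizygous truth
    makes diploid hets genotyping errors); (2) drop males whose missing
    rate exceeds ``max_sample_missing``; (3) drop sites with missing rate
    above ``max_variant_missing``; (4) drop sites with MAF below
    ``min_maf``; (5) in haplotype mode, drop any site with a remaining
    missing call.  Raises if no site survives.
    """
    sub = gm.take_samples(males)
    report = {"n_sites_in": sub.n_sites, "n_males": len(males)}
    het_any = (sub.dosages == 1).any(axis=0)
    sub = sub.take_sites(np.flatnonzero(~het_any))
    report["n_sites_after_het_drop"] = sub.n_sites

    miss = sub.dosages == MISSING
    sample_rate = miss.mean(axis=1) if sub.n_sites else np.zeros(sub.n_samples)
    keep_samples = [s for s, r in zip(sub.samples, sample_rate) if r <= max_sample_missing]
    sub = sub.take_samples(keep_samples)
    report["n_males_retained"] = sub.n_samples

    site_rate = (sub.dosages == MISSING).mean(axis=0)
    sub = sub.take_sites(np.flatnonzero(site_rate <= max_variant_missing))
    report["n_sites_after_missingness"] = sub.n_sites

    af = sub.allele_frequency()
    maf = np.minimum(af, 1 - af)
    sub = sub.take_sites(np.flatnonzero(~np.isnan(maf) & (maf >= min_maf)))
    report["n_sites_after_maf"] = sub.n_sites

    if haplotype_mode:
        any_missing = (sub.dosages == MISSING).any(axis=0)
        sub = sub.take_sites(np.flatnonzero(~any_missing))
        report["n_sites_complete_case"] = sub.n_sites
    if sub.n_sites == 0:
        raise ValueError(f"no Y sites survive filtering; attrition: {report}")
    return sub, report


def count_haplotypes(matrix: np.ndarray, samples: list[str] | None = None):
    """Distinct haplotypes among complete-case allele vectors.

    ``matrix`` is (samples x sites) with no missing values; the haplotype
    of a sample is its full allele vector.  Returns (count, membership)
    where membership maps sample -> haplotype index (indices ordered by
    first occurrence).  The count is invariant to sample order and to
    duplicated samples.
    """
    m = np.asarray(matrix)
    if (m == MISSING).any():
        raise ValueError("haplotype counting requires complete-case data")
    if samples is None:
        samples = [f"S{i}" for i in range(m.shape[0])]
    seen: dict[bytes, int] = {}
    membership = {}
    for name, row in zip(samples, m):
        key = row.tobytes()
        if key not in seen:
            seen[key] = len(seen)
        membership[name] = seen[key]
    return len(seen), membership


def p_distance_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise genotype p-distance.

    Per shared (both-called) site: identical genotypes 0, one shared allele
    (hom vs het) 0.5, opposite homozygotes 1.0; the distance is the mean
    over shared sites.  Pairs with no shared site get NaN.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    d = gm.dosages.astype(float)
    called = gm.dosages != MISSING
    n = gm.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = called[i] & called[j]
            if not ok.any():
                out[i, j] = out[j, i] = np.nan
                continue
            diff = np.abs(d[i, ok] - d[j, ok]) / 2.0
            out[i, j] = out[j, i] = diff.mean()
    return pd.DataFrame(out, index=gm.samples, columns=gm.samples)


def nj_tree(dist: pd.DataFrame, outgroup: str) -> str:
    """Neighbor-joining tree (Saitou-Nei) rooted on the outgroup taxon.

    Standard Q-criterion with a deterministic tie-break (lowest index
    pair); the root splits the outgroup's pendant branch at its midpoint.
    Returns a Newick string with branch lengths.
    """
    taxa = list(dist.index)
    if outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    D = dist.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T, equal_nan=False):
        raise ValueError("distance matrix must be symmetric")
    # Unrooted tree as an undirected graph: node ids 0..n_taxa-1 are leaves.
    names = {i: t for i, t in enumerate(taxa)}
    adj: dict[int, dict[int, float]] = {i: {} for i in range(len(taxa))}
    active = list(range(len(taxa)))
    next_id = len(taxa)
    while len(active) > 2:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), n)  # ties: lowest flat index
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        gi, gj = active[i], active[j]
        u = next_id
        next_id += 1
        adj[u] = {}
        adj[u][gi] = adj.setdefault(gi, {})[u] = li
        adj[gj][u] = adj[u][gj] = lj
        newD = 0.5 * (D[gi, :] + D[gj, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newD)] = newD
        D[: len(newD), -1] = newD
        D[-1, -1] = 0.0
        active = [g for g in active if g not in (gi, gj)] + [u]
    gi, gj = active
    adj[gi][gj] = adj[gj][gi] = max(D[gi, gj] if len(taxa) > 2 else D[0, 1], 0.0)

    # Root on the outgroup's pendant edge, midpoint.
    og = taxa.index(outgroup)
    (nbr, bl), = adj[og].items()
    half = bl / 2.0

    def subtree(node: int, parent: int) -> str:
        kids = [(k, l) for k, l in adj[node].items() if k != parent]
        if not kids:
            return names[node]
        inner = ",".join(f"{subtree(k, node)}:{l:.12g}" for k, l in kids)
        return f"({inner})"

    return f"({names[og]}:{half:.12g},{subtree(nbr, og)}:{half:.12g});"


def relative_depth(
    gene_depth: pd.DataFrame, single_copy: list[str]
) -> pd.DataFrame:
    """Per-gene depth relative to the mean per-bp depth of single-copy genes.

    ``gene_depth`` has columns (gene, total_reads, length_bp).  A score
    near 0 supports gene absence; near 1, single-copy presence.
    """
    t = gene_depth.set_index("gene")
    rate = t["total_reads"] / t["length_bp"]
    sc = [g for g in single_copy if g in rate.index]
    if not sc:
        raise ValueError("no single-copy genes present")
    baseline = rate.loc[sc].mean()
    if baseline <= 0:
        raise ValueError("zero depth on single-copy genes")
    return pd.DataFrame(
        {"gene": rate.index, "relative_depth": (rate / baseline).to_numpy()}
    ).reset_index(drop=True)
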