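"""Synthetic multi-breed cohorts with known ground truth.

Population allele frequencies evolve down an explicit admixture graph under
the Balding-Nichols model: a drift edge with parameter ``F`` draws the child
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), i.e. mean p and variance
F*p*(1-p); an admixture event mixes two parent frequencies linearly.  This
gives closed-form expectations for f-statistics and FST, so downstream
estimators can be validated analytically rather than against another
simulator.  Genotypes are then binomial draws per population, selective
sweeps are implanted by copying one core haplotype into a chosen fraction of
a population's haplotypes, and sequencing-depth tables with sex-specific
X/Y profiles are generated for the sex-assignment module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, SampleMeta


@dataclass
class AdmixtureGraphSpec:
    """Acyclic admixture graph over labelled populations.

    ``edges`` are (parent, child, F) drift edges with F in [0, 1);
    ``admixtures`` are (child, parent_a, parent_b, alpha) events giving the
    child frequency alpha*p_a + (1-alpha)*p_b.  The ancestral (root)
    frequency of each site is drawn uniformly on [anc_low, anc_high].
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    admixtures: list[tuple[str, str, str, float]] = field(default_factory=list)
    anc_low: float = 0.05
    anc_high: float = 0.95
    n_sites: int = 10_000
    seed: int = 0

    def parents(self) -> dict[str, object]:
        par: dict[str, object] = {}
        for p, c, f in self.edges:
            if c in par:
                raise ValueError(f"node {c!r} has multiple incoming events")
            par[c] = ("drift", p, float(f))
        for c, a, b, alpha in self.admixtures:
            if c in par:
                raise ValueError(f"node {c!r} has multiple incoming events")
            par[c] = ("admix", a, b, float(alpha))
        return par

    def validate(self) -> str:
        par = self.parents()
        known = set(self.nodes)
        for c, ev in par.items():
            if c not in known:
                raise ValueError(f"edge child {c!r} not in nodes")
            for up in ev[1:-1]:
                if up not in known:
                    raise ValueError(f"edge parent {up!r} not in nodes")
        roots = [n for n in self.nodes if n not in par]
        if len(roots) != 1:
            raise ValueError(f"graph must have exactly one root, got {roots}")
        for _, _, f in self.edges:
            if not (0.0 <= f < 1.0):
                raise ValueError(f"drift parameter must be in [0,1), got {f}")
        for _, _, _, a in self.admixtures:
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"admixture weight must be in [0,1], got {a}")
        # cycle check via iterative resolution
        resolved = {roots[0]}
        pending = set(par)
        while pending:
            ready = {
                c
                for c in pending
                if all(u in resolved for u in par[c][1:-1])
            }
            if not ready:
                raise ValueError("admixture graph contains a cycle")
            resolved |= ready
            pending -= ready
        return roots[0]


@dataclass
class SweepSpec:
    """Selective sweep implanted into one population's phased haplotypes."""

    population: str
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    carrier_frequency: float = 0.9
    seed: int = 0

    def validate(self, chrom_length: int | None = None) -> None:
        if not (0.0 < self.carrier_frequency <= 1.0):
            raise ValueError("carrier frequency must be in (0,1]")
        if self.end <= self.start or self.start < 0:
            raise ValueError("invalid sweep interval")
        if chrom_length is not None and self.end > chrom_length:
            raise ValueError("sweep interval outside simulated coordinates")


@dataclass
class DepthProfileSpec:
    """Per-individual sequencing-depth profile.

    ``mean_depth`` is the autosomal per-bp read rate.  Males get X and Y at
    half the autosomal rate; females get X at the autosomal rate and Y at
    ``residual_y`` times it (mismapping background).  ``overdispersion`` is
    the coefficient of variation of a per-chromosome gamma multiplier.
    """

    sex: str  # "male" | "female"
    mean_depth: float = 10.0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 2_000_000, "2": 2_000_000, "X": 1_200_000, "Y": 120_000}
    )
    overdispersion: float = 0.05
    residual_y: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")


def simulate_graph_frequencies(spec: AdmixtureGraphSpec) -> pd.DataFrame:
    """Per-population allele-frequency table (n_sites x nodes).

    Frequencies are clipped to [0,1]; sites fixed in every population are
    retained (downstream filters deal with them).
    """
    root = spec.validate()
    rng = np.random.default_rng(spec.seed)
    freqs: dict[str, np.ndarray] = {
        root: rng.uniform(spec.anc_low, spec.anc_high, spec.n_sites)
    }
    par = spec.parents()
    pending = set(par)
    while pending:
        ready = [c for c in pending if all(u in freqs for u in par[c][1:-1])]
        for child in sorted(ready):  # sorted: draw order independent of set order
            ev = par[child]
            if ev[0] == "drift":
                _, parent, f = ev
                p = freqs[parent]
                if f == 0.0:
                    q = p.copy()
                else:
                    scale = (1.0 - f) / f
                    with np.errstate(invalid="ignore"):
                        q = rng.beta(np.maximum(p * scale, 1e-12),
                                     np.maximum((1.0 - p) * scale, 1e-12))
                    # Beta is undefined at fixed parents; fixation is absorbing
                    q = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, q))
            else:
                _, pa, pb, alpha = ev
                q = alpha * freqs[pa] + (1.0 - alpha) * freqs[pb]
            freqs[child] = np.clip(q, 0.0, 1.0)
            pending.discard(child)
    return pd.DataFrame({n: freqs[n] for n in spec.nodes})


# distributions of VCF INFO annotations for sites that should pass / fail the
# GATK-style hard filter; fail sites violate one randomly chosen clause
_PASS_INFO = {
    "QD": (20.0, 6.0, 2.5, None),  # mean, sd, lower clip, upper clip
    "MQ": (60.0, 2.0, 51.0, None),
    "FS": (5.0, 3.0, 0.0, 55.0),
    "SOR": (1.2, 0.5, 0.0, 2.8),
    "MQRankSum": (0.0, 1.0, -4.0, 4.0),
    "ReadPosRankSum": (0.0, 1.0, -4.0, 4.0),
    "QUAL": (600.0, 200.0, 40.0, None),
}
_FAIL_DRAW = {
    "QD": lambda rng, n: rng.uniform(0.0, 1.9, n),
    "MQ": lambda rng, n: rng.uniform(20.0, 49.0, n),
    "FS": lambda rng, n: rng.uniform(61.0, 120.0, n),
    "SOR": lambda rng, n: rng.uniform(3.1, 6.0, n),
    "MQRankSum": lambda rng, n: rng.uniform(-9.0, -5.1, n),
    "ReadPosRankSum": lambda rng, n: rng.uniform(-9.0, -5.1, n),
    "QUAL": lambda rng, n: rng.uniform(1.0, 29.0, n),
}


def simulate_info_annotations(
    n_sites: int, fail_rate: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """INFO/QUAL values from a pass/fail mixture; ``filter_truth`` column holds
    the planted pass (True) / fail (False) status."""
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for key, (mu, sd, lo, hi) in _PASS_INFO.items():
        v = rng.normal(mu, sd, n_sites)
        v = np.clip(v, lo, hi if hi is not None else np.inf)
        cols[key] = v
    fail = rng.random(n_sites) < fail_rate
    idx = np.flatnonzero(fail)
    if idx.size:
        which = rng.integers(0, len(_FAIL_DRAW), idx.size)
        for k, key in enumerate(_FAIL_DRAW):
            sel = idx[which == k]
            if sel.size:
                cols[key][sel] = _FAIL_DRAW[key](rng, sel.size)
    qual = cols.pop("QUAL")
    out = pd.DataFrame(cols)
    out.insert(0, "qual", qual)
    out["filter_truth"] = ~fail
    return out


def simulate_genotypes(
    freqs: pd.DataFrame,
    n_per_pop: dict[str, int],
    phased: bool = False,
    seed: int = 0,
    chrom: str = "1",
    chrom_length: int | None = None,
    missing_rate: float = 0.0,
    info_fail_rate: float = 0.0,
    pop_attrs: dict[str, dict] | None = None,
) -> tuple[GenotypeMatrix, SampleMeta]:
    """Draw diploid genotypes per population from the frequency table.

    Haplotype alleles are independent Bernoulli draws at each site with the
    population's frequency; the dosage is the sum of the sample's two
    haplotypes.  Site positions are distinct uniform draws on the chromosome
    (default length: 1 kb per site), sorted.  ``pop_attrs`` supplies
    region/height_class/sex/yakutia_adjacent metadata per population.
    """
    for pop, n in n_per_pop.items():
        if n <= 0:
            raise ValueError(f"n_per_pop[{pop!r}] must be positive")
        if pop not in freqs.columns:
            raise ValueError(f"no frequencies for population {pop!r}")
    if ((freqs < 0) | (freqs > 1)).any().any():
        raise ValueError("frequencies must lie in [0,1]")
    rng = np.random.default_rng(seed)
    n_sites = len(freqs)
    if chrom_length is None:
        chrom_length = 1000 * n_sites
    pos = np.sort(rng.choice(chrom_length, size=n_sites, replace=False)) + 1

    haps_all, samples, meta_rows = [], [], []
    for pop in freqs.columns:
        if pop not in n_per_pop:
            continue
        n = n_per_pop[pop]
        p = freqs[pop].to_numpy()
        haps = (rng.random((2 * n, n_sites)) < p).astype(np.int8)
        haps_all.append(haps)
        attrs = (pop_attrs or {}).get(pop, {})
        for i in range(n):
            sid = f"{pop}_{i:03d}"
            samples.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "breed": pop,
                    "region": attrs.get("region", "sim"),
                    "height_class": attrs.get("height_class", "unknown"),
                    "sex": attrs.get("sex", "female"),
                    "yakutia_adjacent": bool(attrs.get("yakutia_adjacent", False)),
                }
            )
    haps = np.vstack(haps_all)
    dos = haps[0::2] + haps[1::2]
    if missing_rate > 0:
        miss = rng.random(dos.shape) < missing_rate
        dos = np.where(miss, MISSING, dos).astype(np.int8)
        if phased:
            hm = np.repeat(miss, 2, axis=0)
            haps = np.where(hm, MISSING, haps).astype(np.int8)

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "ref": "A",
            "alt": "G",
        }
    )
    info = simulate_info_annotations(n_sites, fail_rate=info_fail_rate, seed=seed + 1)
    variants = pd.concat([variants, info], axis=1)
    gm = GenotypeMatrix(dos, samples, variants, haps if phased else None)
    return gm, SampleMeta(pd.DataFrame(meta_rows))


def implant_sweep(
    gm: GenotypeMatrix, meta: SampleMeta, spec: SweepSpec, chrom_length: int | None = None
) -> GenotypeMatrix:
    """Copy one core haplotype into ``carrier_frequency`` of the target
    population's haplotypes across the sweep interval.

    Produces the three signals the scan intersects: reduced diversity in the
    target, elevated FST against other populations, and extended haplotype
    homozygosity around the interval centre.  Non-target samples are
    untouched.
    """
    if gm.haplotypes is None:
        raise ValueError("sweep implantation requires phased haplotypes")
    spec.validate(chrom_length)
    pos0 = gm.positions - 1  # 0-based
    in_iv = (gm.chroms == spec.chrom) & (pos0 >= spec.start) & (pos0 < spec.end)
    if not in_iv.any():
        raise ValueError("sweep interval contains no simulated sites")
    target = meta.samples_in(spec.population)
    rows = [gm.samples.index(s) for s in target]
    hap_rows = np.sort(np.concatenate([[2 * r, 2 * r + 1] for r in rows]))
    rng = np.random.default_rng(spec.seed)
    n_carriers = int(round(spec.carrier_frequency * len(hap_rows)))
    carriers = rng.choice(hap_rows, size=n_carriers, replace=False)

    haps = gm.haplotypes.copy()
    core = haps[hap_rows[0], in_iv].copy()  # core haplotype = first target haplotype
    haps[np.ix_(carriers, np.flatnonzero(in_iv))] = core
    dos = gm.dosages.copy()
    # re-derive dosages for target samples where calls are present
    for r in rows:
        pair = haps[2 * r, in_iv] + haps[2 * r + 1, in_iv]
        old = dos[r, in_iv]
        dos[r, np.flatnonzero(in_iv)] = np.where(old == MISSING, MISSING, pair)
    return GenotypeMatrix(dos, list(gm.samples), gm.variants.copy(), haps)


def default_sweep_fixture(
    seed: int,
    n_sites: int = 2000,
    chrom_length: int = 2_000_000,
    drift: float = 0.05,
    sweep_start: int = 990_000,
    sweep_end: int = 1_010_000,
    carrier_frequency: float = 0.9,
    n_per_pop: int = 25,
) -> tuple[GenotypeMatrix, SampleMeta, SweepSpec]:
    """The standard two-population sweep scenario used for validation.

    A pony and a horse population each drift F=0.05 from a shared ancestor
    on one 2-Mb chromosome with 2,000 SNPs; a 20-kb sweep at the centre is
    implanted into the pony haplotypes at 90% carrier frequency.  Returns
    (phased genotypes, metadata, the sweep truth spec).
    """
    spec = AdmixtureGraphSpec(
        nodes=["root", "pony", "horse"],
        edges=[("root", "pony", drift), ("root", "horse", drift)],
        n_sites=n_sites,
        seed=seed,
    )
    freqs = simulate_graph_frequencies(spec)
    gm, meta = simulate_genotypes(
        freqs[["pony", "horse"]],
        {"pony": n_per_pop, "horse": n_per_pop},
        phased=True,
        seed=seed + 1000,
        chrom_length=chrom_length,
    )
    sweep = SweepSpec(
        "pony", "1", sweep_start, sweep_end, carrier_frequency, seed=seed + 2000
    )
    gm = implant_sweep(gm, meta, sweep, chrom_length=chrom_length)
    return gm, meta, sweep


def simulate_depth_table(spec: DepthProfileSpec, sample: str = "S0") -> pd.DataFrame:
    """Per-chromosome read counts and covered bp for one individual.

    Reads are Poisson with a gamma-multiplied rate (overdispersion = CV of
    the multiplier); covered bp is binomial with per-bp coverage probability
    1 - exp(-rate) under a Poisson read-start model.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for chrom, length in spec.chrom_lengths.items():
        rate = spec.mean_depth
        if chrom == "X":
            rate *= 0.5 if spec.sex == "male" else 1.0
        elif chrom == "Y":
            rate *= 0.5 if spec.sex == "male" else spec.residual_y
        if spec.overdispersion > 0:
            shape = 1.0 / spec.overdispersion**2
            rate *= rng.gamma(shape, 1.0 / shape)
        reads = rng.poisson(rate * length)
        p_cov = 1.0 - np.exp(-reads / length) if length > 0 else 0.0
        covered = rng.binomial(length, p_cov) if p_cov > 0 else 0
        rows.append(
            {
                "chrom": chrom,
                "sample": sample,
                "total_reads": int(reads),
                "covered_bp": int(covered),
                "chrom_len": int(length),
            }
        )
    return pd.DataFrame(rows)


def simulate_depth_cohort(
    n_males: int,
    n_females: int,
    mean_depth: float = 10.0,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth tables for a mixed-sex cohort; returns (depth table, truth table)."""
    tables, truth = [], []
    k = 0
    for sex, n in (("male", n_males), ("female", n_females)):
        for _ in range(n):
            sid = f"{sex[0].upper()}{k:03d}"
            spec = DepthProfileSpec(
                sex=sex, mean_depth=mean_depth, seed=seed + k, **spec_kwargs
            )
            tables.append(simulate_depth_table(spec, sample=sid))
            truth.append({"sample": sid, "sex": sex})
            k += 1
    return pd.concat(tables, ignore_index=True), pd.DataFrame(truth)
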