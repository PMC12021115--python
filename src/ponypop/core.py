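"""Shared containers and genomic-interval helpers.

Genotypes are held as a dense diploid dosage matrix (samples x sites) with
codes 0/1/2 for the alternate-allele count and -1 for a missing call.  When
phased haplotypes are available they are carried alongside as a
(2*samples x sites) binary matrix; haplotypes 2*i and 2*i+1 belong to
sample i.  Positions are 1-based in the variant table (VCF convention);
windows and BED-style intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: INFO keys consumed by the hard filter, in VCF header order.
INFO_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


@dataclass
class GenotypeMatrix:
    """Diploid genotype dosages with optional phased haplotypes.

    Attributes
    ----------
    dosages : (n_samples, n_sites) int8 array; -1 marks a missing call.
    samples : sample identifiers, row order of ``dosages``.
    variants : per-site table with at least ``chrom`` and ``pos`` (1-based)
        columns; typically also ``ref``, ``alt``, ``qual`` and INFO columns.
    haplotypes : optional (2*n_samples, n_sites) int8 array of phased
        alleles; -1 marks missing.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample count does not match dosage rows")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant count does not match dosage columns")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * len(self.samples), self.n_sites):
                raise ValueError("haplotype matrix must be (2*samples, sites)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy(dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return self.variants["chrom"].to_numpy()

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        haps = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.samples),
            self.variants.iloc[idx].reset_index(drop=True),
            haps,
        )

    def take_samples(self, names) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.samples)}
        rows = np.array([order[n] for n in names], dtype=int)
        haps = None
        if self.haplotypes is not None:
            hrows = np.empty(2 * len(rows), dtype=int)
            hrows[0::2] = 2 * rows
            hrows[1::2] = 2 * rows + 1
            haps = self.haplotypes[hrows]
        return GenotypeMatrix(
            self.dosages[rows], list(names), self.variants.copy(), haps
        )

    def allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per site over non-missing calls (NaN if none)."""
        d = self.dosages
        called = d != MISSING
        n_chrom = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)


@dataclass
class SampleMeta:
    """Per-sample annotations keyed by sample id."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample", "breed", "region", "height_class", "sex", "yakutia_adjacent")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing column {col!r}")
        self.table = self.table.reset_index(drop=True)

    def breed_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample"], self.table["breed"]))

    def samples_in(self, breeds, column: str = "breed") -> list[str]:
        if isinstance(breeds, str):
            breeds = [breeds]
        mask = self.table[column].isin(breeds)
        return list(self.table.loc[mask, "sample"])


def tile_windows(chrom_length: int, size: int = 10_000) -> np.ndarray:
    """Non-overlapping windows [0,size), [size,2*size), ... covering the chromosome.

    Returns an (n, 2) array of 0-based half-open start/end; the last window is
    truncated at the chromosome end.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    starts = np.arange(0, chrom_length, size, dtype=np.int64)
    ends = np.minimum(starts + size, chrom_length)
    return np.column_stack([starts, ends])


def assign_windows(positions: np.ndarray, size: int = 10_000) -> np.ndarray:
    """Window index (pos-1)//size for 1-based positions."""
    return (np.asarray(positions, dtype=np.int64) - 1) // size


def merge_intervals(intervals: np.ndarray, gap: int = 0) -> np.ndarray:
    """Merge 0-based half-open intervals closer than ``gap`` bp (0 = touching).

    Input is an (n, 2) array on a single chromosome; output is sorted and
    non-overlapping.
    """
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def interval_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of total bp covered by two interval sets on one chromosome."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    if len(a) == 0 and len(b) == 0:
        return 1.0
    inter = 0
    for s1, e1 in a:
        for s2, e2 in b:
            inter += max(0, min(e1, e2) - max(s1, s2))
    union = (a[:, 1] - a[:, 0]).sum() + (b[:, 1] - b[:, 0]).sum() - inter
    return inter / union if union > 0 else 1.0
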