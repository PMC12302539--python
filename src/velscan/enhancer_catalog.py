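"""Distal-enhancer cataloging and RPKM quantification.

H3K27ac marks both promoters and enhancers; the enhancer universe is the
set of peaks whose bodies lie farther than a distance threshold from every
annotated TSS, union-merged across samples into non-overlapping loci with
stable ids.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_core import (
    GenomicInterval,
    IntervalSet,
    PeakSet,
    TSSRecord,
    merge_intervals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CatalogParams",
    "EnhancerCatalog",
    "SignalMatrix",
    "classify_distal",
    "build_catalog",
    "quantify_rpkm",
]


@dataclass(frozen=True)
class CatalogParams:
    """Knobs for catalog construction.

    tss_distance_D: peaks within this many bp of any TSS (closest-edge
        distance) are promoter-proximal and excluded from the enhancer
        universe. 2.5 kb is the prevailing distal/proximal convention.
    merge_min_overlap: bp of overlap required to merge two peaks.
    min_samples_present: loci contributed by fewer samples are dropped.
    """

    tss_distance_D: int = 2500
    merge_min_overlap: int = 1
    min_samples_present: int = 1

    def __post_init__(self) -> None:
        if self.tss_distance_D < 0:
            raise ValueError("tss_distance_D must be >= 0")
        if self.merge_min_overlap < 1:
            raise ValueError("merge_min_overlap must be >= 1")
        if self.min_samples_present < 1:
            raise ValueError("min_samples_present must be >= 1")


@dataclass
class EnhancerCatalog:
    """Cross-sample universe of distal enhancer loci.

    ``source_map`` maps each locus id to the contributing peak labels per
    sample; ``n_samples`` maps each locus id to the number of distinct
    samples with a contributing peak.
    """

    loci: IntervalSet
    source_map: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [iv.id for iv in self.loci]

    def lengths(self) -> pd.Series:
        return pd.Series(
            [iv.length for iv in self.loci], index=self.locus_ids, name="length"
        )

    def to_dataframe(self) -> pd.DataFrame:
        return self.loci.to_dataframe()


@dataclass
class SignalMatrix:
    """Per-locus x per-sample signal: RPKM plus the raw ingredients."""

    rpkm: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series

    @property
    def locus_ids(self) -> list[str]:
        return list(self.rpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rpkm.columns)


def _tss_distance(
    interval: GenomicInterval, positions: np.ndarray
) -> int:
    """Closest-edge distance from the interval body to sorted TSS positions."""
    i = np.searchsorted(positions, interval.start)
    # any TSS inside [start, end)?
    j = np.searchsorted(positions, interval.end)
    if j > i:
        return 0
    best = np.inf
    if i > 0:
        best = interval.start - positions[i - 1]
    if i < len(positions):
        best = min(best, positions[i] - (interval.end - 1))
    return int(best)


def classify_distal(
    peaks: PeakSet,
    annotation: list[TSSRecord],
    params: CatalogParams = CatalogParams(),
) -> tuple[PeakSet, PeakSet]:
    """Partition peaks into (distal, proximal) by TSS distance.

    A peak is proximal iff the closest-edge distance from its body to any
    TSS is <= ``tss_distance_D``; distance is 0 when a TSS falls inside the
    peak. With an empty annotation every peak is distal (warning logged).
    """
    if not annotation:
        warnings.warn(
            "empty TSS annotation: classifying all peaks as distal",
            stacklevel=2,
        )
        tss_by_chrom: dict[str, np.ndarray] = {}
    else:
        grouped: dict[str, list[int]] = defaultdict(list)
        for rec in annotation:
            grouped[rec.chrom].append(rec.tss)
        tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in grouped.items()}

    distal_iv, distal_ex, prox_iv, prox_ex = [], [], [], []
    for iv, ex in zip(peaks.intervals, peaks.extras):
        positions = tss_by_chrom.get(iv.chrom)
        if positions is None or len(positions) == 0:
            d = np.inf
        else:
            d = _tss_distance(iv, positions)
        if d <= params.tss_distance_D:
            prox_iv.append(iv)
            prox_ex.append(ex)
        else:
            distal_iv.append(iv)
            distal_ex.append(ex)
    mk = lambda ivs, exs: PeakSet(
        peaks.sample_id, peaks.condition, ivs, peaks.source_dialect, exs
    )
    return mk(distal_iv, distal_ex), mk(prox_iv, prox_ex)


def build_catalog(
    distal_peaksets: list[PeakSet],
    params: CatalogParams = CatalogParams(),
) -> EnhancerCatalog:
    """Union-merge distal peaks across samples into an enhancer catalog.

    Loci present in fewer than ``min_samples_present`` samples are dropped.
    Ids E000001... are assigned in (chrom, start) order, so the id-to-
    coordinate mapping is a pure function of the input coordinates.
    """
    if not distal_peaksets:
        raise ValueError("build_catalog requires at least one peak set")
    tagged: list[GenomicInterval] = []
    for ps in distal_peaksets:
        for k, iv in enumerate(ps.intervals):
            label = f"{ps.sample_id}::{iv.id or f'peak{k + 1}'}"
            tagged.append(GenomicInterval(iv.chrom, iv.start, iv.end, id=label))
    merged = merge_intervals(tagged, min_overlap=params.merge_min_overlap)

    kept_iv: list[GenomicInterval] = []
    kept_sources: list[dict[str, list[str]]] = []
    for iv, src in zip(merged.intervals, merged.sources):
        per_sample: dict[str, list[str]] = defaultdict(list)
        for label in src:
            sample, peak = label.split("::", 1)
            per_sample[sample].append(peak)
        if len(per_sample) >= params.min_samples_present:
            kept_iv.append(iv)
            kept_sources.append(dict(per_sample))
    if not kept_iv:
        raise ValueError(
            "no loci survive catalog construction; review tss_distance_D and "
            "min_samples_present"
        )
    with_ids = [
        GenomicInterval(iv.chrom, iv.start, iv.end, id=f"E{i + 1:06d}")
        for i, iv in enumerate(kept_iv)
    ]
    source_map = {iv.id: src for iv, src in zip(with_ids, kept_sources)}
    logger.info("catalog: %d loci from %d samples", len(with_ids), len(distal_peaksets))
    return EnhancerCatalog(loci=IntervalSet(with_ids), source_map=source_map)


def quantify_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
) -> SignalMatrix:
    """RPKM = count / ((length/1000) * (library_size/1e6)).

    ``counts`` is loci x samples; ``lengths`` indexed by locus id in bp;
    ``library_sizes`` indexed by sample id in total mapped reads.
    """
    if not counts.index.equals(pd.Index(lengths.index)):
        missing = set(counts.index) ^ set(lengths.index)
        raise ValueError(
            f"locus axis mismatch between counts and lengths (e.g. {sorted(missing)[:3]})"
        )
    if not counts.columns.equals(pd.Index(library_sizes.index)):
        missing = set(counts.columns) ^ set(library_sizes.index)
        raise ValueError(
            f"sample axis mismatch between counts and library sizes "
            f"(e.g. {sorted(missing)[:3]})"
        )
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if (lengths <= 0).any():
        raise ValueError("locus lengths must be positive")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    kb = lengths.to_numpy(dtype=float)[:, None] / 1000.0
    millions = library_sizes.to_numpy(dtype=float)[None, :] / 1e6
    rpkm = counts.to_numpy(dtype=float) / (kb * millions)
    return SignalMatrix(
        rpkm=pd.DataFrame(rpkm, index=counts.index, columns=counts.columns),
        counts=counts,
        lengths=lengths,
        library_sizes=library_sizes,
    )
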