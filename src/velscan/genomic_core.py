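"""Coordinate types, interval algebra and file I/O.

All coordinates are 0-based half-open (BED convention). 1-based inputs are
not supported. Chromosome names are compared as opaque strings — no "chr"
prefix stripping is attempted; mismatched naming between two inputs is
surfaced as a warning by the functions that combine them.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TSSRecord",
    "PeakSet",
    "PairManifest",
    "IntervalSet",
    "NearestTSS",
    "merge_intervals",
    "read_regions",
    "write_regions",
    "nearest_tss",
    "bin_genome",
    "read_tss_table",
    "write_tss_table",
    "read_pair_manifest",
    "write_pair_manifest",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic range ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval has empty chromosome name")
        if self.start < 0:
            raise ValueError(
                f"negative start coordinate in {self.chrom}:{self.start}-{self.end}"
            )
        if self.start >= self.end:
            raise ValueError(
                f"start >= end in {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: the distal/proximal anchor for peaks."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS position for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")


class IntervalSet:
    """A sorted, validated collection of intervals with optional source ids.

    ``sources[i]`` records the ids of the input intervals that were merged
    into ``intervals[i]`` (empty tuple when unknown).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        sources: Sequence[tuple[str, ...]] | None = None,
    ) -> None:
        ivs = list(intervals)
        order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
        self.intervals: list[GenomicInterval] = [ivs[i] for i in order]
        if sources is None:
            self.sources: list[tuple[str, ...]] = [() for _ in self.intervals]
        else:
            if len(sources) != len(ivs):
                raise ValueError("sources length does not match intervals")
            self.sources = [tuple(sources[i]) for i in order]

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.coordinates() == other.coordinates()

    def coordinates(self) -> list[tuple[str, int, int]]:
        return [(iv.chrom, iv.start, iv.end) for iv in self.intervals]

    def total_bases(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "id": [iv.id for iv in self.intervals],
            }
        )


@dataclass
class PeakSet:
    """Peaks for one sample, as read from a BED-dialect file.

    ``extras[i]`` keeps the columns beyond chrom/start/end/name verbatim so
    that dialect-specific fields (scores, summits, q-values) survive a
    round-trip without being interpreted.
    """

    sample_id: str
    condition: str
    intervals: list[GenomicInterval]
    source_dialect: str = "bed3"
    extras: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("PeakSet requires a nonempty sample_id")
        if self.condition not in ("normal", "tumor", "unknown"):
            raise ValueError(f"invalid condition {self.condition!r}")
        if not self.extras:
            self.extras = [() for _ in self.intervals]


@dataclass
class PairManifest:
    """Patient pairing: (patient_id, normal_sample_id, tumor_sample_id)."""

    pairs: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        patients = [p for p, _, _ in self.pairs]
        if len(set(patients)) != len(patients):
            dupes = sorted({p for p in patients if patients.count(p) > 1})
            raise ValueError(f"duplicate patient ids in manifest: {dupes}")
        samples = [s for _, n, t in self.pairs for s in (n, t)]
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise ValueError(f"sample ids appear in more than one pair: {dupes}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(self.pairs)

    @property
    def patient_ids(self) -> list[str]:
        return [p for p, _, _ in self.pairs]


class NearestTSS(NamedTuple):
    """Result of a nearest-TSS query; ``gene_id`` is None when unassigned."""

    gene_id: str | None
    distance: int | None


# ---------------------------------------------------------------------------
# interval algebra


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_overlap: int = 1
) -> IntervalSet:
    """Union-merge intervals into maximal connected components.

    Two intervals are connected when they share >= ``min_overlap`` bases;
    each output interval spans the coordinate union of one connected
    component and records the ids of its members (falling back to
    ``chrom:start-end`` for anonymous inputs).
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)

    merged: list[GenomicInterval] = []
    sources: list[tuple[str, ...]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start = cur_end = None
        cur_ids: list[str] = []
        for iv in ivs:
            label = iv.id if iv.id is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
                cur_ids = [label]
                continue
            # overlap with the component = overlap with its furthest-right member
            if min(cur_end, iv.end) - iv.start >= min_overlap:
                cur_end = max(cur_end, iv.end)
                cur_ids.append(label)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                sources.append(tuple(cur_ids))
                cur_start, cur_end = iv.start, iv.end
                cur_ids = [label]
        if cur_start is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
            sources.append(tuple(cur_ids))
    return IntervalSet(merged, sources)


def nearest_tss(
    interval: GenomicInterval, annotation: Sequence[TSSRecord]
) -> NearestTSS:
    """Gene whose TSS is closest to the interval body.

    Distance is 0 when a TSS lies inside ``[start, end)``; otherwise the gap
    to the closest covered base, signed negative when the TSS lies at lower
    coordinates than the interval. Ties on |distance| resolve to the
    lexicographically smaller gene_id. Returns ``NearestTSS(None, None)``
    when the annotation has no TSS on the interval's chromosome.
    """
    best: tuple[int, str, int] | None = None  # (|d|, gene_id, signed d)
    for rec in annotation:
        if rec.chrom != interval.chrom:
            continue
        if interval.start <= rec.tss < interval.end:
            signed = 0
        elif rec.tss < interval.start:
            signed = rec.tss - interval.start
        else:
            signed = rec.tss - (interval.end - 1)
        key = (abs(signed), rec.gene_id, signed)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return NearestTSS(None, None)
    return NearestTSS(best[1], best[2])


def bin_genome(
    genome: Sequence[tuple[str, int]], width: int = 10_000
) -> IntervalSet:
    """Tile each chromosome with fixed-width bins (last bin may be short)."""
    if width < 1:
        raise ValueError("bin width must be positive")
    bins = []
    for chrom, length in genome:
        for start in range(0, length, width):
            bins.append(
                GenomicInterval(chrom, start, min(start + width, length))
            )
    return IntervalSet(bins)


# ---------------------------------------------------------------------------
# region file I/O

_DIALECT_COLS = {"bed3": range(3, 7), "broadPeak": (9,), "narrowPeak": (10,)}


def _infer_dialect(ncols: int, lineno: int) -> str:
    if 3 <= ncols <= 6:
        return "bed3"
    if ncols == 9:
        return "broadPeak"
    if ncols == 10:
        return "narrowPeak"
    raise ValueError(
        f"line {lineno}: cannot infer dialect from {ncols} columns "
        "(expected 3-6 for BED, 9 for broadPeak, 10 for narrowPeak)"
    )


def read_regions(
    path: str | Path,
    dialect: str = "auto",
    sample_id: str | None = None,
    condition: str = "unknown",
) -> PeakSet:
    """Read a BED3+/narrowPeak/broadPeak file into a :class:`PeakSet`.

    Coordinates follow the BED convention (0-based half-open). Track,
    browser and ``#`` comment lines are skipped. Columns beyond
    chrom/start/end/name are preserved verbatim in ``extras``.
    """
    path = Path(path)
    if dialect not in ("auto", "bed3", "narrowPeak", "broadPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    intervals: list[GenomicInterval] = []
    extras: list[tuple[str, ...]] = []
    resolved = None if dialect == "auto" else dialect
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if resolved is None:
                resolved = _infer_dialect(len(fields), lineno)
            elif dialect != "auto" and len(fields) not in _DIALECT_COLS[resolved]:
                raise ValueError(
                    f"line {lineno}: {len(fields)} columns incompatible with "
                    f"dialect {resolved}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: non-integer coordinates {fields[1]!r}, "
                    f"{fields[2]!r}"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"line {lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
            try:
                intervals.append(GenomicInterval(fields[0], start, end, id=name))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            extras.append(tuple(fields[4:]))
    return PeakSet(
        sample_id=sample_id or path.stem,
        condition=condition,
        intervals=intervals,
        source_dialect=resolved or "bed3",
        extras=extras,
    )


def write_regions(
    regions: IntervalSet | Iterable[GenomicInterval],
    path: str | Path,
    with_ids: bool = False,
) -> None:
    """Write intervals as BED, sorted by (chrom, start)."""
    if not isinstance(regions, IntervalSet):
        regions = IntervalSet(regions)
    path = Path(path)
    with path.open("w") as fh:
        for iv in regions:
            if with_ids:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# tabular I/O (TSV with header throughout)


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise ValueError(f"duplicate gene ids in TSS table: {dupes[:5]}")
    return [
        TSSRecord(r.gene_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples()
    ]


def write_tss_table(records: Sequence[TSSRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "chrom": [r.chrom for r in records],
            "tss": [r.tss for r in records],
            "strand": [r.strand for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_pair_manifest(path: str | Path) -> PairManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "normal_sample_id", "tumor_sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pair manifest missing columns: {sorted(missing)}")
    return PairManifest(
        [
            (r.patient_id, r.normal_sample_id, r.tumor_sample_id)
            for r in df.itertuples()
        ]
    )


def write_pair_manifest(manifest: PairManifest, path: str | Path) -> None:
    pd.DataFrame(
        manifest.pairs, columns=["patient_id", "normal_sample_id", "tumor_sample_id"]
    ).to_csv(path, sep="\t", index=False)


def warn_on_disjoint_chroms(
    chroms_a: Iterable[str], chroms_b: Iterable[str], context: str
) -> None:
    """Warn when two inputs share no chromosome names (likely naming clash)."""
    a, b = set(chroms_a), set(chroms_b)
    if a and b and not (a & b):
        warnings.warn(
            f"{context}: no chromosome names in common "
            f"(first input: {sorted(a)[:3]}..., second: {sorted(b)[:3]}...); "
            "check naming conventions",
            stacklevel=2,
        )
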