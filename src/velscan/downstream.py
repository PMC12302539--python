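"""Post-VEL integration.

Proximal-gene assignment for called loci, differential-expression
classification and VEL/DEG concordance, marker-gene cohort stratification
with group-wise signal averaging, and catalog-vs-catalog overlap reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genomic_core import (
    GenomicInterval,
    IntervalSet,
    NearestTSS,
    TSSRecord,
    nearest_tss,
    warn_on_disjoint_chroms,
)
from .enhancer_catalog import SignalMatrix

__all__ = [
    "DEGParams",
    "OverlapReport",
    "deg_classify",
    "vel_gene_map",
    "concordance_test",
    "stratify_by_marker",
    "group_signal",
    "compare_catalogs",
]


@dataclass(frozen=True)
class DEGParams:
    """Differential-expression thresholds, both applied inclusively.

    A gene is 'up' when log2FC >= +log2fc_threshold and padj <=
    padj_threshold, 'down' with the mirrored fold-change condition,
    otherwise 'ns'.
    """

    log2fc_threshold: float = 1.0
    padj_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.log2fc_threshold <= 0:
            raise ValueError("log2fc_threshold must be > 0")
        if self.padj_threshold <= 0:
            raise ValueError("padj_threshold must be > 0")


@dataclass(frozen=True)
class OverlapReport:
    """Two-catalog overlap summary (>= 1 bp intersection counts)."""

    n_A: int
    n_B: int
    n_A_overlapping: int
    n_B_overlapping: int

    @property
    def fraction_A_new(self) -> float:
        return 1.0 - self.n_A_overlapping / self.n_A

    @property
    def fraction_B_new(self) -> float:
        return 1.0 - self.n_B_overlapping / self.n_B


def deg_classify(
    expression: pd.DataFrame, params: DEGParams = DEGParams()
) -> pd.DataFrame:
    """Classify genes as up / down / ns under the configured thresholds."""
    required = {"gene_id", "log2FC", "padj"}
    missing = required - set(expression.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    dupes = expression.loc[expression["gene_id"].duplicated(), "gene_id"]
    if len(dupes):
        raise ValueError(
            f"duplicate gene ids in expression table: {sorted(dupes.unique())[:5]}"
        )
    out = expression.copy()
    sig = out["padj"] <= params.padj_threshold
    up = sig & (out["log2FC"] >= params.log2fc_threshold)
    down = sig & (out["log2FC"] <= -params.log2fc_threshold)
    out["class"] = np.select([up, down], ["up", "down"], default="ns")
    return out


def vel_gene_map(
    vels: pd.DataFrame, annotation: list[TSSRecord]
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Assign each VEL its proximal (nearest-TSS) gene.

    Returns the per-locus assignment table and, per direction, the unique
    set of assigned genes ('unassigned' loci excluded from the sets).
    """
    rows = []
    for row in vels.itertuples():
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), id=row.id)
        hit: NearestTSS = nearest_tss(iv, annotation)
        rows.append(
            {
                "id": row.id,
                "direction": row.direction,
                "gene_id": hit.gene_id or "unassigned",
                "distance": hit.distance,
            }
        )
    table = pd.DataFrame(rows)
    gene_sets: dict[str, set[str]] = {}
    if not table.empty:
        for direction, sub in table.groupby("direction"):
            gene_sets[direction] = set(
                sub.loc[sub["gene_id"] != "unassigned", "gene_id"]
            )
    return table, gene_sets


def concordance_test(
    vel_genes: set[str], deg_genes: set[str], universe: set[str]
) -> tuple[int, float]:
    """Overlap of two gene sets with an upper-tail hypergeometric p-value.

    p = P(X >= |A intersect B|) when |A| genes are drawn without
    replacement from the universe containing |B| successes.
    """
    for name, s in (("vel_genes", vel_genes), ("deg_genes", deg_genes)):
        extra = s - universe
        if extra:
            raise ValueError(
                f"{name} not a subset of universe: {sorted(extra)[:5]}"
            )
    overlap = len(vel_genes & deg_genes)
    M, n_succ, n_draw = len(universe), len(deg_genes), len(vel_genes)
    p = float(hypergeom.sf(overlap - 1, M, n_succ, n_draw))
    return overlap, min(1.0, p)


def stratify_by_marker(
    expression: pd.DataFrame, marker: str, rule: str = "median"
) -> pd.Series:
    """Split tumor samples into marker-high and -low groups.

    ``expression`` is genes x samples. Median rule: high when strictly
    above the median, ties go low. Tertile rule: top third high, bottom
    third low, middle 'mid'; ties broken by sample id for determinism.
    """
    if marker not in expression.index:
        raise ValueError(f"marker gene {marker!r} absent from expression matrix")
    values = expression.loc[marker]
    if rule == "median":
        med = values.median()
        labels = pd.Series(
            np.where(values > med, "high", "low"), index=values.index
        )
        if (values == values.iloc[0]).all():
            warnings.warn(
                f"all samples have identical {marker} expression; "
                "every sample labelled low",
                stacklevel=2,
            )
        return labels
    if rule == "tertile":
        order = sorted(values.index, key=lambda s: (values[s], s))
        k = len(order) // 3
        labels = pd.Series("mid", index=values.index)
        labels[order[:k]] = "low"
        if k:
            labels[order[-k:]] = "high"
        return labels
    raise ValueError(f"unknown stratification rule {rule!r}")


def group_signal(
    signal: SignalMatrix | pd.DataFrame,
    groups: pd.Series | dict[str, str],
    loci: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean RPKM per locus plus a per-group grand mean.

    ``groups`` maps sample id -> group label over a subset of samples;
    ``loci`` optionally restricts the rows (e.g. to VEL loci or genome
    bins). Returns (tidy per-locus table, group summary).
    """
    rpkm = signal.rpkm if isinstance(signal, SignalMatrix) else signal
    groups = pd.Series(groups)
    missing = set(groups.index) - set(rpkm.columns)
    if missing:
        raise ValueError(f"samples absent from signal matrix: {sorted(missing)[:5]}")
    if loci is not None:
        rpkm = rpkm.loc[loci]
    per_locus_frames = []
    summary_rows = []
    for label in sorted(pd.unique(groups)):
        samples = groups.index[groups == label]
        if len(samples) == 0:
            raise ValueError(f"group {label!r} is empty")
        sub = rpkm[list(samples)]
        mean = sub.mean(axis=1)
        per_locus_frames.append(
            pd.DataFrame(
                {"locus_id": rpkm.index, "group": label, "mean_rpkm": mean.to_numpy()}
            )
        )
        summary_rows.append(
            {"group": label, "n_samples": len(samples), "grand_mean_rpkm": float(mean.mean())}
        )
    per_locus = pd.concat(per_locus_frames, ignore_index=True)
    summary = pd.DataFrame(summary_rows)
    return per_locus, summary


def _as_intervals(x) -> list[GenomicInterval]:
    if isinstance(x, IntervalSet):
        return list(x)
    if isinstance(x, pd.DataFrame):
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in x.itertuples()
        ]
    return list(x)


def compare_catalogs(a, b) -> OverlapReport:
    """Count loci of each catalog overlapping (>= 1 bp) the other."""
    ia, ib = _as_intervals(a), _as_intervals(b)
    if not ia or not ib:
        raise ValueError("both catalogs must be non-empty")
    warn_on_disjoint_chroms(
        (iv.chrom for iv in ia), (iv.chrom for iv in ib), "compare_catalogs"
    )

    def count_overlapping(xs: list[GenomicInterval], ys: list[GenomicInterval]) -> int:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in ys:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        arrs = {
            c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
            for c, v in by_chrom.items()
        }
        n = 0
        for iv in xs:
            if iv.chrom not in arrs:
                continue
            s, e = arrs[iv.chrom]
            if ((s < iv.end) & (e > iv.start)).any():
                n += 1
        return n

    return OverlapReport(
        n_A=len(ia),
        n_B=len(ib),
        n_A_overlapping=count_overlapping(ia, ib),
        n_B_overlapping=count_overlapping(ib, ia),
    )
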