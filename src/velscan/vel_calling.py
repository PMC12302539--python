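"""Variant enhancer locus (VEL) calling.

The core procedure: per patient pair, an enhancer is a gain VEL when its
tumor/normal H3K27ac fold change is >= a threshold (default 2), and a lost
VEL when the normal/tumor ratio passes the same threshold. Per-pair VELs
are merged into a single coordinate file per direction; each merged locus
gets a recurrence r (number of supporting patients), a tail p-value under a
recurrence null, a Benjamini-Hochberg adjusted p, and a significance flag
that combines the adjusted p with a calibrated recurrence threshold r*.

The recurrence null treats each pair i as an independent Bernoulli trial
with its own empirically observed per-pair call rate p_i; the recurrence of
a locus under no shared biology is then Poisson-binomial distributed, and
the p-value is the exact upper tail P(R >= r) computed by the O(n^2)
convolution. A plain binomial on the mean rate is available as a
cross-check null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enhancer_catalog import EnhancerCatalog, SignalMatrix
from .genomic_core import GenomicInterval, IntervalSet, PairManifest, merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "VELParams",
    "PairVELSet",
    "VELResult",
    "pair_vels",
    "merge_pair_vels",
    "recurrence_pvalue",
    "bh_adjust",
    "calibrate_recurrence_threshold",
    "call_vels",
]

VEL_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "id",
    "recurrence",
    "direction",
    "p_value",
    "padj",
    "significant",
    "supporting_patients",
]


@dataclass(frozen=True)
class VELParams:
    """Calling parameters.

    fc_threshold: tumor/normal (or normal/tumor) RPKM ratio at or above
        which a locus is called, applied inclusively (FC exactly at the
        threshold is a call).
    pseudocount: RPKM added to numerator and denominator; bounds the fold
        change and removes division by zero at silent loci.
    alpha: BH-adjusted significance level.
    percent_cutoff: fraction of loci at a candidate recurrence stratum that
        must be significant for the stratum to set r*.
    recurrence_mode: 'at_least' flags loci with r >= r*, 'greater_than'
        with r > r*.
    null_model: 'poisson_binomial' (exact, heterogeneous per-pair rates) or
        'binomial_mean' (binomial on the mean rate).
    """

    fc_threshold: float = 2.0
    pseudocount: float = 0.5
    alpha: float = 0.05
    percent_cutoff: float = 0.85
    recurrence_mode: str = "at_least"
    null_model: str = "poisson_binomial"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.percent_cutoff <= 1:
            raise ValueError("percent_cutoff must be in (0, 1]")
        if self.recurrence_mode not in ("at_least", "greater_than"):
            raise ValueError(f"unknown recurrence_mode {self.recurrence_mode!r}")
        if self.null_model not in ("poisson_binomial", "binomial_mean"):
            raise ValueError(f"unknown null_model {self.null_model!r}")


@dataclass
class PairVELSet:
    """Per-pair calls: gain and lost loci plus the pair's background rates."""

    patient_id: str
    gains: IntervalSet
    losses: IntervalSet
    testable_count: int

    def __post_init__(self) -> None:
        if self.testable_count <= 0:
            raise ValueError("testable_count must be positive")
        shared = set(iv.id for iv in self.gains) & set(iv.id for iv in self.losses)
        if shared:
            raise ValueError(
                f"loci called both gain and lost within pair "
                f"{self.patient_id}: {sorted(shared)[:3]}"
            )

    @property
    def rate_gain(self) -> float:
        return len(self.gains) / self.testable_count

    @property
    def rate_lost(self) -> float:
        return len(self.losses) / self.testable_count


@dataclass
class VELResult:
    """Output of :func:`call_vels`: one table per direction plus r*."""

    gain_table: pd.DataFrame
    lost_table: pd.DataFrame
    r_star_gain: int
    r_star_lost: int
    pair_stats: pd.DataFrame
    conflicting_loci: list[str] = field(default_factory=list)


def pair_vels(
    signal: SignalMatrix,
    pair: tuple[str, str, str],
    catalog: EnhancerCatalog,
    params: VELParams = VELParams(),
) -> PairVELSet:
    """Call gain/lost VELs for one patient pair over the full catalog.

    FC_gain = (RPKM_tumor + eps) / (RPKM_normal + eps); a locus is a gain
    when FC_gain >= fc_threshold and a loss when the reciprocal ratio
    passes the same threshold. Every catalog locus is testable.
    """
    patient_id, normal_id, tumor_id = pair
    for sid in (normal_id, tumor_id):
        if sid not in signal.rpkm.columns:
            raise ValueError(
                f"sample {sid!r} for patient {patient_id!r} missing from signal matrix"
            )
    eps = params.pseudocount
    normal = signal.rpkm[normal_id].to_numpy() + eps
    tumor = signal.rpkm[tumor_id].to_numpy() + eps
    gain_mask = tumor >= params.fc_threshold * normal
    lost_mask = normal >= params.fc_threshold * tumor
    loci = catalog.loci.intervals
    gains = IntervalSet([iv for iv, m in zip(loci, gain_mask) if m])
    losses = IntervalSet([iv for iv, m in zip(loci, lost_mask) if m])
    return PairVELSet(
        patient_id=patient_id,
        gains=gains,
        losses=losses,
        testable_count=len(loci),
    )


def merge_pair_vels(
    pair_sets: list[PairVELSet],
    direction: str,
    params: VELParams = VELParams(),
) -> tuple[IntervalSet, list[set[str]]]:
    """Merge one direction's per-pair VELs into a single coordinate file.

    Returns the merged loci and, aligned with them, the set of supporting
    patients per locus; a patient counts once regardless of how many of its
    VELs fall in the merged component.
    """
    if direction not in ("gain", "lost"):
        raise ValueError(f"direction must be 'gain' or 'lost', got {direction!r}")
    if not pair_sets:
        raise ValueError("merge_pair_vels requires at least one pair set")
    tagged: list[GenomicInterval] = []
    for ps in pair_sets:
        ivs = ps.gains if direction == "gain" else ps.losses
        for iv in ivs:
            tagged.append(
                GenomicInterval(
                    iv.chrom, iv.start, iv.end, id=f"{ps.patient_id}::{iv.id}"
                )
            )
    merged = merge_intervals(tagged, min_overlap=1)
    supports = [
        {label.split("::", 1)[0] for label in src} for src in merged.sources
    ]
    return merged, supports


def recurrence_pvalue(
    r: int,
    rates: list[float] | np.ndarray,
    null_model: str = "poisson_binomial",
) -> float:
    """Upper-tail probability P(R >= r) of the recurrence null.

    R is the number of pairs flagging a given locus by chance; under
    'poisson_binomial' R = sum of independent Bernoulli(p_i) and the tail
    is computed by exact convolution; under 'binomial_mean' R ~
    Binomial(n, mean(p_i)). r = 0 returns 1.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("rates must be nonempty")
    if ((rates < 0) | (rates > 1)).any():
        bad = rates[(rates < 0) | (rates > 1)]
        raise ValueError(f"rates outside [0, 1]: {bad[:3]}")
    n = rates.size
    if not 0 <= r <= n:
        raise ValueError(f"recurrence {r} outside [0, {n}]")
    if r == 0:
        return 1.0
    if null_model == "poisson_binomial":
        pmf = np.zeros(n + 1)
        pmf[0] = 1.0
        for p in rates:
            pmf[1:] = pmf[1:] * (1.0 - p) + pmf[:-1] * p
            pmf[0] *= 1.0 - p
        return float(min(1.0, max(0.0, pmf[r:].sum())))
    if null_model == "binomial_mean":
        from scipy.stats import binom

        return float(binom.sf(r - 1, n, rates.mean()))
    raise ValueError(f"unknown null_model {null_model!r}")


def bh_adjust(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.array([])
    if ((pvalues < 0) | (pvalues > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def _recurrence_cmp(recurrence: np.ndarray, r: int, mode: str) -> np.ndarray:
    return recurrence >= r if mode == "at_least" else recurrence > r


def calibrate_recurrence_threshold(
    table: pd.DataFrame,
    params: VELParams,
    n_pairs: int,
) -> int:
    """Smallest recurrence r* whose stratum is mostly significant.

    For each candidate r in 1..n_pairs, frac(r) is the fraction of loci in
    the stratum selected by ``recurrence_mode`` (r' >= r or r' > r) with
    padj <= alpha; r* is the smallest r with frac(r) >= percent_cutoff.
    Empty strata never qualify. When no r qualifies, n_pairs is returned
    with a warning.
    """
    if table.empty:
        raise ValueError("cannot calibrate on an empty VEL table")
    rec = table["recurrence"].to_numpy()
    sig = (table["padj"].to_numpy() <= params.alpha)
    for r in range(1, n_pairs + 1):
        stratum = _recurrence_cmp(rec, r, params.recurrence_mode)
        if stratum.sum() == 0:
            continue
        frac = sig[stratum].mean()
        if frac >= params.percent_cutoff:
            return r
    logger.warning(
        "no recurrence threshold reaches percent_cutoff=%.2f; returning n_pairs=%d",
        params.percent_cutoff,
        n_pairs,
    )
    return n_pairs


def _direction_table(
    pair_sets: list[PairVELSet],
    direction: str,
    params: VELParams,
    n_pairs: int,
) -> tuple[pd.DataFrame, int]:
    rates = [
        ps.rate_gain if direction == "gain" else ps.rate_lost for ps in pair_sets
    ]
    merged, supports = merge_pair_vels(pair_sets, direction, params)
    prefix = "G" if direction == "gain" else "L"
    rows = []
    for i, (iv, supp) in enumerate(zip(merged.intervals, supports)):
        r = len(supp)
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "id": f"{prefix}{i + 1:06d}",
                "recurrence": r,
                "direction": direction,
                "p_value": recurrence_pvalue(r, rates, params.null_model),
                "supporting_patients": ",".join(sorted(supp)),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[c for c in VEL_TABLE_COLUMNS if c not in ("padj", "significant")],
    )
    if table.empty:
        table = table.reindex(columns=VEL_TABLE_COLUMNS)
        table["padj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
        return table[VEL_TABLE_COLUMNS], n_pairs
    table["padj"] = bh_adjust(table["p_value"].to_numpy())
    r_star = calibrate_recurrence_threshold(table, params, n_pairs)
    table["significant"] = (table["padj"] <= params.alpha) & _recurrence_cmp(
        table["recurrence"].to_numpy(), r_star, params.recurrence_mode
    )
    return table[VEL_TABLE_COLUMNS], r_star


def call_vels(
    signal: SignalMatrix,
    catalog: EnhancerCatalog,
    pairs: PairManifest,
    params: VELParams = VELParams(),
) -> VELResult:
    """End-to-end VEL calling over a paired cohort.

    Composes per-pair fold-change calls, direction-wise merging,
    Poisson-binomial recurrence p-values on that direction's per-pair
    rates, BH adjustment within direction, and recurrence-threshold
    calibration. Gains and losses are processed independently; loci that
    end up in both tables (gain in some pairs, lost in others) are
    retained in both and reported in ``conflicting_loci``.
    """
    if len(pairs) < 2:
        raise ValueError(
            f"recurrence analysis requires >= 2 pairs, got {len(pairs)}"
        )
    pair_sets = [pair_vels(signal, pair, catalog, params) for pair in pairs]
    n_pairs = len(pairs)
    gain_table, r_star_gain = _direction_table(pair_sets, "gain", params, n_pairs)
    lost_table, r_star_lost = _direction_table(pair_sets, "lost", params, n_pairs)

    pair_stats = pd.DataFrame(
        {
            "patient_id": [ps.patient_id for ps in pair_sets],
            "rate_gain": [ps.rate_gain for ps in pair_sets],
            "rate_lost": [ps.rate_lost for ps in pair_sets],
            "n_gain": [len(ps.gains) for ps in pair_sets],
            "n_lost": [len(ps.losses) for ps in pair_sets],
            "testable_count": [ps.testable_count for ps in pair_sets],
        }
    )

    conflicts = _overlapping_ids(gain_table, lost_table)
    if conflicts:
        logger.info(
            "%d loci appear in both gain and lost tables (different pairs)",
            len(conflicts),
        )
    return VELResult(
        gain_table=gain_table,
        lost_table=lost_table,
        r_star_gain=r_star_gain,
        r_star_lost=r_star_lost,
        pair_stats=pair_stats,
        conflicting_loci=conflicts,
    )


def _overlapping_ids(a: pd.DataFrame, b: pd.DataFrame) -> list[str]:
    """Ids of loci in ``a`` overlapping >= 1 bp with any locus in ``b``."""
    out = []
    for chrom, sub_a in a.groupby("chrom"):
        sub_b = b[b["chrom"] == chrom]
        if sub_b.empty:
            continue
        bs = sub_b["start"].to_numpy()
        be = sub_b["end"].to_numpy()
        for _, row in sub_a.iterrows():
            if ((bs < row["end"]) & (be > row["start"])).any():
                out.append(row["id"])
    return out
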