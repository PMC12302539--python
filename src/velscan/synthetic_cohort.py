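"""Synthetic paired tumor/normal H3K27ac cohort with planted VELs.

The generator emulates the study design the caller consumes: a cohort of
patients, each contributing a normal and a tumor sample that share a latent
enhancer landscape. Per-locus baseline activity is log-normal on the
log2-RPKM scale; each sample adds independent Gaussian log2 noise
(biological within-pair variability); planted gain/lost loci shift the
tumor latent signal by a configured log2 effect in a configured number of
supporting pairs. Read counts are Poisson (or negative-binomial) with
expectation 2^latent scaled by locus length and library size, so the latent
value is the expected log2 RPKM. A differential-expression table couples
the proximal genes of planted loci to expression shifts. Ground truth is
returned for parameter-recovery evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_core import (
    GenomicInterval,
    PairManifest,
    PeakSet,
    TSSRecord,
    nearest_tss,
    write_pair_manifest,
    write_regions,
    write_tss_table,
)

__all__ = [
    "PlantSpec",
    "CohortConfig",
    "CohortBundle",
    "simulate_cohort",
    "write_cohort",
    "read_cohort_dir",
    "read_truth_table",
]


@dataclass(frozen=True)
class PlantSpec:
    """One batch of planted VELs: direction, count, effect and recurrence."""

    direction: str
    n_loci: int
    effect_log2fc: float = 2.0
    recurrence_design: int = 8
    couple_expression: bool = True
    expression_log2fc: float = 2.0

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "lost"):
            raise ValueError(f"direction must be gain/lost, got {self.direction!r}")
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be > 0")
        if self.recurrence_design < 1:
            raise ValueError("recurrence_design must be >= 1")


def _default_planted() -> tuple[PlantSpec, ...]:
    return (
        PlantSpec("gain", n_loci=200),
        PlantSpec("lost", n_loci=200),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a simulated cohort.

    Defaults describe the reference design used throughout the test suite:
    20 patient pairs, 5000 enhancers on a two-chromosome 100 Mb genome, 200
    gain and 200 lost loci planted at log2 effect 2 in 8 of 20 pairs,
    within-pair log2 noise sd 0.3, Poisson counts at 5-10 M reads/library.
    """

    n_pairs: int = 20
    n_enhancers: int = 5000
    n_genes: int = 1000
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 60_000_000),
        ("chr2", 40_000_000),
    )
    planted: tuple[PlantSpec, ...] = field(default_factory=_default_planted)
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0
    pair_noise_log2_sd: float = 0.3
    library_size_range: tuple[int, int] = (5_000_000, 10_000_000)
    count_model: str = "poisson"
    nb_dispersion: float = 0.05
    tss_exclusion: int = 5000
    seed: int = 0
    enhancer_length_range: tuple[int, int] = (600, 2000)
    detection_quantile: float = 0.0

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        n_planted = sum(s.n_loci for s in self.planted)
        if self.n_enhancers <= n_planted:
            raise ValueError(
                f"n_enhancers ({self.n_enhancers}) must exceed planted loci "
                f"({n_planted})"
            )
        for s in self.planted:
            if s.recurrence_design > self.n_pairs:
                raise ValueError(
                    f"recurrence_design {s.recurrence_design} exceeds n_pairs "
                    f"{self.n_pairs}"
                )
        if self.baseline_log2_sd < 0 or self.pair_noise_log2_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        if self.count_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.tss_exclusion < 0:
            raise ValueError("tss_exclusion must be >= 0")
        llo, lhi = self.enhancer_length_range
        if llo <= 0 or lhi < llo:
            raise ValueError("enhancer_length_range must be positive and ordered")
        if not 0 <= self.detection_quantile < 1:
            raise ValueError("detection_quantile must be in [0, 1)")


@dataclass
class CohortBundle:
    """Everything :func:`simulate_cohort` produces, ready to write or call."""

    config: CohortConfig
    peaksets: list[PeakSet]
    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series
    manifest: PairManifest
    tss: list[TSSRecord]
    expression: pd.DataFrame
    truth: pd.DataFrame
    catalog_intervals: list[GenomicInterval]


def _place_tss(config: CohortConfig, rng: np.random.Generator) -> list[TSSRecord]:
    chroms = [c for c, _ in config.genome]
    lengths = np.array([l for _, l in config.genome], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(chroms), size=config.n_genes, p=probs)
    positions = np.array(
        [rng.integers(0, config.genome[i][1]) for i in chrom_idx]
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    recs = [
        TSSRecord(f"g{k + 1:05d}", chroms[i], int(p), s)
        for k, (i, p, s) in enumerate(zip(chrom_idx, positions, strands))
    ]
    return sorted(recs, key=lambda r: (r.chrom, r.tss))


def _place_enhancers(
    config: CohortConfig,
    tss: list[TSSRecord],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Uniform non-overlapping placement keeping clear of every TSS."""
    tss_by_chrom: dict[str, np.ndarray] = {}
    for rec in tss:
        tss_by_chrom.setdefault(rec.chrom, [])
        tss_by_chrom[rec.chrom].append(rec.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    chroms = [c for c, _ in config.genome]
    glen = {c: l for c, l in config.genome}
    lengths = np.array([l for _, l in config.genome], dtype=float)
    probs = lengths / lengths.sum()
    llo, lhi = config.enhancer_length_range

    accepted: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    n_placed = 0
    attempts = 0
    max_attempts = 50 * config.n_enhancers
    while n_placed < config.n_enhancers:
        if attempts >= max_attempts:
            raise ValueError(
                "could not place all enhancers: genome too small for "
                "n_enhancers with the given tss_exclusion"
            )
        attempts += 1
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        length = int(rng.integers(llo, lhi + 1))
        if glen[chrom] <= length:
            continue
        start = int(rng.integers(0, glen[chrom] - length))
        end = start + length
        positions = tss_by_chrom.get(chrom)
        if positions is not None and len(positions):
            i = np.searchsorted(positions, start - config.tss_exclusion)
            j = np.searchsorted(positions, end + config.tss_exclusion)
            if j > i:  # a TSS within the exclusion zone
                continue
        clash = any(s < end and e > start for s, e in accepted[chrom])
        if clash:
            continue
        accepted[chrom].append((start, end))
        n_placed += 1

    out: list[GenomicInterval] = []
    flat = sorted(
        (chrom, s, e) for chrom, ivs in accepted.items() for s, e in ivs
    )
    for k, (chrom, s, e) in enumerate(flat):
        out.append(GenomicInterval(chrom, s, e, id=f"E{k + 1:06d}"))
    return out


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full paired cohort; identical seed gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    tss = _place_tss(config, rng)
    loci = _place_enhancers(config, tss, rng)
    locus_ids = [iv.id for iv in loci]
    lengths = pd.Series([iv.length for iv in loci], index=locus_ids, name="length")

    patients = [f"P{j + 1:02d}" for j in range(config.n_pairs)]
    manifest = PairManifest([(p, f"{p}_N", f"{p}_T") for p in patients])
    sample_ids = [s for _, n, t in manifest for s in (n, t)]

    n_loci, n_pairs = config.n_enhancers, config.n_pairs
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_loci)
    # independent within-pair noise per sample: latent = baseline + noise
    noise = rng.normal(0.0, config.pair_noise_log2_sd, size=(n_loci, 2 * n_pairs))
    latent = baseline[:, None] + noise  # columns ordered P01_N, P01_T, ...

    # plant effects: shift the tumor column of each supporting pair
    available = rng.permutation(n_loci)
    cursor = 0
    truth_rows = []
    for spec in config.planted:
        chosen = available[cursor : cursor + spec.n_loci]
        cursor += spec.n_loci
        sign = 1.0 if spec.direction == "gain" else -1.0
        for li in chosen:
            supp = rng.choice(n_pairs, size=spec.recurrence_design, replace=False)
            for j in supp:
                latent[li, 2 * j + 1] += sign * spec.effect_log2fc
            iv = loci[li]
            gene = nearest_tss(iv, tss)
            truth_rows.append(
                {
                    "locus_id": iv.id,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "direction": spec.direction,
                    "effect_log2fc": spec.effect_log2fc,
                    "recurrence_design": spec.recurrence_design,
                    "supporting_pairs": ",".join(
                        sorted(patients[j] for j in supp)
                    ),
                    "proximal_gene": gene.gene_id or "unassigned",
                    "couple_expression": spec.couple_expression,
                    "expression_log2fc": sign * spec.expression_log2fc,
                }
            )
    truth_columns = [
        "locus_id",
        "chrom",
        "start",
        "end",
        "direction",
        "effect_log2fc",
        "recurrence_design",
        "supporting_pairs",
        "proximal_gene",
        "couple_expression",
        "expression_log2fc",
    ]
    truth = pd.DataFrame(truth_rows, columns=truth_columns)
    truth = truth.sort_values("locus_id").reset_index(drop=True)

    lib_lo, lib_hi = config.library_size_range
    library_sizes = pd.Series(
        rng.integers(lib_lo, lib_hi + 1, size=2 * n_pairs),
        index=sample_ids,
        name="library_size",
    )

    # expected count so that the latent value is the expected log2 RPKM
    kb = lengths.to_numpy(dtype=float)[:, None] / 1000.0
    millions = library_sizes.to_numpy(dtype=float)[None, :] / 1e6
    mu = np.exp2(latent) * kb * millions
    if config.count_model == "poisson":
        counts_arr = rng.poisson(mu)
    else:
        disp = config.nb_dispersion
        if disp == 0:
            counts_arr = rng.poisson(mu)
        else:
            # gamma-poisson: var = mu + disp * mu^2
            shape = 1.0 / disp
            counts_arr = rng.poisson(rng.gamma(shape, mu / shape))
    counts = pd.DataFrame(counts_arr, index=locus_ids, columns=sample_ids)
    counts.index.name = "locus_id"

    # per-sample peak files; default detection_quantile 0 keeps every locus
    rpkm = counts.to_numpy(dtype=float) / (kb * millions)
    peaksets = []
    for si, sid in enumerate(sample_ids):
        col = rpkm[:, si]
        if config.detection_quantile > 0:
            cut = np.quantile(col, config.detection_quantile)
            keep = col > cut
        else:
            keep = np.ones(n_loci, dtype=bool)
        condition = "normal" if sid.endswith("_N") else "tumor"
        peaksets.append(
            PeakSet(
                sample_id=sid,
                condition=condition,
                intervals=[iv for iv, k in zip(loci, keep) if k],
                source_dialect="bed3",
            )
        )

    expression = _expression_table(config, truth, tss, rng)

    return CohortBundle(
        config=config,
        peaksets=peaksets,
        counts=counts,
        lengths=lengths,
        library_sizes=library_sizes,
        manifest=manifest,
        tss=tss,
        expression=expression,
        truth=truth,
        catalog_intervals=loci,
    )


def _expression_table(
    config: CohortConfig,
    truth: pd.DataFrame,
    tss: list[TSSRecord],
    rng: np.random.Generator,
) -> pd.DataFrame:
    gene_ids = [r.gene_id for r in tss]
    log2fc = rng.normal(0.0, 0.2, size=len(gene_ids))
    padj = rng.uniform(0.0, 1.0, size=len(gene_ids))
    expr = pd.DataFrame({"gene_id": gene_ids, "log2FC": log2fc, "padj": padj})
    expr = expr.set_index("gene_id")
    coupled = truth[truth["couple_expression"] & (truth["proximal_gene"] != "unassigned")]
    # first planted locus claiming a gene wins (rare collisions)
    seen: set[str] = set()
    for row in coupled.itertuples():
        g = row.proximal_gene
        if g in seen:
            continue
        seen.add(g)
        expr.loc[g, "log2FC"] = row.expression_log2fc
        expr.loc[g, "padj"] = 1e-6
    return expr.reset_index()


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(bundle: CohortBundle, out_dir: str | Path, force: bool = False) -> Path:
    """Write the cohort directory layout.

    peaks/<sample>.bed (BED4 with locus ids), counts.tsv, libsizes.tsv,
    pairs.tsv, tss.tsv, expression.tsv, truth.tsv. Refuses a non-empty
    target unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True to overwrite"
        )
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    for ps in bundle.peaksets:
        write_regions(ps.intervals, out / "peaks" / f"{ps.sample_id}.bed", with_ids=True)
    bundle.counts.to_csv(out / "counts.tsv", sep="\t")
    bundle.library_sizes.rename_axis("sample_id").to_frame().to_csv(
        out / "libsizes.tsv", sep="\t"
    )
    write_pair_manifest(bundle.manifest, out / "pairs.tsv")
    write_tss_table(bundle.tss, out / "tss.tsv")
    bundle.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return out


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"locus_id": str, "proximal_gene": str})


def read_cohort_dir(cohort_dir: str | Path) -> dict:
    """Read a written cohort back into in-memory pieces for the caller."""
    from .genomic_core import read_pair_manifest, read_regions, read_tss_table

    d = Path(cohort_dir)
    counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col=0)
    libsizes = pd.read_csv(d / "libsizes.tsv", sep="\t", index_col=0)[
        "library_size"
    ]
    manifest = read_pair_manifest(d / "pairs.tsv")
    tss = read_tss_table(d / "tss.tsv")
    condition = {}
    for p, n, t in manifest:
        condition[n] = "normal"
        condition[t] = "tumor"
    peaksets = [
        read_regions(p, dialect="auto", condition=condition.get(p.stem, "unknown"))
        for p in sorted((d / "peaks").glob("*.bed"))
    ]
    expression = None
    if (d / "expression.tsv").exists():
        expression = pd.read_csv(d / "expression.tsv", sep="\t")
    truth = None
    if (d / "truth.tsv").exists():
        truth = read_truth_table(d / "truth.tsv")
    return {
        "counts": counts,
        "library_sizes": libsizes,
        "manifest": manifest,
        "tss": tss,
        "peaksets": peaksets,
        "expression": expression,
        "truth": truth,
    }
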