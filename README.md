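# velscan

Paired tumor/normal H3K27ac variant-enhancer-locus (VEL) analysis.

H3K27ac ChIP-seq marks active enhancers. When tumor and adjacent normal
tissue from the same patient are profiled, enhancers whose acetylation
changes strongly within a pair point at regulatory rewiring in the tumor.
`velscan` implements the full calling procedure for a paired cohort:

1. **Distal enhancer catalog** — peaks farther than a distance *D*
   (default 2.5 kb) from every annotated TSS are union-merged across
   samples into a catalog of non-overlapping loci with stable ids; signal
   per locus is quantified as RPKM
   (count / (length<sub>kb</sub> · library-size<sub>millions</sub>)).
2. **Per-pair VEL calls** — for patient *i*, locus *e* is a **gain VEL**
   when (RPKM<sub>tumor</sub> + ε)/(RPKM<sub>normal</sub> + ε) ≥ τ and a
   **lost VEL** when the reciprocal ratio passes the same threshold
   (τ = 2, inclusive; ε = 0.5 RPKM).
3. **Recurrence statistics** — per-pair VELs are merged into one
   coordinate file per direction; each merged locus gets a recurrence
   *r* = number of supporting patients, a p-value
   P(R ≥ r) where R = Σ<sub>i</sub> Bernoulli(p<sub>i</sub>) is
   Poisson-binomial over the empirically observed per-pair call rates
   p<sub>i</sub> (exact O(n²) convolution), and a Benjamini–Hochberg
   adjusted p within its direction.
4. **Threshold calibration** — the recurrence cut-off r\* is the smallest
   *r* for which ≥ 85 % of loci at recurrence ≥ r have padj ≤ α
   (α = 0.05); a locus is significant when padj ≤ α **and** r ≥ r\*.
5. **Downstream integration** — proximal-gene (nearest-TSS) assignment,
   DEG classification (|log2FC| ≥ 1, padj ≤ 0.01) and VEL–DEG overlap
   with a hypergeometric test, marker-gene high/low cohort stratification
   with group-wise signal averaging, and catalog-vs-catalog overlap
   reports.

Because real paired patient data of this kind is restricted-access, the
package ships a first-class synthetic cohort generator
(`velscan.synthetic_cohort`) that emulates the study design — a shared
log-normal enhancer landscape, within-pair log2 noise, Poisson or
negative-binomial counts given library size, and planted gain/lost VELs
with configured effect size and patient recurrence — together with the
ground truth needed to score the caller.

## Worked example

Simulate the reference cohort (20 pairs, 5000 enhancers, 200 gain and 200
lost VELs planted at log2 effect 2 in 8 of 20 pairs), call VELs, and score
the calls against the planted truth:

```bash
velscan simulate --out demo_cohort --seed 7
# cohort written to demo_cohort: 20 pairs, 5000 enhancers, planted {'gain': 200, 'lost': 200}

velscan call --cohort demo_cohort --out demo_results
# catalog 5000 loci; gain 1540 merged / 205 significant (r*=3);
# lost 1609 merged / 204 significant (r*=3)

velscan evaluate --results demo_results --truth demo_cohort/truth.tsv
```

```json
{
  "gain": {
    "n_planted": 200, "n_calls": 205, "n_recovered": 200,
    "sensitivity": 1.0, "empirical_fdr": 0.0244,
    "median_recurrence_error": 0.0
  },
  "lost": {
    "n_planted": 200, "n_calls": 204, "n_recovered": 199,
    "sensitivity": 0.995, "empirical_fdr": 0.0245,
    "median_recurrence_error": 0.0
  }
}
```

Reading this: of 1540 merged gain loci, 205 pass padj ≤ 0.05 at the
calibrated recurrence threshold r\* = 3; all 200 planted gains are among
them (sensitivity 1.0) and 5 calls are background (empirical FDR 0.024).
The median difference between called recurrence and the designed 8
supporting pairs is 0. `demo_results/report.json` records the resolved
parameters, per-pair background rates and per-stage counts.

The same machinery is available as library calls — see
`velscan.call_vels`, `velscan.simulate_cohort` and
`velscan.pipeline.run_call`.

## Layout of a cohort directory

```
cohort/
  peaks/<sample>.bed   # BED4, locus id in column 4
  counts.tsv           # loci x samples raw counts
  libsizes.tsv         # sample id, total mapped reads
  pairs.tsv            # patient_id, normal_sample_id, tumor_sample_id
  tss.tsv              # gene_id, chrom, tss, strand
  expression.tsv       # gene_id, log2FC, padj
  truth.tsv            # planted loci (synthetic cohorts only)
```
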