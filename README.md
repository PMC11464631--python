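# ctmon — tumour-informed ctDNA monitoring from UMI-tagged sequencing

`ctmon` implements the analysis core of tumour-informed liquid-biopsy
monitoring: a per-patient panel of up to 30 somatic variants (selected from
tumour–normal sequencing) is followed in plasma cell-free DNA across
treatment, using ultra-deep targeted sequencing (~100,000× raw) with unique
molecular identifiers (UMIs).  The toolkit is aimed at method developers and
bioinformaticians who need a tested, reproducible reference implementation
of each analysis stage, exercisable end to end on synthetic UMI-tagged reads
with known ground truth.

## What it computes

1. **UMI consensus error correction.**  Reads sharing a (corrected) UMI and
   mapping position are copies of one cfDNA molecule.  Strict-majority
   consensus per family suppresses substitution errors, stratified by
   correction level: 2-fold, 3-fold and 4-fold (families with ≥ 4 copies);
   singletons are discarded.  UMI errors are absorbed by a directional
   Hamming-distance-1 merge.
2. **Beta-binomial background models.**  For every nucleotide change
   (12 types) and correction level, background alt counts at variant-free
   panel positions are fitted with a beta-binomial
   (overdispersed binomial, P(k | n, α, β)), by a depth-weighted method of
   moments with a pseudo-prior fallback for sparse strata.
3. **Ultra-sensitive detection.**  Each monitored variant's alt count is
   scored per level with an inclusive upper tail P(X ≥ altC); levels are
   integrated with Fisher's method and pooled into altC, depth and
   MAF = altC/depth.  A variant is *detected* at p < 0.05; Benjamini–
   Hochberg FDR is reported across the sample's assessable variants.
4. **Sample positivity.**  Palliative setting: ctDNA-positive when the
   residual-tumour p-value (Fisher over all assessable variants) is < 0.05.
   Adjuvant setting: positive when ≥ 3 variants are individually detected.
   Germline fingerprint SNVs verify sample identity.
5. **Longitudinal monitoring.**  Per timepoint: quality filters (consensus
   depth < 1000×, indels, MAF > mean + 3 SD outliers), mean variant AF,
   T0/T1/T2 timepoint assignment, and ascending/descending dynamics
   (later − earlier ≥ 0 ⇒ `asc`, i.e. stable counts as ascending).
   Biomarker correlation (S100, LDH, PET MTV/TLG) aggregates to one value
   per patient and uses Spearman's rho with the t-transformation
   t = ρ·√((n−2)/(1−ρ²)), df = n − 2 patients.
6. **Synthetic data.**  A simulator of the whole regime — family-size
   distributions tuned to the 100,000× → ~6,000× dedup ratio, substitution
   errors, spiked variants at AF 0.01 %–5 %, multi-timepoint responder and
   progressor courses — so every stage can be validated against ground
   truth.

## Worked example

Run the built-in simulated cohort (one responder R01, one progressor P02,
one relapsing adjuvant patient AR03, one tumour-free adjuvant patient AF04;
three timepoints each):

```sh
ctmon run --seed 11 --out-dir run
```

`run/monitoring.tsv` then contains (excerpt):

```
patient  cohort      sample     timepoint  mean_AF       n_variants_used  positive  dynamics_from_previous
R01      palliative  R01_d000   T0         0.020252973   10               True
R01      palliative  R01_d021   T1         0.0020766951  10               False     desc
R01      palliative  R01_d084   T2         0             10               False     desc
P02      palliative  P02_d000   T0         0.018723846   10               True
P02      palliative  P02_d021   T1         0.08197483    10               True      asc
P02      palliative  P02_d084   T2         0.318594      10               True      asc
AR03     adjuvant    AR03_d084  T2         0.076081658   10               True      asc
AF04     adjuvant    AF04_d084  T2         0             10               False     asc
```

Reading it: the responder's mean variant allele fraction collapses from
~2 % to undetectable (`desc` dynamics, ctDNA-negative at T2), the
progressor's burden rises ~16× with `asc` dynamics and stays positive, the
adjuvant relapse becomes detectable at day 21, and the tumour-free adjuvant
patient is negative at every timepoint — no false-positive sample.
`run/correlations.tsv` reports the Spearman/t statistics of mean AF against
the simulated S100 biomarker (with only 4 patients the rank correlation is
degenerate at ρ = 1 and flagged accordingly; the statistic is meaningful on
larger cohorts).  Per-sample pileups, error models, calls and summaries are
under `run/pileups/`, `run/models/` and `run/calls/`.

The same stages are available individually (`ctmon simulate`,
`ctmon consensus`, `ctmon fit-error-model`, `ctmon call`, `ctmon monitor`)
and as library functions.

## Layout

| module | contents |
| --- | --- |
| `ctmon.simdata` | simulation configs, read/family generator, patient courses, count-level generators, BAM/FASTA export |
| `ctmon.consensus` | UMI grouping and correction, strict-majority consensus, level pileups, error-rate measurement |
| `ctmon.errormodel` | beta-binomial fitting, tail p-values, Fisher level integration, model TSV I/O |
| `ctmon.detection` | variant calls, residual-tumour p, cohort positivity rules, fingerprint QC, panel selection, VCF I/O |
| `ctmon.monitor` | timepoint filters, mean AF, dynamics, pseudo-count log transform, Spearman/t correlations, biomarker matching |
| `ctmon.pipeline` / `ctmon.cli` | end-to-end orchestration, run report, QC flags, `ctmon` command |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
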