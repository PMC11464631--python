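# Methods

## Setting and model

Tumour-informed plasma monitoring follows a per-patient panel of somatic
variants in cell-free DNA.  At the allele fractions of interest
(10⁻⁴–10⁻²) raw sequencing error dominates the signal, so the analysis is
built on two error-suppression layers:

1. **Molecular consensus.**  Every original cfDNA molecule is tagged with a
   fixed single-stranded UMI before amplification; all reads sharing a
   corrected UMI and mapping position form a *family*.  A family of k ≥ 2
   copies emits a consensus base when one base holds a strict majority
   (> 50 % of members); discordant families and singletons emit nothing.
   Consensus calls are stratified by *correction level* — 2-fold (k = 2),
   3-fold (k = 3), 4-fold (k ≥ 4) — because the residual error rate falls
   steeply with k: for iid substitution error e per read base, a 2-fold
   family is wrong only when both copies carry the same substitution
   (≈ e²/3), a 4-fold family needs three identical errors.  At e = 10⁻³
   this predicts residual rates of ≈ 3×10⁻⁷ (2-fold) and ≈ 10⁻⁹ (4-fold),
   far below the 10⁻³–10⁻² detection targets.
2. **Beta-binomial null.**  Residual consensus errors vary between sites
   and runs, so alt counts at background positions are modelled per
   nucleotide change s and level ℓ as beta-binomial:
   X | n ~ Binomial(n, p), p ~ Beta(α, β).  The null hypothesis for a
   monitored variant is scored with the inclusive upper tail
   p = P(X ≥ altC | n, α̂, β̂).

Per-level p-values are combined with Fisher's method over the levels with
coverage (χ² with 2k df; a single contributing level reproduces its own
p-value exactly), and counts pool additively into altC, depth and
MAF = altC/depth.  The sample-level residual-tumour p-value is Fisher's
method over the assessable monitored variants (Stouffer and Bonferroni
min-p are available alternatives behind a flag; Fisher is the default).

## UMI grouping

UMIs at one position are merged when within Hamming distance 1,
directionally: the smaller family adopts the larger family's UMI, ties
resolved to the lexicographically smaller sequence, chains followed to
their root.  Candidate neighbours are found by single-base-edit lookup
(O(3·L) per UMI), so grouping a million families is vectorised and cheap.
Mapping position is the 5′-most aligned reference coordinate; strand is
ignored (the UMIs are single-stranded, not duplex).  Base qualities are
retained in I/O but do not enter the count-based consensus.

## Error-model fitting

Per (substitution, level) stratum with site depths nᵢ and alt counts kᵢ
(sites with depth < 100 ignored; ≥ 20 usable sites required):

* depth-weighted mean m = Σkᵢ / Σnᵢ and depth-weighted variance v of the
  per-site fractions kᵢ/nᵢ;
* intra-class correlation ρ = (v − m(1−m)/n̄) / (m(1−m)(1 − 1/n̄)) with n̄
  the mean depth; then α = m(1−ρ)/ρ, β = (1−m)(1−ρ)/ρ (`moments`).

When the stratum is sparse, all-zero, or not genuinely overdispersed
(v ≤ binomial variance, or ρ below a 10⁻⁹ floor), a deterministic
pseudo-prior of strength s = 1000 is used instead: α = m·s + 0.5,
β = (1−m)·s + 0.5 (`pseudo-prior`), with m replaced by the level's pooled
mean — or by a pooled pseudo-count 0.5/Σnᵢ when even the pooled counts are
zero.  Strata with no observations at all inherit the level's pooled mean
(`pooled-fallback`).  The fallback deliberately errs conservative: on
ultra-clean backgrounds the +0.5 pseudo-count raises the null mean above
the empirical rate, costing a little sensitivity rather than specificity.
Monitored positions are always excluded from training (signal would leak
into the null).

Tail probabilities are computed from a log-space pmf recurrence,
log pmf(k+1) − log pmf(k) = log((n−k)(α+k)) − log((k+1)(β+n−k−1)),
cumulated in log space from the upper end.  This avoids differences of
log-gamma values at huge arguments — the naive betaln form loses ~10⁻⁶
relative precision once α+β reaches 10⁹ — and keeps full relative
precision in tiny tails.  P(X ≥ 0) is exactly 1.

## Decision rules and thresholds

| parameter | default | origin |
| --- | --- | --- |
| per-variant detection threshold | p < 0.05 | published rule |
| adjuvant sample positivity | ≥ 3 variants detected | published rule |
| palliative sample positivity | residual-tumour p < 0.05 | published rule |
| monitoring depth filter | consensus depth (levels ≥ 2) < 1000× | published rule |
| MAF outlier filter | > mean + 3 SD at the timepoint, single pass | published rule |
| indels | excluded from monitoring statistics | published rule |
| correlation eligibility | ≥ 3 analysable variants per sample | published rule |
| timepoint windows | T0 ± 7 d of treatment start, T1 ± 7 d of second course, T2 ± 21 d of follow-up PET | published design |
| biomarker windows | S100/LDH ± 7 d, MTV/TLG ± 21 d | published design |
| fingerprint genotyping | AF < 0.1 hom-ref, 0.1–0.9 het, > 0.9 hom-alt; pass ≥ 0.90 concordance over ≥ 10 SNVs with depth ≥ 100 | package choice |
| panel filters | homopolymer run ≥ 6, population AF > 10⁻³, off-target; drivers first, then tumour AF descending, top 30 | thresholds are package choices, structure published |
| fragment-size QC band | median 140–200 bp | package choice (mononucleosomal cfDNA) |

The timepoint-change rule groups *stable with ascending* (`asc` iff
later − earlier ≥ 0), matching the published grouping of "ascending or
stable" trajectories; a sample inside several timepoint windows takes the
nearer anchor, ties to the earlier label.  For plotting on log axes, zeros
are replaced by half the minimum non-zero value before log₁₀.

Spearman correlations aggregate matched (mean AF, biomarker) pairs to one
mean pair per patient before ranking — repeated samples of a patient are
not independent — and report t = ρ·√((n−2)/(1−ρ²)) with df = n − 2
patients, two-sided.  |ρ| = 1 is reported as degenerate (t infinite,
p = 0 flagged) rather than silently extrapolated.

## Synthetic data: what it emulates, and what not

The read-level generator reproduces the structure the statistics rely on:
molecules per position (raw depth / mean family size), a configurable
family-size law, per-copy iid substitution errors (uniform over the three
alternatives by default, or per-substitution rates), spiked variants by
true AF, unique-per-position UMIs of length 12, and multi-timepoint
courses with responder (AF ×1 → ×0.1 → 0) and progressor (×1 → ×4 → ×16)
templates.  The default family-size law is a shifted negative binomial
(1 + NB(r = 0.8, µ = 14); E[size] = 15, P(singleton) ≈ 0.10) tuned
analytically so that ~100,000× raw coverage collapses to ~6,000× consensus
depth after singleton exclusion, the regime of the study design.  The
published raw-to-dedup depth ratio and a separately quoted read-duplication
fraction cannot both hold under any single-size law; the depth ratio, which
the statistics depend on, was kept.

Reads are single-position observations (pileup semantics): the method
consumes per-position counts, so fragment extent, quality ramps, adapters
and alignment artefacts are deliberately out of scope.  Errors are
substitution-only; UMI collisions are off by default (a flag enables
them).  Consequently, passing tests demonstrate the correctness of the
statistical machinery under its stated model — not robustness to mapping
error, strand bias, FFPE damage spectra or duplex-resolvable artefacts,
none of which the simulator produces.

A count-level generator (`simulate_pileup`, `simulate_site_observations`)
draws consensus counts directly from the binomial/beta-binomial process.
It exists for calibration, power and positivity-rule studies where
read-level simulation adds nothing but runtime; the read-level path remains
the reference route and the two agree on shared statistics (tested).

## Numerical and design choices

* Strict-majority consensus with discard on no-majority maximises
  specificity; for 2-copy families it coincides with requiring unanimity.
* Families of ≥ 4 copies all pool into the 4-fold level.
* The single-pass outlier filter computes mean and SD over the variants
  surviving the depth and indel filters, *including* the outlier candidate
  itself; depth and indel filters commute, the outlier filter runs last.
* The moment fit's overdispersion floor (ρ > 10⁻⁹) and the pseudo-prior
  strength (s = 1000) are deterministic tie-breaks, not tuned quantities.
* Correlation eligibility ("three analysable variants") is interpreted as
  assessable-by-depth, not detected — detection-conditioning would bias
  mean AF upward at low burden.
* Null-calibration studies use a total background error of 2×10⁻⁴
  (split evenly across the three alternatives) with intra-class
  correlation ρ = 10⁻⁴ — "mild" overdispersion on the scale of the
  study's reported error rates; at depth 5000 this puts the p < 0.05
  detection boundary at alt counts ≥ 3 with a true tail mass of ~0.02,
  so the per-variant false-positive rate is conservative by construction
  of the discrete test.
* Problem sizes in tests and the acceptance script are chosen to make every
  stochastic check well-powered at desk scale: ≥ 10⁶ consensus bases for
  error-rate bounds, 10⁴ training + 2×10³ held-out sites for calibration,
  100 seeded courses for rule-recovery, and a 4-patient × 3-timepoint
  default cohort (raw depth 20,000×, 10-variant panels) for the end-to-end
  determinism contract.  The consensus-level *strict* separation test runs
  at raw error 0.03, where the 2-fold and 4-fold rates (≈ 3×10⁻⁴ vs
  ≈ 10⁻⁵) are separable at three binomial standard errors with 10⁶
  families; at the study's raw error of 10⁻³ both residual rates are
  below 10⁻⁶ and only the ≤ ordering and the absolute bounds (< 0.1 %,
  < 0.01 %) are empirically decidable.

## Known limitations

* No duplex (double-strand) consensus; fixed single-stranded UMIs only.
* No local realignment or overlapping-mate handling; input is taken as
  aligned and pre-processed.
* Indels are carried through calling but never scored from the SNV pileup;
  monitoring statistics exclude them by design.
* The beta-binomial null is per nucleotide change and level but not
  strand- or sequence-context-specific.
* Survival modelling is out of scope: the package exports positivity and
  asc/desc group labels for standard survival packages.
* With very few patients the rank correlation degenerates (|ρ| = 1);
  results are flagged, not suppressed.
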