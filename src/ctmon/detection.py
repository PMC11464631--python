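"""Per-variant calls, sample-level residual-tumour p-value and positivity.

A tumour-informed panel monitors up to 30 patient-specific somatic variants
in plasma.  For each monitored variant, per-level alt counts are extracted
from the level pileup, scored against the matching beta-binomial null and
integrated over correction levels; a variant is *detected* when its
combined p-value falls below 0.05.  Benjamini-Hochberg FDR is computed
across the sample's assessable monitored variants.

Sample-level positivity depends on the clinical setting:

* palliative — positive when the residual-tumour p-value (Fisher's method
  over all assessable variants) is < 0.05;
* adjuvant — positive when at least 3 variants are individually detected,
  trading sensitivity for near-perfect specificity in tumour-free patients.

Germline fingerprint SNVs verify that a plasma sample belongs to the
patient; they never enter tumour-burden statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .consensus import LEVELS
from .errormodel import (ErrorModel, bb_tail_pvalue, combine_levels,
                         fisher_combine)

DETECTION_P = 0.05
ADJUVANT_MIN_DETECTED = 3
FINGERPRINT_PASS = 0.90
FINGERPRINT_MIN_SNVS = 10
FINGERPRINT_MIN_DEPTH = 100
PANEL_MAX_VARIANTS = 30
MAX_POPULATION_AF = 1e-3
MIN_HOMOPOLYMER_RUN = 6

CALLS_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "variant_class",
    "level2_altC", "level2_depth", "level3_altC", "level3_depth",
    "level4_altC", "level4_depth",
    "altC", "depth", "MAF", "p", "fdr", "detected", "assessable", "reason",
]


@dataclass(frozen=True)
class MonitoredVariant:
    """One panel entry: a monitored somatic variant or a fingerprint SNV."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = "SNV"       # SNV | indel | promoter-SNV
    role: str = "monitored"          # monitored | fingerprint
    tumour_af: float | None = None
    driver: bool = False
    population_af: float | None = None
    germline_genotype: str | None = None  # fingerprint expectation: 0/0, 0/1, 1/1

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class VariantCall:
    """Integrated per-sample statistics of one monitored variant."""

    variant: MonitoredVariant
    alt_count: int = 0
    depth: int = 0
    maf: float = float("nan")
    p: float = float("nan")
    fdr: float = float("nan")
    detected: bool = False
    assessable: bool = False
    reason: str = ""
    level_stats: dict[int, tuple[int, int, float]] = field(default_factory=dict)

    @property
    def depth_ge2(self) -> int:
        """Pooled depth over correction levels >= 2 (all of them)."""
        return self.depth


@dataclass
class FingerprintResult:
    concordance: float
    n_used: int
    passed: bool
    assessable: bool


@dataclass
class SampleResult:
    sample_id: str
    cohort: str
    calls: list[VariantCall]
    residual_tumour_p: float
    n_detected: int
    n_assessable: int
    ctdna_positive: bool
    qc: dict

    def summary(self) -> dict:
        return {
            "sample": self.sample_id,
            "cohort": self.cohort,
            "residual_tumour_p": self.residual_tumour_p,
            "n_detected": self.n_detected,
            "n_assessable": self.n_assessable,
            "ctdna_positive": bool(self.ctdna_positive),
            "qc": self.qc,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# variant calling


def _level_counts(pileup: pd.DataFrame, variant: MonitoredVariant):
    """(level, alt_count, depth) per correction level at the variant site."""
    site = pileup[(pileup["chrom"] == variant.chrom) & (pileup["pos"] == variant.pos)]
    out = []
    for level in LEVELS:
        row = site[site["level"] == level]
        if row.empty:
            out.append((level, 0, 0))
        else:
            r = row.iloc[0]
            out.append((level, int(r[f"n{variant.alt}"]), int(r["depth"])))
    return out


def call_variants(pileup: pd.DataFrame, panel: Sequence[MonitoredVariant],
                  model: ErrorModel, *, alpha: float = DETECTION_P
                  ) -> list[VariantCall]:
    """Score every monitored panel variant against the background model.

    Per level the alt count is tested with the matching (substitution,
    level) beta-binomial null; levels integrate by Fisher's method and
    pooled counts.  ``detected`` means combined p < ``alpha``; FDR is
    Benjamini-Hochberg across the sample's assessable monitored variants.
    Indels and sites absent from the pileup are reported non-assessable.
    """
    calls = []
    for variant in panel:
        if variant.role != "monitored":
            continue
        call = VariantCall(variant=variant)
        if variant.variant_class == "indel":
            call.reason = "indel: not scored from SNV pileup"
            calls.append(call)
            continue
        stats = _level_counts(pileup, variant)
        per_level = []
        for level, alt, depth in stats:
            if depth > 0:
                p = bb_tail_pvalue(alt, depth, model.get(variant.substitution, level))
            else:
                p = float("nan")
            per_level.append((level, alt, depth, p))
            call.level_stats[level] = (alt, depth, p)
        combined = combine_levels(per_level)
        if not combined.assessable:
            call.reason = "no consensus coverage at variant position"
            calls.append(call)
            continue
        call.alt_count = combined.alt_count
        call.depth = combined.depth
        call.maf = combined.maf
        call.p = combined.p
        call.assessable = True
        call.detected = combined.p < alpha
        calls.append(call)

    assessable = [c for c in calls if c.assessable]
    if assessable:
        _, fdrs, _, _ = multipletests([c.p for c in assessable], method="fdr_bh")
        for c, q in zip(assessable, fdrs):
            c.fdr = float(q)
    return calls


def residual_tumour_p(calls: Sequence[VariantCall], *,
                      method: str = "fisher") -> float:
    """Sample-level p-value that no tumour signal is present.

    Combines the assessable monitored variants' p-values.  ``fisher`` is
    the default; ``stouffer`` (unweighted z-average) and ``bonferroni``
    (min-p with correction) are available alternatives.
    """
    ps = [c.p for c in calls if c.assessable]
    if not ps:
        raise ValueError("no assessable variants: residual tumour p undefined")
    if method == "fisher":
        return fisher_combine(ps)
    if method == "stouffer":
        z = sum(norm.isf(min(p, 1 - 1e-16)) for p in ps) / math.sqrt(len(ps))
        return float(norm.sf(z))
    if method == "bonferroni":
        return float(min(1.0, min(ps) * len(ps)))
    raise ValueError(f"unknown combination method {method!r}")


def classify_sample(calls: Sequence[VariantCall], cohort: str, *,
                    residual_p: float | None = None,
                    alpha: float = DETECTION_P,
                    min_detected: int = ADJUVANT_MIN_DETECTED) -> bool:
    """Cohort-specific ctDNA positivity decision.

    palliative: positive iff the residual-tumour p-value < ``alpha``.
    adjuvant:   positive iff >= ``min_detected`` variants are detected.
    Pure function of its inputs; repeated invocation is identical.
    """
    if cohort == "palliative":
        if residual_p is None:
            residual_p = residual_tumour_p(calls)
        return residual_p < alpha
    if cohort == "adjuvant":
        return sum(1 for c in calls if c.detected) >= min_detected
    raise ValueError(f"unknown cohort {cohort!r}; expected palliative or adjuvant")


def summarize_sample(sample_id: str, calls: Sequence[VariantCall], cohort: str,
                     *, qc: Mapping | None = None) -> SampleResult:
    """Bundle calls into a :class:`SampleResult` with positivity and QC."""
    n_assessable = sum(1 for c in calls if c.assessable)
    n_detected = sum(1 for c in calls if c.detected)
    try:
        rp = residual_tumour_p(calls)
    except ValueError:
        rp = float("nan")
    positive = (classify_sample(calls, cohort, residual_p=rp)
                if n_assessable else False)
    return SampleResult(
        sample_id=sample_id, cohort=cohort, calls=list(calls),
        residual_tumour_p=rp, n_detected=n_detected,
        n_assessable=n_assessable, ctdna_positive=positive,
        qc=dict(qc or {}))


# ---------------------------------------------------------------------------
# fingerprint concordance


def genotype_from_af(af: float) -> str:
    """Bin a plasma allele fraction into a diploid genotype call."""
    if af < 0.1:
        return "0/0"
    if af <= 0.9:
        return "0/1"
    return "1/1"


def check_fingerprint(plasma: pd.DataFrame,
                      genotypes: Mapping[str, str], *,
                      min_snvs: int = FINGERPRINT_MIN_SNVS,
                      min_depth: int = FINGERPRINT_MIN_DEPTH,
                      pass_threshold: float = FINGERPRINT_PASS
                      ) -> FingerprintResult:
    """Compare plasma genotypes at fingerprint SNVs to the germline truth.

    ``plasma`` needs columns ``snv, af, depth``; ``genotypes`` maps the SNV
    key to the expected germline genotype.  SNVs below ``min_depth`` are
    ignored; fewer than ``min_snvs`` usable SNVs leaves the check not
    assessable.  Concordance >= ``pass_threshold`` (inclusive) passes.
    """
    usable = plasma[plasma["depth"] >= min_depth]
    usable = usable[usable["snv"].isin(genotypes)]
    n = len(usable)
    if n < min_snvs:
        return FingerprintResult(float("nan"), n, False, False)
    match = sum(
        genotype_from_af(float(row.af)) == genotypes[row.snv]
        for row in usable.itertuples(index=False))
    conc = match / n
    return FingerprintResult(conc, n, conc >= pass_threshold, True)


# ---------------------------------------------------------------------------
# panel selection


def max_homopolymer_run(context: str) -> int:
    """Longest single-base run in a sequence context."""
    best = run = 0
    prev = ""
    for ch in context:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def select_panel(candidates: pd.DataFrame, *,
                 fingerprints: Sequence[MonitoredVariant] = (),
                 max_variants: int = PANEL_MAX_VARIANTS,
                 max_population_af: float = MAX_POPULATION_AF,
                 min_homopolymer: int = MIN_HOMOPOLYMER_RUN,
                 min_candidates_warn: int = 3) -> tuple[list[MonitoredVariant], list[str]]:
    """Build a patient-specific monitoring panel from somatic candidates.

    ``candidates`` needs columns ``chrom, pos, ref, alt, tumour_af, driver,
    population_af, context, on_target`` (``variant_class`` optional).
    Filters: homopolymer run >= ``min_homopolymer`` in the local context,
    off-target sites, population AF > ``max_population_af``.  Survivors are
    ranked drivers first, then by tumour AF (clonality proxy) descending;
    the top ``max_variants`` are kept and fingerprint SNVs appended.

    Returns (panel, warnings); fewer than ``min_candidates_warn`` survivors
    still yields a panel but with a sensitivity warning.
    """
    required = {"chrom", "pos", "ref", "alt", "tumour_af", "driver",
                "population_af", "context", "on_target"}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidates missing columns: {sorted(missing)}")
    keep = []
    for row in candidates.itertuples(index=False):
        if not bool(row.on_target):
            continue
        if row.population_af is not None and float(row.population_af) > max_population_af:
            continue
        if max_homopolymer_run(str(row.context)) >= min_homopolymer:
            continue
        keep.append(row)
    keep.sort(key=lambda r: (-bool(r.driver), -float(r.tumour_af),
                             str(r.chrom), int(r.pos)))
    warnings = []
    if len(keep) < min_candidates_warn:
        warnings.append(
            f"only {len(keep)} monitorable variants survive filtering; "
            "sample-level sensitivity is limited")
    panel = [MonitoredVariant(
        chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
        variant_class=str(getattr(r, "variant_class", "SNV")),
        role="monitored", tumour_af=float(r.tumour_af),
        driver=bool(r.driver), population_af=float(r.population_af),
    ) for r in keep[:max_variants]]
    panel.extend(fingerprints)
    return panel, warnings


# ---------------------------------------------------------------------------
# panel VCF and calls TSV I/O


def write_panel_vcf(panel: Sequence[MonitoredVariant], path, *,
                    contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a panel as VCF 4.2 with ROLE/CLASS INFO keys."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    contigs = contig_lengths or {}
    for chrom in sorted({v.chrom for v in panel}):
        header.contigs.add(chrom, length=contigs.get(chrom, 10_000_000))
    header.info.add("ROLE", 1, "String", "monitored or fingerprint")
    header.info.add("CLASS", 1, "String", "variant class (SNV, indel, promoter-SNV)")
    header.info.add("TUMOUR_AF", 1, "Float", "tumour allele fraction")
    header.info.add("DRIVER", 0, "Flag", "driver mutation")
    header.info.add("GERMLINE_GT", 1, "String", "expected germline genotype")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(panel, key=lambda v: (v.chrom, v.pos)):
            rec = vcf.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            rec.info["ROLE"] = v.role
            rec.info["CLASS"] = v.variant_class
            if v.tumour_af is not None:
                rec.info["TUMOUR_AF"] = v.tumour_af
            if v.driver:
                rec.info["DRIVER"] = True
            if v.germline_genotype is not None:
                rec.info["GERMLINE_GT"] = v.germline_genotype
            vcf.write(rec)


def read_panel_vcf(path) -> list[MonitoredVariant]:
    import pysam

    panel = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            panel.append(MonitoredVariant(
                chrom=rec.contig, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                variant_class=info.get("CLASS", "SNV"),
                role=info.get("ROLE", "monitored"),
                tumour_af=(float(info["TUMOUR_AF"])
                           if "TUMOUR_AF" in info else None),
                driver=bool(info.get("DRIVER", False)),
                germline_genotype=info.get("GERMLINE_GT", None),
            ))
    return panel


def calls_to_frame(sample_id: str, calls: Sequence[VariantCall]) -> pd.DataFrame:
    """Flatten variant calls to the on-disk TSV layout."""
    rows = []
    for c in calls:
        row = {
            "sample": sample_id, "chrom": c.variant.chrom, "pos": c.variant.pos,
            "ref": c.variant.ref, "alt": c.variant.alt,
            "variant_class": c.variant.variant_class,
        }
        for level in LEVELS:
            alt, depth, _ = c.level_stats.get(level, (0, 0, float("nan")))
            row[f"level{level}_altC"] = alt
            row[f"level{level}_depth"] = depth
        row.update({"altC": c.alt_count, "depth": c.depth, "MAF": c.maf,
                    "p": c.p, "fdr": c.fdr, "detected": c.detected,
                    "assessable": c.assessable, "reason": c.reason})
        rows.append(row)
    return pd.DataFrame(rows, columns=CALLS_COLUMNS)
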