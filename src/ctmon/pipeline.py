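"""End-to-end orchestration: simulate -> consensus -> fit -> call -> monitor.

`run_pipeline` executes the full monitoring workflow on a simulated cohort
(or on user-provided family tables) and writes every intermediate artifact:
level pileups, error-model TSVs, per-sample call tables and summaries, the
monitoring table, the correlation report and a machine-readable run report.
Identical configuration and seed give byte-identical primary outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import pileup_from_family_table, write_pileup
from .detection import (ADJUVANT_MIN_DETECTED, DETECTION_P, FINGERPRINT_PASS,
                        MonitoredVariant, calls_to_frame, call_variants,
                        summarize_sample)
from .errormodel import fit_background, observations_from_pileup
from .monitor import (MIN_MONITOR_DEPTH, OUTLIER_SD, TimepointSummary,
                      assign_timepoints, build_course, correlation_report,
                      course_table, filter_timepoint, match_biomarkers,
                      mean_af)
from .simdata import (SimConfig, SimulatedCourse, progressor_template,
                      responder_template, simulate_patient_course)

FRAGMENT_BAND = (140, 200)  # bp: plausible mononucleosomal cfDNA median


@dataclass
class RunConfig:
    """Effective settings of one pipeline run.

    Thresholds default to the published values where the study states them
    (detection p < 0.05, monitoring depth >= 1000x, 3 SD outlier bound,
    adjuvant >= 3 detected variants); the rest are package choices.
    """

    cohort: str = "palliative"
    seed: int = 0
    out_dir: str = "ctmon_run"
    detection_p: float = DETECTION_P
    min_monitor_depth: int = MIN_MONITOR_DEPTH
    outlier_sd: float = OUTLIER_SD
    adjuvant_min_detected: int = ADJUVANT_MIN_DETECTED
    fingerprint_pass: float = FINGERPRINT_PASS
    panel_max_variants: int = 30
    # demo-cohort simulation knobs (scaled-down study regime)
    sim_n_background: int = 30
    sim_raw_depth: int = 20_000
    sim_n_variants: int = 10
    sim_base_af: float = 0.02
    sim_error_rate: float = 1e-3
    sim_n_responders: int = 1
    sim_n_progressors: int = 1
    sim_n_adjuvant_relapse: int = 1
    sim_n_adjuvant_free: int = 1

    def validate(self) -> None:
        if self.detection_p < 0:
            raise ValueError("threshold detection_p must be non-negative")
        for name in ("min_monitor_depth", "outlier_sd",
                     "adjuvant_min_detected", "fingerprint_pass",
                     "panel_max_variants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.cohort not in ("palliative", "adjuvant"):
            raise ValueError(f"unknown cohort {self.cohort!r}")

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        """Hash of the scientific settings (output location excluded, so
        identical analyses hash identically wherever they are written)."""
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class QCReport:
    status: str  # pass | warn | fail
    flags: list[str] = field(default_factory=list)


def qc_sample(*, median_fragment_bp: float | None = None,
              mean_dedup_depth: float | None = None,
              fingerprint_concordance: float | None = None,
              fragment_band: tuple[int, int] = FRAGMENT_BAND,
              min_depth: float = MIN_MONITOR_DEPTH,
              fingerprint_pass: float = FINGERPRINT_PASS) -> QCReport:
    """Sample-level quality control: fragment size, depth, fingerprint.

    The overall status is the worst flag: fingerprint discordance fails the
    sample outright; fragment sizes outside the mononucleosomal band or a
    mean deduplicated depth below the monitoring threshold only warn.
    """
    if median_fragment_bp is None and mean_dedup_depth is None and \
            fingerprint_concordance is None:
        raise ValueError("qc_sample needs at least one metric")
    flags = []
    status = "pass"
    if median_fragment_bp is not None and not (
            fragment_band[0] <= median_fragment_bp <= fragment_band[1]):
        flags.append("fragment size outside expected cfDNA band")
        status = "warn"
    if mean_dedup_depth is not None and mean_dedup_depth < min_depth:
        flags.append("low sequencing depth")
        status = "warn"
    if fingerprint_concordance is not None and \
            fingerprint_concordance < fingerprint_pass:
        flags.append("fingerprint mismatch")
        status = "fail"
    return QCReport(status=status, flags=flags)


# ---------------------------------------------------------------------------
# demo cohort


def _demo_courses(cfg: RunConfig) -> list[SimulatedCourse]:
    """Simulated study cohort: responders, progressors and adjuvant patients."""
    base = SimConfig(
        n_background_positions=cfg.sim_n_background,
        monitored_variants=[
            (cfg.sim_n_background + 1 + i, "C", "T", cfg.sim_base_af)
            for i in range(cfg.sim_n_variants)],
        raw_depth_per_position=cfg.sim_raw_depth,
        error_rates=cfg.sim_error_rate,
        seed=cfg.seed,
    )
    courses = []
    specs = (
        [("R", "palliative", responder_template())] * cfg.sim_n_responders
        + [("P", "palliative", progressor_template())] * cfg.sim_n_progressors
        + [("AR", "adjuvant", progressor_template(multipliers=(0.0, 0.5, 4.0)))]
        * cfg.sim_n_adjuvant_relapse
        + [("AF", "adjuvant", [(0, 0.0), (21, 0.0), (84, 0.0)])]
        * cfg.sim_n_adjuvant_free
    )
    for i, (tag, cohort, template) in enumerate(specs):
        pat_cfg = dataclasses.replace(base, seed=cfg.seed + 1000 + i)
        courses.append(simulate_patient_course(
            template, pat_cfg, patient_id=f"{tag}{i + 1:02d}", cohort=cohort))
    return courses


def _simulated_biomarkers(courses: Sequence[SimulatedCourse],
                          seed: int) -> pd.DataFrame:
    """Per-sample S100-like biomarker proportional to the true tumour burden.

    Emulates the empirical coupling of blood biomarkers to ctDNA burden:
    value = baseline + scale * true mean AF, with log-normal noise.
    """
    rng = np.random.default_rng(seed + 77)
    rows = []
    for course in courses:
        for sample in course.samples:
            true_af = float(sample.truth.variants["true_af"].mean())
            value = (0.05 + 40.0 * true_af) * float(rng.lognormal(0, 0.15))
            rows.append({"patient": course.patient_id,
                         "date": sample.collection_date.isoformat(),
                         "analyte": "S100", "value": round(value, 6)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the run


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow on the configured (simulated) cohort.

    Writes per-sample pileups, error models, calls and summaries plus the
    cohort-level monitoring table, correlation report and ``report.json``
    under ``cfg.out_dir``.  Returns the run report as a dict.
    """
    cfg.validate()
    out = cfg.out_dir
    for sub in ("pileups", "models", "calls"):
        os.makedirs(os.path.join(out, sub), exist_ok=True)

    courses = _demo_courses(cfg)
    biomarkers = _simulated_biomarkers(courses, cfg.seed)
    stage_counts: dict[str, int] = {"patients": len(courses), "samples": 0,
                                    "reads": 0, "consensus_rows": 0,
                                    "variant_calls": 0}
    patient_courses = []
    matched_rows = []
    sample_records = []

    for course in courses:
        panel = [MonitoredVariant(chrom="sim1", pos=int(p), ref=r, alt=a)
                 for p, r, a, _ in course.samples[0].truth.variants[
                     ["pos", "ref", "alt", "true_af"]].itertuples(index=False)]
        monitored_pos = [v.pos for v in panel]
        summaries = []
        for sample in course.samples:
            stage_counts["samples"] += 1
            stage_counts["reads"] += len(sample.family_table)
            pileup = pileup_from_family_table(sample.family_table)
            stage_counts["consensus_rows"] += len(pileup)
            write_pileup(pileup, os.path.join(out, "pileups",
                                              f"{sample.sample_id}.tsv"))

            obs = observations_from_pileup(pileup, sample.truth.ref_bases,
                                           exclude_positions=monitored_pos)
            model = fit_background(obs)
            model.save_tsv(os.path.join(out, "models",
                                        f"{sample.sample_id}.tsv"))

            calls = call_variants(pileup, panel, model, alpha=cfg.detection_p)
            stage_counts["variant_calls"] += len(calls)
            frame = calls_to_frame(sample.sample_id, calls)
            frame.to_csv(os.path.join(out, "calls",
                                      f"{sample.sample_id}.tsv"),
                         sep="\t", index=False)

            dedup_depth = float(pileup.groupby("pos")["depth"].sum().mean())
            qc = qc_sample(mean_dedup_depth=dedup_depth,
                           min_depth=cfg.min_monitor_depth)
            result = summarize_sample(sample.sample_id, calls, course.cohort,
                                      qc={"status": qc.status, "flags": qc.flags,
                                          "mean_dedup_depth": round(dedup_depth, 1)})
            result.save_json(os.path.join(out, "calls",
                                          f"{sample.sample_id}.json"))
            sample_records.append(result.summary())

            kept, _ = filter_timepoint(frame, min_depth=cfg.min_monitor_depth,
                                       outlier_sd=cfg.outlier_sd)
            af = mean_af(kept) if len(kept) else float("nan")
            summaries.append(TimepointSummary(
                sample_id=sample.sample_id,
                collection_date=sample.collection_date,
                timepoint="",  # assigned below
                mean_af=af, n_variants_used=len(kept),
                ctdna_positive=result.ctdna_positive))

        labels = assign_timepoints(
            [s.collection_date for s in summaries],
            ici_start=course.anchors["ici_start"],
            cycle2_date=course.anchors["cycle2_date"],
            pet2_date=course.anchors["pet2_date"])
        summaries = [dataclasses.replace(s, timepoint=l)
                     for s, l in zip(summaries, labels)]
        patient_courses.append(build_course(course.patient_id, course.cohort,
                                            summaries))

        matched = match_biomarkers(
            pd.DataFrame({"patient": course.patient_id,
                          "sample": [s.sample_id for s in summaries],
                          "date": [s.collection_date for s in summaries]}),
            biomarkers)
        af_by_sample = {s.sample_id: s.mean_af for s in summaries
                        if s.correlation_eligible}
        for row in matched.itertuples(index=False):
            if row.sample in af_by_sample:
                matched_rows.append({"patient": row.patient,
                                     "analyte": row.analyte,
                                     "mean_af": af_by_sample[row.sample],
                                     "value": row.value})

    monitoring = course_table(patient_courses)
    monitoring.to_csv(os.path.join(out, "monitoring.tsv"), sep="\t",
                      index=False, float_format="%.8g")
    correlations = (correlation_report(pd.DataFrame(matched_rows))
                    if matched_rows else pd.DataFrame(
                        columns=["analyte", "rho", "n", "df", "t", "p"]))
    correlations.to_csv(os.path.join(out, "correlations.tsv"), sep="\t",
                        index=False, float_format="%.8g")
    biomarkers.to_csv(os.path.join(out, "biomarkers.tsv"), sep="\t",
                      index=False)

    report = {
        "version": __version__,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stage_counts": stage_counts,
        "samples": sample_records,
        "outputs": ["monitoring.tsv", "correlations.tsv", "biomarkers.tsv"],
    }
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
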