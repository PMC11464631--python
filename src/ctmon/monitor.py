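"""Longitudinal monitoring: filters, timepoints, dynamics and correlations.

Per-sample variant calls become per-timepoint summaries of circulating
tumour DNA burden: quality filters drop unreliable variant positions, the
mean allele fraction of the survivors is the monitoring statistic, samples
map onto the clinical timepoints (T0 baseline, T1 second treatment course,
T2 first follow-up imaging), and adjacent-timepoint changes classify each
interval as ascending-or-stable (``asc``) or descending (``desc``) ctDNA.
Correlation against blood or imaging biomarkers aggregates to one value per
patient (repeated samples from one patient are not independent) and uses
Spearman's rho with the t-transformation, t = rho * sqrt((n-2)/(1-rho^2)),
with n - 2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from scipy.stats import t as t_dist

MIN_MONITOR_DEPTH = 1000      # consensus depth (levels >= 2) below which a variant drops
OUTLIER_SD = 3.0              # MAF outlier threshold: mean + 3 SD at the timepoint
MIN_VARIANTS_CORRELATION = 3  # analysable variants required for correlation use

#: biomarker matching windows in days around a liquid biopsy
BIOMARKER_WINDOWS = {"S100": 7, "LDH": 7, "MTV": 21, "TLG": 21}

TIMEPOINT_WINDOWS = {"T0": 7, "T1": 7, "T2": 21}


# ---------------------------------------------------------------------------
# per-timepoint filtering and summary


def filter_timepoint(calls: pd.DataFrame, *,
                     min_depth: int = MIN_MONITOR_DEPTH,
                     outlier_sd: float = OUTLIER_SD
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the monitoring quality filters to one timepoint's calls.

    Removes, in order: (a) variants whose pooled consensus depth (levels
    >= 2) is below ``min_depth``; (b) small insertions/deletions; (c) in a
    single pass, variants with MAF more than ``outlier_sd`` standard
    deviations above the mean MAF of the variants surviving (a) and (b) —
    the population statistics include the candidate itself.

    ``calls`` needs columns ``depth, variant_class, MAF`` (the flattened
    call layout).  Returns (kept, removed-with-reason).  An empty survivor
    set is legal here; callers flag the timepoint as not analysable.
    """
    calls = calls.copy()
    reasons = pd.Series("", index=calls.index, dtype=object)

    low = calls["depth"] < min_depth
    reasons[low] = "low depth"
    indel = (calls["variant_class"] == "indel") & ~low
    reasons[indel] = "indel"

    surviving = calls[~low & ~indel]
    out_mask = pd.Series(False, index=calls.index)
    if len(surviving) >= 2:
        mafs = surviving["MAF"].astype(float)
        bound = mafs.mean() + outlier_sd * mafs.std(ddof=1)
        out = surviving.index[mafs > bound]
        out_mask[out] = True
        reasons[out] = "MAF outlier"

    removed = ~(reasons == "")
    kept = calls[~removed].copy()
    dropped = calls[removed].copy()
    dropped["reason"] = reasons[removed]
    return kept, dropped


def mean_af(filtered_calls: pd.DataFrame) -> float:
    """Unweighted mean MAF of the variants surviving all filters."""
    if filtered_calls.empty:
        raise ValueError("mean AF undefined: no variants survive filtering")
    return float(filtered_calls["MAF"].astype(float).mean())


@dataclass(frozen=True)
class TimepointSummary:
    sample_id: str
    collection_date: date
    timepoint: str              # T0 | T1 | T2 | other
    mean_af: float              # NaN when not analysable
    n_variants_used: int
    ctdna_positive: bool

    @property
    def analysable(self) -> bool:
        return self.n_variants_used >= 1 and not math.isnan(self.mean_af)

    @property
    def correlation_eligible(self) -> bool:
        return self.n_variants_used >= MIN_VARIANTS_CORRELATION


@dataclass
class PatientCourse:
    patient_id: str
    cohort: str
    timepoints: list[TimepointSummary]
    dynamics: list[str] = field(default_factory=list)  # asc | desc per adjacent pair

    def __post_init__(self):
        dates = [t.collection_date for t in self.timepoints]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("timepoint dates must be strictly increasing")
        if not self.dynamics:
            self.dynamics = [
                classify_dynamics(a.mean_af, b.mean_af)
                if (a.analysable and b.analysable) else "undefined"
                for a, b in zip(self.timepoints, self.timepoints[1:])
            ]


# ---------------------------------------------------------------------------
# timepoint assignment and dynamics


def assign_timepoints(sample_dates: Sequence[date], *,
                      ici_start: date | None = None,
                      cycle2_date: date | None = None,
                      pet2_date: date | None = None,
                      windows: Mapping[str, int] = TIMEPOINT_WINDOWS
                      ) -> list[str]:
    """Label samples T0/T1/T2/other by proximity to the clinical anchors.

    T0: within 7 days of treatment start; T1: within 7 days of the second
    treatment course; T2: within 21 days of the follow-up PET/CT.  A sample
    inside several windows takes the nearer anchor; distance ties resolve
    to the earlier label.  Missing anchors leave their label unassignable.
    """
    anchors = [("T0", ici_start), ("T1", cycle2_date), ("T2", pet2_date)]
    labels = []
    for d in sample_dates:
        best: tuple[int, int] | None = None  # (distance, label order)
        label = "other"
        for order, (name, anchor) in enumerate(anchors):
            if anchor is None:
                continue
            dist = abs((d - anchor).days)
            if dist <= windows[name] and (best is None or (dist, order) < best):
                best = (dist, order)
                label = name
        labels.append(label)
    return labels


def classify_dynamics(earlier_af: float, later_af: float) -> str:
    """``asc`` when the change later - earlier is >= 0 (stable counts as
    ascending), ``desc`` when it is negative."""
    if math.isnan(earlier_af) or math.isnan(later_af):
        raise ValueError("dynamics undefined: missing endpoint")
    return "asc" if later_af - earlier_af >= 0 else "desc"


# ---------------------------------------------------------------------------
# transforms and correlation


def pseudocount_log(values: Sequence[float]) -> np.ndarray:
    """log10 transform with the half-minimum pseudo-count for zeros.

    Zeros are replaced by min(non-zero values) / 2 before taking log10
    (the convention used for plotting monitoring values on log axes).
    All-zero input is undefined and raises.
    """
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("values must be non-negative")
    nz = arr[arr > 0]
    if nz.size == 0:
        raise ValueError("pseudo-count transform undefined: all values are zero")
    out = arr.copy()
    out[out == 0] = nz.min() / 2.0
    return np.log10(out)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int              # number of patients
    t: float
    p: float
    degenerate: bool = False

    @property
    def df(self) -> int:
        return self.n - 2


def t_transform(rho: float, n: int) -> float:
    """t statistic of a Spearman rho with n - 2 degrees of freedom."""
    if n < 3:
        raise ValueError("t-transformation requires n >= 3")
    if abs(rho) >= 1:
        return math.inf if rho > 0 else -math.inf
    return rho * math.sqrt((n - 2) / (1.0 - rho * rho))


def spearman_t(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman correlation with t-transformed two-sided p-value.

    ``x`` and ``y`` must hold one aggregate value per patient (use
    :func:`aggregate_per_patient` first); ranks use average tie handling.
    |rho| = 1 is reported as degenerate with t infinite and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3 patients")
    rho = float(spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        return CorrelationResult(rho, n, math.copysign(math.inf, rho), 0.0,
                                 degenerate=True)
    t = t_transform(rho, n)
    p = 2.0 * float(t_dist.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, n, t, min(1.0, p))


def aggregate_per_patient(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean x and y per patient: one row per patient for correlation.

    ``pairs`` needs columns ``patient, x, y`` (one row per matched
    biopsy-biomarker pair).
    """
    return (pairs.groupby("patient", sort=True)[["x", "y"]]
            .mean().reset_index())


def match_biomarkers(samples: pd.DataFrame, biomarkers: pd.DataFrame, *,
                     windows: Mapping[str, int] = BIOMARKER_WINDOWS
                     ) -> pd.DataFrame:
    """Match each liquid biopsy to biomarker records within the analyte
    window (S100/LDH +-7 days, MTV/TLG +-21 days).

    The nearest record wins; distance ties resolve to the earlier record.
    ``samples``: columns ``sample, date`` (datetime-like); ``biomarkers``:
    columns ``date, analyte, value`` (a ``patient`` column, if present in
    both, restricts matches within patient).  Unmatched biopsies are simply
    absent from the result.
    """
    samples = samples.copy()
    biomarkers = biomarkers.copy()
    samples["date"] = pd.to_datetime(samples["date"])
    biomarkers["date"] = pd.to_datetime(biomarkers["date"])
    use_patient = "patient" in samples.columns and "patient" in biomarkers.columns
    rows = []
    for s in samples.itertuples(index=False):
        cands = biomarkers
        if use_patient:
            cands = cands[cands["patient"] == s.patient]
        for analyte, window in windows.items():
            sub = cands[cands["analyte"] == analyte]
            if sub.empty:
                continue
            delta = (sub["date"] - s.date).dt.days
            ok = sub[delta.abs() <= window]
            if ok.empty:
                continue
            ok = ok.assign(_dist=(ok["date"] - s.date).dt.days.abs())
            ok = ok.sort_values(["_dist", "date"], kind="mergesort")
            best = ok.iloc[0]
            row = {"sample": s.sample, "sample_date": s.date,
                   "analyte": analyte, "biomarker_date": best["date"],
                   "value": float(best["value"]),
                   "delta_days": int((best["date"] - s.date).days)}
            if use_patient:
                row["patient"] = s.patient
            rows.append(row)
    return pd.DataFrame(rows)


def correlation_report(matched: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte Spearman/t correlation of mean AF against biomarkers.

    ``matched`` needs columns ``patient, analyte, mean_af, value``.  Pairs
    aggregate to one (mean AF, value) per patient per analyte before
    ranking.  Analytes with fewer than 3 patients are skipped.
    """
    rows = []
    for analyte, sub in matched.groupby("analyte", sort=True):
        pairs = sub.rename(columns={"mean_af": "x", "value": "y"})
        agg = aggregate_per_patient(pairs[["patient", "x", "y"]])
        if len(agg) < 3:
            continue
        res = spearman_t(agg["x"], agg["y"])
        rows.append({"analyte": analyte, "rho": res.rho, "n": res.n,
                     "df": res.df, "t": res.t, "p": res.p})
    return pd.DataFrame(rows, columns=["analyte", "rho", "n", "df", "t", "p"])


# ---------------------------------------------------------------------------
# course assembly and plotting


def build_course(patient_id: str, cohort: str,
                 summaries: Sequence[TimepointSummary]) -> PatientCourse:
    ordered = sorted(summaries, key=lambda s: s.collection_date)
    return PatientCourse(patient_id, cohort, list(ordered))


def course_table(courses: Sequence[PatientCourse]) -> pd.DataFrame:
    """Monitoring table: one row per patient timepoint."""
    rows = []
    for course in courses:
        for i, tp in enumerate(course.timepoints):
            rows.append({
                "patient": course.patient_id, "cohort": course.cohort,
                "sample": tp.sample_id, "timepoint": tp.timepoint,
                "date": tp.collection_date.isoformat(),
                "mean_AF": tp.mean_af,
                "n_variants_used": tp.n_variants_used,
                "positive": bool(tp.ctdna_positive),
                "dynamics_from_previous":
                    course.dynamics[i - 1] if i else "",
            })
    return pd.DataFrame(rows, columns=[
        "patient", "cohort", "sample", "timepoint", "date", "mean_AF",
        "n_variants_used", "positive", "dynamics_from_previous"])


def plot_course(course: PatientCourse, path) -> None:
    """Monitoring curve: mean AF over time on a log axis (zeros get the
    half-minimum pseudo-count)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    days = [tp.collection_date for tp in course.timepoints if tp.analysable]
    afs = [tp.mean_af for tp in course.timepoints if tp.analysable]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if afs:
        if any(a > 0 for a in afs):
            ax.plot(days, 10.0 ** pseudocount_log(afs), "o-")
            ax.set_yscale("log")
        else:
            ax.plot(days, afs, "o-")
    ax.set_xlabel("collection date")
    ax.set_ylabel("mean variant AF")
    ax.set_title(f"{course.patient_id} ({course.cohort})")
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
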