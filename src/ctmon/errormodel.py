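"""Beta-binomial background-error models and tail p-values.

Sequencing errors at a panel position are not binomial: the per-site error
probability itself varies between sites, runs and library preparations, so
alt counts are overdispersed.  A beta-binomial — binomial counts whose
success probability is Beta(alpha, beta) distributed — captures this
site-to-site variation.  One model is fitted per (substitution type,
correction level) stratum: 12 nucleotide changes x 3 levels, because error
spectra are change-specific (e.g. oxidative G>T, deamination C>T) and
consensus correction suppresses them differently at each duplication level.

A monitored variant's alt count at a given level is then scored against the
matching null model with an inclusive upper-tail p-value P(X >= altC), and
per-level p-values are integrated over levels with Fisher's method, while
alt and depth counts pool additively into a single MAF.

Fitting uses a depth-weighted method of moments with a pseudo-prior
fallback for sparse or underdispersed strata; both paths are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from .consensus import BASES, LEVELS

SUBSTITUTIONS = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a)

#: pseudo-prior strength used by the fallback fit (pseudo-observations)
PRIOR_STRENGTH = 1000.0
#: minimum usable stratum: sites with depth >= MIN_DEPTH, at least MIN_SITES
MIN_SITES = 20
MIN_DEPTH = 100
#: smallest intra-class correlation accepted from the moment fit
RHO_FLOOR = 1e-9

MODEL_COLUMNS = ["substitution", "level", "alpha", "beta", "n_sites", "fit_method"]


@dataclass(frozen=True)
class ErrorModelParams:
    """Beta-binomial null parameters for one (substitution, level) stratum."""

    substitution: str
    level: int
    alpha: float
    beta: float
    n_training_sites: int
    fit_method: str  # "moments", "pseudo-prior", "pooled-fallback"

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0.0 < self.mean < 0.5:
            raise ValueError(
                f"implied error mean {self.mean:.3g} outside (0, 0.5) for "
                f"{self.substitution} level {self.level}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class SiteObservation:
    """Alt count of one substitution at one site and level."""

    pos: int
    level: int
    depth: int
    alt_count: int

    def __post_init__(self):
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("require 0 <= alt_count <= depth")


# ---------------------------------------------------------------------------
# fitting


def moment_fit(depths: np.ndarray, alts: np.ndarray) -> tuple[float, float] | None:
    """Depth-weighted method-of-moments estimate of (alpha, beta).

    Returns None when the stratum is underdispersed relative to binomial
    sampling noise (or degenerate), signalling the caller to fall back.
    """
    w = depths.astype(float)
    W = w.sum()
    m = alts.sum() / W
    if m <= 0 or m >= 0.5:
        return None
    p = alts / depths
    denom = W - (w ** 2).sum() / W
    if denom <= 0:
        return None
    v = float(w @ (p - m) ** 2 / denom)
    n_bar = W / len(w)
    binom_v = m * (1 - m) / n_bar
    if v <= binom_v:
        return None
    rho = (v - binom_v) / (m * (1 - m) * (1 - 1 / n_bar))
    if rho <= RHO_FLOOR or rho >= 1:
        return None
    scale = (1 - rho) / rho
    return m * scale, (1 - m) * scale


def _pseudo_prior(m: float, method: str = "pseudo-prior") -> tuple[float, float, str]:
    alpha = m * PRIOR_STRENGTH + 0.5
    beta = (1.0 - m) * PRIOR_STRENGTH + 0.5
    return alpha, beta, method


def fit_stratum(depths: Sequence[int], alts: Sequence[int], *,
                substitution: str, level: int,
                pooled_mean: float | None = None) -> ErrorModelParams:
    """Fit one (substitution, level) stratum.

    Sites with depth < MIN_DEPTH are ignored.  The moment fit is used when
    the stratum has >= MIN_SITES usable sites and shows genuine
    overdispersion; otherwise a pseudo-prior of strength
    :data:`PRIOR_STRENGTH` centred on the stratum mean (or ``pooled_mean``
    when the stratum is empty or all-zero) is used.
    """
    depths = np.asarray(depths, dtype=np.int64)
    alts = np.asarray(alts, dtype=np.int64)
    if depths.size and ((alts < 0).any() or (alts > depths).any()):
        raise ValueError("alt counts must satisfy 0 <= alt <= depth")
    if (depths == 0).any():
        raise ValueError("zero-depth observations are not usable for fitting")
    usable = depths >= MIN_DEPTH
    depths, alts = depths[usable], alts[usable]
    n_sites = int(depths.size)

    if n_sites == 0:
        m = pooled_mean if pooled_mean and pooled_mean > 0 else 1e-6
        a, b, meth = _pseudo_prior(m, "pooled-fallback")
        return ErrorModelParams(substitution, level, a, b, 0, meth)

    total_depth = int(depths.sum())
    m = alts.sum() / total_depth
    if m == 0:
        # degenerate all-zero stratum: pooled pseudo-count mean
        m = (pooled_mean if pooled_mean and pooled_mean > 0
             else 0.5 / total_depth)
        a, b, meth = _pseudo_prior(m)
        return ErrorModelParams(substitution, level, a, b, n_sites, meth)

    if n_sites >= MIN_SITES:
        mom = moment_fit(depths, alts)
        if mom is not None:
            return ErrorModelParams(substitution, level, mom[0], mom[1],
                                    n_sites, "moments")
    a, b, meth = _pseudo_prior(min(m, 0.499))
    return ErrorModelParams(substitution, level, a, b, n_sites, meth)


class ErrorModel:
    """Collection of fitted strata with pooled-fallback lookup."""

    def __init__(self, params: Iterable[ErrorModelParams]):
        self._params: dict[tuple[str, int], ErrorModelParams] = {
            (p.substitution, p.level): p for p in params}

    def get(self, substitution: str, level: int) -> ErrorModelParams:
        """Parameters for a stratum; strata never fitted raise KeyError."""
        try:
            return self._params[(substitution, level)]
        except KeyError:
            raise KeyError(f"no error model for {substitution} level {level}")

    def __contains__(self, key) -> bool:
        return tuple(key) in self._params

    def __iter__(self):
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    # -- persistence --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "substitution": p.substitution, "level": p.level,
            "alpha": p.alpha, "beta": p.beta,
            "n_sites": p.n_training_sites, "fit_method": p.fit_method,
        } for p in sorted(self._params.values(),
                          key=lambda p: (p.substitution, p.level))]
        return pd.DataFrame(rows, columns=MODEL_COLUMNS)

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ErrorModel":
        return cls(ErrorModelParams(
            substitution=row.substitution, level=int(row.level),
            alpha=float(row.alpha), beta=float(row.beta),
            n_training_sites=int(row.n_sites), fit_method=row.fit_method,
        ) for row in frame.itertuples(index=False))

    @classmethod
    def load_tsv(cls, path) -> "ErrorModel":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def fit_background(observations: pd.DataFrame) -> ErrorModel:
    """Fit all (substitution, level) strata from a site-observation table.

    ``observations`` needs columns ``substitution, level, depth, alt_count``
    and must already exclude monitored variant positions (training on
    monitored sites would leak signal into the null).  Strata absent from
    the table inherit a pseudo-prior centred on the pooled mean at the same
    level, recorded as ``pooled-fallback``.
    """
    required = {"substitution", "level", "depth", "alt_count"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    obs = observations[observations["depth"] > 0]
    params = []
    for level in LEVELS:
        at_level = obs[obs["level"] == level]
        pooled_mean = None
        if len(at_level) and at_level["depth"].sum() > 0:
            pooled_mean = float(at_level["alt_count"].sum() / at_level["depth"].sum())
            if pooled_mean == 0:
                pooled_mean = 0.5 / float(at_level["depth"].sum())
        for sub in SUBSTITUTIONS:
            stratum = at_level[at_level["substitution"] == sub]
            params.append(fit_stratum(
                stratum["depth"].to_numpy(), stratum["alt_count"].to_numpy(),
                substitution=sub, level=level, pooled_mean=pooled_mean))
    return ErrorModel(params)


def observations_from_pileup(pileup: pd.DataFrame,
                             ref_bases: Mapping[int, str],
                             exclude_positions: Iterable[int] = ()
                             ) -> pd.DataFrame:
    """Expand a level pileup into per-substitution site observations.

    Every (position, level) row yields three observations — one per
    possible alternative base — with the consensus depth as trials.
    ``exclude_positions`` (monitored variants) are dropped.
    """
    excl = set(int(p) for p in exclude_positions)
    rows = {"pos": [], "substitution": [], "level": [], "depth": [],
            "alt_count": []}
    for row in pileup.itertuples(index=False):
        pos = int(row.pos)
        if pos in excl:
            continue
        refb = ref_bases[pos]
        for altb in BASES:
            if altb == refb:
                continue
            rows["pos"].append(pos)
            rows["substitution"].append(f"{refb}>{altb}")
            rows["level"].append(int(row.level))
            rows["depth"].append(int(row.depth))
            rows["alt_count"].append(int(getattr(row, f"n{altb}")))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tail p-values


def _bb_logpmf_all(n: int, alpha: float, beta: float) -> np.ndarray:
    """Log pmf at k = 0..n via a cumulative log-recurrence.

    Avoids differences of gammaln at huge arguments (which lose ~1e-6
    relative precision once alpha+beta reaches 1e9) by accumulating
    log pmf(k+1) - log pmf(k) = log((n-k)(alpha+k)) - log((k+1)(beta+n-k-1)).
    """
    j = np.arange(n, dtype=np.float64)
    log0 = float(np.sum(np.log(beta + j) - np.log(alpha + beta + j)))
    k = j  # 0..n-1
    inc = (np.log(n - k) + np.log(alpha + k)
           - np.log(k + 1) - np.log(beta + n - k - 1))
    out = np.empty(n + 1)
    out[0] = log0
    np.cumsum(inc, out=out[1:])
    out[1:] += log0
    return out


def bb_logpmf(k, n: int, alpha: float, beta: float):
    """Log pmf of the beta-binomial distribution (vectorised over k)."""
    k = np.asarray(k, dtype=np.int64)
    if (k < 0).any() or (k > n).any():
        raise ValueError("require 0 <= k <= n")
    return _bb_logpmf_all(n, alpha, beta)[k]


def _shape_params(params) -> tuple[float, float]:
    """Accept either fitted :class:`ErrorModelParams` or a plain
    ``(alpha, beta)`` pair."""
    if isinstance(params, ErrorModelParams):
        return params.alpha, params.beta
    alpha, beta = params
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    return float(alpha), float(beta)


def bb_sf_table(n: int, params) -> np.ndarray:
    """Inclusive survival table: entry k is P(X >= k), k = 0..n.

    Computed by a reverse log-space cumulation of the pmf so tiny tail
    values keep full relative precision; entry 0 is exactly 1.
    """
    alpha, beta = _shape_params(params)
    logp = _bb_logpmf_all(n, alpha, beta)
    rev = np.logaddexp.accumulate(logp[::-1])[::-1]
    sf = np.exp(rev)
    sf[0] = 1.0
    return np.minimum(sf, 1.0)


def bb_tail_pvalue(alt_count: int, depth: int, params) -> float:
    """Inclusive upper-tail p-value P(X >= altC) under the stratum's null.

    ``params`` is an :class:`ErrorModelParams` or a bare ``(alpha, beta)``
    pair.  ``alt_count = 0`` gives exactly 1; the p-value is strictly
    decreasing in ``alt_count`` at fixed depth and parameters.
    """
    alpha, beta = _shape_params(params)
    if not 0 <= alt_count <= depth:
        raise ValueError("require 0 <= alt_count <= depth")
    if alt_count == 0:
        return 1.0
    logp = _bb_logpmf_all(depth, alpha, beta)[alt_count:]
    return float(min(1.0, math.exp(logsumexp(logp))))


def bb_tail_pvalues(alt_counts, depth: int, params) -> np.ndarray:
    """Vectorised tail p-values for many sites sharing (depth, params)."""
    alt_counts = np.asarray(alt_counts, dtype=np.int64)
    if alt_counts.size == 0:
        return np.empty(0)
    if (alt_counts < 0).any() or (alt_counts > depth).any():
        raise ValueError("require 0 <= alt_count <= depth")
    return bb_sf_table(depth, params)[alt_counts]


# ---------------------------------------------------------------------------
# level integration


@dataclass(frozen=True)
class CombinedCall:
    """Integrated statistics of one variant over all correction levels."""

    alt_count: int
    depth: int
    maf: float
    p: float
    n_levels: int
    assessable: bool


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi2 with 2k degrees of freedom."""
    ps = [float(p) for p in pvalues]
    if not ps:
        raise ValueError("fisher_combine needs at least one p-value")
    if any(p <= 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    if len(ps) == 1:
        return ps[0]
    stat = -2.0 * sum(math.log(p) for p in ps)
    return float(chi2.sf(stat, df=2 * len(ps)))


def combine_levels(level_stats: Sequence[tuple[int, int, int, float]]) -> CombinedCall:
    """Integrate per-level (level, alt_count, depth, p) into one call.

    Counts pool additively (MAF = pooled altC / pooled depth); p-values of
    levels with depth > 0 combine by Fisher's method.  With a single
    contributing level the combined p equals that level's p.  All depths
    zero -> the variant is not assessable (distinct from p = 1).
    """
    contributing = [(lv, a, d, p) for lv, a, d, p in level_stats if d > 0]
    if not contributing:
        return CombinedCall(0, 0, float("nan"), float("nan"), 0, False)
    alt = int(sum(a for _, a, _, _ in contributing))
    depth = int(sum(d for _, _, d, _ in contributing))
    p = fisher_combine([p for _, _, _, p in contributing])
    return CombinedCall(alt, depth, alt / depth, p, len(contributing), True)
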