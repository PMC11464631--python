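"""Synthetic UMI-tagged reads and patient courses with known ground truth.

The generator emulates the sequencing regime of tumour-informed plasma
monitoring: a small capture panel (up to 30 patient-specific somatic
variants plus background positions), raw on-target depth around 100,000x,
PCR/optical duplicate families over each original cfDNA molecule, and
substitution errors applied independently to every read copy.  After
singleton exclusion the default configuration yields a consensus depth of
roughly 6,000x per position.

Reads are simulated as single-position observations (pileup semantics): the
downstream statistics consume per-position counts, so fragment extent adds
nothing but cost.  Errors are substitution-only; small indels are excluded
from monitoring downstream and are not simulated.

Two generator tiers exist:

* read-level — :func:`simulate_families` / :func:`simulate_patient_course` /
  :func:`write_reads`, exercising the full grouping + consensus machinery;
* count-level — :func:`simulate_pileup` / :func:`simulate_site_observations`,
  drawing consensus counts directly from the binomial / beta-binomial
  process for calibration and power studies at scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import BASES, FAMILY_TABLE_COLUMNS, _codes_to_umi

SUBSTITUTIONS = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a)

#: default shifted negative binomial family-size law: size = 1 + NB(r, p),
#: tuned so E[size] = 15 and P(size = 1) ~ 0.097, reproducing the study's
#: ~100,000x raw -> ~6,000x post-dedup depth ratio.
DEFAULT_FAMILY_SIZES = ("nbinom", 0.8, 14.0)


@dataclass(frozen=True)
class Variant:
    """A monitored variant position with its true allele fraction."""

    pos: int
    ref: str
    alt: str
    af: float

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES or self.ref == self.alt:
            raise ValueError(f"invalid substitution {self.ref}>{self.alt}")


@dataclass
class SimConfig:
    """Study-regime configuration of the read-level simulator.

    Parameters
    ----------
    n_background_positions
        Variant-free panel positions used for error-model training.
    monitored_variants
        ``(pos, ref, alt, true AF)`` tuples; defaults to a 30-variant panel
        at AF 1% placed after the background positions.
    raw_depth_per_position
        Raw read depth target per position (study intent: ~100,000x).
    family_size_distribution
        Either ``("nbinom", r, mu)`` for size = 1 + NegBinomial(r, mu), or a
        ``{size: probability}`` mapping (keys are literal family sizes).
    error_rates
        Total per-read-base substitution error probability; either a scalar
        (spread uniformly over the three alternatives) or a mapping
        ``"X>Y" -> probability``.  Each individual rate must lie in
        [0, 0.05].
    umi_length
        Bases per UMI.  12 keeps spurious Hamming-1 adjacency of distinct
        molecules rare at ~6,000 families per position.
    allow_umi_collisions
        If False (default) UMIs are redrawn until unique per position, so
        every family maps to exactly one truth record.
    """

    n_background_positions: int = 60
    monitored_variants: Sequence[tuple[int, str, str, float]] | None = None
    raw_depth_per_position: int = 100_000
    family_size_distribution: object = DEFAULT_FAMILY_SIZES
    error_rates: object = 1e-3
    umi_length: int = 12
    allow_umi_collisions: bool = False
    chrom: str = "sim1"
    seed: int = 0

    def __post_init__(self):
        if self.monitored_variants is None:
            start = self.n_background_positions + 1
            self.monitored_variants = [
                (start + i, "C", "T", 0.01) for i in range(30)
            ]
        self.validate()

    # -- derived quantities -------------------------------------------------

    def variants(self) -> list[Variant]:
        return [Variant(int(p), r, a, float(f)) for p, r, a, f in self.monitored_variants]

    def error_rate_matrix(self) -> np.ndarray:
        """(4, 4) matrix of per-read-base substitution probabilities."""
        mat = np.zeros((4, 4))
        if isinstance(self.error_rates, Mapping):
            for sub, rate in self.error_rates.items():
                r, a = sub.split(">")
                mat[BASES.index(r), BASES.index(a)] = float(rate)
        else:
            e = float(self.error_rates)
            for i in range(4):
                for j in range(4):
                    if i != j:
                        mat[i, j] = e / 3.0
        return mat

    def size_pmf(self, max_size: int = 200) -> np.ndarray:
        """P(size = k) for k = 0..max_size (index 0 unused)."""
        pmf = np.zeros(max_size + 1)
        dist = self.family_size_distribution
        if isinstance(dist, Mapping):
            for k, p in dist.items():
                pmf[int(k)] = float(p)
        else:
            from scipy.stats import nbinom
            _, r, mu = dist
            p = r / (r + mu)
            pmf[1:] = nbinom.pmf(np.arange(max_size), r, p)
        return pmf / pmf.sum()

    def mean_family_size(self) -> float:
        pmf = self.size_pmf()
        return float(np.arange(pmf.size) @ pmf)

    def p_family_ge2(self) -> float:
        return float(self.size_pmf()[2:].sum())

    def expected_consensus_depth(self) -> float:
        """Expected post-dedup depth: families per position x P(size >= 2)."""
        return self.raw_depth_per_position * self.p_family_ge2() / self.mean_family_size()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_background_positions < 0:
            raise ValueError("n_background_positions must be >= 0")
        if self.raw_depth_per_position < 1:
            raise ValueError("raw_depth_per_position must be >= 1")
        if self.umi_length < 4:
            raise ValueError("umi_length must be >= 4")
        for p, r, a, f in self.monitored_variants:
            Variant(int(p), r, a, float(f))
            if not 0.0 <= float(f) <= 1.0:
                raise ValueError(f"monitored_variants: AF {f} at pos {p} not in [0, 1]")
            if int(p) < 1:
                raise ValueError(f"monitored_variants: position {p} must be >= 1")
        mat = self.error_rate_matrix()
        if (mat < 0).any() or (mat > 0.05).any():
            raise ValueError("error_rates: each substitution rate must be in [0, 0.05]")
        if mat.sum(axis=1).max() > 0.15:
            raise ValueError("error_rates: total error per base exceeds 0.15")
        dist = self.family_size_distribution
        if isinstance(dist, Mapping):
            if not dist or any(int(k) < 1 or v < 0 for k, v in dist.items()):
                raise ValueError("family_size_distribution: sizes >= 1, probabilities >= 0")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("family_size_distribution: probabilities must sum to 1")
        else:
            tag, r, mu = dist
            if tag != "nbinom" or r <= 0 or mu <= 0:
                raise ValueError("family_size_distribution: expected ('nbinom', r>0, mu>0)")


@dataclass
class TruthSet:
    """Ground truth of one simulated sample."""

    ref_bases: dict[int, str]
    variants: pd.DataFrame  # pos, ref, alt, true_af
    families: pd.DataFrame  # pos, umi, true_base, size

    def true_base(self, pos: int) -> str:
        return self.ref_bases[pos]


def _reference(config: SimConfig, rng: np.random.Generator) -> dict[int, str]:
    variants = {v.pos: v.ref for v in config.variants()}
    n_bg = config.n_background_positions
    positions = sorted(set(range(1, n_bg + 1)) | set(variants))
    bases = np.array(BASES)[rng.integers(0, 4, size=len(positions))]
    ref = {p: str(b) for p, b in zip(positions, bases)}
    ref.update(variants)
    return ref


def _draw_sizes(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    pmf = config.size_pmf()
    return rng.choice(pmf.size, size=n, p=pmf)


def _unique_umis(n: int, length: int, rng: np.random.Generator,
                 allow_collisions: bool) -> np.ndarray:
    space = 4 ** length
    codes = rng.integers(0, space, size=n)
    if not allow_collisions:
        for _ in range(64):
            _, first = np.unique(codes, return_index=True)
            dup = np.ones(n, dtype=bool)
            dup[first] = False
            if not dup.any():
                break
            codes[dup] = rng.integers(0, space, size=int(dup.sum()))
    return codes


def simulate_families(config: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate a UMI family read table for one sample.

    Each position receives ``raw_depth / E[family size]`` molecules; each
    molecule's true base is the reference, or the variant allele with
    probability equal to the true AF at monitored positions.  Every read
    copy is then perturbed independently by the configured substitution
    error process.  Deterministic for a fixed seed.

    Returns the read table (``chrom, pos, umi, copy_index, base, qual``) and
    the matching :class:`TruthSet`.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ref = _reference(config, rng)
    positions = np.fromiter(ref.keys(), dtype=np.int64)
    positions.sort()
    n_fam_per_pos = max(1, round(config.raw_depth_per_position / config.mean_family_size()))
    n_fam = n_fam_per_pos * positions.size

    fam_pos = np.repeat(positions, n_fam_per_pos)
    sizes = _draw_sizes(config, n_fam, rng)
    ref_codes = np.array([BASES.index(ref[p]) for p in positions], dtype=np.int8)
    fam_true = np.repeat(ref_codes, n_fam_per_pos).astype(np.int64)
    af_by_pos = {v.pos: (v.af, BASES.index(v.alt)) for v in config.variants()}
    for pos, (af, alt_code) in af_by_pos.items():
        if af <= 0:
            continue
        sel = np.flatnonzero(fam_pos == pos)
        flips = rng.random(sel.size) < af
        fam_true[sel[flips]] = alt_code

    umi_codes = np.empty(n_fam, dtype=np.int64)
    for i in range(positions.size):  # uniqueness is per position
        sl = slice(i * n_fam_per_pos, (i + 1) * n_fam_per_pos)
        umi_codes[sl] = _unique_umis(n_fam_per_pos, config.umi_length, rng,
                                     config.allow_umi_collisions)

    # expand families to reads and apply substitution errors
    reads_per_fam = sizes
    n_reads = int(reads_per_fam.sum())
    fam_of_read = np.repeat(np.arange(n_fam), reads_per_fam)
    read_true = fam_true[fam_of_read]
    offsets = np.concatenate(([0], np.cumsum(reads_per_fam)[:-1]))
    copy_index = np.arange(n_reads) - np.repeat(offsets, reads_per_fam)

    err_mat = config.error_rate_matrix()
    total_err = err_mat.sum(axis=1)
    read_base = read_true.copy()
    u = rng.random(n_reads)
    has_err = u < total_err[read_true]
    if has_err.any():
        idx = np.flatnonzero(has_err)
        cond = err_mat / np.where(total_err[:, None] > 0, total_err[:, None], 1.0)
        cum = np.cumsum(cond, axis=1)
        draw = rng.random(idx.size)
        rows = cum[read_true[idx]]
        read_base[idx] = (draw[:, None] < rows).argmax(axis=1)

    umi_str = _codes_to_umi(umi_codes, config.umi_length)
    table = pd.DataFrame({
        "chrom": config.chrom,
        "pos": fam_pos[fam_of_read],
        "umi": umi_str[fam_of_read],
        "copy_index": copy_index,
        "base": np.array(BASES)[read_base],
        "qual": np.int64(37),
    }, columns=FAMILY_TABLE_COLUMNS)

    truth = TruthSet(
        ref_bases=ref,
        variants=pd.DataFrame(
            [(v.pos, v.ref, v.alt, v.af) for v in config.variants()],
            columns=["pos", "ref", "alt", "true_af"]),
        families=pd.DataFrame({
            "pos": fam_pos, "umi": umi_str,
            "true_base": np.array(BASES)[fam_true], "size": sizes}),
    )
    return table, truth


# ---------------------------------------------------------------------------
# patient courses


@dataclass(frozen=True)
class SimulatedSample:
    sample_id: str
    day: int
    collection_date: date
    family_table: pd.DataFrame
    truth: TruthSet


@dataclass
class SimulatedCourse:
    patient_id: str
    cohort: str
    samples: list[SimulatedSample]
    metadata: pd.DataFrame  # patient, sample, date, day, cohort
    anchors: dict[str, date]


def responder_template(days: Sequence[int] = (0, 21, 84),
                       multipliers: Sequence[float] = (1.0, 0.1, 0.0)):
    """AF trajectory of a patient responding to therapy: decay to zero."""
    return list(zip(days, multipliers))


def progressor_template(days: Sequence[int] = (0, 21, 84),
                        multipliers: Sequence[float] = (1.0, 4.0, 16.0)):
    """AF trajectory of a progressing patient: rising allele fractions."""
    return list(zip(days, multipliers))


def simulate_patient_course(course: Sequence[tuple[int, object]],
                            config: SimConfig, *,
                            patient_id: str = "P01",
                            cohort: str = "palliative",
                            start_date: date = date(2021, 1, 4)
                            ) -> SimulatedCourse:
    """Simulate one sample per timepoint of a patient course.

    ``course`` lists ``(day, afs)`` with strictly increasing days; ``afs``
    is either a scalar multiplier applied to the panel's configured AFs or a
    sequence of per-variant AFs.  All timepoints share the panel; each draws
    an independent child seed from ``config.seed``.
    """
    if not course:
        raise ValueError("course must contain at least one timepoint")
    days = [d for d, _ in course]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("course timepoints must be strictly increasing")
    base = config.variants()
    children = np.random.SeedSequence(config.seed).spawn(len(course))
    samples = []
    for i, ((day, afs), child) in enumerate(zip(course, children)):
        if np.isscalar(afs):
            new_afs = [min(1.0, v.af * float(afs)) for v in base]
        else:
            afs = list(afs)
            if len(afs) != len(base):
                raise ValueError("per-variant AF list length does not match panel")
            new_afs = [float(a) for a in afs]
        cfg = dataclasses.replace(
            config,
            monitored_variants=[(v.pos, v.ref, v.alt, a) for v, a in zip(base, new_afs)])
        table, truth = simulate_families(cfg, np.random.default_rng(child))
        samples.append(SimulatedSample(
            sample_id=f"{patient_id}_d{day:03d}",
            day=int(day),
            collection_date=start_date + timedelta(days=int(day)),
            family_table=table,
            truth=truth,
        ))
    anchors = {
        "ici_start": start_date,
        "cycle2_date": start_date + timedelta(days=21),
        "pet2_date": start_date + timedelta(days=84),
    }
    meta = pd.DataFrame({
        "patient": patient_id,
        "sample": [s.sample_id for s in samples],
        "date": [s.collection_date.isoformat() for s in samples],
        "day": [s.day for s in samples],
        "cohort": cohort,
    })
    return SimulatedCourse(patient_id, cohort, samples, meta, anchors)


# ---------------------------------------------------------------------------
# count-level generators


def simulate_pileup(*, positions: Sequence[int], ref_bases: Mapping[int, str],
                    variants: Sequence[Variant] = (),
                    consensus_depth: int = 6000,
                    level_weights: Mapping[int, float] | None = None,
                    error_mean: float = 2e-4, error_rho: float = 1e-4,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw a level pileup directly from the consensus-count process.

    Per (position, level) the consensus depth is multinomial over levels;
    background errors per substitution are beta-binomial with total mean
    ``error_mean`` (split evenly over the three alternatives) and intra-class
    correlation ``error_rho``; true variant molecules add a further binomial
    component at the variant's AF.
    """
    if level_weights is None:
        level_weights = {2: 0.40, 3: 0.21, 4: 0.39}  # nbinom default, given >= 2
    levels = sorted(level_weights)
    w = np.array([level_weights[l] for l in levels], dtype=float)
    w = w / w.sum()
    af_at = {v.pos: v for v in variants}
    mu = error_mean / 3.0
    if error_rho > 0:
        m = (1.0 - error_rho) / error_rho
        a, b = mu * m, (1 - mu) * m
    rows = []
    for pos in positions:
        refb = ref_bases[pos]
        depths = rng.multinomial(consensus_depth, w)
        for lvl, d in zip(levels, depths):
            counts = {base: 0 for base in BASES}
            for altb in BASES:
                if altb == refb:
                    continue
                if error_rho > 0:
                    p = rng.beta(a, b)
                else:
                    p = mu
                k = rng.binomial(d, p) if d else 0
                counts[altb] += int(k)
            v = af_at.get(pos)
            if v is not None and v.af > 0 and d:
                counts[v.alt] += int(rng.binomial(d, v.af))
            n_err = sum(counts.values())
            counts[refb] = max(0, d - n_err)
            total = sum(counts.values())
            rows.append({"chrom": "sim1", "pos": pos, "level": lvl,
                         "depth": total, "nA": counts["A"], "nC": counts["C"],
                         "nG": counts["G"], "nT": counts["T"]})
    return pd.DataFrame(rows)


def simulate_site_observations(n_sites: int, *, depth: int = 5000,
                               error_mean: float = 2e-4, error_rho: float = 1e-4,
                               level: int = 2,
                               rng: np.random.Generator) -> pd.DataFrame:
    """Variant-free per-site alt-count observations for error-model work.

    Each site has a random reference base and three substitution
    observations drawn from a beta-binomial with per-substitution mean
    ``error_mean / 3`` and intra-class correlation ``error_rho``.

    Returns columns ``pos, ref, substitution, level, depth, alt_count``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    refs = rng.integers(0, 4, size=n_sites)
    mu = error_mean / 3.0
    rows = {"pos": [], "ref": [], "substitution": [], "level": [],
            "depth": [], "alt_count": []}
    n_obs = 3 * n_sites
    if error_rho > 0:
        m = (1.0 - error_rho) / error_rho
        p = rng.beta(mu * m, (1 - mu) * m, size=n_obs)
    else:
        p = np.full(n_obs, mu)
    ks = rng.binomial(depth, p)
    i = 0
    for site in range(n_sites):
        refb = BASES[refs[site]]
        for altb in BASES:
            if altb == refb:
                continue
            rows["pos"].append(site + 1)
            rows["ref"].append(refb)
            rows["substitution"].append(f"{refb}>{altb}")
            rows["level"].append(level)
            rows["depth"].append(depth)
            rows["alt_count"].append(int(ks[i]))
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read/reference output


def write_reads(family_table: pd.DataFrame, out_dir, *,
                umi_tag: str = "RX", prefix: str = "sim",
                reference: Mapping[int, str] | None = None,
                chrom_length: int | None = None) -> tuple[str, str]:
    """Write a family table as a coordinate-sorted BAM plus reference FASTA.

    Each read becomes a 1 bp alignment (pileup semantics) carrying its UMI in
    ``umi_tag``.  Returns ``(bam_path, fasta_path)``.  An empty table raises
    before any file is created.
    """
    import os

    import pysam

    if family_table.empty:
        raise ValueError("cannot write an empty family table")
    os.makedirs(out_dir, exist_ok=True)
    chroms = sorted(family_table["chrom"].unique())
    max_pos = int(family_table["pos"].max())
    length = chrom_length or max_pos + 10

    fasta_path = os.path.join(out_dir, f"{prefix}.fa")
    with open(fasta_path, "w") as fh:
        for chrom in chroms:
            seq = ["N"] * length
            if reference:
                for p, b in reference.items():
                    if 1 <= p <= length:
                        seq[p - 1] = b
            fh.write(f">{chrom}\n")
            for i in range(0, length, 60):
                fh.write("".join(seq[i:i + 60]) + "\n")

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": length} for c in chroms]}
    bam_path = os.path.join(out_dir, f"{prefix}.bam")
    table = family_table.sort_values(["chrom", "pos", "umi", "copy_index"],
                                     kind="mergesort")
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        tid = {c: i for i, c in enumerate(chroms)}
        for i, row in enumerate(table.itertuples(index=False)):
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = f"r{i:09d}:{row.umi}:{row.copy_index}"
            rec.query_sequence = row.base
            rec.query_qualities = pysam.qualitystring_to_array(chr(33 + int(row.qual)))
            rec.reference_id = tid[row.chrom]
            rec.reference_start = int(row.pos) - 1
            rec.cigartuples = [(0, 1)]
            rec.mapping_quality = 60
            rec.flag = 0
            rec.set_tag(umi_tag, str(row.umi))
            bam.write(rec)
    pysam.index(bam_path)
    return bam_path, fasta_path
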