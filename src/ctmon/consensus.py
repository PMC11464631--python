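"""UMI family grouping, consensus calling and level-stratified pileups.

Ultra-deep targeted sequencing of cell-free DNA tags every original plasma
DNA molecule with a unique molecular identifier (UMI) before amplification,
so all sequencing reads carrying the same (corrected) UMI at the same mapping
position are copies of one molecule.  Collapsing each family of copies to a
consensus base suppresses polymerase and sequencer substitution errors; the
more copies, the stronger the suppression.  Families are stratified into
*correction levels*: 2-fold (exactly two copies), 3-fold (three copies) and
4-fold (four or more copies).  Families with a single read carry no error
correction and are discarded.

The module offers two equivalent routes:

* an object route (:func:`group_reads` -> :func:`call_consensus` ->
  :func:`build_pileup`) convenient for inspection and small inputs, and
* a vectorised route (:func:`pileup_from_family_table`) used by the
  simulator and the pipeline for millions of reads.

Both produce the same :class:`LevelPileup` table (tested), with one row per
(chrom, pos, level) holding the consensus depth and per-base counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
LEVELS = (2, 3, 4)
#: maximum correction level; families with >= LEVEL_CAP copies are pooled
LEVEL_CAP = 4

FAMILY_TABLE_COLUMNS = ["chrom", "pos", "umi", "copy_index", "base", "qual"]
PILEUP_COLUMNS = ["chrom", "pos", "level", "depth", "nA", "nC", "nG", "nT"]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class UmiFamily:
    """All read base observations sharing a corrected UMI and position."""

    chrom: str
    pos: int  # 1-based reference coordinate
    corrected_umi: str
    member_bases: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_bases)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("UmiFamily requires at least one member base")


@dataclass(frozen=True)
class ConsensusCall:
    """A consensus base at a correction level (2-, 3- or 4-fold)."""

    chrom: str
    pos: int
    base: str
    level: int

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level}")
        if self.base not in BASES:
            raise ValueError(f"base must be one of {BASES}, got {self.base!r}")


# ---------------------------------------------------------------------------
# UMI encoding helpers


def _umi_to_codes(umis: Sequence[str]) -> tuple[np.ndarray, int]:
    """Encode equal-length ACGT UMIs as base-4 integers.

    The encoding is order-preserving (A<C<G<T maps to 0<1<2<3), so numeric
    comparisons coincide with lexicographic comparisons on the strings.
    """
    arr = np.asarray(umis, dtype="U")
    if arr.size == 0:
        return np.empty(0, dtype=np.int64), 0
    length = len(arr[0])
    if length == 0 or not all(len(u) == length for u in arr):
        raise ValueError("UMIs must be non-empty and of equal length")
    lut = np.full(128, -1, dtype=np.int8)
    for b, c in BASE_TO_CODE.items():
        lut[ord(b)] = c
    cp = arr.astype(f"U{length}").view(np.uint32).reshape(arr.size, length)
    if cp.max(initial=0) >= 128:
        raise ValueError("UMIs contain non-ACGT characters")
    digits = lut[cp]
    if (digits < 0).any():
        raise ValueError("UMIs contain non-ACGT characters")
    weights = 4 ** np.arange(length - 1, -1, -1, dtype=np.int64)
    return digits.astype(np.int64) @ weights, length


def _codes_to_umi(codes: np.ndarray, length: int) -> np.ndarray:
    digits = (codes[:, None] // (4 ** np.arange(length - 1, -1, -1, dtype=np.int64))) % 4
    chars = np.array(list(BASES), dtype="U1")[digits]
    return chars.view(f"U{length}").ravel()


def _correct_codes_at_position(codes: np.ndarray, counts: np.ndarray,
                               length: int) -> np.ndarray:
    """Directional Hamming-1 merge of the *sorted unique* UMI codes at one
    position.

    Each UMI whose family is smaller than (or, on ties, lexicographically
    larger than) a Hamming-distance-1 neighbour is re-assigned to that
    neighbour's UMI; chains (A->B->C) resolve to the final root.  Returns the
    index of the corrected UMI for each input UMI.
    """
    n = codes.size
    parent = np.arange(n)
    if n <= 1:
        return parent
    weights = 4 ** np.arange(length - 1, -1, -1, dtype=np.int64)
    digits = (codes[:, None] // weights[None, :]) % 4
    # all single-base edits of every UMI (3L candidates each)
    delta = np.arange(4)[None, None, :] - digits[:, :, None]
    cand = codes[:, None, None] + delta * weights[None, :, None]
    cand = cand.reshape(n, -1)
    idx = np.searchsorted(codes, cand)
    idx_c = np.clip(idx, 0, n - 1)
    hit = (codes[idx_c] == cand) & (cand != codes[:, None])
    src, slot = np.nonzero(hit)
    dst = idx_c[src, slot]
    # keep only edges pointing at a strictly "better" family
    better = (counts[dst] > counts[src]) | (
        (counts[dst] == counts[src]) & (codes[dst] < codes[src])
    )
    src, dst = src[better], dst[better]
    if src.size:
        # per source UMI keep the best target: largest family, ties -> smaller UMI
        order = np.lexsort((codes[dst], -counts[dst], src))
        first = np.ones(order.size, dtype=bool)
        first[1:] = src[order][1:] != src[order][:-1]
        sel = order[first]
        parent[src[sel]] = dst[sel]
        while True:  # resolve chains; pointers strictly ascend, so this terminates
            squashed = parent[parent]
            if np.array_equal(squashed, parent):
                break
            parent = squashed
    return parent


# ---------------------------------------------------------------------------
# vectorised route


def _family_arrays(table: pd.DataFrame, correct_umis: bool = True):
    """Group a read table into families and return per-family arrays.

    Returns (chrom_categories, fam_chrom_code, fam_pos, fam_umi_code,
    base_count_matrix, umi_length).
    """
    required = {"chrom", "pos", "umi", "base"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"family table missing columns: {sorted(missing)}")
    bad = table["umi"].isna() | (table["umi"].astype(str).str.len() == 0)
    if bad.any():
        ids = list(table.index[bad][:20])
        raise ValueError(f"records missing a UMI: {ids}")

    chrom_codes, chrom_cats = pd.factorize(table["chrom"], sort=True)
    pos = table["pos"].to_numpy(np.int64)
    umi_labels, umi_uniques = pd.factorize(table["umi"])
    uniq_codes, length = _umi_to_codes(np.asarray(umi_uniques))
    read_code = uniq_codes[umi_labels]
    base_code = np.array([BASE_TO_CODE.get(b, -1) for b in table["base"]], dtype=np.int8)
    if (base_code < 0).any():
        raise ValueError("family table contains non-ACGT bases")

    order = np.lexsort((read_code, pos, chrom_codes))
    chrom_s, pos_s = chrom_codes[order], pos[order]
    code_s, base_s = read_code[order], base_code[order]

    # position-block boundaries
    newblock = np.ones(order.size, dtype=bool)
    newblock[1:] = (chrom_s[1:] != chrom_s[:-1]) | (pos_s[1:] != pos_s[:-1])
    starts = np.flatnonzero(newblock)
    ends = np.append(starts[1:], order.size)

    corrected = code_s.copy()
    if correct_umis:
        for s, e in zip(starts, ends):
            block = code_s[s:e]
            cu, inv, cnt = np.unique(block, return_inverse=True, return_counts=True)
            if cu.size > 1:
                root = _correct_codes_at_position(cu, cnt, length)
                corrected[s:e] = cu[root][inv]

    # family id = run of equal (chrom, pos, corrected umi); needs a re-sort of
    # corrected codes within each block
    order2 = np.lexsort((corrected, pos_s, chrom_s))
    chrom_f, pos_f = chrom_s[order2], pos_s[order2]
    code_f, base_f = corrected[order2], base_s[order2]
    newfam = np.ones(order2.size, dtype=bool)
    newfam[1:] = (chrom_f[1:] != chrom_f[:-1]) | (pos_f[1:] != pos_f[:-1]) | (
        code_f[1:] != code_f[:-1]
    )
    fam_id = np.cumsum(newfam) - 1
    n_fam = fam_id[-1] + 1 if fam_id.size else 0

    counts = np.zeros((n_fam, 4), dtype=np.int64)
    np.add.at(counts, (fam_id, base_f.astype(np.int64)), 1)
    fam_first = np.flatnonzero(newfam)
    return (chrom_cats, chrom_f[fam_first], pos_f[fam_first], code_f[fam_first],
            counts, length)


def _consensus_from_counts(counts: np.ndarray):
    """Strict-majority consensus per family from a (n, 4) base-count matrix.

    Returns (keep mask, consensus base code, level) for kept families:
    size >= 2 and the top base holds more than half of the members.
    """
    sizes = counts.sum(axis=1)
    maj = counts.argmax(axis=1)
    majcnt = counts.max(axis=1)
    keep = (sizes >= 2) & (2 * majcnt > sizes)
    level = np.minimum(sizes, LEVEL_CAP)
    return keep, maj, level, sizes


def pileup_from_family_table(table: pd.DataFrame, *,
                             correct_umis: bool = True) -> pd.DataFrame:
    """Vectorised family grouping + consensus + level pileup.

    Parameters
    ----------
    table
        Read table with columns ``chrom, pos, umi, base`` (``copy_index`` and
        ``qual`` are carried by the on-disk format but ignored here; base
        qualities do not enter the count-based consensus).
    correct_umis
        Apply the directional Hamming-distance-1 UMI merge before grouping.

    Returns
    -------
    DataFrame with columns ``chrom, pos, level, depth, nA, nC, nG, nT``,
    sorted by (chrom, pos, level).
    """
    if table.empty:
        return pd.DataFrame(columns=PILEUP_COLUMNS).astype(
            {c: int for c in PILEUP_COLUMNS[1:]} | {"chrom": object})
    chrom_cats, fam_chrom, fam_pos, _, counts, _ = _family_arrays(
        table, correct_umis=correct_umis)
    keep, maj, level, _ = _consensus_from_counts(counts)

    kc, kp = fam_chrom[keep], fam_pos[keep]
    kl, kb = level[keep], maj[keep]
    if kc.size == 0:
        return pd.DataFrame(columns=PILEUP_COLUMNS).astype(
            {c: int for c in PILEUP_COLUMNS[1:]} | {"chrom": object})

    # aggregate consensus calls per (chrom, pos, level, base)
    order = np.lexsort((kb, kl, kp, kc))
    kc, kp, kl, kb = kc[order], kp[order], kl[order], kb[order]
    newrow = np.ones(kc.size, dtype=bool)
    newrow[1:] = (kc[1:] != kc[:-1]) | (kp[1:] != kp[:-1]) | (kl[1:] != kl[:-1])
    row_id = np.cumsum(newrow) - 1
    n_rows = row_id[-1] + 1
    mat = np.zeros((n_rows, 4), dtype=np.int64)
    np.add.at(mat, (row_id, kb.astype(np.int64)), 1)
    first = np.flatnonzero(newrow)
    out = pd.DataFrame({
        "chrom": np.asarray(chrom_cats)[kc[first]],
        "pos": kp[first],
        "level": kl[first],
        "depth": mat.sum(axis=1),
        "nA": mat[:, 0], "nC": mat[:, 1], "nG": mat[:, 2], "nT": mat[:, 3],
    })
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# object route


def group_reads(records, *, correct_umis: bool = True) -> list[UmiFamily]:
    """Partition read records into UMI families.

    ``records`` is a DataFrame (or anything accepted by the DataFrame
    constructor) with columns ``chrom, pos, umi, base``.  UMIs at the same
    position within Hamming distance 1 are merged into the larger family's
    corrected UMI (ties break to the lexicographically smaller UMI).

    Every input read belongs to exactly one returned family.
    """
    table = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if table.empty:
        return []
    chrom_cats, fam_chrom, fam_pos, fam_code, counts, length = _family_arrays(
        table, correct_umis=correct_umis)
    umis = _codes_to_umi(fam_code, length)
    families = []
    for i in range(counts.shape[0]):
        bases = []
        for b, c in zip(BASES, counts[i]):
            bases.extend([b] * int(c))
        families.append(UmiFamily(
            chrom=str(np.asarray(chrom_cats)[fam_chrom[i]]),
            pos=int(fam_pos[i]),
            corrected_umi=str(umis[i]),
            member_bases=tuple(bases),
        ))
    return families


def call_consensus(family: UmiFamily) -> ConsensusCall | None:
    """Strict-majority consensus for one family.

    Singletons carry no error correction and yield ``None``; so do families
    without a strict majority (>50% of members), e.g. a discordant pair.
    The correction level is the family size capped at 4 ("4-fold" pools all
    families with >= 4 copies).
    """
    if family.size < 2:
        return None
    tally: dict[str, int] = defaultdict(int)
    for b in family.member_bases:
        tally[b] += 1
    base, top = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
    if 2 * top <= family.size:
        return None
    return ConsensusCall(chrom=family.chrom, pos=family.pos, base=base,
                         level=min(family.size, LEVEL_CAP))


def build_pileup(calls: Iterable[ConsensusCall],
                 reference: Mapping[int, str] | None = None) -> pd.DataFrame:
    """Tabulate consensus calls into a level-stratified pileup.

    If ``reference`` (pos -> base) is given, calls at positions absent from
    it raise ``ValueError``.
    """
    rows: dict[tuple[str, int, int], np.ndarray] = {}
    for call in calls:
        if reference is not None and call.pos not in reference:
            raise ValueError(f"consensus call at position {call.pos} not on reference")
        key = (call.chrom, call.pos, call.level)
        if key not in rows:
            rows[key] = np.zeros(4, dtype=np.int64)
        rows[key][BASE_TO_CODE[call.base]] += 1
    if not rows:
        return pd.DataFrame(columns=PILEUP_COLUMNS).astype(
            {c: int for c in PILEUP_COLUMNS[1:]} | {"chrom": object})
    recs = [
        {"chrom": c, "pos": p, "level": lv, "depth": int(v.sum()),
         "nA": int(v[0]), "nC": int(v[1]), "nG": int(v[2]), "nT": int(v[3])}
        for (c, p, lv), v in sorted(rows.items())
    ]
    return pd.DataFrame(recs, columns=PILEUP_COLUMNS)


# ---------------------------------------------------------------------------
# error-rate measurement and I/O


def error_rate(pileup: pd.DataFrame, truth_bases: Mapping[int, str]) -> pd.DataFrame:
    """Empirical consensus error rate per correction level against truth.

    ``truth_bases`` maps position -> the true base of every position in the
    pileup.  Returns one row per level plus a pooled ``ge2`` row, with
    columns ``level, n_calls, n_errors, rate``; ``rate`` is NaN (flagged by
    ``defined=False``) where a level has zero calls — an undefined rate is
    never reported as 0.
    """
    if pileup.empty:
        rows = [{"level": str(l), "n_calls": 0, "n_errors": 0,
                 "rate": np.nan, "defined": False} for l in LEVELS]
        rows.append({"level": "ge2", "n_calls": 0, "n_errors": 0,
                     "rate": np.nan, "defined": False})
        return pd.DataFrame(rows)
    missing = set(pileup["pos"]) - set(truth_bases)
    if missing:
        raise ValueError(f"no truth base for positions {sorted(missing)[:10]}")
    truth = pileup["pos"].map(truth_bases)
    truth_count = np.zeros(len(pileup), dtype=np.int64)
    for b in BASES:
        sel = (truth == b).to_numpy()
        truth_count[sel] = pileup.loc[sel, f"n{b}"].to_numpy()
    err = pileup["depth"].to_numpy() - truth_count
    frame = pd.DataFrame({"level": pileup["level"].to_numpy(),
                          "n_calls": pileup["depth"].to_numpy(),
                          "n_errors": err})
    rows = []
    for l in LEVELS:
        sub = frame[frame["level"] == l]
        n, e = int(sub["n_calls"].sum()), int(sub["n_errors"].sum())
        rows.append({"level": str(l), "n_calls": n, "n_errors": e,
                     "rate": (e / n) if n else np.nan, "defined": n > 0})
    n, e = int(frame["n_calls"].sum()), int(frame["n_errors"].sum())
    rows.append({"level": "ge2", "n_calls": n, "n_errors": e,
                 "rate": (e / n) if n else np.nan, "defined": n > 0})
    return pd.DataFrame(rows)


def write_pileup(pileup: pd.DataFrame, path) -> None:
    """Write a pileup TSV with deterministic (chrom, pos, level) ordering."""
    out = pileup.sort_values(["chrom", "pos", "level"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup file missing columns: {sorted(missing)}")
    return df


def family_table_from_bam(path, *, umi_tag: str = "RX") -> pd.DataFrame:
    """Load single-position read observations from a UMI-tagged BAM.

    Each alignment contributes one observation at its 5'-most aligned
    reference coordinate (1-based); the UMI is taken from ``umi_tag``
    (default the de-facto standard ``RX``).  Strand is ignored: the UMIs are
    fixed single-stranded identifiers, not duplex pairs.
    """
    import pysam

    rows = {"chrom": [], "pos": [], "umi": [], "copy_index": [], "base": [],
            "qual": []}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            if not rec.has_tag(umi_tag):
                raise ValueError(f"read {rec.query_name} lacks UMI tag {umi_tag}")
            rows["chrom"].append(rec.reference_name)
            rows["pos"].append(rec.reference_start + 1)
            rows["umi"].append(rec.get_tag(umi_tag))
            rows["copy_index"].append(0)
            rows["base"].append(rec.query_sequence[0])
            q = rec.query_qualities
            rows["qual"].append(int(q[0]) if q is not None else 0)
    return pd.DataFrame(rows, columns=FAMILY_TABLE_COLUMNS)


def pileup_from_bam(path, *, umi_tag: str = "RX",
                    correct_umis: bool = True) -> pd.DataFrame:
    """BAM route to a level pileup; equals the family-table route."""
    return pileup_from_family_table(family_table_from_bam(path, umi_tag=umi_tag),
                                    correct_umis=correct_umis)
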