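"""EST screening cascade: vector masking, insertless calls, quality/polyA/
complexity trimming, resequencing dedup and sister-status propagation.

The cascade mirrors how raw single-pass cDNA reads are turned into a
high-quality trimmed set before clustering:

1.  vector/adapter masking (end-anchored, mismatch-tolerant),
2.  insertless-clone classification from the 5'-anchored masked run,
3.  sliding-window quality trimming (window mean phred),
4.  first length filter,
5.  polyA / polyT tail flagging and trimming near the read ends,
6.  second length filter and low-complexity filter,
7.  per-clone dedup of resequenced reads (longest high-quality kept),
8.  sister-status propagation (insertless/contaminant states are clone-level
    properties and copy to the other end read; quality-type failures do not),
9.  contaminant screening from an external homology table.

Each read ends with exactly one terminal status; per-library statistics are
reported in the attempted/insertless/contaminated/passing schema used for
EST-project sequencing reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import seqio
from ._util import complement_intervals, merge_intervals, revcomp, round_half_up
from .seqio import CloneRecord, Direction, ESTRecord, HitRow, Status

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass
class TrimParams:
    """Thresholds of the screening cascade.

    window/qual_threshold: sliding-window quality trimmer (11 bases, mean
    phred 15).  min_length: high-quality bases required to keep a read (100).
    low_complexity_max: maximal tolerated fraction of repeat-covered bases
    (0.50).  insertless_vector_5p / insertless_insert_max: the two-clause
    insertless rule (>=200 masked from the 5' end, or a shorter masked run
    followed by <100 unmasked bases).  polya_end_window / polya_min_run:
    where a tail may start and how long it must be.
    """

    window: int = 11
    qual_threshold: float = 15.0
    min_length: int = 100
    low_complexity_max: float = 0.50
    insertless_vector_5p: int = 200
    insertless_insert_max: int = 100
    polya_end_window: int = 50
    polya_min_run: int = 12

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0 < self.low_complexity_max <= 1):
            raise ValueError("low_complexity_max must be in (0, 1]")
        if min(self.qual_threshold, self.min_length, self.polya_min_run) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class TrimResult:
    """Outcome of the cascade for one read.

    ``kept`` is the retained half-open interval on the *original* read
    coordinates, or None when the read fails; ``reasons`` lists the rules
    applied, in order.
    """

    est_id: str
    kept: Optional[Interval]
    status: Status
    polyA_flag: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def kept_len(self) -> int:
        return 0 if self.kept is None else self.kept[1] - self.kept[0]


# ---------------------------------------------------------------------------
# vector masking

def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _end_anchored_match(
    read: np.ndarray, vector: np.ndarray, min_match: int, max_rate: float
) -> int:
    """Longest k such that read[:k] matches some vector substring ending
    anywhere, with mismatches <= max_rate*k.  Returns 0 if none >= min_match."""
    best = 0
    lr, lv = len(read), len(vector)
    for j in range(lv):
        m = min(lr, lv - j)
        if m < min_match:
            continue
        mism = np.cumsum(read[:m] != vector[j : j + m])
        ks = np.arange(1, m + 1)
        ok = np.nonzero((mism <= max_rate * ks) & (ks >= min_match))[0]
        if ok.size:
            best = max(best, int(ok[-1]) + 1)
    return best


def _interior_matches(
    bases: str, vector: str, min_match: int, max_rate: float, seed_len: int = 12
) -> list[Interval]:
    """Seed-and-extend interior vector hits (exact seed, mismatch-tolerant
    extension to maximal length with rate <= max_rate)."""
    out = []
    seeds: dict[str, list[int]] = {}
    for j in range(len(vector) - seed_len + 1):
        seeds.setdefault(vector[j : j + seed_len], []).append(j)
    i = 0
    while i <= len(bases) - seed_len:
        word = bases[i : i + seed_len]
        hit_end = 0
        for j in seeds.get(word, []):
            # extend left
            s, vs = i, j
            mism = 0
            while s > 0 and vs > 0:
                if bases[s - 1] != vector[vs - 1]:
                    if (mism + 1) > max_rate * (i + seed_len - s + 1):
                        break
                    mism += 1
                s -= 1
                vs -= 1
            # extend right
            e, ve = i + seed_len, j + seed_len
            while e < len(bases) and ve < len(vector):
                if bases[e] != vector[ve]:
                    if (mism + 1) > max_rate * (e - s + 1):
                        break
                    mism += 1
                e += 1
                ve += 1
            if e - s >= min_match:
                out.append((s, e))
                hit_end = max(hit_end, e)
        i = max(i + 1, hit_end - seed_len + 1)
    return out


def mask_vector(
    record: ESTRecord | str,
    vectors: Sequence[str],
    min_match: int = 20,
    max_mismatch_rate: float = 0.05,
) -> list[Interval]:
    """Mask vector/adapter sequence on a read.

    End-anchored matches (a vector substring covering the very start or very
    end of the read) of length >= min_match at mismatch rate <=
    max_mismatch_rate are masked, as are interior vector hits; overlapping
    intervals are merged and returned sorted by start.
    """
    bases = record.bases if isinstance(record, ESTRecord) else record
    if not vectors:
        raise ValueError("vectors must be non-empty")
    read = _encode(bases)
    intervals: list[Interval] = []
    candidates = []
    for v in vectors:
        candidates.append(v.upper())
        candidates.append(revcomp(v.upper()))
    for v in candidates:
        venc = _encode(v)
        k5 = _end_anchored_match(read, venc, min_match, max_mismatch_rate)
        if k5:
            intervals.append((0, k5))
        k3 = _end_anchored_match(read[::-1], venc[::-1], min_match, max_mismatch_rate)
        if k3:
            intervals.append((len(bases) - k3, len(bases)))
        intervals.extend(
            _interior_matches(bases, v, min_match, max_mismatch_rate)
        )
    return merge_intervals(intervals)


# ---------------------------------------------------------------------------
# insertless classification

def classify_insertless(mask: list[Interval], read_len: int, p: TrimParams) -> bool:
    """Two-clause insertless rule on the 5'-anchored masked run.

    True iff the masked run anchored at position 0 is >= insertless_vector_5p
    long, or it is shorter and the unmasked stretch immediately after it is
    < insertless_insert_max bases.
    """
    merged = merge_intervals(mask)
    vec5 = 0
    if merged and merged[0][0] == 0:
        vec5 = merged[0][1]
    if vec5 >= p.insertless_vector_5p:
        return True
    # unmasked stretch following the (possibly empty) 5' masked run
    nxt = read_len
    for s, e in merged:
        if s > vec5:
            nxt = s
            break
    return (nxt - vec5) < p.insertless_insert_max


# ---------------------------------------------------------------------------
# quality trimming

def quality_trim(quals: Sequence[int], p: TrimParams) -> Optional[Interval]:
    """Longest interval whose every in-window mean phred is >= the threshold.

    Every length-``window`` sub-window fully inside the returned interval has
    mean quality >= qual_threshold; candidate intervals shorter than the
    window are judged by their whole-interval mean.  Ties go to the 5'-most
    interval.  Returns None when no base qualifies at all; callers apply the
    min-length rule separately.
    """
    q = np.asarray(quals, dtype=float)
    n = len(q)
    if n == 0:
        raise ValueError("quals must be non-empty")
    w = p.window
    if n >= w:
        csum = np.concatenate([[0.0], np.cumsum(q)])
        means = (csum[w:] - csum[:-w]) / w  # mean of window starting at i
        ok = means >= p.qual_threshold
        best: Optional[Interval] = None
        i = 0
        while i < len(ok):
            if ok[i]:
                j = i
                while j + 1 < len(ok) and ok[j + 1]:
                    j += 1
                cand = (i, j + w)  # all windows i..j pass
                if best is None or (cand[1] - cand[0]) > (best[1] - best[0]):
                    best = cand
                i = j + 1
            i += 1
        if best is not None:
            return best
    # no full window passes: longest sub-window interval by its own mean
    csum = np.concatenate([[0.0], np.cumsum(q)])
    for length in range(min(w - 1, n), 0, -1):
        means = (csum[length:] - csum[:-length]) / length
        hits = np.nonzero(means >= p.qual_threshold)[0]
        if hits.size:
            s = int(hits[0])
            return (s, s + length)
    return None


# ---------------------------------------------------------------------------
# polyA / polyT tails

def _tail_run(sub: str, ch: str, p: TrimParams, three_prime: bool) -> Optional[Interval]:
    """Qualifying tail run of ``ch`` near one end, tolerating one non-``ch``
    base per 12 bases of run.  Returns the run interval or None."""
    n = len(sub)
    win = min(p.polya_end_window, n)
    is_ch = np.asarray([c == ch for c in sub], dtype=int)
    csum = np.concatenate([[0], np.cumsum(1 - is_ch)])  # non-ch prefix counts

    def mismatches(s: int, e: int) -> int:
        return int(csum[e] - csum[s])

    # run boundaries must be the target base; tolerance applies only inside
    if three_prime:
        lo = n - win
        best_s = None
        for s in range(lo, n - p.polya_min_run + 1):
            if sub[s] != ch:
                continue
            for e in range(n, s + p.polya_min_run - 1, -1):
                if sub[e - 1] == ch and mismatches(s, e) <= (e - s) // 12:
                    best_s = s if best_s is None else min(best_s, s)
                    break
        if best_s is not None:
            return (best_s, n)
    else:
        for e in range(n, p.polya_min_run - 1, -1):
            if sub[e - 1] != ch:
                continue
            for s in range(0, min(win, e - p.polya_min_run + 1)):
                if sub[s] == ch and mismatches(s, e) <= (e - s) // 12:
                    return (0, e)
    return None


def detect_polya(bases: str, p: TrimParams) -> tuple[bool, Optional[Interval]]:
    """Flag and locate a polyA (3') or polyT (5') tail near the read ends.

    A run of >= polya_min_run A's starting within polya_end_window of the 3'
    end — or T's ending within polya_end_window of the 5' end — sets the
    flag; the trim interval extends the run through its end of the read.  The
    3' A-tail wins when both are present (the caller may re-run detection on
    the trimmed read to catch the other end).
    """
    if not bases:
        raise ValueError("bases must be non-empty")
    tail3 = _tail_run(bases, "A", p, three_prime=True)
    if tail3 is not None:
        return True, tail3
    tail5 = _tail_run(bases, "T", p, three_prime=False)
    if tail5 is not None:
        return True, tail5
    return False, None


# ---------------------------------------------------------------------------
# low complexity

def low_complexity_fraction(bases: str) -> float:
    """Fraction of positions covered by simple repeats.

    Covered positions are those inside homopolymer runs of length >= 5 or
    inside perfect tandem runs of a 2- or 3-mer with >= 4 copies; the
    fraction is the size of the union of covered positions over the length.
    """
    n = len(bases)
    if n == 0:
        raise ValueError("bases must be non-empty")
    covered = np.zeros(n, dtype=bool)
    # homopolymer runs >= 5
    i = 0
    while i < n:
        j = i
        while j + 1 < n and bases[j + 1] == bases[i]:
            j += 1
        if j - i + 1 >= 5:
            covered[i : j + 1] = True
        i = j + 1
    # tandem runs of 2-/3-mers with >= 4 copies (maximal stretches where
    # seq[j] == seq[j-p]); partial trailing copies are part of the stretch
    for period in (2, 3):
        s = 0
        while s < n - period:
            e = s + period
            while e < n and bases[e] == bases[e - period]:
                e += 1
            if (e - s) // period >= 4:
                covered[s:e] = True
                s = e - period + 1
            else:
                s += 1
    return float(covered.sum()) / n


# ---------------------------------------------------------------------------
# clone-level logic

def screen_contaminants(
    records: Iterable[ESTRecord],
    hits: Iterable[HitRow],
    contaminant_subjects: set[str],
    strong=None,
) -> list[ESTRecord]:
    """Mark reads with a strong hit to a listed contaminant subject.

    ``strong`` is a :class:`estkit.annotate.StrongMatchConfig`; the default
    is the standard strong-match threshold (E <= 1e-5).
    """
    from .annotate import StrongMatchConfig, filter_strong

    strong = strong or StrongMatchConfig()
    flagged = {
        h.query_id
        for h in filter_strong(list(hits), strong)
        if h.subject_id in contaminant_subjects
    }
    records = list(records)
    for r in records:
        if r.est_id in flagged:
            r.status = Status.CONTAMINANT
    return records


def dedup_resequenced(
    clone: CloneRecord, results: Mapping[str, TrimResult]
) -> dict[Direction, Optional[str]]:
    """Keep the longest passing read per direction; mark the rest DUPLICATE.

    Ties are broken toward the lexicographically smaller est_id, for
    determinism.  Returns the retained est_id per direction (None when no
    read of that direction passed).
    """
    retained: dict[Direction, Optional[str]] = {}
    for direction, ids in (
        (Direction.FWD_5P, clone.fwd_est_ids),
        (Direction.REV_3P, clone.rev_est_ids),
    ):
        passing = [
            i for i in ids if results[i].status is Status.PASS and results[i].kept
        ]
        if not passing:
            retained[direction] = None
            continue
        passing.sort(key=lambda i: (-results[i].kept_len, i))
        retained[direction] = passing[0]
        for i in passing[1:]:
            results[i].status = Status.DUPLICATE
            results[i].reasons.append("duplicate_of:" + passing[0])
    return retained


def propagate_sister_status(
    clone: CloneRecord, results: Mapping[str, TrimResult]
) -> Mapping[str, TrimResult]:
    """Copy clone-level failure states (insertless, contaminant) to sisters.

    Quality-type failures (LOW_QUALITY, LOW_COMPLEXITY, SHORT) stay with the
    individual read.  When two sisters carry *different* propagating statuses
    each keeps its own and a warning is logged.  DUPLICATE reads are left
    alone.
    """
    ids = [i for i in clone.est_ids if i in results]
    present = {results[i].status for i in ids} & seqio.PROPAGATING_STATUSES
    if not present:
        return results
    if len(present) > 1:
        logger.warning(
            "clone %s: conflicting propagating statuses %s; keeping per-read statuses",
            clone.clone_id,
            sorted(s.value for s in present),
        )
        return results
    (status,) = present
    for i in ids:
        r = results[i]
        if r.status in (status, Status.DUPLICATE, *seqio.PROPAGATING_STATUSES):
            continue
        r.status = status
        r.kept = None
        r.reasons.append("sister_propagated:" + status.value)
    return results


# ---------------------------------------------------------------------------
# library statistics (sequencing-report schema)

@dataclass
class LibraryStats:
    """Per-library screening statistics with derived percentages."""

    library: str
    attempted_ests: int
    attempted_clones: int
    insertless_clones: int
    contaminated_clones: int
    clones_passing: int
    ests_passing: int
    mean_trimmed_len: Optional[float] = None
    sd_trimmed_len: Optional[float] = None

    def _pct(self, count: int, base: int) -> float:
        return round_half_up(100.0 * count / base, 1) if base else 0.0

    @property
    def pct_insertless(self) -> float:
        return self._pct(self.insertless_clones, self.attempted_clones)

    @property
    def pct_contaminated(self) -> float:
        return self._pct(self.contaminated_clones, self.attempted_clones)

    @property
    def pct_clones_passing(self) -> float:
        return self._pct(self.clones_passing, self.attempted_clones)

    @property
    def pct_ests_passing(self) -> float:
        return self._pct(self.ests_passing, self.attempted_ests)


def aggregate_library_stats(rows: Sequence[LibraryStats], label: str = "Total") -> LibraryStats:
    """Totals row: count columns are column sums, percentages recomputed from
    the pooled counts."""
    return LibraryStats(
        library=label,
        attempted_ests=sum(r.attempted_ests for r in rows),
        attempted_clones=sum(r.attempted_clones for r in rows),
        insertless_clones=sum(r.insertless_clones for r in rows),
        contaminated_clones=sum(r.contaminated_clones for r in rows),
        clones_passing=sum(r.clones_passing for r in rows),
        ests_passing=sum(r.ests_passing for r in rows),
    )


def stats_frame(rows: Sequence[LibraryStats]) -> pd.DataFrame:
    """Render stats rows (plus a totals row) as a report table."""
    all_rows = list(rows)
    if len(all_rows) > 1:
        all_rows.append(aggregate_library_stats(all_rows))
    recs = []
    for r in all_rows:
        recs.append(
            {
                "library": r.library,
                "attempted_ests": r.attempted_ests,
                "attempted_clones": r.attempted_clones,
                "insertless_clones": r.insertless_clones,
                "pct_insertless": r.pct_insertless,
                "contaminated_clones": r.contaminated_clones,
                "pct_contaminated": r.pct_contaminated,
                "clones_passing": r.clones_passing,
                "pct_clones_passing": r.pct_clones_passing,
                "ests_passing": r.ests_passing,
                "pct_ests_passing": r.pct_ests_passing,
                "mean_trimmed_len": r.mean_trimmed_len,
                "sd_trimmed_len": r.sd_trimmed_len,
            }
        )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# the full cascade

def _trim_one(rec: ESTRecord, vectors: Sequence[str], p: TrimParams,
              min_match: int, max_mismatch_rate: float) -> TrimResult:
    res = TrimResult(rec.est_id, kept=None, status=Status.PASS)
    mask = mask_vector(rec, vectors, min_match, max_mismatch_rate) if vectors else []
    # sequencing errors can fray a vector hit into fragments or detach it
    # from the read start; unmasked islands shorter than a matchable hit
    # (< min_match) between or before masked intervals cannot be confirmed
    # as insert, so bridge them into the mask
    if mask and 0 < mask[0][0] < min_match:
        mask = [(0, mask[0][1])] + list(mask[1:])
    bridged = list(mask[:1])
    for s, e in mask[1:]:
        if s - bridged[-1][1] < min_match:
            bridged[-1] = (bridged[-1][0], e)
        else:
            bridged.append((s, e))
    mask = bridged
    rec.mask = mask
    if mask:
        res.reasons.append("vector_masked")
    if classify_insertless(mask, len(rec), p):
        res.status = Status.INSERTLESS
        res.reasons.append("insertless")
        return res
    # quality trim within each unmasked segment; best interval wins
    best: Optional[Interval] = None
    for s, e in complement_intervals(mask, len(rec)):
        iv = quality_trim(rec.quals[s:e], p)
        if iv is None:
            continue
        cand = (s + iv[0], s + iv[1])
        if best is None or (cand[1] - cand[0]) > (best[1] - best[0]):
            best = cand
    if best is None or (best[1] - best[0]) < p.min_length:
        res.status = Status.LOW_QUALITY
        res.reasons.append("low_quality")
        return res
    res.reasons.append("quality_trimmed")
    ks, ke = best
    # tail trimming; run twice so a read can lose both a 3' A and 5' T tail
    for _ in range(2):
        flag, iv = detect_polya(rec.bases[ks:ke], p)
        if not flag:
            break
        res.polyA_flag = True
        rec.polyA_flag = True
        res.reasons.append("polyA_trimmed")
        s, e = iv
        if s > 0:  # 3' tail: run through the segment end
            ke = ks + s
        else:  # 5' tail
            ks = ks + e
        if ke - ks <= 0:
            break
    if ke - ks < p.min_length:
        res.status = Status.SHORT
        res.reasons.append("short")
        return res
    if low_complexity_fraction(rec.bases[ks:ke]) > p.low_complexity_max:
        res.status = Status.LOW_COMPLEXITY
        res.reasons.append("low_complexity")
        return res
    res.kept = (ks, ke)
    return res


def run_cleanup(
    records: Sequence[ESTRecord],
    vectors: Sequence[str],
    p: TrimParams | None = None,
    contaminant_hits: Sequence[HitRow] | None = None,
    contaminant_subjects: set[str] | None = None,
    strong=None,
    min_match: int = 20,
    max_mismatch_rate: float = 0.05,
) -> tuple[dict[str, TrimResult], pd.DataFrame]:
    """Run the whole screening cascade and report per-library statistics.

    Returns (est_id -> TrimResult, stats table).  Every read receives exactly
    one terminal status; reads whose trimming succeeded and survived the
    clone-level rules stay PASS with a kept interval.
    """
    p = p or TrimParams()
    results: dict[str, TrimResult] = {}
    for rec in records:
        results[rec.est_id] = _trim_one(rec, vectors, p, min_match, max_mismatch_rate)

    clones = seqio.pair_sisters(records)
    for clone in clones:
        dedup_resequenced(clone, results)
    for clone in clones:
        propagate_sister_status(clone, results)

    if contaminant_hits and contaminant_subjects:
        screen_contaminants(records, contaminant_hits, contaminant_subjects, strong)
        for rec in records:
            if rec.status is Status.CONTAMINANT:
                r = results[rec.est_id]
                if r.status is not Status.CONTAMINANT:
                    r.status = Status.CONTAMINANT
                    r.kept = None
                    r.reasons.append("contaminant")
        for clone in clones:
            propagate_sister_status(clone, results)

    # keep record statuses in sync with the authoritative results
    for rec in records:
        rec.status = results[rec.est_id].status
        rec.polyA_flag = results[rec.est_id].polyA_flag

    by_lib: dict[str, list[CloneRecord]] = {}
    for clone in clones:
        by_lib.setdefault(clone.library, []).append(clone)
    rows = []
    for lib in sorted(by_lib):
        lib_clones = by_lib[lib]
        est_ids = [i for c in lib_clones for i in c.est_ids]
        statuses = {i: results[i].status for i in est_ids}

        def clone_has(clone: CloneRecord, status: Status) -> bool:
            return any(statuses[i] is status for i in clone.est_ids)

        kept_lens = [
            results[i].kept_len for i in est_ids if statuses[i] is Status.PASS
        ]
        rows.append(
            LibraryStats(
                library=lib,
                attempted_ests=len(est_ids),
                attempted_clones=len(lib_clones),
                insertless_clones=sum(clone_has(c, Status.INSERTLESS) for c in lib_clones),
                contaminated_clones=sum(clone_has(c, Status.CONTAMINANT) for c in lib_clones),
                clones_passing=sum(clone_has(c, Status.PASS) for c in lib_clones),
                ests_passing=sum(s is Status.PASS for s in statuses.values()),
                mean_trimmed_len=float(np.mean(kept_lens)) if kept_lens else None,
                sd_trimmed_len=float(np.std(kept_lens, ddof=1)) if len(kept_lens) > 1 else None,
            )
        )
    return results, stats_frame(rows)
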