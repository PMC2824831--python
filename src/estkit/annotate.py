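"""Post-processing of tabular homology search results.

Nothing here runs a search; the inputs are parsed hit tables (see
:mod:`estkit.seqio`) from BLASTx/tBLASTx-style programs.  The operations are
the standard desk analyses over such tables:

* strong-match filtering by E-value (<= 1e-5) or bit score (>= 40),
* k-of-n agreement across several method-database combinations,
* full-length transcript assessment from the best protein alignment
  (are the query flanks long enough to cover the parts of the subject
  missing from the alignment, in nucleotide terms),
* KO/pathway coverage accounting and two-species pathway overlay,
* 3-way reciprocal-best-hit triangulation with Venn-region counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from ._util import round_half_up
from .seqio import HitRow


class MatchMode(Enum):
    EVALUE = "EVALUE"
    BITSCORE = "BITSCORE"


@dataclass(frozen=True)
class StrongMatchConfig:
    """What counts as a strong homology match.

    EVALUE mode keeps rows with evalue <= max_evalue (default 1e-5);
    BITSCORE mode keeps rows with bitscore >= min_bitscore (default 40).
    """

    max_evalue: float = 1e-5
    min_bitscore: float = 40.0
    mode: MatchMode = MatchMode.EVALUE

    def __post_init__(self) -> None:
        if self.max_evalue <= 0 or self.min_bitscore <= 0:
            raise ValueError("thresholds must be positive")

    def is_strong(self, hit: HitRow) -> bool:
        if self.mode is MatchMode.EVALUE:
            return hit.evalue <= self.max_evalue
        return hit.bitscore >= self.min_bitscore


def filter_strong(hits: Sequence[HitRow], cfg: StrongMatchConfig | None = None) -> list[HitRow]:
    """Keep only strong matches; a subset of the input, idempotent."""
    cfg = cfg or StrongMatchConfig()
    return [h for h in hits if cfg.is_strong(h)]


# ---------------------------------------------------------------------------
# k-of-n search agreement

@dataclass
class AgreementResult:
    n_searches: int
    histogram: dict[int, int]        # k -> number of ids matched by exactly k searches
    unmatched: int
    percentages: dict[int, float]    # over matched ids only


def agreement_matrix(
    strong_hits_by_search: Mapping[str, set[str]], universe: set[str]
) -> AgreementResult:
    """How many searches agree on each id.

    For every id in ``universe``, count the number k of search tags whose
    strong-match set contains it; ids with k = 0 are tallied separately and
    excluded from the percentage base.
    """
    n = len(strong_hits_by_search)
    if n < 1:
        raise ValueError("need at least one search tag")
    histogram = {k: 0 for k in range(1, n + 1)}
    unmatched = 0
    for cid in universe:
        k = sum(cid in s for s in strong_hits_by_search.values())
        if k == 0:
            unmatched += 1
        else:
            histogram[k] += 1
    matched = sum(histogram.values())
    percentages = {
        k: (round_half_up(100.0 * v / matched, 1) if matched else 0.0)
        for k, v in histogram.items()
    }
    return AgreementResult(n, histogram, unmatched, percentages)


# ---------------------------------------------------------------------------
# full-length assessment

DEFAULT_RIBOSOMAL_PATTERN = r"ribosomal protein"


@dataclass
class FullLengthVerdict:
    """Can the query theoretically span the subject's full coding sequence?

    The alignment leaves (s_start - 1) subject residues uncovered at the
    N-terminal side and (s_len - s_end) at the C-terminal side; in
    nucleotides that is three times as many.  The query is full-length when
    its unaligned flanks are at least that long on the matching sides.
    """

    contig_id: str
    subject_id: str
    orientation: str  # "FWD" | "REV"
    missing_5p_nt: int
    missing_3p_nt: int
    upstream_avail_nt: int
    downstream_avail_nt: int
    is_full_length: bool
    is_ribosomal: bool = False


def assess_full_length(
    best_hit: HitRow, ribosomal_pattern: str = DEFAULT_RIBOSOMAL_PATTERN
) -> FullLengthVerdict:
    """Full-length verdict from the single best protein alignment of a query.

    Requires the extended columns q_len and s_len (subject coordinates in
    amino acids).  A reversed query (q_start > q_end) swaps which query
    flank faces the subject's N-terminus.
    """
    h = best_hit
    if h.q_len is None or h.s_len is None:
        raise ValueError(
            f"hit {h.query_id!r}->{h.subject_id!r} lacks q_len/s_len; "
            "a 14-column table is required for full-length assessment"
        )
    missing_5p = (h.s_start - 1) * 3
    missing_3p = (h.s_len - h.s_end) * 3
    if h.reverse:
        orientation = "REV"
        upstream = h.q_len - h.q_start
        downstream = h.q_end - 1
    else:
        orientation = "FWD"
        upstream = h.q_start - 1
        downstream = h.q_len - h.q_end
    is_full = upstream >= missing_5p and downstream >= missing_3p
    is_ribo = bool(
        h.s_desc and re.search(ribosomal_pattern, h.s_desc, flags=re.IGNORECASE)
    )
    return FullLengthVerdict(
        contig_id=h.query_id,
        subject_id=h.subject_id,
        orientation=orientation,
        missing_5p_nt=missing_5p,
        missing_3p_nt=missing_3p,
        upstream_avail_nt=upstream,
        downstream_avail_nt=downstream,
        is_full_length=is_full,
        is_ribosomal=is_ribo,
    )


def best_hit_per_query(
    hits: Sequence[HitRow], cfg: StrongMatchConfig | None = None
) -> dict[str, HitRow]:
    """Single best strong hit per query: highest bitscore, then lowest
    evalue, then lexicographically smallest subject id."""
    best: dict[str, HitRow] = {}
    for h in filter_strong(hits, cfg) if cfg else hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore, cur.evalue, cur.subject_id
        ):
            best[h.query_id] = h
    return best


# ---------------------------------------------------------------------------
# pathway coverage

@dataclass
class PathwayDef:
    pathway_id: str
    name: str
    ko_set: set[str]

    def __post_init__(self) -> None:
        if not self.ko_set:
            raise ValueError(f"pathway {self.pathway_id}: ko_set must be non-empty")


@dataclass
class PathwayCoverage:
    pathway_id: str
    name: str
    present: int
    total: int
    percent: float


def pathway_coverage(
    ko_present: set[str], defs: Sequence[PathwayDef]
) -> list[PathwayCoverage]:
    """Per-pathway presence accounting: percent = 100 * present / total,
    half-up to one decimal."""
    out = []
    for d in defs:
        present = len(d.ko_set & ko_present)
        out.append(
            PathwayCoverage(
                pathway_id=d.pathway_id,
                name=d.name,
                present=present,
                total=len(d.ko_set),
                percent=round_half_up(100.0 * present / len(d.ko_set), 1),
            )
        )
    return out


class OverlayCategory(Enum):
    BOTH = "BOTH"
    ONLY_A = "ONLY_A"
    ONLY_B = "ONLY_B"
    NEITHER = "NEITHER"


def overlay_sets(
    koA: set[str], koB: set[str], defs: Sequence[PathwayDef]
) -> dict[str, OverlayCategory]:
    """Two-dataset overlay over the union of all pathway-defined KOs
    (the coloured-pathway-map comparison: both / only A / only B / neither)."""
    universe: set[str] = set()
    for d in defs:
        universe |= d.ko_set
    out = {}
    for ko in sorted(universe):
        if ko in koA and ko in koB:
            out[ko] = OverlayCategory.BOTH
        elif ko in koA:
            out[ko] = OverlayCategory.ONLY_A
        elif ko in koB:
            out[ko] = OverlayCategory.ONLY_B
        else:
            out[ko] = OverlayCategory.NEITHER
    return out


# ---------------------------------------------------------------------------
# 3-way reciprocal best hits

@dataclass
class TriadResult:
    """Mutually-best triangles across three sequence sets plus Venn counts.

    ``venn`` keys: A, B, C (sequences in no reciprocal best pair), AB, AC,
    BC (sequences in a reciprocal best pair for that species pair but not in
    a triad, counted as pairs) and ABC (triad count).
    """

    triads: list[tuple[str, str, str]]
    venn: dict[str, int] = field(default_factory=dict)


def _reciprocal_pairs(best_xy: Mapping[str, str], best_yx: Mapping[str, str]) -> set[tuple[str, str]]:
    return {
        (x, y)
        for x, y in best_xy.items()
        if best_yx.get(y) == x
    }


def reciprocal_triads(
    hitsAB: Sequence[HitRow], hitsBA: Sequence[HitRow],
    hitsAC: Sequence[HitRow], hitsCA: Sequence[HitRow],
    hitsBC: Sequence[HitRow], hitsCB: Sequence[HitRow],
    cfg: StrongMatchConfig | None = None,
) -> TriadResult:
    """3-way reciprocal best-hit triangulation.

    After strong-match filtering (bit score >= 40 by default, matching the
    all-against-all tBLASTx convention), the best hit per query is taken in
    each of the six directions.  (a, b, c) is a triad iff every one of the
    six best-hit arrows within the triangle is mutual: a<->b, a<->c, b<->c.
    Venn pairwise regions count reciprocal best pairs for a species pair
    that do not extend to a triad; the exclusive regions count sequences
    (queries seen in the tables) in no reciprocal pair at all.
    """
    cfg = cfg or StrongMatchConfig(mode=MatchMode.BITSCORE)

    def best(hits: Sequence[HitRow]) -> dict[str, str]:
        return {q: h.subject_id for q, h in best_hit_per_query(hits, cfg).items()}

    bAB, bBA = best(hitsAB), best(hitsBA)
    bAC, bCA = best(hitsAC), best(hitsCA)
    bBC, bCB = best(hitsBC), best(hitsCB)

    pAB = _reciprocal_pairs(bAB, bBA)
    pAC = _reciprocal_pairs(bAC, bCA)
    pBC = _reciprocal_pairs(bBC, bCB)

    triads = sorted(
        (a, b, c)
        for (a, b) in pAB
        for c in [bAC.get(a)]
        if c is not None and (a, c) in pAC and (b, c) in pBC
    )
    in_triad_a = {t[0] for t in triads}
    in_triad_b = {t[1] for t in triads}
    in_triad_c = {t[2] for t in triads}

    universe_a = set(bAB) | set(bAC) | set(bBA.values()) | set(bCA.values())
    universe_b = set(bBA) | set(bBC) | set(bAB.values()) | set(bCB.values())
    universe_c = set(bCA) | set(bCB) | set(bAC.values()) | set(bBC.values())
    paired_a = {a for a, _ in pAB} | {a for a, _ in pAC}
    paired_b = {b for _, b in pAB} | {b for b, _ in pBC}
    paired_c = {c for _, c in pAC} | {c for _, c in pBC}

    venn = {
        "ABC": len(triads),
        "AB": len({pr for pr in pAB if not (pr[0] in in_triad_a and pr[1] in in_triad_b)}),
        "AC": len({pr for pr in pAC if not (pr[0] in in_triad_a and pr[1] in in_triad_c)}),
        "BC": len({pr for pr in pBC if not (pr[0] in in_triad_b and pr[1] in in_triad_c)}),
        "A": len(universe_a - paired_a),
        "B": len(universe_b - paired_b),
        "C": len(universe_c - paired_c),
    }
    return TriadResult(triads=triads, venn=venn)


# ---------------------------------------------------------------------------
# table ingestion helpers for KO/pathway inputs

def read_ko_table(path) -> dict[str, str]:
    """TSV of (sequence_id, KO) -> mapping; blank/comment lines skipped."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, ko = line.split("\t")[:2]
            out[seq_id] = ko
    return out


def read_pathway_defs(path) -> list[PathwayDef]:
    """TSV of (pathway_id, name, comma-separated KO list)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, name, kos = line.split("\t")[:3]
            out.append(PathwayDef(pid, name, {k for k in kos.split(",") if k}))
    return out
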