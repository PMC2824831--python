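"""Molecular-marker detection: microsatellites (SSRs) and SNPs.

SSRs are perfect tandem repeats of a 2–4 bp motif.  Motifs are reported both
as read and in canonical form — the lexicographic minimum over all cyclic
rotations of the motif and of its reverse complement — so that e.g. GTT,
TGT and AAC all count as the same AAC class.  Under this equivalence the
non-degenerate motif space collapses to 4 dinucleotide, 10 trinucleotide and
33 tetranucleotide classes.

SNPs are called from contig alignment columns: a column is a biallelic SNP
when enough reads cover it and both alleles are seen at least twice, and is
classed as a transition (purine<->purine or pyrimidine<->pyrimidine, i.e.
{A,G} or {C,T}) or a transversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Optional, Sequence

from ._util import revcomp

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

#: default minimum copy numbers per unit length (dinucleotide repeats must
#: run longer than tetranucleotide repeats to be convincing)
DEFAULT_MIN_COPIES = {2: 6, 3: 5, 4: 4}


class Region(Enum):
    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"
    UNKNOWN = "UNKNOWN"


class SNPClass(Enum):
    TRANSITION = "TRANSITION"
    TRANSVERSION = "TRANSVERSION"


class InvalidMotifError(ValueError):
    """Homopolymer or periodic string offered as an SSR motif."""


@dataclass
class SSRHit:
    seq_id: str
    motif: str
    canonical_motif: str
    unit_len: int
    copies: int
    interval: Interval
    region: Region = Region.UNKNOWN


@dataclass
class SNPCall:
    contig_id: str
    column: int
    alleles: tuple[str, str]
    depths: tuple[int, int]
    klass: SNPClass


def _is_periodic(motif: str) -> bool:
    """True when the motif is a whole number of repeats of a shorter unit."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return True
    return False


def canonical_motif(motif: str) -> str:
    """Canonical representative of an SSR motif class.

    The lexicographically smallest string among all cyclic rotations of the
    motif and of its reverse complement.  Homopolymers and periodic motifs
    (e.g. ACAC as a 4-mer) are rejected — they belong to a shorter unit.
    """
    motif = motif.upper()
    if not (2 <= len(motif) <= 4):
        raise InvalidMotifError(f"motif length must be 2-4, got {motif!r}")
    if any(c not in "ACGT" for c in motif):
        raise InvalidMotifError(f"motif must be ACGT only, got {motif!r}")
    if _is_periodic(motif):
        raise InvalidMotifError(f"motif {motif!r} is periodic (or a homopolymer)")
    forms = set()
    for s in (motif, revcomp(motif)):
        for i in range(len(s)):
            forms.add(s[i:] + s[:i])
    return min(forms)


def motif_classes(unit_len: int) -> set[str]:
    """All distinct canonical motif classes for a unit length (enumeration
    over every non-degenerate motif of that length)."""
    out = set()
    for combo in product("ACGT", repeat=unit_len):
        m = "".join(combo)
        if _is_periodic(m):
            continue
        out.add(canonical_motif(m))
    return out


def find_ssrs(
    seq: str,
    seq_id: str = "",
    min_copies: dict[int, int] | None = None,
) -> list[SSRHit]:
    """All maximal perfect tandem repeats of 2–4 bp motifs meeting the copy
    thresholds, sorted by start.

    A repeat stretch may end mid-copy; the interval covers the whole stretch
    while ``copies`` counts full copies only.  When stretches of different
    unit lengths overlap the same locus, the smallest unit wins (a pure
    AC-repeat is not additionally reported as an ACAC repeat; that case is
    already excluded by motif validity, but e.g. a dinucleotide stretch
    embedded in a longer tetranucleotide stretch resolves to the
    dinucleotide).
    """
    if not seq:
        raise ValueError("seq must be non-empty")
    seq = seq.upper()
    min_copies = dict(DEFAULT_MIN_COPIES, **(min_copies or {}))
    n = len(seq)
    hits: list[SSRHit] = []
    for period in (2, 3, 4):
        need = min_copies[period]
        s = 0
        while s < n - period:
            e = s + period
            while e < n and seq[e] == seq[e - period]:
                e += 1
            copies = (e - s) // period
            motif = seq[s : s + period]
            if copies >= need and not _is_periodic(motif):
                hits.append(
                    SSRHit(
                        seq_id=seq_id,
                        motif=motif,
                        canonical_motif=canonical_motif(motif),
                        unit_len=period,
                        copies=copies,
                        interval=(s, e),
                    )
                )
            s = e - period + 1 if e - s > period else s + 1
    # resolve overlapping reports of one locus toward the smallest unit
    kept: list[SSRHit] = []
    for h in hits:
        shadowed = any(
            g.unit_len < h.unit_len
            and g.interval[0] < h.interval[1]
            and h.interval[0] < g.interval[1]
            for g in hits
        )
        if not shadowed:
            kept.append(h)
    kept.sort(key=lambda h: (h.interval[0], h.unit_len))
    return kept


def classify_ssr_region(
    hit: SSRHit, cds: Optional[Interval], strand: str = "+"
) -> Region:
    """Locate an SSR relative to a coding interval by its midpoint.

    ``cds`` is a half-open interval on the given sequence; ``strand`` is the
    strand of the coding sequence.  A hit straddling a boundary is assigned
    by its midpoint, not split.  Without a CDS the region is UNKNOWN.
    """
    if cds is None:
        return Region.UNKNOWN
    mid = (hit.interval[0] + hit.interval[1]) / 2
    if cds[0] <= mid < cds[1]:
        return Region.CDS
    left_of_cds = mid < cds[0]
    if strand == "+":
        return Region.UTR5 if left_of_cds else Region.UTR3
    return Region.UTR3 if left_of_cds else Region.UTR5


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def call_snps(
    contig_id: str,
    columns: Sequence[Sequence[str]],
    min_depth: int = 4,
    min_minor: int = 2,
) -> list[SNPCall]:
    """Call biallelic SNPs from per-column member bases.

    ``columns[j]`` holds the base each aligned member contributes at column
    j (gaps '-' and N are ignored).  A column is a SNP when its depth is >=
    min_depth, exactly two bases are observed, and both are seen >=
    min_minor times.  Columns with three or more observed bases are skipped
    and logged.  The class is TRANSITION for {A,G} or {C,T}, else
    TRANSVERSION.
    """
    calls = []
    for j, col in enumerate(columns):
        counts: dict[str, int] = {}
        for b in col:
            b = b.upper()
            if b in "ACGT":
                counts[b] = counts.get(b, 0) + 1
        if len(counts) > 2:
            logger.info("contig %s column %d: %d alleles, skipped", contig_id, j, len(counts))
            continue
        if len(counts) != 2:
            continue
        if sum(counts.values()) < min_depth or min(counts.values()) < min_minor:
            continue
        alleles = tuple(sorted(counts, key=lambda b: (-counts[b], b)))
        pair = set(alleles)
        klass = (
            SNPClass.TRANSITION
            if pair == _PURINES or pair == _PYRIMIDINES
            else SNPClass.TRANSVERSION
        )
        calls.append(
            SNPCall(
                contig_id=contig_id,
                column=j,
                alleles=alleles,  # type: ignore[arg-type]
                depths=(counts[alleles[0]], counts[alleles[1]]),
                klass=klass,
            )
        )
    return calls
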