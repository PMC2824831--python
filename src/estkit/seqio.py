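"""Sequence, quality and homology-table I/O plus the clone/sister-read model.

An EST library is a set of single-pass reads from cDNA clones, each clone
typically sequenced from both ends (a 5' forward read and a 3' reverse read,
the "sister" or "end" pair).  Everything downstream — trimming, clustering,
marker detection — keys off the clone identity parsed from the read name, so
the naming convention is an explicit, configurable part of this module.

Supported formats: FASTA plus a whitespace-integer ``.qual`` file (phred
scores), FASTQ with offset-33 qualities, and 12/14/15-column tab-separated
homology hit tables in the BLAST ``outfmt 6`` column order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import PairedFastaQualIterator


class Direction(Enum):
    FWD_5P = "5p"
    REV_3P = "3p"


class Status(Enum):
    PASS = "PASS"
    INSERTLESS = "INSERTLESS"
    CONTAMINANT = "CONTAMINANT"
    LOW_QUALITY = "LOW_QUALITY"
    LOW_COMPLEXITY = "LOW_COMPLEXITY"
    SHORT = "SHORT"
    DUPLICATE = "DUPLICATE"


#: statuses that copy to the sister read of the same clone
PROPAGATING_STATUSES = frozenset({Status.INSERTLESS, Status.CONTAMINANT})


class FormatError(ValueError):
    """Malformed input file (record named in the message where possible)."""


class NamingError(ValueError):
    """A read id that does not parse under the configured naming pattern."""


@dataclass(frozen=True)
class NamingConfig:
    """How est_ids encode clone identity and read direction.

    ``pattern`` must expose named groups ``clone`` and ``dir``; ``dir_map``
    translates the captured direction token.  The default matches ids like
    ``CCAG_0001_A01.b`` (5' read) / ``CCAG_0001_A01.g`` (3' read).
    """

    pattern: str = r"^(?P<clone>.+)\.(?P<dir>[bg])$"
    dir_map: dict = field(
        default_factory=lambda: {"b": Direction.FWD_5P, "g": Direction.REV_3P}
    )

    def parse(self, est_id: str) -> tuple[str, Direction]:
        m = re.match(self.pattern, est_id)
        if not m:
            raise NamingError(f"est_id {est_id!r} does not match pattern {self.pattern!r}")
        token = m.group("dir")
        if token not in self.dir_map:
            raise NamingError(f"direction token {token!r} in {est_id!r} not in dir_map")
        return m.group("clone"), self.dir_map[token]


@dataclass
class ESTRecord:
    """One read: bases, per-base phred scores, vector mask and screening status.

    ``mask`` holds 0-based half-open intervals flagged as vector/adapter.
    ``status`` starts at PASS and only ever moves away from it.
    """

    est_id: str
    clone_id: str
    direction: Direction
    bases: str
    quals: list[int]
    library: str = ""
    mask: list[tuple[int, int]] = field(default_factory=list)
    status: Status = Status.PASS
    polyA_flag: bool = False

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise FormatError(
                f"record {self.est_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class CloneRecord:
    """A cDNA clone and the est_ids of its reads, per direction.

    Directions hold lists (not single ids) because a clone may have been
    resequenced; deduplication picks one read per direction later.
    """

    clone_id: str
    fwd_est_ids: list[str] = field(default_factory=list)
    rev_est_ids: list[str] = field(default_factory=list)
    library: str = ""

    @property
    def est_ids(self) -> list[str]:
        return self.fwd_est_ids + self.rev_est_ids


@dataclass
class HitRow:
    """One tabular homology alignment (BLAST outfmt-6 column order).

    Coordinates keep the file's 1-based inclusive convention; for BLASTx /
    tBLASTx rows a q_start > q_end encodes a minus-strand query frame.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    q_len: Optional[int] = None
    s_len: Optional[int] = None
    s_desc: Optional[str] = None
    search_tag: str = ""

    @property
    def reverse(self) -> bool:
        """True when the query aligns on the minus strand (q_start > q_end)."""
        return self.q_start > self.q_end


def read_fasta_qual(
    seq_path: str | Path,
    qual_path: str | Path,
    naming: NamingConfig | None = None,
    library: str = "",
) -> list[ESTRecord]:
    """Read paired FASTA + .qual files into ESTRecords (all statuses PASS).

    Records must appear in the same order with the same ids in both files;
    a bases/quals length mismatch raises :class:`FormatError` naming the
    offending record, an unparsable id raises :class:`NamingError`.
    """
    naming = naming or NamingConfig()
    out = []
    with open(seq_path) as fh_seq, open(qual_path) as fh_qual:
        for rec in PairedFastaQualIterator(fh_seq, fh_qual):
            out.append(_to_est_record(rec, naming, library))
    return out


def read_fastq(path: str | Path, naming: NamingConfig | None = None, library: str = "") -> list[ESTRecord]:
    """Read a FASTQ file (offset-33 qualities) into ESTRecords."""
    naming = naming or NamingConfig()
    return [_to_est_record(rec, naming, library) for rec in SeqIO.parse(str(path), "fastq")]


def _to_est_record(rec: SeqRecord, naming: NamingConfig, library: str) -> ESTRecord:
    quals = list(rec.letter_annotations.get("phred_quality", []))
    bases = str(rec.seq).upper()
    if len(quals) != len(bases):
        raise FormatError(
            f"record {rec.id!r}: {len(bases)} bases but {len(quals)} quality values"
        )
    clone_id, direction = naming.parse(rec.id)
    return ESTRecord(rec.id, clone_id, direction, bases, quals, library=library)


def write_fasta(
    records: Iterable[ESTRecord],
    path: str | Path,
    qual_path: str | Path | None = None,
    trimmed_only: bool = False,
    kept: dict[str, tuple[int, int]] | None = None,
) -> None:
    """Write records as FASTA (and optionally a matching .qual file).

    With ``trimmed_only`` each record is restricted to its kept interval from
    ``kept`` (est_id -> half-open interval); records without one are skipped.
    """
    seq_recs = []
    for r in records:
        bases, quals = r.bases, r.quals
        if trimmed_only:
            if kept is None or r.est_id not in kept or kept[r.est_id] is None:
                continue
            s, e = kept[r.est_id]
            bases, quals = bases[s:e], quals[s:e]
        sr = SeqRecord(Seq(bases), id=r.est_id, description="")
        sr.letter_annotations["phred_quality"] = quals
        seq_recs.append(sr)
    SeqIO.write(seq_recs, str(path), "fasta")
    if qual_path is not None:
        SeqIO.write(seq_recs, str(qual_path), "qual")


#: BLAST outfmt-6 column order, optionally extended with qlen/slen [+ desc]
HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_hit_table(
    path: str | Path,
    search_tag: str = "",
    allow_desc: bool = True,
) -> list[HitRow]:
    """Parse a 12/14-column tab-separated hit table (15th column = subject
    description when ``allow_desc``).  Any other column count is a
    :class:`FormatError` carrying the line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            n = len(parts)
            if n not in (12, 14) and not (allow_desc and n == 15):
                raise FormatError(
                    f"{path}:{lineno}: expected 12, 14{' or 15' if allow_desc else ''} "
                    f"tab-separated columns, got {n}"
                )
            try:
                row = HitRow(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    aln_len=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    search_tag=search_tag,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if n >= 14:
                row.q_len = int(parts[12])
                row.s_len = int(parts[13])
            if n == 15:
                row.s_desc = parts[14]
            rows.append(row)
    return rows


def write_hit_table(rows: Iterable[HitRow], path: str | Path) -> None:
    """Write hit rows back out in the tab-separated dialect they came from."""
    with open(path, "w") as fh:
        for r in rows:
            cols = [
                r.query_id, r.subject_id, f"{r.pct_identity:g}", str(r.aln_len),
                str(r.mismatches), str(r.gap_opens), str(r.q_start), str(r.q_end),
                str(r.s_start), str(r.s_end), f"{r.evalue:g}", f"{r.bitscore:g}",
            ]
            if r.q_len is not None and r.s_len is not None:
                cols += [str(r.q_len), str(r.s_len)]
                if r.s_desc is not None:
                    cols.append(r.s_desc)
            fh.write("\t".join(cols) + "\n")


def normalize_orientation(row: HitRow) -> tuple[HitRow, bool]:
    """Return a copy with ascending query coordinates plus a reverse flag."""
    if not row.reverse:
        return row, False
    fixed = HitRow(**{**row.__dict__, "q_start": row.q_end, "q_end": row.q_start})
    return fixed, True


def pair_sisters(records: Iterable[ESTRecord]) -> list[CloneRecord]:
    """Group reads into clones by clone_id; a partition of the input.

    Clones with reads in only one direction (or resequenced, with several
    reads in one direction) are allowed.  Output is sorted by clone_id.
    """
    clones: dict[str, CloneRecord] = {}
    for r in records:
        c = clones.setdefault(r.clone_id, CloneRecord(r.clone_id, library=r.library))
        if r.direction is Direction.FWD_5P:
            c.fwd_est_ids.append(r.est_id)
        else:
            c.rev_est_ids.append(r.est_id)
    for c in clones.values():
        c.fwd_est_ids.sort()
        c.rev_est_ids.sort()
    return [clones[k] for k in sorted(clones)]
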