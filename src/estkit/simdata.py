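"""Seeded generator of synthetic transcriptomes, clone libraries and hit
tables for end-to-end testing of the toolkit without real trace data.

The library model emulates a directional cDNA clone library sequenced from
both ends: each clone carries an insert sampled from one transcript; the 5'
read is vector + the insert's 5' portion, the 3' read is vector + the
reverse complement of (insert 3' end + polyA tail).  Reads carry a linearly
decaying mean phred with Gaussian noise (realistic 3' quality collapse) and
uniform substitution errors.  Configurable fractions of clones are planted
as insertless (vector-only or vector plus a sub-100 bp stub), contaminant
(reads drawn from a foreign sequence) or low-complexity; the planted truth
is returned alongside the reads so recovery can be scored exactly.

Abundance: non-normalized libraries sample transcripts with Zipf-like
weights (rank^-alpha), normalized libraries sample uniformly — a simple
statistical stand-in for duplex-specific-nuclease flattening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np

from ._util import revcomp
from .seqio import CloneRecord, Direction, ESTRecord, HitRow

_BASES = np.array(list("ACGT"))

#: synthetic cloning-vector flank used by default on both read ends
DEFAULT_VECTOR = (
    "GTCGACGGTATCGATAAGCTTGATATCGAATTCCTGCAGCCCGGGGGATCCACTAGTTCT"
    "AGAGCGGCCGCCACCGCGGTGGAGCTC"
)


@dataclass
class SimConfig:
    """Study conditions for one simulated clone library.

    Defaults describe a mid-sized directional library: 50 transcripts of
    0.9-1.5 kb, 1,000 clones read from both ends at 450-700 bp, phred
    starting near 40 and decaying 0.05/base (so quality collapses past
    ~500 bases), 15-30 base polyA tails, and small planted artifact
    fractions comparable to what EST projects report.  ``error_rate``
    scales the quality-implied substitution probability 10^(-q/10) per
    base (1.0 = errors exactly as the phred scores promise, 0 = error-free
    reads), so errors concentrate in the decayed read tail as they do in
    real chromatogram basecalls.
    """

    seed: int = 0
    n_transcripts: int = 50
    transcript_len: tuple[int, int] = (900, 1500)
    n_clones: int = 1000
    normalized: bool = False
    abundance_alpha: float = 1.0
    vector_seq: str = DEFAULT_VECTOR
    read_len: tuple[int, int] = (450, 700)
    qual_profile: tuple[float, float, float] = (40.0, 0.05, 3.0)
    error_rate: float = 1.0
    polyA_len: tuple[int, int] = (15, 30)
    frac_insertless: float = 0.01
    frac_contaminant: float = 0.02
    frac_low_complexity: float = 0.01
    library: str = "SIM"

    def __post_init__(self) -> None:
        fr = (self.frac_insertless, self.frac_contaminant, self.frac_low_complexity)
        if any(not (0 <= f <= 1) for f in fr) or sum(fr) > 1:
            raise ValueError("artifact fractions must be in [0,1] and sum <= 1")


@dataclass
class CloneTruth:
    clone_id: str
    transcript_id: Optional[str]
    insert_interval: Optional[tuple[int, int]]  # on the transcript
    artifact: Optional[str]  # "insertless" | "contaminant" | "low_complexity" | None


@dataclass
class SimTruth:
    """Planted ground truth: per-clone provenance and per-read kept spans."""

    clones: dict[str, CloneTruth] = field(default_factory=dict)
    read_insert_span: dict[str, tuple[int, int]] = field(default_factory=dict)
    contaminant_ids: set[str] = field(default_factory=set)

    def clones_with(self, artifact: str) -> set[str]:
        return {c for c, t in self.clones.items() if t.artifact == artifact}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _identity(a: str, b: str) -> float:
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def simulate_transcriptome(cfg: SimConfig) -> list[tuple[str, str, int]]:
    """Random mutually dissimilar transcripts, each with a designated CDS.

    Pairwise identity is rejection-checked below 90% (random sequences
    essentially always pass; the check guards against pathological draws).
    Returns (transcript_id, sequence, protein length in aa).
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[tuple[str, str, int]] = []
    attempts = 0
    while len(out) < cfg.n_transcripts:
        attempts += 1
        if attempts > 100 * max(cfg.n_transcripts, 1):
            raise RuntimeError("cannot satisfy pairwise dissimilarity constraint")
        n = int(rng.integers(cfg.transcript_len[0], cfg.transcript_len[1] + 1))
        seq = _random_dna(rng, n)
        if any(_identity(seq, s) >= 0.9 for _, s, _ in out):
            continue
        cds_len = ((n * 6 // 10) // 3) * 3
        out.append((f"T{len(out):04d}", seq, cds_len // 3))
    return out


def _read_quals(rng: np.random.Generator, n: int, profile: tuple[float, float, float]) -> list[int]:
    start, decay, sd = profile
    mean = start - decay * np.arange(n)
    q = rng.normal(mean, sd)
    return np.clip(np.rint(q), 2, 60).astype(int).tolist()


def _with_errors(
    rng: np.random.Generator, seq: str, quals: list[int], scale: float
) -> str:
    """Substitute bases at the rate the phred scores promise (10^(-q/10)),
    times ``scale``; errors therefore concentrate in the decayed read tail."""
    if scale <= 0:
        return seq
    q = np.asarray(quals, dtype=float)
    p = np.minimum(scale * 10.0 ** (-q / 10.0), 0.3)
    hit = rng.random(len(q)) < p
    arr = np.array(list(seq))
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _low_complexity_seq(rng: np.random.Generator, n: int) -> str:
    unit = ["AT", "AC", "AG", "A"][int(rng.integers(0, 4))]
    return (unit * (n // len(unit) + 1))[:n]


def simulate_library(
    transcriptome: list[tuple[str, str, int]], cfg: SimConfig
) -> tuple[list[ESTRecord], list[CloneRecord], SimTruth]:
    """Emit paired-end clone reads with planted artifacts and full truth.

    Artifact counts are exact: round(frac * n_clones) clones per category,
    assigned to a seeded random subset.  Every read is explained in the
    returned :class:`SimTruth`.
    """
    if not transcriptome:
        raise ValueError("transcriptome must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_clones
    ranks = np.arange(1, len(transcriptome) + 1, dtype=float)
    weights = (
        np.full(len(ranks), 1.0 / len(ranks))
        if cfg.normalized
        else (ranks ** -cfg.abundance_alpha) / np.sum(ranks ** -cfg.abundance_alpha)
    )

    order = rng.permutation(n)
    n_ins = int(round(cfg.frac_insertless * n))
    n_con = int(round(cfg.frac_contaminant * n))
    n_low = int(round(cfg.frac_low_complexity * n))
    artifact_of: dict[int, str] = {}
    for idx in order[:n_ins]:
        artifact_of[idx] = "insertless"
    for idx in order[n_ins : n_ins + n_con]:
        artifact_of[idx] = "contaminant"
    for idx in order[n_ins + n_con : n_ins + n_con + n_low]:
        artifact_of[idx] = "low_complexity"

    contaminant_seq = _random_dna(rng, 2000)
    vector = cfg.vector_seq
    records: list[ESTRecord] = []
    truth = SimTruth()

    def emit(est_id: str, clone_id: str, direction: Direction, payload: str,
             insert_span: Optional[tuple[int, int]]) -> None:
        read_len = int(rng.integers(cfg.read_len[0], cfg.read_len[1] + 1))
        bases = payload[:read_len]
        quals = _read_quals(rng, len(bases), cfg.qual_profile)
        bases = _with_errors(rng, bases, quals, cfg.error_rate)
        records.append(
            ESTRecord(est_id, clone_id, direction, bases, quals, library=cfg.library)
        )
        if insert_span is not None:
            truth.read_insert_span[est_id] = insert_span

    for idx in range(n):
        clone_id = f"{cfg.library}_{idx:05d}"
        artifact = artifact_of.get(idx)
        vlen5 = int(rng.integers(30, min(55, len(vector)) + 1))
        vprefix = vector[-vlen5:]
        if artifact == "insertless":
            # vector-only or vector + a sub-100 bp stub: both insertless clauses
            stub = _random_dna(rng, int(rng.integers(0, 100)))
            payload5 = (vector * 20)[: cfg.read_len[1] + 10] if rng.random() < 0.5 else vprefix + stub + vector
            payload3 = (vector * 20)[: cfg.read_len[1] + 10]
            emit(f"{clone_id}.b", clone_id, Direction.FWD_5P, payload5, None)
            emit(f"{clone_id}.g", clone_id, Direction.REV_3P, payload3, None)
            truth.clones[clone_id] = CloneTruth(clone_id, None, None, "insertless")
            continue
        if artifact == "contaminant":
            s = int(rng.integers(0, len(contaminant_seq) - 700))
            payload5 = vprefix + contaminant_seq[s : s + 700]
            payload3 = vprefix + revcomp(contaminant_seq[s : s + 700])
            emit(f"{clone_id}.b", clone_id, Direction.FWD_5P, payload5, None)
            emit(f"{clone_id}.g", clone_id, Direction.REV_3P, payload3, None)
            truth.clones[clone_id] = CloneTruth(clone_id, "CONTAM", None, "contaminant")
            truth.contaminant_ids |= {f"{clone_id}.b", f"{clone_id}.g"}
            continue
        if artifact == "low_complexity":
            junk = _low_complexity_seq(rng, 700)
            emit(f"{clone_id}.b", clone_id, Direction.FWD_5P, vprefix + junk, None)
            emit(f"{clone_id}.g", clone_id, Direction.REV_3P, vprefix + junk, None)
            truth.clones[clone_id] = CloneTruth(clone_id, None, None, "low_complexity")
            continue

        t_idx = int(rng.choice(len(transcriptome), p=weights))
        t_id, t_seq, _ = transcriptome[t_idx]
        # 5'-truncated insert, as oligo-dT-primed cDNA tends to be
        trunc = int(rng.integers(0, max(1, len(t_seq) // 3)))
        insert = t_seq[trunc:]
        tail = "A" * int(rng.integers(cfg.polyA_len[0], cfg.polyA_len[1] + 1))
        payload5 = vprefix + insert + tail + vector
        payload3 = vprefix + revcomp(insert + tail) + revcomp(vector)
        emit(f"{clone_id}.b", clone_id, Direction.FWD_5P, payload5, (trunc, len(t_seq)))
        emit(f"{clone_id}.g", clone_id, Direction.REV_3P, payload3, (trunc, len(t_seq)))
        truth.clones[clone_id] = CloneTruth(clone_id, t_id, (trunc, len(t_seq)), None)

    clones: dict[str, CloneRecord] = {}
    for r in records:
        c = clones.setdefault(r.clone_id, CloneRecord(r.clone_id, library=cfg.library))
        (c.fwd_est_ids if r.direction is Direction.FWD_5P else c.rev_est_ids).append(r.est_id)
    return records, [clones[k] for k in sorted(clones)], truth


def make_contaminant_hits(
    truth: SimTruth, subject_id: str = "PHIX_SYNTH", seed: int = 0
) -> tuple[list[HitRow], set[str]]:
    """Synthetic contaminant-screen hit table from the planted truth:
    one strong hit per contaminant read against a listed subject."""
    rng = np.random.default_rng(seed)
    hits = [
        HitRow(
            query_id=est_id, subject_id=subject_id, pct_identity=99.0,
            aln_len=500, mismatches=5, gap_opens=0,
            q_start=1, q_end=500, s_start=1, s_end=500,
            evalue=float(10.0 ** -rng.integers(20, 80)), bitscore=900.0,
            search_tag="contaminant_screen",
        )
        for est_id in sorted(truth.contaminant_ids)
    ]
    return hits, {subject_id}


def simulate_hit_tables(
    n_genes: int, ortho_frac: float, seed: int = 0
) -> tuple[dict[str, list[HitRow]], list[tuple[str, str, str]]]:
    """Six directed hit tables over three gene sets with planted triads.

    floor(ortho_frac * n_genes) genes are true 1:1:1 orthologs whose six
    within-triangle hits are mutually best; every query also gets decoy hits
    with strictly lower bitscores.  Returns ({"AB": rows, "BA": ..., "AC",
    "CA", "BC", "CB"}, planted triads).
    """
    if not (0 <= ortho_frac <= 1):
        raise ValueError("ortho_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = {s: [f"{s}{i:04d}" for i in range(n_genes)] for s in "ABC"}
    n_ortho = int(np.floor(ortho_frac * n_genes))
    tables: dict[str, list[HitRow]] = {d: [] for d in ("AB", "BA", "AC", "CA", "BC", "CB")}
    triads = []

    def row(q: str, s: str, bits: float, tag: str) -> HitRow:
        return HitRow(
            query_id=q, subject_id=s, pct_identity=float(rng.uniform(60, 99)),
            aln_len=300, mismatches=10, gap_opens=1,
            q_start=1, q_end=300, s_start=1, s_end=300,
            evalue=float(2.0 ** -bits), bitscore=bits, search_tag=tag,
        )

    for i in range(n_genes):
        a, b, c = names["A"][i], names["B"][i], names["C"][i]
        if i < n_ortho:
            bits = float(rng.uniform(200, 400))
            for d, (q, s) in {
                "AB": (a, b), "BA": (b, a), "AC": (a, c),
                "CA": (c, a), "BC": (b, c), "CB": (c, b),
            }.items():
                tables[d].append(row(q, s, bits, d))
            triads.append((a, b, c))
        else:
            # best hits point at mismatched partners -> reciprocity broken
            j = (i + 1) % n_genes
            tables["AB"].append(row(a, names["B"][j], float(rng.uniform(100, 150)), "AB"))
            tables["BA"].append(row(b, names["A"][i], float(rng.uniform(100, 150)), "BA"))
        # decoys, strictly weaker than any planted best hit
        for d, (q, pool) in {"AB": (a, "B"), "AC": (a, "C"), "BC": (b, "C")}.items():
            decoy = names[pool][int(rng.integers(0, n_genes))]
            tables[d].append(row(q, decoy, float(rng.uniform(41, 99)), d))
    return tables, triads
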