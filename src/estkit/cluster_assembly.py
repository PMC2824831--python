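"""Kmer-seeded overlap clustering, double-linkage merging and consensus
building for trimmed ESTs.

Clustering follows the classic whole-genome-shotgun recipe: candidate read
pairs are those sharing at least one exact k-mer (k = 16 by default, both
strands considered); a candidate pair becomes an edge when a local alignment
confirms an overlap of at least ``min_seed_span`` aligned columns at
``min_identity`` identity; clusters are the connected components.  Clusters
are then merged by *double linkage*: two clusters fuse when two or more
distinct clones each have one end read in one cluster and the sister read in
the other — a single bridging clone is treated as a possible chimera and
ignored.

Consensus building is a deliberately simple star-layout assembler (no
quality-aware multiple alignment): the longest member is the backbone, other
members are placed by pairwise alignment to it, and columns are resolved by
majority vote.  Members that fail to align to the backbone seed further
contigs, so a cluster always yields at least one contig and may yield more
(long-insert clones, chimeras, splice forms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from ._util import UnionFind, revcomp, round_half_up
from .seqio import CloneRecord


@dataclass
class ClusterParams:
    """Overlap-clustering thresholds.

    k: exact seed length for candidate pairing.  min_seed_span: minimum
    aligned columns for an accepted overlap (32).  min_identity: minimum
    overlap identity (0.98).  double_link_min_clones: bridging clones needed
    to merge two clusters (2).  consensus_min_identity: member-to-backbone
    identity required to join a contig (0.90).
    """

    k: int = 16
    min_seed_span: int = 32
    min_identity: float = 0.98
    double_link_min_clones: int = 2
    consensus_min_identity: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.k < 8:
            raise ValueError("k must be >= 8")


@dataclass
class Cluster:
    cluster_id: str
    member_est_ids: set[str]

    def clone_ids(self, clone_of: dict[str, str]) -> set[str]:
        return {clone_of[i] for i in self.member_est_ids if i in clone_of}


@dataclass
class Contig:
    contig_id: str
    cluster_id: str
    consensus: str
    member_est_ids: set[str]
    depth: list[int] = field(default_factory=list)


# local alignment scoring chosen to make the 98%-identity cut sharp:
# a mismatch (+1 vs -2) costs three matches of headroom
_ALIGNER = Align.PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-2,
    open_gap_score=-3, extend_gap_score=-3,
)


def _align(a: str, b: str):
    alns = _ALIGNER.align(a, b)
    try:
        return alns[0]
    except IndexError:
        return None


def _identity_span(aln) -> tuple[float, int]:
    c = aln.counts()
    span = c.identities + c.mismatches + c.gaps
    return (c.identities / span if span else 0.0), span


def overlap_identity(a: str, b: str, p: ClusterParams | None = None) -> Optional[tuple[float, int]]:
    """Best local-alignment identity and span between two sequences.

    Scoring is match +1 / mismatch -2 / gap -3; identity is identities over
    aligned columns (gap columns included), span is the column count.
    Returns None when the best alignment spans fewer than ``min_seed_span``
    columns.  Orientation is the caller's business: sequences are compared
    as given.
    """
    p = p or ClusterParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _align(a, b)
    if aln is None:
        return None
    ident, span = _identity_span(aln)
    if span < p.min_seed_span:
        return None
    return ident, span


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _qualifying_overlap(a: str, b: str, p: ClusterParams) -> bool:
    for bb in (b, revcomp(b)):
        res = overlap_identity(a, bb, p)
        if res is not None and res[0] >= p.min_identity:
            return True
    return False


def kmer_cluster(
    ests: Sequence[tuple[str, str]], p: ClusterParams | None = None
) -> list[Cluster]:
    """Cluster reads by confirmed k-mer-seeded overlaps (both strands).

    Candidate pairs share at least one exact k-mer (forward or reverse
    complement); an edge requires a local alignment at >= min_identity over
    >= min_seed_span columns.  Clusters are connected components; ids are
    ``CL_<smallest member est_id>``.  Pairs already connected through earlier
    edges are not re-aligned, which keeps the edge verification near-linear
    in practice without changing the resulting components.
    """
    p = p or ClusterParams()
    seqs = dict(ests)
    ids = [i for i, _ in ests]
    uf = UnionFind()
    for i in ids:
        uf.add(i)

    buckets: dict[str, list[str]] = {}
    for i in ids:
        seen = set()
        for strand in (seqs[i], revcomp(seqs[i])):
            for w in _kmers(strand, p.k):
                key = min(w, revcomp(w))  # strand-neutral bucket key
                if key not in seen:
                    seen.add(key)
                    buckets.setdefault(key, []).append(i)

    tested: set[tuple[str, str]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for xi in range(len(members)):
            for yi in range(xi + 1, len(members)):
                a, b = sorted((members[xi], members[yi]))
                if a == b or (a, b) in tested or uf.connected(a, b):
                    continue
                tested.add((a, b))
                if _qualifying_overlap(seqs[a], seqs[b], p):
                    uf.union(a, b)

    clusters = []
    for group in uf.groups():
        cid = "CL_" + min(group)
        clusters.append(Cluster(cid, set(group)))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def double_linkage_merge(
    clusters: Sequence[Cluster],
    clones: Sequence[CloneRecord],
    p: ClusterParams | None = None,
) -> list[Cluster]:
    """Merge clusters bridged by >= double_link_min_clones sister-read clones.

    Two clusters are connected when at least that many distinct clones have
    one read in each; merged clusters are the connected components of that
    graph, so chains of pairwise-linked clusters coalesce.  Merging never
    splits a cluster.
    """
    p = p or ClusterParams()
    cluster_of: dict[str, str] = {}
    for c in clusters:
        for est in c.member_est_ids:
            cluster_of[est] = c.cluster_id

    bridge_clones: dict[tuple[str, str], set[str]] = {}
    for clone in clones:
        touched = {cluster_of[i] for i in clone.est_ids if i in cluster_of}
        for pair in _pairs(sorted(touched)):
            bridge_clones.setdefault(pair, set()).add(clone.clone_id)

    uf = UnionFind()
    for c in clusters:
        uf.add(c.cluster_id)
    for (ca, cb), bridging in bridge_clones.items():
        if len(bridging) >= p.double_link_min_clones:
            uf.union(ca, cb)

    by_id = {c.cluster_id: c for c in clusters}
    merged = []
    for group in uf.groups():
        members: set[str] = set()
        for cid in group:
            members |= by_id[cid].member_est_ids
        merged.append(Cluster("CL_" + min(members), members))
    merged.sort(key=lambda c: c.cluster_id)
    return merged


def _pairs(items):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield (items[i], items[j])


def build_consensus(
    cluster: Cluster, seqs: dict[str, str], p: ClusterParams | None = None
) -> list[Contig]:
    """Star-layout consensus: longest member is the backbone, others are
    placed on it by pairwise alignment (better strand wins) and columns are
    resolved by per-column majority vote, ties toward the alphabetically
    first base.  Flanks of members extending past the backbone are placed
    ungapped, so error-free tiled reads reconstruct the full covered region.
    Members failing the identity threshold seed further contigs recursively.
    """
    p = p or ClusterParams()
    remaining = sorted(cluster.member_est_ids)
    contigs: list[Contig] = []
    serial = 0
    while remaining:
        backbone_id = max(remaining, key=lambda i: (len(seqs[i]), i))
        placed: dict[str, tuple[int, str]] = {backbone_id: (0, seqs[backbone_id])}
        leftovers = [e for e in remaining if e != backbone_id]
        # progressive rounds: members aligning to the consensus built so far
        # are placed and extend it, so chains of tiled reads coalesce even
        # when they do not touch the backbone directly
        while leftovers:
            consensus, _ = _vote(placed)
            lo = min(off for off, _ in placed.values())
            still = []
            for est in leftovers:
                placement = _place_on_backbone(consensus, seqs[est], p)
                if placement is None:
                    still.append(est)
                else:
                    placed[est] = (lo + placement[0], placement[1])
            if len(still) == len(leftovers):
                break
            leftovers = still
        consensus, depth = _vote(placed)
        serial += 1
        contigs.append(
            Contig(
                contig_id=f"{cluster.cluster_id}_ctg{serial}",
                cluster_id=cluster.cluster_id,
                consensus=consensus,
                member_est_ids=set(placed),
                depth=depth,
            )
        )
        remaining = leftovers
    return contigs


def _place_on_backbone(backbone: str, member: str, p: ClusterParams):
    """Offset and oriented sequence for a member, or None if it does not
    align at consensus_min_identity over min_seed_span columns."""
    best = None
    for seq in (member, revcomp(member)):
        aln = _align(backbone, seq)
        if aln is None:
            continue
        ident, span = _identity_span(aln)
        if span < p.min_seed_span or ident < p.consensus_min_identity:
            continue
        score = aln.score
        if best is None or score > best[0]:
            bs = int(aln.aligned[0][0][0])
            ms = int(aln.aligned[1][0][0])
            best = (score, bs - ms, seq)
    if best is None:
        return None
    return best[1], best[2]


def _vote(placed: dict[str, tuple[int, str]]) -> tuple[str, list[int]]:
    lo = min(off for off, _ in placed.values())
    hi = max(off + len(s) for off, s in placed.values())
    n = hi - lo
    counts = np.zeros((n, 4), dtype=np.int32)
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for off, s in placed.values():
        start = off - lo
        for j, ch in enumerate(s):
            idx = index.get(ch)
            if idx is not None:
                counts[start + j, idx] += 1
    depth = counts.sum(axis=1)
    # argmax on ties picks the lowest index = alphabetically first base
    bases = np.array(["A", "C", "G", "T"])[counts.argmax(axis=1)]
    consensus = "".join(b if d > 0 else "N" for b, d in zip(bases, depth))
    return consensus, depth.tolist()


# ---------------------------------------------------------------------------
# cluster statistics (clustering-report schema)

@dataclass
class ClusterStats:
    """Cluster category counts with percentages of the cluster total."""

    library: str
    n_clusters: int
    n_contigs: int
    clusters_one_est: int
    clusters_one_clone: int
    clusters_multi_clone: int

    def __post_init__(self) -> None:
        # holds by construction for stats computed from clusters; externally
        # supplied report rows are allowed through with a warning so their
        # percentage arithmetic can still be audited
        cats = self.clusters_one_est + self.clusters_one_clone + self.clusters_multi_clone
        if cats != self.n_clusters:
            logging.getLogger(__name__).warning(
                "category counts %d do not sum to n_clusters %d", cats, self.n_clusters
            )

    def _pct(self, count: int) -> float:
        return round_half_up(100.0 * count / self.n_clusters, 1) if self.n_clusters else 0.0

    @property
    def pct_one_est(self) -> float:
        return self._pct(self.clusters_one_est)

    @property
    def pct_one_clone(self) -> float:
        return self._pct(self.clusters_one_clone)

    @property
    def pct_multi_clone(self) -> float:
        return self._pct(self.clusters_multi_clone)


def cluster_stats(
    clusters: Sequence[Cluster],
    contigs: Sequence[Contig],
    clones: Sequence[CloneRecord],
    library: str = "",
) -> ClusterStats:
    """Count clusters with one EST, with several ESTs of one clone, and with
    more than one clone (the three categories partition the clusters)."""
    clone_of: dict[str, str] = {}
    for clone in clones:
        for est in clone.est_ids:
            clone_of[est] = clone.clone_id
    one_est = one_clone = multi = 0
    for c in clusters:
        if len(c.member_est_ids) == 1:
            one_est += 1
        elif len(c.clone_ids(clone_of)) <= 1:
            one_clone += 1
        else:
            multi += 1
    return ClusterStats(
        library=library,
        n_clusters=len(clusters),
        n_contigs=len(contigs),
        clusters_one_est=one_est,
        clusters_one_clone=one_clone,
        clusters_multi_clone=multi,
    )


def aggregate_cluster_stats(rows: Sequence[ClusterStats], label: str = "Total") -> ClusterStats:
    """Totals row: sums of the count columns; percentages derive from them."""
    return ClusterStats(
        library=label,
        n_clusters=sum(r.n_clusters for r in rows),
        n_contigs=sum(r.n_contigs for r in rows),
        clusters_one_est=sum(r.clusters_one_est for r in rows),
        clusters_one_clone=sum(r.clusters_one_clone for r in rows),
        clusters_multi_clone=sum(r.clusters_multi_clone for r in rows),
    )


def cluster_stats_frame(rows: Sequence[ClusterStats]) -> pd.DataFrame:
    all_rows = list(rows)
    if len(all_rows) > 1:
        all_rows.append(aggregate_cluster_stats(all_rows))
    return pd.DataFrame(
        {
            "library": r.library,
            "n_clusters": r.n_clusters,
            "n_contigs": r.n_contigs,
            "clusters_one_est": r.clusters_one_est,
            "pct_one_est": r.pct_one_est,
            "clusters_one_clone": r.clusters_one_clone,
            "pct_one_clone": r.pct_one_clone,
            "clusters_multi_clone": r.clusters_multi_clone,
            "pct_multi_clone": r.pct_multi_clone,
        }
        for r in all_rows
    )
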