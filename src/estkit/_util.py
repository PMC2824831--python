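"""Small shared helpers: rounding, DNA ops, intervals, union-find."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (preserves case, N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as printed tables conventionally do.

    Python's built-in ``round`` is banker's rounding; report tables in this
    package use half-up at one decimal instead.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals; result sorted by start."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ps, pe = out[-1]
        if s <= pe:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def complement_intervals(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Gaps of ``length`` not covered by the (merged) intervals."""
    out = []
    pos = 0
    for s, e in merge_intervals(intervals):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


class UnionFind:
    """Disjoint-set forest over arbitrary hashable items."""

    def __init__(self) -> None:
        self._parent: dict = {}

    def add(self, x) -> None:
        self._parent.setdefault(x, x)

    def find(self, x):
        self.add(x)
        root = x
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[x] != root:  # path compression
            self._parent[x], x = root, self._parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[rb] = ra

    def connected(self, a, b) -> bool:
        return self.find(a) == self.find(b)

    def groups(self) -> list[set]:
        comp: dict = {}
        for x in self._parent:
            comp.setdefault(self.find(x), set()).add(x)
        return list(comp.values())
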