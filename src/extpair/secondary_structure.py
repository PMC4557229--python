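"""Reduce an annotation to a bracket-encodable layered structure.

Dot-bracket notation needs one partner per residue and a pseudoknot order
(bracket level) per pair such that pairs within a level never cross.
Conflicts between detected pairs are resolved by priority (canonical >
more H-bonds > smaller span > lexicographic), and losers plus pairs that
cannot be bracket-encoded (one-H-bond non-canonical interactions, and all
non-canonical pairs in non-extended mode) are kept in a side list so no
annotation is silently lost.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from functools import lru_cache

from .basepair_annotation import AnnotationResult, BasePair, LWFamily, UNASSIGNED
from .structure_io import StructureModel, sequence_of


@dataclass(frozen=True, slots=True)
class PairedPosition:
    """A bracket-encoded pair: 1-based global indices, i < j."""

    i: int
    j: int
    order: int
    canonical: bool
    lw: LWFamily | None
    saenger: str = UNASSIGNED
    n_hbonds: int = 0

    def __post_init__(self):
        if not (0 < self.i < self.j):
            raise ValueError(f"need 0 < i < j, got ({self.i}, {self.j})")
        if self.order < 0:
            raise ValueError("pseudoknot order must be >= 0")


@dataclass(frozen=True, slots=True)
class SideInteraction:
    """An annotated interaction not encoded in dot-bracket."""

    i: int
    j: int
    lw: LWFamily | None
    saenger: str
    n_hbonds: int


@dataclass(slots=True)
class SecondaryStructure:
    """Sequence plus layered pairs and non-encodable side interactions."""

    sequence: str
    paired: list[PairedPosition] = field(default_factory=list)
    side_interactions: list[SideInteraction] = field(default_factory=list)
    chain_breaks: list[int] = field(default_factory=list)  # break AFTER these indices
    source_id: str = ""

    def __post_init__(self):
        seen: set[int] = set()
        n = len(self.sequence)
        for p in self.paired:
            if p.j > n:
                raise ValueError(f"pair ({p.i},{p.j}) outside sequence of length {n}")
            for idx in (p.i, p.j):
                if idx in seen:
                    raise ValueError(f"index {idx} paired twice")
                seen.add(idx)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def pair_map(self) -> dict[int, int]:
        """Symmetric position -> partner map over bracketed pairs."""
        m: dict[int, int] = {}
        for p in self.paired:
            m[p.i] = p.j
            m[p.j] = p.i
        return m

    def n_orders(self) -> int:
        return max((p.order for p in self.paired), default=-1) + 1


def resolve_partners(annotation: AnnotationResult,
                     extended: bool = True) -> tuple[list[BasePair], list[BasePair]]:
    """Split annotated pairs into bracket-eligible ``kept`` and ``side``.

    Canonical pairs are always eligible; non-canonical pairs only in
    extended mode and only when mediated by more than one H-bond.  When a
    residue occurs in several eligible pairs the winner is chosen by
    canonical flag, then H-bond count, then smaller index span, then
    lexicographic (i, j); losers join the side list.
    """
    eligible: list[BasePair] = []
    side: list[BasePair] = []
    for pair in annotation.pairs:
        if pair.canonical or (extended and pair.n_hbonds >= 2):
            eligible.append(pair)
        else:
            side.append(pair)

    eligible.sort(key=lambda p: (
        not p.canonical, -p.n_hbonds, p.idx_j - p.idx_i, (p.idx_i, p.idx_j),
    ))
    taken: set[int] = set()
    kept: list[BasePair] = []
    for pair in eligible:
        if pair.idx_i in taken or pair.idx_j in taken:
            side.append(pair)
        else:
            taken.update((pair.idx_i, pair.idx_j))
            kept.append(pair)
    kept.sort(key=lambda p: (p.idx_i, p.idx_j))
    side.sort(key=lambda p: (p.idx_i, p.idx_j))
    return kept, side


def _max_noncrossing(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Maximum-cardinality crossing-free subset (interval DP).

    Assumes one partner per position.  Ties are broken toward including
    the earliest pairs, i.e. the lexicographically smallest pair set.
    """
    partner: dict[int, int] = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    positions = sorted(partner)
    pos_index = {p: k for k, p in enumerate(positions)}
    npos = len(positions)

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * npos + 100))
    try:
        @lru_cache(maxsize=None)
        def best(lo: int, hi: int) -> tuple[int, frozenset]:
            if lo >= hi:
                return 0, frozenset()
            p = positions[lo]
            q = partner[p]
            qi = pos_index[q]
            skip = best(lo + 1, hi)
            if q <= p or qi >= hi:
                return skip
            inner = best(lo + 1, qi)
            outer = best(qi + 1, hi)
            take = (1 + inner[0] + outer[0], inner[1] | outer[1] | {(p, q)})
            return take if take[0] >= skip[0] else skip

        _, chosen = best(0, npos)
    finally:
        best.cache_clear()
        sys.setrecursionlimit(old_limit)
    return sorted(chosen)


def crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Pairs (i,j) and (k,l) cross iff i < k < j < l (either order)."""
    (i, j), (k, l) = sorted((a, b))
    return i < k < j < l


def _search_coloring(pairs: list[tuple[int, int]], upper: int,
                     node_budget: int = 200_000) -> dict[tuple[int, int], int] | None:
    """Minimum proper coloring of the crossing graph with < ``upper`` colors.

    Deterministic branch and bound (vertices by degree, symmetry-broken
    color choice).  Returns None when no improvement exists or the node
    budget runs out.
    """
    m = len(pairs)
    adj = [[False] * m for _ in range(m)]
    for a in range(m):
        for b in range(a + 1, m):
            if crosses(pairs[a], pairs[b]):
                adj[a][b] = adj[b][a] = True
    order = sorted(range(m), key=lambda v: (-sum(adj[v]), pairs[v]))
    nodes = 0

    def try_k(k: int) -> list[int] | None:
        nonlocal nodes
        colors = [-1] * m

        def rec(pos: int, used: int) -> bool:
            nonlocal nodes
            nodes += 1
            if nodes > node_budget:
                raise TimeoutError
            if pos == m:
                return True
            v = order[pos]
            banned = {colors[u] for u in range(m) if adj[v][u] and colors[u] >= 0}
            for c in range(min(used + 1, k)):  # new colors introduced in order
                if c in banned:
                    continue
                colors[v] = c
                if rec(pos + 1, max(used, c + 1)):
                    return True
                colors[v] = -1
            return False

        return list(colors) if rec(0, 0) else None

    best = None
    try:
        for k in range(1, upper):
            sol = try_k(k)
            if sol is not None:
                best = sol
                break
    except TimeoutError:
        return None
    if best is None:
        return None
    # canonical relabeling: classes by descending size, then smallest pair
    classes: dict[int, list[tuple[int, int]]] = {}
    for v, c in enumerate(best):
        classes.setdefault(c, []).append(pairs[v])
    ranked = sorted(classes.values(), key=lambda cl: (-len(cl), min(cl)))
    return {pair: level for level, cls in enumerate(ranked) for pair in sorted(cls)}


def assign_orders(kept: list[tuple[int, int]]) -> dict[tuple[int, int], int]:
    """Layer pairs into pseudoknot orders using the fewest levels.

    Order 0 is a maximum crossing-free subset (interval dynamic program,
    lexicographic tie-breaks) and the remainder recurses into orders 1,
    2, ...  When that peeling is not level-minimal — rare, but possible,
    since its tie-break can pin a bad maximum subset — a bounded exact
    search replaces it with a minimum layering (levels then ranked by
    size).  Deterministic throughout.
    """
    seen: set[int] = set()
    for i, j in kept:
        if i in seen or j in seen:
            raise ValueError("assign_orders requires one partner per residue")
        seen.update((i, j))

    orders: dict[tuple[int, int], int] = {}
    remaining = sorted((min(i, j), max(i, j)) for i, j in kept)
    all_pairs = list(remaining)
    level = 0
    while remaining:
        layer = _max_noncrossing(remaining)
        for pair in layer:
            orders[pair] = level
        remaining = [p for p in remaining if p not in set(layer)]
        level += 1
    if level > 2 and len(all_pairs) <= 60:
        improved = _search_coloring(all_pairs, upper=level)
        if improved is not None:
            return improved
    return orders


def build_secondary_structure(model: StructureModel, annotation: AnnotationResult,
                              extended: bool = True) -> SecondaryStructure:
    """Compose sequence extraction, partner resolution and layering."""
    chain_seqs = sequence_of(model)
    sequence = "".join(seq for _, seq in chain_seqs)
    breaks: list[int] = []
    offset = 0
    for _, seq in chain_seqs[:-1]:
        offset += len(seq)
        breaks.append(offset)

    kept, side = resolve_partners(annotation, extended=extended)
    orders = assign_orders([(p.idx_i, p.idx_j) for p in kept])
    paired = [
        PairedPosition(
            i=p.idx_i, j=p.idx_j, order=orders[(p.idx_i, p.idx_j)],
            canonical=p.canonical, lw=p.lw, saenger=p.saenger, n_hbonds=p.n_hbonds,
        )
        for p in kept
    ]
    side_out = [
        SideInteraction(i=p.idx_i, j=p.idx_j, lw=p.lw, saenger=p.saenger,
                        n_hbonds=p.n_hbonds)
        for p in side
    ]
    return SecondaryStructure(
        sequence=sequence, paired=paired, side_interactions=side_out,
        chain_breaks=breaks, source_id=model.source_id,
    )
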