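"""Shared fixtures: templates, small models, random-structure helpers."""

from __future__ import annotations

import random

import pytest

from extpair.basepair_annotation import LWFamily, UNASSIGNED
from extpair.secondary_structure import (
    PairedPosition,
    SecondaryStructure,
    assign_orders,
)
from extpair.synthetic_fixtures import all_templates, hairpin, ideal_duplex


@pytest.fixture(scope="session")
def templates():
    return all_templates()


@pytest.fixture(scope="session")
def gc_duplex():
    return ideal_duplex("GGCC")


@pytest.fixture(scope="session")
def gnra_hairpin():
    return hairpin("GCG", "GAGA")


def random_pair_set(rng: random.Random, n_positions: int, n_pairs: int):
    """Random one-partner-per-position pair set on 1..n_positions."""
    positions = rng.sample(range(1, n_positions + 1), 2 * n_pairs)
    rng.shuffle(positions)
    return sorted(
        (min(a, b), max(a, b))
        for a, b in zip(positions[::2], positions[1::2])
    )


def random_secondary_structure(rng: random.Random, max_orders: int = 4,
                               lw_labels: list[LWFamily] | None = None,
                               n_min: int = 8, n_max: int = 40) -> SecondaryStructure:
    """Random structure whose layering needs at most ``max_orders`` levels."""
    while True:
        n = rng.randint(n_min, n_max)
        n_pairs = rng.randint(0, n // 2)
        pairs = random_pair_set(rng, n, n_pairs)
        orders = assign_orders(pairs)
        if orders and max(orders.values()) >= max_orders:
            continue
        seq = "".join(rng.choice("ACGU") for _ in range(n))
        paired = [
            PairedPosition(
                i=i, j=j, order=orders[(i, j)],
                canonical=rng.random() < 0.6,
                lw=rng.choice(lw_labels) if lw_labels else None,
                saenger=UNASSIGNED,
            )
            for i, j in pairs
        ]
        return SecondaryStructure(sequence=seq, paired=paired)


def brute_force_min_layers(pairs: list[tuple[int, int]]) -> int:
    """Minimum number of crossing-free layers, by exhaustive coloring.

    Independent oracle for the layering operation: computes the chromatic
    number of the crossing graph by trying k = 1, 2, ... assignments.
    """
    from extpair.secondary_structure import crosses

    if not pairs:
        return 0
    m = len(pairs)
    edges = [
        (a, b) for a in range(m) for b in range(a + 1, m)
        if crosses(pairs[a], pairs[b])
    ]
    if not edges:
        return 1

    def colorable(k: int) -> bool:
        colors = [-1] * m

        def rec(v: int) -> bool:
            if v == m:
                return True
            used = {colors[b if a == v else a]
                    for a, b in edges if v in (a, b)
                    and colors[b if a == v else a] >= 0}
            for c in range(k):
                if c not in used:
                    colors[v] = c
                    if rec(v + 1):
                        return True
                    colors[v] = -1
            return False

        return rec(0)

    k = 2
    while not colorable(k):
        k += 1
    return k
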