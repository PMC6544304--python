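"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own machinery: patch
extraction by pairwise union-find, the mosaic richness index by direct
summation over those patches, and greedy tie-following search by naive
full recomputation. They exist so the fast implementations can be checked
against something written a different way.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mosaicopt import (
    Landscape,
    LandState,
    ObjectiveConfig,
    SarParams,
    build_state_params,
    default_params,
)

CODE = {"G": LandState.G, "F": LandState.F, "A": LandState.AG, "X": LandState.X}


def land(*rows: str, parcel_area: float = 1.0, owners=None) -> Landscape:
    """Build a landscape from strings like ``\"GFA\", \"AXG\"``."""
    states = np.array(
        [[int(CODE[ch]) for ch in row] for row in rows], dtype=np.int8
    )
    return Landscape(states=states, parcel_area=parcel_area, owners=owners)


@pytest.fixture
def params() -> SarParams:
    """Study-system SAR parameters (c_G=19.95, z=0.51, ratios 0.5 / 0.05)."""
    return default_params()


@pytest.fixture
def config(params) -> ObjectiveConfig:
    """Pure mosaic-richness objective (w=1, no extensions)."""
    return ObjectiveConfig(sar=params)


@pytest.fixture
def unit_config() -> ObjectiveConfig:
    """c=1, z=1 for every state: B_L = N^2, easy to hand-check."""
    c = {s: 1.0 for s in (LandState.G, LandState.F, LandState.AG)}
    z = {s: 1.0 for s in (LandState.G, LandState.F, LandState.AG)}
    return ObjectiveConfig(sar=SarParams(c=c, z=z))


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_patches(landscape: Landscape) -> list[set[tuple[int, int]]]:
    """Patches by naive O(M^2) pairwise union-find over same-state adjacency."""
    rows, cols = landscape.shape
    cells = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if landscape.states[r, c] != int(LandState.X)
    ]
    parent = {cell: cell for cell in cells}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(cells, 2):
        if landscape.states[a] != landscape.states[b]:
            continue
        if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1:
            parent[find(a)] = find(b)
    groups: dict[tuple[int, int], set] = {}
    for cell in cells:
        groups.setdefault(find(cell), set()).add(cell)
    return list(groups.values())


def oracle_richness(landscape: Landscape, config: ObjectiveConfig) -> float:
    """Mosaic richness index via the union-find patches, straight off the formula."""
    total = 0.0
    for patch in oracle_patches(landscape):
        cell = next(iter(patch))
        s = LandState(landscape.states[cell])
        n = len(patch)
        total += n * config.sar.c[s] * (n * landscape.parcel_area) ** config.sar.z[s]
    return total


def oracle_moves(landscape: Landscape, used=frozenset()):
    """All legal unrestricted exchanges among vegetation states."""
    rows, cols = landscape.shape
    veg = (int(LandState.G), int(LandState.F), int(LandState.AG))
    cells = [
        (r, c) for r in range(rows) for c in range(cols)
        if landscape.states[r, c] in veg and (r, c) not in used
    ]
    out = []
    for a, b in itertools.combinations(cells, 2):
        if landscape.states[a] != landscape.states[b]:
            out.append((a, b))
    return out


def oracle_swap(landscape: Landscape, a, b) -> Landscape:
    states = landscape.states.copy()
    states[a], states[b] = states[b], states[a]
    return landscape.with_states(states)


def oracle_search_all(landscape: Landscape, config: ObjectiveConfig, tol=1e-9):
    """Recursive tie-following greedy search by brute force.

    Returns the list of paths, each a list of (a, b) moves, honouring the
    once-per-parcel rule by pruning. Independent of the package's search
    module: every candidate is scored by full recomputation.
    """
    paths = []

    def recurse(land, moves, used, b_now):
        scored = []
        for a, b in oracle_moves(land, used):
            d = oracle_richness(oracle_swap(land, a, b), config) - b_now
            scored.append(((a, b), d))
        eps = tol * max(1.0, abs(b_now))
        improving = [(mv, d) for mv, d in scored if d > eps]
        if not improving:
            paths.append(list(moves))
            return
        dmax = max(d for _, d in improving)
        tied = [(mv, d) for mv, d in improving if d >= dmax - tol * max(1.0, dmax)]
        for (a, b), d in tied:
            recurse(
                oracle_swap(land, a, b),
                moves + [(a, b)],
                used | {a, b},
                b_now + d,
            )

    recurse(landscape, [], frozenset(), oracle_richness(landscape, config))
    return paths


def all_3x3_landscapes():
    """Every arrangement of 3 G, 3 F, 3 Ag parcels on a 3x3 grid (1,680)."""
    out = []
    for g_pos in itertools.combinations(range(9), 3):
        rest = [i for i in range(9) if i not in g_pos]
        for f_pos in itertools.combinations(rest, 3):
            states = np.full(9, int(LandState.AG), dtype=np.int8)
            states[list(g_pos)] = int(LandState.G)
            states[list(f_pos)] = int(LandState.F)
            out.append(Landscape(states=states.reshape(3, 3)))
    return out
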