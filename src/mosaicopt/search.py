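"""Greedy parcel-exchange local search with exhaustive tie branching.

The optimizer is a hill climber over one-exchange neighbourhoods: at every
step it evaluates the objective gain ΔB of every legal parcel exchange and
applies one of the moves that increase B the most, stopping when no exchange
improves B (a *locally optimal landscape*). Ties — several exchanges sharing
the maximal gain — are frequent on symmetric landscapes; the exhaustive
search follows every tied branch, producing the complete set of *locally
optimal paths* from an initial landscape.

Exchange rules restrict the neighbourhood: which state pairs may swap,
whether both parcels must belong to one owner (intra-property), or to a
designated owner pair (inter-property, the environmental-reserve-quota
trading scenario), and whether a parcel may change state more than once
along a path.

ΔB is computed incrementally. For the pure mosaic richness index, swapping
parcels a and b only reshapes the patch structure of their two states:
removing a cell from a patch can split it into up to four fragments (found
by a local flood fill), and adding a cell merges the fragments/patches it
touches. Per-landscape caches make each candidate O(1) after an O(patch)
precomputation; tests validate the increments against full recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigError, PathExplosionError
from .grid import (
    VON_NEUMANN,
    ExchangeMove,
    Landscape,
    LandState,
    apply_exchange,
)
from .objective import ObjectiveConfig, evaluate, mosaic_richness

__all__ = [
    "ExchangeRules",
    "SearchLimits",
    "Path",
    "SearchResult",
    "CraResult",
    "enumerate_moves",
    "best_moves",
    "search_all_paths",
    "search_single",
    "cra_run",
]

ALL_PAIRS = frozenset(
    {
        frozenset({LandState.G, LandState.AG}),
        frozenset({LandState.F, LandState.AG}),
        frozenset({LandState.G, LandState.F}),
    }
)

_OFFS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class ExchangeRules:
    """Which exchanges are legal, and how ties and reuse are handled."""

    allowed_pairs: frozenset = ALL_PAIRS
    mode: str = "unrestricted"  # unrestricted | intra_property | inter_property
    owner_pair: Optional[tuple[int, int]] = None
    max_exchanges: Optional[int] = None
    once_per_parcel: str = "prune_in_search"  # prune_in_search | post_filter | off
    tie_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.mode not in ("unrestricted", "intra_property", "inter_property"):
            raise ConfigError(f"unknown exchange mode {self.mode!r}")
        if self.mode == "inter_property" and self.owner_pair is None:
            raise ConfigError("inter_property mode requires owner_pair")
        if self.once_per_parcel not in ("prune_in_search", "post_filter", "off"):
            raise ConfigError(f"unknown once_per_parcel mode {self.once_per_parcel!r}")
        if self.max_exchanges is not None and self.max_exchanges < 1:
            raise ConfigError("max_exchanges must be >= 1 when set")


@dataclass(frozen=True)
class SearchLimits:
    """Node budget for the exhaustive tie-following search."""

    node_budget: int = 1_000_000
    on_budget: str = "error"  # error -> PathExplosionError, truncate -> flag & stop

    def __post_init__(self) -> None:
        if self.on_budget not in ("error", "truncate"):
            raise ConfigError(f"unknown on_budget mode {self.on_budget!r}")


@dataclass(frozen=True)
class Path:
    """One locally optimal path: landscapes, moves and objective trajectory."""

    initial: Landscape
    moves: tuple[ExchangeMove, ...]
    landscapes: tuple[Landscape, ...]
    trajectory: tuple[float, ...]
    terminal_flag: bool

    def __post_init__(self) -> None:
        if len(self.landscapes) != len(self.moves) + 1:
            raise ValueError("need one landscape per move plus the initial one")

    @property
    def length(self) -> int:
        return len(self.moves)

    @property
    def terminal(self) -> Landscape:
        return self.landscapes[-1]

    @property
    def terminal_value(self) -> float:
        return self.trajectory[-1]

    def reuses_parcel(self) -> bool:
        seen: set[tuple[int, int]] = set()
        for mv in self.moves:
            for p in mv.parcels:
                if p in seen:
                    return True
                seen.add(p)
        return False


@dataclass
class SearchResult:
    """All locally optimal paths found from one initial landscape."""

    paths: list[Path]
    distinct_ends: list[Landscape]
    stats: dict

    @property
    def n_paths(self) -> int:
        return len(self.paths)


@dataclass(frozen=True)
class CraResult:
    """Bounded inter-property run plus net land transfer per owner."""

    path: Path
    #: owner id -> state -> net parcel-count change over the run
    net_transfer: dict[int, dict[LandState, int]]


# ---------------------------------------------------------------------------
# Incremental ΔB engine (pure mosaic richness index)
# ---------------------------------------------------------------------------


class _DeltaEngine:
    """Per-landscape cache answering ΔB queries for candidate swaps."""

    def __init__(self, landscape: Landscape, config: ObjectiveConfig):
        self.landscape = landscape
        self.config = config
        self.states = landscape.states
        rows, cols = landscape.shape
        self.rows, self.cols = rows, cols
        m = rows * cols
        # parcel-count -> B contribution lookup per state: c * A**z * n**(z+1)
        area = landscape.parcel_area
        ns = np.arange(m + 1, dtype=float)
        self._pw = {}
        self._labels = {}
        self._sizes = {}
        self.B = 0.0
        for s in (LandState.G, LandState.F, LandState.AG):
            c, z = config.sar.c[s], config.sar.z[s]
            self._pw[s] = c * area**z * ns ** (z + 1.0)
            labels, n = ndimage.label(self.states == np.int8(s), structure=VON_NEUMANN)
            sizes = np.bincount(labels.ravel(), minlength=n + 1)
            self._labels[s] = labels
            self._sizes[s] = sizes
            self.B += float(self._pw[s][sizes[1:]].sum()) if n else 0.0
        self._removal_cache: dict[tuple[int, int], tuple[float, list[int], dict]] = {}

    def _removal(self, cell: tuple[int, int]) -> tuple[float, list[int], dict]:
        """Effect of deleting `cell` from its own state's mask.

        Returns (delta_B, fragment sizes, member-cell -> fragment-index map).
        """
        cached = self._removal_cache.get(cell)
        if cached is not None:
            return cached
        s = LandState(self.states[cell])
        labels = self._labels[s]
        lab = labels[cell]
        comp_size = int(self._sizes[s][lab])
        frag_sizes: list[int] = []
        frag_of: dict[tuple[int, int], int] = {}
        r0, c0 = cell
        for dr, dc in _OFFS:
            start = (r0 + dr, c0 + dc)
            if not (0 <= start[0] < self.rows and 0 <= start[1] < self.cols):
                continue
            if labels[start] != lab or start in frag_of:
                continue
            idx = len(frag_sizes)
            stack = [start]
            frag_of[start] = idx
            count = 0
            while stack:
                r, c = stack.pop()
                count += 1
                for dr2, dc2 in _OFFS:
                    nxt = (r + dr2, c + dc2)
                    if (
                        0 <= nxt[0] < self.rows
                        and 0 <= nxt[1] < self.cols
                        and nxt != cell
                        and labels[nxt] == lab
                        and nxt not in frag_of
                    ):
                        frag_of[nxt] = idx
                        stack.append(nxt)
            frag_sizes.append(count)
        pw = self._pw[s]
        delta = sum(pw[n] for n in frag_sizes) - pw[comp_size]
        out = (float(delta), frag_sizes, frag_of)
        self._removal_cache[cell] = out
        return out

    def _addition(
        self,
        cell: tuple[int, int],
        state: LandState,
        removed: tuple[int, int],
        frag_sizes: list[int],
        frag_of: dict,
    ) -> float:
        """Gain from adding `cell` to `state`'s mask after `removed` left it."""
        labels = self._labels[state]
        sizes = self._sizes[state]
        removed_lab = labels[removed]
        pw = self._pw[state]
        seen: set = set()
        total = 0
        old = 0.0
        r0, c0 = cell
        for dr, dc in _OFFS:
            t = (r0 + dr, c0 + dc)
            if not (0 <= t[0] < self.rows and 0 <= t[1] < self.cols) or t == removed:
                continue
            lab = labels[t]
            if lab == 0:
                continue
            if lab == removed_lab:
                key = ("f", frag_of[t])
                size = frag_sizes[frag_of[t]]
            else:
                key = ("c", int(lab))
                size = int(sizes[lab])
            if key in seen:
                continue
            seen.add(key)
            total += size
            old += pw[size]
        return float(pw[total + 1] - old)

    def delta(self, a: tuple[int, int], b: tuple[int, int]) -> float:
        """ΔB of swapping the states of parcels a and b."""
        sa = LandState(self.states[a])
        sb = LandState(self.states[b])
        d_rem_a, frags_a, frag_of_a = self._removal(a)
        d_rem_b, frags_b, frag_of_b = self._removal(b)
        gain_b_in_sa = self._addition(b, sa, a, frags_a, frag_of_a)
        gain_a_in_sb = self._addition(a, sb, b, frags_b, frag_of_b)
        return d_rem_a + gain_b_in_sa + d_rem_b + gain_a_in_sb


# ---------------------------------------------------------------------------
# Move enumeration and selection
# ---------------------------------------------------------------------------


def _legal_pairs(
    landscape: Landscape,
    rules: ExchangeRules,
    used_parcels: Iterable[tuple[int, int]] = (),
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All legal (a, b) cell pairs, a before b in row-major order."""
    used = set(used_parcels) if rules.once_per_parcel == "prune_in_search" else set()
    states = landscape.states
    owners = landscape.owners
    if rules.mode != "unrestricted" and owners is None:
        raise ConfigError(f"mode {rules.mode!r} requires an owners grid")
    cells_by_state: dict[LandState, list[tuple[int, int]]] = {}
    rows, cols = landscape.shape
    for s in (LandState.G, LandState.F, LandState.AG):
        rr, cc = np.nonzero(states == np.int8(s))
        cells_by_state[s] = [
            cell for cell in zip(rr.tolist(), cc.tolist()) if cell not in used
        ]
    pairs = []
    for pair in rules.allowed_pairs:
        s1, s2 = sorted(pair, key=int)
        for a in cells_by_state[s1]:
            for b in cells_by_state[s2]:
                if rules.mode == "intra_property" and owners[a] != owners[b]:
                    continue
                if rules.mode == "inter_property":
                    o1, o2 = rules.owner_pair
                    if {int(owners[a]), int(owners[b])} != {o1, o2}:
                        continue
                pairs.append((a, b) if a < b else (b, a))
    pairs.sort()
    return pairs


def enumerate_moves(
    landscape: Landscape,
    config: ObjectiveConfig,
    rules: ExchangeRules,
    used_parcels: Iterable[tuple[int, int]] = (),
    moves_so_far: Sequence[ExchangeMove] = (),
    _engine: Optional[_DeltaEngine] = None,
) -> list[tuple[ExchangeMove, float]]:
    """All legal exchanges with their objective gain, row-major order.

    With the pure richness objective (``w = 1``) gains come from the
    incremental engine; blended objectives fall back to full re-evaluation
    per candidate.
    """
    pairs = _legal_pairs(landscape, rules, used_parcels)
    out = []
    if config.w == 1.0:
        eng = _engine if _engine is not None else _DeltaEngine(landscape, config)
        for a, b in pairs:
            mv = ExchangeMove(a, b, LandState(landscape.states[a]), LandState(landscape.states[b]))
            out.append((mv, eng.delta(a, b)))
    else:
        base = evaluate(landscape, config, moves_so_far)
        for a, b in pairs:
            mv = ExchangeMove(a, b, LandState(landscape.states[a]), LandState(landscape.states[b]))
            nxt = apply_exchange(landscape, mv)
            out.append((mv, evaluate(nxt, config, tuple(moves_so_far) + (mv,)) - base))
    return out


def _tied_best(
    scored: list[tuple[ExchangeMove, float]], tie_tol: float, b_scale: float
) -> list[tuple[ExchangeMove, float]]:
    """Strictly improving moves within tie tolerance of the maximal gain."""
    improve_eps = tie_tol * max(1.0, abs(b_scale))
    improving = [(mv, d) for mv, d in scored if d > improve_eps]
    if not improving:
        return []
    dmax = max(d for _, d in improving)
    thr = dmax - tie_tol * max(1.0, abs(dmax))
    return [(mv, d) for mv, d in improving if d >= thr]


def best_moves(
    landscape: Landscape,
    config: ObjectiveConfig,
    rules: ExchangeRules,
    used_parcels: Iterable[tuple[int, int]] = (),
    moves_so_far: Sequence[ExchangeMove] = (),
) -> list[ExchangeMove]:
    """The tied set of maximal strictly-improving exchanges (may be empty)."""
    scored = enumerate_moves(landscape, config, rules, used_parcels, moves_so_far)
    b = evaluate(landscape, config, moves_so_far)
    return [mv for mv, _ in _tied_best(scored, rules.tie_tol, b)]


# ---------------------------------------------------------------------------
# Searches
# ---------------------------------------------------------------------------


def _make_path(
    initial: Landscape,
    moves: Sequence[ExchangeMove],
    trajectory: Sequence[float],
    terminal_flag: bool,
) -> Path:
    landscapes = [initial]
    for mv in moves:
        landscapes.append(apply_exchange(landscapes[-1], mv))
    return Path(
        initial=initial,
        moves=tuple(moves),
        landscapes=tuple(landscapes),
        trajectory=tuple(trajectory),
        terminal_flag=terminal_flag,
    )


def search_all_paths(
    initial: Landscape,
    config: ObjectiveConfig,
    rules: ExchangeRules = ExchangeRules(),
    limits: SearchLimits = SearchLimits(),
) -> SearchResult:
    """Depth-first expansion of every tied best move at every step.

    Each completed branch is one locally optimal path. Paths are distinct
    move sequences: two orderings of the same exchanges count as two paths.
    Distinct end landscapes are deduplicated by exact grid equality.
    """
    b0 = evaluate(initial, config)
    paths: list[Path] = []
    nodes = 0
    cap_hit = False
    # stack entries: (landscape, moves tuple, trajectory tuple, used parcel frozenset)
    stack: list[tuple[Landscape, tuple, tuple, frozenset]] = [
        (initial, (), (b0,), frozenset())
    ]
    while stack:
        land, moves, traj, used = stack.pop()
        if nodes >= limits.node_budget:
            if limits.on_budget == "error":
                raise PathExplosionError(
                    f"node budget {limits.node_budget} exceeded during tie-following search"
                )
            cap_hit = True
            break
        nodes += 1
        at_cap = rules.max_exchanges is not None and len(moves) >= rules.max_exchanges
        scored = enumerate_moves(land, config, rules, used, moves)
        tied = _tied_best(scored, rules.tie_tol, traj[-1])
        if not tied or at_cap:
            paths.append(_make_path(initial, moves, traj, terminal_flag=not tied))
            continue
        # reversed so the row-major-first branch is explored (and recorded) first
        for mv, d in reversed(tied):
            stack.append(
                (
                    apply_exchange(land, mv),
                    moves + (mv,),
                    traj + (traj[-1] + d,),
                    used | {mv.parcel_a, mv.parcel_b},
                )
            )
    if rules.once_per_parcel == "post_filter":
        paths = [p for p in paths if not p.reuses_parcel()]
    distinct: dict[bytes, Landscape] = {}
    for p in paths:
        distinct.setdefault(p.terminal.grid_key(), p.terminal)
    return SearchResult(
        paths=paths,
        distinct_ends=list(distinct.values()),
        stats={"nodes_expanded": nodes, "cap_hit": cap_hit, "n_paths": len(paths)},
    )


def search_single(
    initial: Landscape,
    config: ObjectiveConfig,
    rules: ExchangeRules = ExchangeRules(),
    tie_breaker: str = "lexicographic",
    seed: int = 0,
) -> Path:
    """One greedy path, breaking ties deterministically or by seeded draw."""
    if tie_breaker not in ("lexicographic", "seeded_random"):
        raise ConfigError(f"unknown tie_breaker {tie_breaker!r}")
    rng = np.random.default_rng(seed)
    land = initial
    moves: list[ExchangeMove] = []
    traj = [evaluate(initial, config)]
    used: set[tuple[int, int]] = set()
    while True:
        if rules.max_exchanges is not None and len(moves) >= rules.max_exchanges:
            tied_left = best_moves(land, config, rules, used, moves)
            return _make_path(initial, moves, traj, terminal_flag=not tied_left)
        scored = enumerate_moves(land, config, rules, used, moves)
        tied = _tied_best(scored, rules.tie_tol, traj[-1])
        if not tied:
            return _make_path(initial, moves, traj, terminal_flag=True)
        pick = tied[0] if tie_breaker == "lexicographic" else tied[int(rng.integers(len(tied)))]
        mv, d = pick
        land = apply_exchange(land, mv)
        moves.append(mv)
        traj.append(traj[-1] + d)
        used |= {mv.parcel_a, mv.parcel_b}


def cra_run(
    landscape: Landscape,
    config: ObjectiveConfig,
    rules: ExchangeRules,
    n_parcels: int,
) -> CraResult:
    """Bounded reserve-quota trade: greedy inter-property exchanges.

    Runs the single-path greedy search restricted to exchanges between the
    two designated owners, stopping after ``n_parcels`` exchanges (the
    negotiated trade area) or earlier if no exchange improves the objective.
    Reports the net parcel-count change per owner and state.
    """
    if rules.mode != "inter_property" or rules.owner_pair is None:
        raise ConfigError("cra_run requires inter_property rules with owner_pair")
    if n_parcels < 1:
        raise ConfigError("n_parcels must be >= 1")
    bounded = replace(rules, max_exchanges=n_parcels)
    path = search_single(landscape, config, bounded, tie_breaker="lexicographic")
    owners = landscape.owners
    transfer: dict[int, dict[LandState, int]] = {
        o: {s: 0 for s in (LandState.G, LandState.F, LandState.AG)}
        for o in rules.owner_pair
    }
    for mv in path.moves:
        for cell, before, after in (
            (mv.parcel_a, mv.state_a, mv.state_b),
            (mv.parcel_b, mv.state_b, mv.state_a),
        ):
            o = int(owners[cell])
            if o in transfer:
                transfer[o][before] -= 1
                transfer[o][after] += 1
    return CraResult(path=path, net_transfer=transfer)
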