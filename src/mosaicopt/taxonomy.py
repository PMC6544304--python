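"""Classification and ranking of locally optimal paths.

Among all locally optimal paths from one initial landscape:

* a *minimal path* reaches a locally optimal landscape in the fewest
  exchanges;
* a *dominant minimal path* is a minimal path whose mosaic richness index at
  every intermediate step is at least that of every other minimal path at
  the same step;
* a *minimal deviant* departs minimally from dominance: either a minimal
  path that is not dominant (one or more intermediate landscapes below the
  stepwise maximum) or a locally optimal path exactly one exchange longer
  than minimal.

Dominant minimal paths, where they exist, head the ranking of viable
candidates; when none exists (trajectories of the minimal paths cross), the
deviants become the viable candidates. The viable-candidate list always
excludes paths that change any parcel's state more than once.

Under the pure mosaic richness index, global optimality of a terminal
landscape is decidable by inspection: for a fixed number of parcels per
state, fewer patches always score higher (Bernoulli's inequality plus
induction), so a landscape is globally optimal exactly when every
vegetation state present forms a single patch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import ConfigError, EmptyResultError
from .grid import Landscape, LandState, find_patches
from .objective import ObjectiveConfig
from .search import Path, SearchResult

__all__ = [
    "PathClassification",
    "classify",
    "is_global_optimum",
    "rank",
    "once_per_parcel_filter",
]


@dataclass(frozen=True)
class PathClassification:
    """Partition of locally optimal paths into the taxonomy classes."""

    minimal: tuple[Path, ...]
    dominant_minimal: tuple[Path, ...]
    deviants: tuple[Path, ...]
    #: path -> "non_dominant_minimal" | "extra_exchange"
    deviation_reason: dict[int, str]
    viable_candidates: tuple[Landscape, ...]

    @property
    def min_length(self) -> int:
        return self.minimal[0].length


def once_per_parcel_filter(paths: Sequence[Path]) -> list[Path]:
    """Drop every path in which any parcel occurs in more than one move."""
    return [p for p in paths if not p.reuses_parcel()]


def classify(
    result: SearchResult,
    tie_tol: float = 1e-9,
    include_non_dominant_minimal: bool = True,
    include_extra_exchange: bool = True,
) -> PathClassification:
    """Split a search result into minimal / dominant-minimal / deviant paths.

    The two deviation criteria can be toggled independently; both are on by
    default. Viable candidates are the distinct end landscapes of dominant
    minimal and deviant paths after the once-per-parcel filter.
    """
    if not result.paths:
        raise EmptyResultError("no paths to classify")
    min_len = min(p.length for p in result.paths)
    minimal = [p for p in result.paths if p.length == min_len]
    # stepwise upper envelope over minimal paths
    envelope = [
        max(p.trajectory[t] for p in minimal) for t in range(min_len + 1)
    ]
    dominant = []
    non_dominant = []
    for p in minimal:
        tol = [tie_tol * max(1.0, abs(e)) for e in envelope]
        if all(p.trajectory[t] >= envelope[t] - tol[t] for t in range(min_len + 1)):
            dominant.append(p)
        else:
            non_dominant.append(p)
    deviants: list[Path] = []
    reasons: dict[int, str] = {}
    if include_non_dominant_minimal:
        for p in non_dominant:
            deviants.append(p)
            reasons[id(p)] = "non_dominant_minimal"
    if include_extra_exchange:
        for p in result.paths:
            if p.length == min_len + 1:
                deviants.append(p)
                reasons[id(p)] = "extra_exchange"
    viable_pool = once_per_parcel_filter(list(dominant) + deviants)
    seen: dict[bytes, Landscape] = {}
    for p in viable_pool:
        seen.setdefault(p.terminal.grid_key(), p.terminal)
    return PathClassification(
        minimal=tuple(minimal),
        dominant_minimal=tuple(dominant),
        deviants=tuple(deviants),
        deviation_reason=reasons,
        viable_candidates=tuple(seen.values()),
    )


def is_global_optimum(
    landscape: Landscape, config: Optional[ObjectiveConfig] = None
) -> bool:
    """True iff every vegetation state present forms exactly one patch.

    Only valid under the pure mosaic richness index (``w = 1``); the
    fewest-patches argument does not extend to architecture or cost
    objectives, so those raise.
    """
    if config is not None and (config.w != 1.0 or config.architecture_mode != "none"):
        raise ConfigError(
            "single-patch global-optimality criterion only holds for the pure index"
        )
    patch_counts: dict[LandState, int] = {}
    for p in find_patches(landscape):
        patch_counts[p.state] = patch_counts.get(p.state, 0) + 1
    return all(n == 1 for n in patch_counts.values())


def _rank_key(p: Path, dominant_ids: set[int]):
    return (
        0 if id(p) in dominant_ids else 1,
        p.length,
        tuple(-b for b in p.trajectory),
        -p.terminal_value,
        tuple((mv.parcel_a, mv.parcel_b) for mv in p.moves),
    )


def rank(classification: PathClassification) -> tuple[list[Path], pd.DataFrame]:
    """Total order over classified paths plus a per-step trajectory table.

    Dominant minimal paths come first; the rest sort by length (ascending),
    then stepwise trajectory (descending, lexicographic), then terminal
    value; the move list is the final deterministic tiebreak. The table has
    columns ``path_id, step, B`` for plotting richness along each path.
    """
    pool = list(
        dict.fromkeys(
            list(classification.dominant_minimal)
            + list(classification.minimal)
            + list(classification.deviants)
        )
    )
    if not pool:
        raise EmptyResultError("empty classification")
    dominant_ids = {id(p) for p in classification.dominant_minimal}
    ordered = sorted(pool, key=lambda p: _rank_key(p, dominant_ids))
    rows = [
        {"path_id": i, "step": t, "B": b}
        for i, p in enumerate(ordered)
        for t, b in enumerate(p.trajectory)
    ]
    return ordered, pd.DataFrame(rows, columns=["path_id", "step", "B"])
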