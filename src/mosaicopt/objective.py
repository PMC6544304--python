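"""Mosaic richness index and optional architecture / cost extensions.

The core objective is the *mosaic richness index*

    B = sum over patches L of  B_L,      B_L = N_L * c_j * (N_L * A)**z_j,

where ``N_L`` is the number of parcels in patch ``L``, ``A`` the parcel area
and ``(c_j, z_j)`` the SAR parameters of the patch's vegetation state. The
patch SAR is weighted by the parcel count so that one connected patch of N
parcels always scores higher than the same parcels split across several
patches (Bernoulli's inequality: ``(N1+N2)**(z+1) > N1**(z+1) + N2**(z+1)``
for ``z > 0``), which is what makes consolidation the optimal behaviour.

Two optional extensions can be blended in with a weight ``w``:

* patch architecture, rewarding forest/grassland patches that are close to
  one another (reciprocal nearest-centroid distances) or that border
  agriculture on few parcels (reciprocal adjacency counts);
* a path cost term, the reciprocal of the accumulated cost of all parcel
  state changes along an exchange pathway.

Architecture and cost are alternatives, not combinable; the analysis default
is the pure index (``w = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, MissingCostError
from .grid import (
    ExchangeMove,
    Landscape,
    LandState,
    Patch,
    agri_adjacent_count,
    find_patches,
    patch_centroid,
)
from .sar import SarParams, default_params

__all__ = [
    "ObjectiveConfig",
    "patch_richness",
    "mosaic_richness",
    "architecture_distance",
    "architecture_adjacency",
    "cost_term",
    "evaluate",
]

ARCHITECTURE_MODES = ("none", "distance", "adjacency", "both")


@dataclass(frozen=True)
class ObjectiveConfig:
    """Objective settings.

    ``w`` blends the mosaic richness index with the selected extension
    (``w = 1``: pure index). ``cost_table`` maps ordered state-change pairs
    ``(from_state, to_state)`` to non-negative costs. The degenerate caps
    replace reciprocals of zero (a state with fewer than two patches, no
    agricultural adjacency, or a zero-cost path) with a finite value so the
    objective stays finite and monotone.
    """

    sar: SarParams = field(default_factory=default_params)
    w: float = 1.0
    architecture_mode: str = "none"
    cost_table: Optional[dict[tuple[LandState, LandState], float]] = None
    distance_cap: float = 1.0
    adjacency_cap: float = 2.0
    cost_cap: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ConfigError("w must lie in [0, 1]")
        if self.architecture_mode not in ARCHITECTURE_MODES:
            raise ConfigError(f"unknown architecture_mode {self.architecture_mode!r}")
        if self.architecture_mode != "none" and self.cost_table is not None:
            raise ConfigError("architecture and cost extensions are alternatives")
        if self.cost_table is not None and any(v < 0 for v in self.cost_table.values()):
            raise ConfigError("costs must be non-negative")
        for cap in (self.distance_cap, self.adjacency_cap, self.cost_cap):
            if cap <= 0:
                raise ConfigError("degenerate caps must be positive")


def patch_richness(patch: Patch, config: ObjectiveConfig, parcel_area: float = None) -> float:
    """Parcel-count-weighted SAR value of one patch: N * c * (N*A)**z."""
    if patch.state == LandState.X:
        return 0.0
    area = parcel_area if parcel_area is not None else patch.parcel_area
    n = patch.n_parcels
    c = config.sar.c[patch.state]
    z = config.sar.z[patch.state]
    return n * c * (n * area) ** z


def mosaic_richness(landscape: Landscape, config: ObjectiveConfig) -> float:
    """Mosaic richness index B: sum of patch richness over all patches."""
    return sum(
        patch_richness(p, config, landscape.parcel_area) for p in find_patches(landscape)
    )


def _state_patches(patches: Sequence[Patch], state: LandState) -> list[Patch]:
    return [p for p in patches if p.state == state]


def architecture_distance(landscape: Landscape, cap: float = 1.0) -> float:
    """Proximity architecture term P_A1.

    For forest and for grassland separately, sum over patches the distance
    from each patch centroid to the nearest other same-state patch centroid
    (Euclidean, parcel side-length units) and take the reciprocal; the two
    reciprocals are added. A state with fewer than two patches has no such
    distance and contributes the cap.
    """
    patches = find_patches(landscape)
    total = 0.0
    for state in (LandState.F, LandState.G):
        group = _state_patches(patches, state)
        if len(group) < 2:
            total += cap
            continue
        cents = np.array([patch_centroid(p) for p in group])
        diff = cents[:, None, :] - cents[None, :, :]
        d = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(d, np.inf)
        total += 1.0 / float(d.min(axis=1).sum())
    return total


def architecture_adjacency(landscape: Landscape, cap: float = 2.0) -> float:
    """Agriculture-adjacency architecture term P_A2.

    Reciprocal of the total number of forest parcels adjacent to agriculture
    plus the reciprocal for grassland; a zero total (no contact with
    agriculture at all) contributes the cap.
    """
    patches = find_patches(landscape)
    total = 0.0
    for state in (LandState.F, LandState.G):
        s = sum(agri_adjacent_count(p, landscape) for p in _state_patches(patches, state))
        total += (1.0 / s) if s > 0 else cap
    return total


def cost_term(
    moves: Sequence[ExchangeMove],
    cost_table: dict[tuple[LandState, LandState], float],
    cap: float = 1.0,
) -> float:
    """Reciprocal accumulated cost C of a pathway's parcel state changes.

    Each exchange contributes two individual parcel state changes (parcel a:
    state_a → state_b, parcel b: state_b → state_a), each priced by the
    ordered-pair cost table. An empty pathway (or zero total cost) yields
    the cap.
    """
    total = 0.0
    for mv in moves:
        for pair in ((mv.state_a, mv.state_b), (mv.state_b, mv.state_a)):
            if pair not in cost_table:
                raise MissingCostError(
                    f"no cost entry for change {pair[0].code}->{pair[1].code}"
                )
            total += cost_table[pair]
    return (1.0 / total) if total > 0 else cap


def evaluate(
    landscape: Landscape,
    config: ObjectiveConfig,
    moves_so_far: Sequence[ExchangeMove] = (),
) -> float:
    """Full objective value under the configured extension.

    ``w = 1`` (the analysis default) reduces to the pure mosaic richness
    index; otherwise the architecture term(s) or the path cost term are
    blended in as ``w*B + (1-w)*extra``.
    """
    b = mosaic_richness(landscape, config)
    if config.w == 1.0:
        return b
    if config.cost_table is not None:
        extra = cost_term(moves_so_far, config.cost_table, config.cost_cap)
    elif config.architecture_mode == "distance":
        extra = architecture_distance(landscape, config.distance_cap)
    elif config.architecture_mode == "adjacency":
        extra = architecture_adjacency(landscape, config.adjacency_cap)
    elif config.architecture_mode == "both":
        extra = architecture_distance(landscape, config.distance_cap) + architecture_adjacency(
            landscape, config.adjacency_cap
        )
    else:
        raise ConfigError("w < 1 requires an architecture mode or a cost table")
    return config.w * b + (1.0 - config.w) * extra
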