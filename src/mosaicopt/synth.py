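"""Synthetic landscapes, synthetic quadrat tables, and packaged fixtures.

The generator reproduces the study conditions of the hypothetical-landscape
experiments: 6×6 rasters of 36 square parcels with 12 parcels each of
grassland, forest and agriculture, assigned uniformly at random, and
1 m² quadrat presence tables whose combination-averaged accumulation curve
follows a target power law (default the grassland calibration,
c = 19.95 species/m², z = 0.51, 15 quadrats).

The two published 6×6 initial landscapes exist only as raster figures in
the source article; no verified cell-by-cell transcription could be
packaged. Requesting them by name raises
:class:`~mosaicopt.errors.FixtureUnavailableError`; clearly-labelled
*synthetic* stand-ins with the same shape and state counts (fixed seeds)
are shipped instead, alongside an invented two-owner demo grid for
reserve-quota trading runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from scipy.optimize import nnls

from .errors import (
    CountMismatchError,
    FixtureUnavailableError,
    InfeasibleTargetError,
    UnknownFixtureError,
)
from .grid import Landscape, LandState
from .sar import QuadratTable

__all__ = [
    "LandscapeSpec",
    "random_landscape",
    "synth_quadrats",
    "load_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for a random landscape with exact per-state parcel counts."""

    rows: int = 6
    cols: int = 6
    state_counts: dict = field(
        default_factory=lambda: {LandState.G: 12, LandState.F: 12, LandState.AG: 12}
    )
    #: optional (block_rows, block_cols): partition into a grid of rectangular
    #: ownership blocks, owner ids assigned row-major from 0
    owner_blocks: Optional[tuple[int, int]] = None
    seed: int = 0


def random_landscape(spec: LandscapeSpec, parcel_area: float = 1.0) -> Landscape:
    """Uniformly random assignment of the exact state counts to the grid."""
    total = spec.rows * spec.cols
    counts = {LandState(k): v for k, v in spec.state_counts.items()}
    if any(v < 0 for v in counts.values()) or sum(counts.values()) != total:
        raise CountMismatchError(
            f"state counts {counts} do not fill a {spec.rows}x{spec.cols} grid"
        )
    flat = np.concatenate(
        [np.full(n, int(s), dtype=np.int8) for s, n in sorted(counts.items())]
    )
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(flat)
    states = flat.reshape(spec.rows, spec.cols)
    owners = None
    if spec.owner_blocks is not None:
        br, bc = spec.owner_blocks
        rr = np.minimum(np.arange(spec.rows) * br // spec.rows, br - 1)
        cc = np.minimum(np.arange(spec.cols) * bc // spec.cols, bc - 1)
        owners = (rr[:, None] * bc + cc[None, :]).astype(np.int64)
    return Landscape(states=states, parcel_area=parcel_area, owners=owners)


def _expected_union(p: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """E[distinct species in k quadrats] under independent Bernoulli occupancy."""
    return np.array([(1.0 - (1.0 - p) ** k).sum() for k in ks])


def synth_quadrats(
    n_quadrats: int = 15,
    pool_size: int = 160,
    target_c: float = 19.95,
    target_z: float = 0.51,
    seed: int = 0,
    quadrat_area: float = 1.0,
) -> QuadratTable:
    """Quadrat presence table whose accumulation curve tracks c·(kA)^z.

    Each species occupies each quadrat independently with a species-specific
    probability. The probability profile is solved numerically so the
    expected k-quadrat union richness matches the target power law at every
    k: species counts are distributed over a grid of occupancy levels by
    non-negative least squares (the expected curve is linear in the counts),
    then rounded to integers by largest remainder. Occupancy is then sampled
    with the given seed.
    """
    if n_quadrats < 1:
        raise ValueError("n_quadrats must be >= 1")
    ks = np.arange(1, n_quadrats + 1)
    target = target_c * (ks * quadrat_area) ** target_z
    if target[-1] > pool_size:
        raise InfeasibleTargetError(
            f"target richness {target[-1]:.1f} at k={n_quadrats} exceeds pool {pool_size}"
        )
    if target_z == 0:
        # flat curve: a fixed core of always-present species
        k_core = int(round(target_c * quadrat_area**0))
        p = np.zeros(pool_size)
        p[:k_core] = 1.0
    else:
        # occupancy levels bounded below at 0.05: very rare species inflate
        # union-curve variance without improving the (already tiny) fit residual
        levels = np.concatenate(([1.0], np.geomspace(0.9, 0.05, 29)))
        design = 1.0 - (1.0 - levels[None, :]) ** ks[:, None]
        weights, _ = nnls(design, target)
        if weights.sum() > pool_size:
            raise InfeasibleTargetError(
                f"target curve needs ~{weights.sum():.0f} species, pool is {pool_size}"
            )
        counts = np.floor(weights).astype(int)
        remainder = weights - counts
        short = int(round(weights.sum())) - counts.sum()
        for idx in np.argsort(remainder)[::-1][:short]:
            counts[idx] += 1
        p = np.repeat(levels, counts)
        p = np.pad(p, (0, pool_size - p.size))
    rng = np.random.default_rng(seed)
    presence = rng.random((pool_size, n_quadrats)) < p[:, None]
    # drop species never observed; richness only depends on observed presence
    keep = presence.any(axis=1)
    covers = presence[keep].astype(float)
    species_ids = tuple(f"sp{i + 1}" for i in np.nonzero(keep)[0])
    return QuadratTable(species_ids=species_ids, covers=covers, quadrat_area=quadrat_area)


#: Packaged fixtures. The figure-derived names are deliberately absent: no
#: verifiable transcription of the published 6×6 grids exists in text form.
FIXTURE_NAMES = ("fig4a_synthetic", "fig5a_synthetic", "demo_two_owner")

_UNAVAILABLE = {
    "fig4a": "fig4a_synthetic",
    "fig5a": "fig5a_synthetic",
}


def load_fixture(name: str) -> Landscape:
    """Load a packaged fixture landscape by name.

    ``fig4a_synthetic`` / ``fig5a_synthetic`` are synthetic stand-ins for
    the two published hypothetical 6×6 initial landscapes (same shape and
    per-state counts, random arrangement at fixed seeds 0 and 1);
    ``demo_two_owner`` is an invented two-property grid for bounded
    inter-property trading demos. Requesting ``fig4a``/``fig5a`` directly
    raises :class:`FixtureUnavailableError`, because the published grids
    appear only as figure images and no cell-by-cell transcription could be
    verified and packaged.
    """
    if name in _UNAVAILABLE:
        raise FixtureUnavailableError(
            f"fixture {name!r} is a published figure with no verifiable text "
            f"transcription available; use {_UNAVAILABLE[name]!r} (a synthetic "
            "stand-in with the same shape and state counts) instead"
        )
    if name not in FIXTURE_NAMES:
        raise UnknownFixtureError(f"unknown fixture {name!r}")
    from .io import read_landscape  # deferred: io imports grid, not synth

    pkg = resources.files("mosaicopt") / "fixtures"
    land = read_landscape(str(pkg / f"{name}.csv"))
    owners_path = pkg / f"{name}_owners.csv"
    if owners_path.is_file():
        owners = np.loadtxt(str(owners_path), delimiter=",", dtype=np.int64, ndmin=2)
        land = Landscape(states=land.states, parcel_area=land.parcel_area, owners=owners)
    return land
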