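"""Raster landscape model: land states, patches, and parcel exchanges.

A landscape is a rectangular grid of square *parcels*, each entirely in one
land state: grassland (``G``), forest (``F``), agriculture (``Ag``), or the
immutable excluded state ``X`` (urban and water cells, which never participate
in exchanges and contribute nothing to any objective).

A *patch* is a maximal set of same-state parcels connected under the von
Neumann (4-neighbour) adjacency; diagonal contact does not connect. Patches of
the three vegetation states partition the non-excluded grid.

A *parcel exchange* swaps the land states of two parcels (G↔Ag, F↔Ag or G↔F),
so per-state parcel counts — in particular the total agricultural area — are
conserved by construction.

Coordinates are 0-based ``(row, col)``, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Optional

import numpy as np
from scipy import ndimage

from .errors import ExcludedParcelError, InvalidStateError, SameStateError

__all__ = [
    "LandState",
    "Landscape",
    "Patch",
    "ExchangeMove",
    "VON_NEUMANN",
    "find_patches",
    "apply_exchange",
    "patch_centroid",
    "agri_adjacent_count",
]


class LandState(IntEnum):
    """Land state of a parcel. ``X`` is immutable and inert."""

    G = 0   # grassland
    F = 1   # forest
    AG = 2  # agriculture
    X = 3   # excluded: urban / water

    @property
    def code(self) -> str:
        return _CODES[self]

    @classmethod
    def from_code(cls, code: str) -> "LandState":
        try:
            return _FROM_CODE[code]
        except KeyError:
            raise KeyError(f"unknown land-state code {code!r}") from None


_CODES = {LandState.G: "G", LandState.F: "F", LandState.AG: "Ag", LandState.X: "X"}
_FROM_CODE = {"G": LandState.G, "F": LandState.F, "Ag": LandState.AG, "X": LandState.X}

#: Vegetation states that carry a species-area relationship.
VEGETATION_STATES = (LandState.G, LandState.F, LandState.AG)

#: 4-connected structuring element used for all patch extraction.
VON_NEUMANN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

_NEIGHBOUR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class Landscape:
    """A rectangular raster of land states.

    Parameters
    ----------
    states
        ``(rows, cols)`` int8 array of :class:`LandState` values.
    parcel_area
        Area of one square parcel, in arbitrary area units (default 1, the
        1 m² quadrat scale the SAR parameters are calibrated at).
    owners
        Optional same-shape integer array of owner identifiers; ``-1`` marks
        unowned / state land.
    """

    states: np.ndarray
    parcel_area: float = 1.0
    owners: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        if states.ndim != 2 or states.size == 0:
            raise ValueError("states must be a non-empty 2-D grid")
        if self.parcel_area <= 0:
            raise ValueError("parcel_area must be positive")
        object.__setattr__(self, "states", states)
        if self.owners is not None:
            owners = np.asarray(self.owners, dtype=np.int64)
            if owners.shape != states.shape:
                raise ValueError("owners grid must match states shape")
            object.__setattr__(self, "owners", owners)

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape

    @property
    def n_parcels(self) -> int:
        """Total number of parcels, excluded cells included."""
        return self.states.size

    def state_counts(self) -> dict[LandState, int]:
        """Number of parcels per land state."""
        counts = np.bincount(self.states.ravel(), minlength=4)
        return {s: int(counts[s]) for s in LandState}

    def mask(self, state: LandState) -> np.ndarray:
        return self.states == np.int8(state)

    def grid_key(self) -> bytes:
        """Hashable exact-equality key for the state grid (owners ignored)."""
        return self.states.tobytes()

    def with_states(self, states: np.ndarray) -> "Landscape":
        return Landscape(states=states, parcel_area=self.parcel_area, owners=self.owners)

    def iter_cells(self) -> Iterator[tuple[int, int]]:
        rows, cols = self.shape
        for r in range(rows):
            for c in range(cols):
                yield (r, c)

    def __eq__(self, other: object) -> bool:  # exact grid equality
        if not isinstance(other, Landscape):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.parcel_area == other.parcel_area
            and bool(np.array_equal(self.states, other.states))
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.parcel_area, self.grid_key()))


@dataclass(frozen=True)
class Patch:
    """A maximal von Neumann-connected set of same-state parcels."""

    state: LandState
    parcels: frozenset[tuple[int, int]]
    parcel_area: float = 1.0

    @property
    def n_parcels(self) -> int:
        return len(self.parcels)

    @property
    def area(self) -> float:
        return self.n_parcels * self.parcel_area


@dataclass(frozen=True)
class ExchangeMove:
    """Swap of land states between two parcels; states recorded pre-move."""

    parcel_a: tuple[int, int]
    parcel_b: tuple[int, int]
    state_a: LandState
    state_b: LandState

    @property
    def parcels(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.parcel_a, self.parcel_b)


def _label_state(mask: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(mask, structure=VON_NEUMANN)


def find_patches(landscape: Landscape) -> list[Patch]:
    """Extract all patches of the landscape.

    Every non-excluded parcel belongs to exactly one returned patch. Patches
    are returned in a deterministic order: by state code (``Ag``, ``F``,
    ``G``), then by smallest row-major parcel index within the patch.

    Notes
    -----
    Connected-component labelling is delegated to
    :func:`scipy.ndimage.label` with a 4-connected structuring element.
    """
    patches: list[Patch] = []
    for state in sorted(VEGETATION_STATES, key=lambda s: s.code):
        labels, n = _label_state(landscape.mask(state))
        if n == 0:
            continue
        cols = landscape.shape[1]
        state_patches = []
        for lab in range(1, n + 1):
            rr, cc = np.nonzero(labels == lab)
            cells = frozenset(zip(rr.tolist(), cc.tolist()))
            first = min(r * cols + c for r, c in cells)
            state_patches.append((first, Patch(state, cells, landscape.parcel_area)))
        state_patches.sort(key=lambda t: t[0])
        patches.extend(p for _, p in state_patches)
    return patches


def apply_exchange(
    landscape: Landscape,
    move: ExchangeMove,
    allowed_pairs: Optional[frozenset[frozenset[LandState]]] = None,
) -> Landscape:
    """Return a new landscape with the two parcels' states swapped.

    Raises
    ------
    SameStateError
        If the two parcels are in the same state.
    ExcludedParcelError
        If either parcel is in state ``X``.
    DisallowedPairError
        If ``allowed_pairs`` is given and the state pair is not in it.
    """
    a, b = move.parcel_a, move.parcel_b
    sa = LandState(landscape.states[a])
    sb = LandState(landscape.states[b])
    if sa == LandState.X or sb == LandState.X:
        raise ExcludedParcelError(f"exchange touches excluded parcel at {a if sa == LandState.X else b}")
    if sa == sb:
        raise SameStateError(f"parcels {a} and {b} are both {sa.code}")
    if allowed_pairs is not None and frozenset((sa, sb)) not in allowed_pairs:
        from .errors import DisallowedPairError

        raise DisallowedPairError(f"pair {sa.code}<->{sb.code} is not an allowed exchange")
    states = landscape.states.copy()
    states[a], states[b] = states[b], states[a]
    return landscape.with_states(states)


def patch_centroid(patch: Patch, parcel_area: Optional[float] = None) -> tuple[float, float]:
    """Centroid of a patch in parcel side-length units, ``(x, y)``.

    The centre of cell ``(row, col)`` sits at ``(col + 0.5, row + 0.5)`` side
    lengths; the centroid is the arithmetic mean of member cell centres. The
    side length is ``sqrt(parcel_area)`` in area units, but distances within
    the package are kept in side-length units, so the scale factor cancels.
    """
    if patch.n_parcels < 1:
        raise ValueError("patch must contain at least one parcel")
    rows = [r for r, _ in patch.parcels]
    cols = [c for _, c in patch.parcels]
    x = sum(cols) / len(cols) + 0.5
    y = sum(rows) / len(rows) + 0.5
    return (x, y)


def agri_adjacent_count(patch: Patch, landscape: Landscape) -> int:
    """Number of parcels of a G or F patch with ≥1 agricultural neighbour.

    Each member parcel is counted at most once, regardless of how many of its
    von Neumann neighbours are agricultural.
    """
    if patch.state not in (LandState.G, LandState.F):
        raise InvalidStateError(
            f"agri-adjacency is defined for G and F patches, not {patch.state.code}"
        )
    rows, cols = landscape.shape
    ag = np.int8(LandState.AG)
    count = 0
    for r, c in patch.parcels:
        for dr, dc in _NEIGHBOUR_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and landscape.states[rr, cc] == ag:
                count += 1
                break
    return count
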