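"""Mosaic richness index, architecture terms, costs, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicopt import (
    ConfigError,
    ExchangeMove,
    LandState,
    MissingCostError,
    ObjectiveConfig,
    Patch,
    SarParams,
    architecture_adjacency,
    architecture_distance,
    cost_term,
    evaluate,
    find_patches,
    mosaic_richness,
    patch_richness,
)

from conftest import land, oracle_richness


def _gpatch(n, area=1.0):
    return Patch(LandState.G, frozenset((0, i) for i in range(n)), area)


class TestPatchRichness:
    def test_singleton_equals_sar_value(self, config):
        assert patch_richness(_gpatch(1), config) == pytest.approx(19.95)

    def test_two_parcels_unit_params(self, unit_config):
        # N * c * (N*A)^z = 2 * 1 * 2^1
        assert patch_richness(_gpatch(2), unit_config) == pytest.approx(4.0)

    def test_twelve_parcel_grassland_patch(self, config):
        expected = 19.95 * 12**1.51  # N*c*(N*A)^z = c*N^(z+1) at A=1
        val = patch_richness(_gpatch(12), config)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(850.2, abs=0.5)

    def test_excluded_patch_scores_zero(self, config):
        assert patch_richness(Patch(LandState.X, frozenset({(0, 0)})), config) == 0.0


class TestMosaicRichness:
    def test_all_excluded_is_zero(self, config):
        assert mosaic_richness(land("XX", "XX"), config) == 0.0

    def test_single_patch_beats_split(self, config):
        one = land("GGGGGGGGGGGG")
        two = land("GGGGGGXGGGGGG")  # two 6-parcel patches
        b_one = mosaic_richness(one, config)
        b_two = mosaic_richness(two, config)
        assert b_one == pytest.approx(19.95 * 12**1.51, rel=1e-12)
        assert b_two == pytest.approx(2 * 19.95 * 6**1.51, rel=1e-12)
        assert b_one > b_two

    def test_additive_over_disjoint_state_regions(self, config):
        full = land("GGX", "XXX", "AAF")
        parts = [land("GGX", "XXX", "XXX"), land("XXX", "XXX", "AAX"), land("XXX", "XXX", "XXF")]
        assert mosaic_richness(full, config) == pytest.approx(
            sum(mosaic_richness(p, config) for p in parts)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_find_oracle(self, seed, config):
        rng = np.random.default_rng(seed)
        from mosaicopt import Landscape

        landscape = Landscape(states=rng.integers(0, 4, size=(6, 6)).astype(np.int8))
        assert mosaic_richness(landscape, config) == pytest.approx(
            oracle_richness(landscape, config), rel=1e-12
        )

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_invariant_under_rotation_and_reflection(self, k, config):
        rng = np.random.default_rng(k)
        from mosaicopt import Landscape

        landscape = Landscape(states=rng.integers(0, 4, size=(5, 7)).astype(np.int8))
        b = mosaic_richness(landscape, config)
        rotated = Landscape(states=np.rot90(landscape.states, k=k).copy())
        flipped = Landscape(states=np.fliplr(landscape.states).copy())
        assert mosaic_richness(rotated, config) == pytest.approx(b, rel=1e-12)
        assert mosaic_richness(flipped, config) == pytest.approx(b, rel=1e-12)

    def test_parcel_area_scaling(self, config):
        landscape = land("GAF", "FGA")
        scaled = land("GAF", "FGA", parcel_area=4.0)
        expected = sum(
            p.n_parcels
            * config.sar.c[p.state]
            * (p.n_parcels * 4.0) ** config.sar.z[p.state]
            for p in find_patches(scaled)
        )
        assert mosaic_richness(scaled, config) == pytest.approx(expected, rel=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n1=st.integers(1, 500),
    n2=st.integers(1, 500),
    z=st.floats(1e-6, 1.0),
    c=st.floats(1e-3, 50.0),
)
def test_merge_monotonicity(n1, n2, z, c):
    """One patch of N1+N2 parcels always outscores the split (Bernoulli)."""
    merged = c * (n1 + n2) ** (z + 1)
    split = c * (n1 ** (z + 1) + n2 ** (z + 1))
    assert merged > split


class TestArchitectureTerms:
    def test_distance_two_forest_patches(self):
        # forest singletons at (0,0) and (0,3): centroids 3 side-lengths apart
        landscape = land("FAAF", "GGGG")
        val = architecture_distance(landscape, cap=1.0)
        assert val == pytest.approx(1.0 / 6.0 + 1.0)

    def test_distance_degenerate_all_single(self):
        landscape = land("FG", "FG")
        assert architecture_distance(landscape, cap=1.0) == pytest.approx(2.0)

    def test_moving_forest_patches_closer_increases_term(self):
        far = land("FAAAF", "GGGGG")
        near = land("FAFAA", "GGGGG")
        assert architecture_distance(near, 1.0) > architecture_distance(far, 1.0)

    def test_adjacency_counts(self):
        # 3x4 fixture: forest column touching agriculture twice,
        # grassland parcels touching agriculture four times
        landscape = land(
            "FAGG",
            "FAGG",
            "GAGG",
        )
        # E(F): both forest parcels adjacent to column-1 agriculture -> 2
        # E(G): (2,0) plus the three right-block cells in column 2 -> 4
        assert architecture_adjacency(landscape, cap=2.0) == pytest.approx(1 / 2 + 1 / 4)

    def test_adjacency_degenerate_no_contact(self):
        landscape = land("FG", "FG")
        assert architecture_adjacency(landscape, cap=2.0) == pytest.approx(4.0)


class TestCostTerm:
    table = {
        (LandState.G, LandState.AG): 3.0,  # grassland parcel converted to agriculture
        (LandState.AG, LandState.G): 2.0,
    }

    def test_empty_path_hits_cap(self):
        assert cost_term([], self.table, cap=7.0) == 7.0

    def test_one_exchange_two_changes(self):
        mv = ExchangeMove((0, 0), (0, 1), LandState.G, LandState.AG)
        assert cost_term([mv], self.table) == pytest.approx(1.0 / 5.0)

    def test_doubling_costs_halves_term(self):
        mv = ExchangeMove((0, 0), (0, 1), LandState.G, LandState.AG)
        doubled = {k: 2 * v for k, v in self.table.items()}
        assert cost_term([mv], doubled) == pytest.approx(cost_term([mv], self.table) / 2)

    def test_missing_entry(self):
        mv = ExchangeMove((0, 0), (0, 1), LandState.G, LandState.F)
        with pytest.raises(MissingCostError):
            cost_term([mv], self.table)


class TestEvaluate:
    def test_pure_index(self, config):
        landscape = land("GAF", "FGA")
        assert evaluate(landscape, config) == mosaic_richness(landscape, config)

    def test_w_zero_distance_is_architecture_only(self, params):
        cfg = ObjectiveConfig(sar=params, w=0.0, architecture_mode="distance")
        landscape = land("FAAF", "GGGG")
        assert evaluate(landscape, cfg) == pytest.approx(architecture_distance(landscape, 1.0))

    def test_w_half_blends(self, params):
        cfg = ObjectiveConfig(sar=params, w=0.5, architecture_mode="adjacency")
        landscape = land("FAGG", "FAGG", "GAGG")
        expected = 0.5 * mosaic_richness(landscape, cfg) + 0.5 * architecture_adjacency(
            landscape, 2.0
        )
        assert evaluate(landscape, cfg) == pytest.approx(expected)

    def test_cost_mode_uses_moves(self, params):
        cfg = ObjectiveConfig(sar=params, w=0.5, cost_table=TestCostTerm.table)
        landscape = land("GA")
        mv = ExchangeMove((0, 0), (0, 1), LandState.G, LandState.AG)
        expected = 0.5 * mosaic_richness(landscape, cfg) + 0.5 / 5.0
        assert evaluate(landscape, cfg, [mv]) == pytest.approx(expected)

    def test_architecture_and_cost_are_alternatives(self, params):
        with pytest.raises(ConfigError):
            ObjectiveConfig(
                sar=params, w=0.5, architecture_mode="distance", cost_table=TestCostTerm.table
            )

    def test_w_out_of_range(self, params):
        with pytest.raises(ConfigError):
            ObjectiveConfig(sar=params, w=1.5)
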