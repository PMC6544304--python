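"""Greedy tie-following local search: enumeration, ties, paths, CRA runs."""

import numpy as np
import pytest

from mosaicopt import (
    ConfigError,
    ExchangeRules,
    Landscape,
    LandState,
    PathExplosionError,
    SearchLimits,
    apply_exchange,
    best_moves,
    cra_run,
    enumerate_moves,
    evaluate,
    mosaic_richness,
    search_all_paths,
    search_single,
)
from mosaicopt.search import ALL_PAIRS

from conftest import land, oracle_richness, oracle_search_all


RULES = ExchangeRules()


class TestEnumerateMoves:
    def test_single_pair(self, config):
        moves = enumerate_moves(land("GA"), config, RULES)
        assert len(moves) == 1
        mv, _ = moves[0]
        assert {mv.state_a, mv.state_b} == {LandState.G, LandState.AG}

    def test_one_move_per_pair_type(self, config):
        moves = enumerate_moves(land("GFA"), config, RULES)
        assert len(moves) == 3
        pairs = {frozenset({mv.state_a, mv.state_b}) for mv, _ in moves}
        assert pairs == ALL_PAIRS

    def test_restricted_pair_set(self, config):
        only_gf = ExchangeRules(
            allowed_pairs=frozenset({frozenset({LandState.G, LandState.F})})
        )
        moves = enumerate_moves(land("GFA"), config, only_gf)
        assert len(moves) == 1

    def test_intra_property_blocks_cross_owner(self, config):
        owners = np.array([[1, 2]])
        landscape = land("GA", owners=owners)
        rules = ExchangeRules(mode="intra_property")
        assert enumerate_moves(landscape, config, rules) == []

    def test_excluded_cells_never_move(self, config):
        moves = enumerate_moves(land("GXA"), config, RULES)
        assert len(moves) == 1
        mv, _ = moves[0]
        assert (0, 1) not in (mv.parcel_a, mv.parcel_b)

    def test_used_parcels_pruned(self, config):
        moves = enumerate_moves(land("GA", "AG"), config, RULES, used_parcels={(0, 0)})
        assert all((0, 0) not in mv.parcels for mv, _ in moves)

    @pytest.mark.parametrize("seed", range(10))
    def test_incremental_delta_matches_full_recompute(self, seed, config):
        rng = np.random.default_rng(seed)
        states = rng.integers(0, 4, size=(6, 6)).astype(np.int8)
        landscape = Landscape(states=states)
        b0 = mosaic_richness(landscape, config)
        for mv, delta in enumerate_moves(landscape, config, RULES):
            full = mosaic_richness(apply_exchange(landscape, mv), config) - b0
            assert delta == pytest.approx(full, rel=1e-9, abs=1e-9)


class TestBestMoves:
    def test_local_optimum_has_no_moves(self, config):
        assert best_moves(land("GGFFAA"), config, RULES) == []

    def test_symmetric_tie_on_alternating_strip(self, config):
        landscape = land("GAGA")
        tied = best_moves(landscape, config, RULES)
        assert len(tied) == 2
        ends = {apply_exchange(landscape, mv).grid_key() for mv in tied}
        assert ends == {land("GGAA").grid_key(), land("AAGG").grid_key()}
        # brute-force check that these really are the argmax moves
        b0 = oracle_richness(landscape, config)
        gains = {}
        for mv, _ in enumerate_moves(landscape, config, RULES):
            nxt = apply_exchange(landscape, mv)
            gains[mv] = oracle_richness(nxt, config) - b0
        best = max(gains.values())
        expected = {mv for mv, g in gains.items() if g >= best - 1e-9 * best}
        assert set(tied) == expected

    def test_unique_best_move(self, config):
        # asymmetric strip: joining the two G's next to each other wins alone
        landscape = land("GAG", "FFA")
        tied = best_moves(landscape, config, RULES)
        b0 = oracle_richness(landscape, config)
        gains = []
        for mv, _ in enumerate_moves(landscape, config, RULES):
            gains.append(oracle_richness(apply_exchange(landscape, mv), config) - b0)
        assert len(tied) == sum(1 for g in gains if g >= max(gains) - 1e-9 * max(gains))


class TestSearchAllPaths:
    def test_alternating_strip_two_branches(self, config):
        result = search_all_paths(land("GAGA"), config, RULES)
        assert result.n_paths == 2
        assert all(p.length == 1 for p in result.paths)
        assert len(result.distinct_ends) == 2
        from mosaicopt import is_global_optimum

        assert all(is_global_optimum(end) for end in result.distinct_ends)

    def test_already_optimal_yields_empty_path(self, config):
        result = search_all_paths(land("GGFFAA"), config, RULES)
        assert result.n_paths == 1
        assert result.paths[0].length == 0
        assert result.paths[0].terminal_flag

    @pytest.mark.parametrize("seed", range(6))
    def test_path_set_matches_bruteforce_oracle(self, seed, config):
        rng = np.random.default_rng(seed)
        states = rng.permutation(
            np.array([0, 0, 1, 1, 2, 2, 2, 2, 2], dtype=np.int8)
        ).reshape(3, 3)
        landscape = Landscape(states=states)
        result = search_all_paths(landscape, config, RULES)
        expected = oracle_search_all(landscape, config)
        got = sorted(tuple((mv.parcel_a, mv.parcel_b) for mv in p.moves) for p in result.paths)
        assert got == sorted(tuple(p) for p in expected)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_strict_ascent_conservation_termination(self, seed, config):
        rng = np.random.default_rng(seed)
        states = rng.permutation(np.repeat(np.arange(3, dtype=np.int8), 5)).reshape(3, 5)
        landscape = Landscape(states=states)
        counts0 = landscape.state_counts()
        result = search_all_paths(landscape, config, RULES)
        for p in result.paths:
            assert all(b1 > b0 for b0, b1 in zip(p.trajectory, p.trajectory[1:]))
            for step_land in p.landscapes:
                assert step_land.state_counts() == counts0
            # terminal really admits no improving pruned move
            used = {c for mv in p.moves for c in mv.parcels}
            assert best_moves(p.terminal, config, RULES, used_parcels=used) == []

    def test_node_budget_hard_fail(self, config):
        landscape = land("GAGAGA", "AGAGAG")
        with pytest.raises(PathExplosionError):
            search_all_paths(landscape, config, RULES, SearchLimits(node_budget=3))

    def test_node_budget_truncate_flags(self, config):
        landscape = land("GAGAGA", "AGAGAG")
        result = search_all_paths(
            landscape, config, RULES, SearchLimits(node_budget=3, on_budget="truncate")
        )
        assert result.stats["cap_hit"]

    def test_post_filter_drops_reused_parcels(self, config):
        rules = ExchangeRules(once_per_parcel="post_filter")
        rng = np.random.default_rng(12)
        states = rng.permutation(np.repeat(np.arange(3, dtype=np.int8), 12)).reshape(6, 6)
        result = search_all_paths(Landscape(states=states), config, rules)
        assert all(not p.reuses_parcel() for p in result.paths)

    def test_distinct_ends_deduplicated(self, config):
        result = search_all_paths(land("GAGA"), config, RULES)
        keys = [e.grid_key() for e in result.distinct_ends]
        assert len(keys) == len(set(keys))


class TestSearchSingle:
    def test_locally_optimal_input(self, config):
        path = search_single(land("GGFFAA"), config, RULES)
        assert path.length == 0 and path.terminal_flag

    def test_seeded_determinism(self, config):
        landscape = land("GAGA", "FAFG")
        p1 = search_single(landscape, config, RULES, tie_breaker="seeded_random", seed=5)
        p2 = search_single(landscape, config, RULES, tie_breaker="seeded_random", seed=5)
        assert p1.moves == p2.moves

    def test_lexicographic_is_first_branch_of_all_paths(self, config):
        landscape = land("GAGA", "AFGF")
        single = search_single(landscape, config, RULES)
        allp = search_all_paths(landscape, config, RULES)
        assert single.moves == allp.paths[0].moves

    def test_trajectory_strictly_increasing(self, config):
        rng = np.random.default_rng(2)
        states = rng.permutation(np.repeat(np.arange(3, dtype=np.int8), 12)).reshape(6, 6)
        path = search_single(Landscape(states=states), config, RULES)
        assert all(b1 > b0 for b0, b1 in zip(path.trajectory, path.trajectory[1:]))


class TestCraRun:
    @pytest.fixture
    def demo(self):
        from mosaicopt import load_fixture

        return load_fixture("demo_two_owner")

    def _rules(self):
        return ExchangeRules(mode="inter_property", owner_pair=(1, 2))

    def test_requires_owner_pair(self, demo, config):
        with pytest.raises(ConfigError):
            cra_run(demo, config, ExchangeRules(), n_parcels=10)

    def test_stops_within_budget(self, demo, config):
        res = cra_run(demo, config, self._rules(), n_parcels=10)
        assert res.path.length <= 10

    def test_single_parcel_budget(self, demo, config):
        res = cra_run(demo, config, self._rules(), n_parcels=1)
        assert res.path.length <= 1

    def test_only_cross_owner_moves(self, demo, config):
        res = cra_run(demo, config, self._rules(), n_parcels=10)
        owners = demo.owners
        for mv in res.path.moves:
            assert {int(owners[mv.parcel_a]), int(owners[mv.parcel_b])} == {1, 2}

    def test_no_cross_pairs_yields_empty_path(self, config):
        owners = np.array([[1, 1], [2, 2]])
        landscape = land("GA", "GA", owners=owners)
        # owners 1 and 3 share no parcels -> no legal moves
        rules = ExchangeRules(mode="inter_property", owner_pair=(1, 3))
        res = cra_run(landscape, config, rules, n_parcels=5)
        assert res.path.length == 0

    def test_net_transfer_balances(self, demo, config):
        res = cra_run(demo, config, self._rules(), n_parcels=10)
        for state in (LandState.G, LandState.F, LandState.AG):
            total = sum(d[state] for d in res.net_transfer.values())
            assert total == 0
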