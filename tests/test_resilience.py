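from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_snapshots
from cyclenet import (
    GeneratorConfig,
    PlantedCycle,
    SnapshotSequence,
    attack_frame,
    generate,
    rank_association,
    remove_nodes,
    run_attack,
    snapshots_to_events,
    temporal_distances,
    temporal_efficiency,
    trr_and_ltcc,
    window_sensitivity,
)


def complete_window(n):
    return frozenset(combinations(range(n), 2))


class TestTemporalDistances:
    def test_complete_single_window_all_ones(self):
        seq = SnapshotSequence(nodes=tuple(range(4)), edges=(complete_window(4),))
        D = temporal_distances(seq, 1)
        assert (D.to_numpy() == 1).all()

    def test_edgeless_all_unreachable(self):
        seq = SnapshotSequence(nodes=(0, 1, 2), edges=(frozenset(),) * 2)
        D = temporal_distances(seq, 1).to_numpy()
        off = ~np.eye(3, dtype=bool)
        assert np.isinf(D[off]).all()
        assert (np.diag(D) == 1).all()

    def test_toy_node5_reaches_node1_in_first_window(self, toy):
        D = temporal_distances(toy, 1)
        assert D.loc[5, 1] == 1  # multi-hop within window: 5-4-3-1

    def test_matches_time_expanded_oracle(self, rng):
        for _ in range(20):
            seq = random_snapshots(rng, n_max=8, t_max=4)
            D = temporal_distances(seq, 1)
            expected = oracles.brute_earliest_arrival(seq, 1)
            for i in seq.nodes:
                for j in seq.nodes:
                    assert D.loc[i, j] == expected[(i, j)]

    def test_later_start_window(self, toy):
        D = temporal_distances(toy, 3)
        assert D.loc[1, 1] == 3
        assert D.loc[5, 1] == 3  # edge (1,5) in the final window
        assert np.isinf(D.loc[5, 2])  # {2,3,4} unreachable from {1,5}


class TestEfficiencyTrrLtcc:
    def test_complete_static_graph_has_unit_efficiency(self):
        seq = SnapshotSequence(nodes=tuple(range(5)),
                               edges=(complete_window(5),) * 3)
        assert temporal_efficiency(seq) == 1.0
        assert temporal_efficiency(seq, "averaged") == 1.0

    def test_edgeless_network_zero(self):
        seq = SnapshotSequence(nodes=(0, 1, 2), edges=(frozenset(),) * 2)
        assert temporal_efficiency(seq) == 0.0
        trr, ltcc = trr_and_ltcc(seq)
        assert trr == 0.0 and ltcc == 1

    def test_single_node_rejected(self):
        seq = SnapshotSequence(nodes=(0,), edges=(frozenset(),))
        with pytest.raises(ValueError):
            temporal_efficiency(seq)

    def test_toy_efficiency_matches_oracle(self, toy):
        assert temporal_efficiency(toy) == pytest.approx(
            oracles.brute_efficiency(toy, 1)
        )

    def test_static_connected_graph_fully_reachable(self):
        path = frozenset({(0, 1), (1, 2), (2, 3)})
        seq = SnapshotSequence(nodes=tuple(range(4)), edges=(path,) * 3)
        trr, ltcc = trr_and_ltcc(seq)
        assert trr == 1.0 and ltcc == 4

    def test_trr_ltcc_match_oracle(self, rng):
        for _ in range(15):
            seq = random_snapshots(rng, n_max=8, t_max=4, p=0.15)
            assert trr_and_ltcc(seq) == pytest.approx(oracles.brute_trr_ltcc(seq))

    def test_monotone_under_edge_addition(self, rng):
        for _ in range(20):
            seq = random_snapshots(rng, n_max=8, t_max=4, p=0.12)
            e0 = temporal_efficiency(seq)
            trr0, ltcc0 = trr_and_ltcc(seq)
            t = int(rng.integers(seq.n_windows))
            free = [
                (i, j)
                for i in range(seq.n_nodes)
                for j in range(i + 1, seq.n_nodes)
                if (i, j) not in seq.edges[t]
            ]
            if not free:
                continue
            extra = free[int(rng.integers(len(free)))]
            windows = list(seq.edges)
            windows[t] = seq.edges[t] | {extra}
            aug = seq.replace_edges(windows)
            assert temporal_efficiency(aug) >= e0 - 1e-12
            trr1, ltcc1 = trr_and_ltcc(aug)
            assert trr1 >= trr0 and ltcc1 >= ltcc0


class TestRemoveNodes:
    def test_empty_removal_is_identity(self, toy):
        assert remove_nodes(toy, []).edges == toy.edges

    def test_full_removal_empties_every_window(self, toy):
        gone = remove_nodes(toy, toy.nodes)
        assert all(e == frozenset() for e in gone.edges)
        assert gone.nodes == toy.nodes  # V unchanged

    def test_toy_remove_node3(self, toy):
        cut = remove_nodes(toy, [3])
        assert cut.window(2) == frozenset({(1, 2), (2, 4), (2, 5)})

    def test_unknown_node_rejected(self, toy):
        with pytest.raises(KeyError):
            remove_nodes(toy, [42])


class TestRunAttack:
    @pytest.fixture
    def seq(self, rng):
        return random_snapshots(rng, n_max=10, t_max=4, p=0.3)

    def scores_for(self, seq):
        return pd.Series({v: float(v) for v in seq.nodes})

    def test_zero_node_budget_has_zero_impact(self, seq):
        r = run_attack(seq, self.scores_for(seq), "targeted",
                       budgets=[0.01], seeds=[0])[0]
        assert len(r.removed) == 0
        assert r.delta_e == r.delta_trr == r.delta_ltcc == 0.0

    def test_full_budget_destroys_everything(self, seq):
        r = run_attack(seq, self.scores_for(seq), "targeted",
                       budgets=[1.0], seeds=[0])[0]
        assert r.delta_e == pytest.approx(1.0)
        assert r.e_disrupted == 0.0

    def test_random_runs_are_bitwise_reproducible(self, seq):
        a = run_attack(seq, None, "random", budgets=[0.3], seeds=[5, 6])
        b = run_attack(seq, None, "random", budgets=[0.3], seeds=[5, 6])
        assert [r.removed for r in a] == [r.removed for r in b]
        assert [r.delta_e for r in a] == [r.delta_e for r in b]

    def test_targeted_removal_nested_and_monotone_in_budget(self, seq):
        rs = run_attack(seq, self.scores_for(seq), "targeted",
                        budgets=[0.2, 0.5, 0.8], seeds=[0])
        for small, big in zip(rs, rs[1:]):
            assert set(small.removed) <= set(big.removed)
            assert big.delta_e >= small.delta_e - 1e-12

    def test_hybrid_splits_budget(self, seq):
        r = run_attack(seq, self.scores_for(seq), "hybrid",
                       budgets=[0.5], seeds=[1])[0]
        k = len(r.removed)
        targeted_part = r.removed[: (k + 1) // 2]
        order = sorted(seq.nodes, key=lambda v: -float(v))
        assert list(targeted_part) == order[: (k + 1) // 2]

    def test_zero_initial_efficiency_reported_as_error(self):
        seq = SnapshotSequence(nodes=(0, 1, 2), edges=(frozenset(),))
        r = run_attack(seq, pd.Series({0: 1.0, 1: 0.5, 2: 0.0}),
                       "targeted", budgets=[0.5], seeds=[0])[0]
        assert r.error is not None and np.isnan(r.delta_e)

    def test_attack_frame_shape(self, seq):
        rs = run_attack(seq, None, "random", budgets=[0.2], seeds=[0, 1, 2])
        df = attack_frame(rs)
        assert list(df.columns) == ["strategy", "budget", "seed", "dE", "dTRR", "dLTCC"]
        assert len(df) == 3


class TestRankAssociation:
    def test_monotone_transform_gives_one(self):
        rho, kt = rank_association([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0 and kt == 1.0

    def test_reversed_ranking_gives_minus_one(self):
        rho, _ = rank_association([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == -1.0

    def test_single_adjacent_swap_on_five_items(self):
        rho, _ = rank_association([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert rho == pytest.approx(0.9)

    def test_constant_vector_is_undefined(self):
        rho, kt = rank_association([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(kt)


class TestWindowSensitivity:
    @pytest.fixture
    def stationary_events(self):
        planted = (PlantedCycle((0, 1, 2), 1.0), PlantedCycle((2, 3, 4), 1.0))
        seq, _ = generate(
            GeneratorConfig(n_nodes=8, n_windows=16, planted=planted,
                            noise_q=0.05),
            seed=11,
        )
        return snapshots_to_events(seq)

    def test_multiplier_one_is_exactly_self_consistent(self, stationary_events):
        out = window_sensitivity(stationary_events, delta_t0=1.0,
                                 multipliers=(1.0,), metric="tcn", max_len=3)
        assert out.loc[0, "rho"] == 1.0

    def test_stationary_structure_stays_stable(self, stationary_events):
        out = window_sensitivity(stationary_events, delta_t0=1.0,
                                 multipliers=(0.5, 1.0, 2.0), metric="tcn",
                                 max_len=3)
        # the persistent backbone dominates the ranking at every scale
        assert (out["rho"] > 0.7).all()

    def test_degenerate_horizon_rejected(self):
        events = pd.DataFrame({"source": [0], "target": [1], "time": [0.5]})
        with pytest.raises(ValueError, match="windows"):
            window_sensitivity(events, delta_t0=10.0, multipliers=(1.0,))
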