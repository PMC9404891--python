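"""Association index, centrality, David's Score and kinship counts."""

import numpy as np
import pytest

from troopcall.social import (
    AgonisticBout,
    DAIMatrix,
    ProximityRecord,
    SocialMetricsError,
    UnknownIndividualError,
    compute_dai,
    count_relatives,
    dai_value,
    davids_score,
    eigenvector_centrality,
)
from troopcall.synthetic import TroopConfig, make_roster, simulate_agonistic


def prox(focal, partner, overlap, session, length=100.0):
    return ProximityRecord(focal, partner, overlap, session, length)


class TestDAI:
    def test_formula_value(self):
        assert dai_value(10, 100, 100) == pytest.approx(10 / 190)

    def test_formula_upper_bound(self):
        assert dai_value(50, 50, 50) == 1.0

    def test_zero_denominator_maps_to_zero(self):
        assert dai_value(0, 0, 0) == 0.0

    def test_pair_without_records_scores_zero(self):
        records = [prox("a", "b", 10, "a-1")]
        m = compute_dai(records, ["a", "b", "c"])
        frame = m.to_frame()
        assert frame.loc["a", "c"] == 0.0 and frame.loc["b", "c"] == 0.0

    def test_two_individuals_always_within_one_meter(self):
        records = [
            prox("a", "b", 100, "a-1"),
            prox("b", "a", 100, "b-1"),
        ]
        m = compute_dai(records, ["a", "b"])
        assert m.to_frame().loc["a", "b"] == pytest.approx(1.0)

    def test_balanced_records_match_hand_formula(self):
        # D_ab = (10+10)/2 = 10 from the two focal perspectives,
        # D_a = D_b = 100 -> 10/190
        records = [prox("a", "b", 10, "a-1"), prox("b", "a", 10, "b-1")]
        m = compute_dai(records, ["a", "b"])
        assert m.to_frame().loc["a", "b"] == pytest.approx(10 / 190)

    def test_record_order_and_session_split_invariance(self):
        base = [
            prox("a", "b", 30, "a-1"),
            prox("b", "a", 20, "b-1"),
            prox("a", "c", 50, "a-1"),
        ]
        split = [
            prox("a", "c", 50, "a-1"),
            prox("a", "b", 12, "a-1"),
            prox("a", "b", 18, "a-1"),  # same session, same total
            prox("b", "a", 20, "b-1"),
        ]
        ids = ["a", "b", "c"]
        assert np.allclose(compute_dai(base, ids).values, compute_dai(split, ids).values)
        assert np.allclose(
            compute_dai(base, ids).values, compute_dai(base[::-1], ids).values
        )

    def test_unknown_id_is_named_in_error(self):
        with pytest.raises(UnknownIndividualError, match="zz"):
            compute_dai([prox("a", "zz", 1, "a-1")], ["a", "b"])

    def test_negative_duration_rejected(self):
        with pytest.raises(SocialMetricsError):
            prox("a", "b", -1, "a-1")

    def test_matrix_invariants(self, dai_matrix):
        v = dai_matrix.values
        assert np.allclose(v, v.T)
        assert np.all(np.diag(v) == 0)
        assert v.min() >= 0 and v.max() <= 1
        # troop-level association is present at the defaults
        assert v[np.triu_indices(v.shape[0], 1)].mean() > 0


class TestEigenvectorCentrality:
    def test_complete_graph_is_uniform(self):
        n = 5
        v = np.ones((n, n)) - np.eye(n)
        res = eigenvector_centrality(DAIMatrix(tuple("abcde"), v * 0.5))
        assert np.allclose(res.scores, 1 / np.sqrt(n), atol=1e-10)

    def test_star_graph_center_leaf_ratio_sqrt3(self):
        v = np.zeros((4, 4))
        v[0, 1:] = v[1:, 0] = 1.0
        res = eigenvector_centrality(DAIMatrix(("c", "l1", "l2", "l3"), v))
        assert res.scores[0] / res.scores[1] == pytest.approx(np.sqrt(3), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((27, 27))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        m = DAIMatrix(tuple(f"i{k}" for k in range(27)), a)
        res = eigenvector_centrality(m)
        w, vecs = np.linalg.eigh(a)
        lead = np.abs(vecs[:, np.argmax(w)])
        assert np.max(np.abs(res.scores - lead)) < 1e-8
        # eigen-residual contract
        assert np.max(np.abs(a @ res.scores - res.eigenvalue * res.scores)) < 1e-10

    def test_matches_networkx_on_association_matrix(self, dai_matrix):
        nx = pytest.importorskip("networkx")
        g = nx.from_numpy_array(dai_matrix.values)
        expected = nx.eigenvector_centrality_numpy(g, weight="weight")
        ours = eigenvector_centrality(dai_matrix).scores
        vec = np.array([expected[k] for k in range(len(ours))])
        vec = np.abs(vec) / np.linalg.norm(vec)
        assert np.allclose(ours, vec, atol=1e-6)

    def test_isolated_individual_scores_zero(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.7
        res = eigenvector_centrality(DAIMatrix(("a", "b", "c"), v))
        assert res.scores[2] == 0.0
        assert res.scores[0] == pytest.approx(res.scores[1])

    def test_all_zero_matrix_raises(self):
        with pytest.raises(SocialMetricsError):
            eigenvector_centrality(DAIMatrix(("a", "b"), np.zeros((2, 2))))

    def test_nonconvergence_reports_diagnostics(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        m = DAIMatrix(tuple(f"i{k}" for k in range(6)), a)
        with pytest.raises(SocialMetricsError, match="iterations"):
            eigenvector_centrality(m, tol=1e-15, max_iter=2)


class TestDavidsScore:
    def test_one_sided_dyad_hand_value(self):
        # A wins every bout: P_AB = 1 -> w=(1,0), w2=(0,0), l=(0,1), l2=(0,0)
        bouts = [AgonisticBout("a", "b")] * 5
        res = davids_score(bouts, ["a", "b"])
        assert res.ds == pytest.approx([1.0, -1.0])
        assert list(res.rank) == [1, 2]

    def test_balanced_round_robin_is_flat(self):
        ids = ["a", "b", "c"]
        bouts = []
        for i in ids:
            for j in ids:
                if i != j:
                    bouts.append(AgonisticBout(i, j))
        res = davids_score(bouts, ids)
        assert np.allclose(res.ds, 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_pij_scores_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"i{k}" for k in range(8)]
        bouts = [
            AgonisticBout(*rng.choice(ids, size=2, replace=False))
            for _ in range(60)
        ]
        res = davids_score(bouts, ids)
        assert abs(res.ds.sum()) < 1e-9

    def test_dij_shrinks_toward_chance(self):
        bouts = [AgonisticBout("a", "b")] * 3
        pij = davids_score(bouts, ["a", "b"], correction="pij")
        dij = davids_score(bouts, ["a", "b"], correction="dij")
        assert abs(dij.ds[0]) < abs(pij.ds[0])
        assert abs(dij.ds.sum()) < 1e-9

    def test_steeper_generators_spread_scores(self):
        spreads = []
        for steep in (0.0, 1.0, 4.0):
            config = TroopConfig(seed=7, dominance_steepness=steep)
            roster = make_roster(config)
            res = davids_score(simulate_agonistic(roster, config), roster)
            spreads.append(res.ds.std())
        assert spreads[0] < spreads[1] < spreads[2]

    def test_deterministic_ladder_orders_by_strength(self):
        config = TroopConfig(seed=3, dominance_steepness=60.0)
        roster = make_roster(config)
        res = davids_score(simulate_agonistic(roster, config), roster)
        strength = {i.id: i.latent_strength for i in roster}
        order = np.argsort(-res.ds)
        strengths = [strength[res.individuals[k]] for k in order]
        assert all(a > b for a, b in zip(strengths, strengths[1:]))

    def test_unknown_id_rejected(self):
        with pytest.raises(UnknownIndividualError):
            davids_score([AgonisticBout("a", "zz")], ["a", "b"])

    def test_tied_scores_rank_by_roster_order(self):
        res = davids_score([], ["b", "a"])
        assert list(res.rank) == [1, 2]  # all DS equal -> roster order


class TestRelatives:
    def test_matriline_size_minus_one(self, roster):
        counts = count_relatives(roster)
        sizes = {}
        for ind in roster:
            if ind.matriline:
                sizes[ind.matriline] = sizes.get(ind.matriline, 0) + 1
        for ind in roster:
            expected = sizes[ind.matriline] - 1 if ind.matriline else 0
            assert counts[ind.id] == expected
        assert 0 in counts.values()  # migrants exist at the defaults

    def test_single_matriline_means_everyone_related(self):
        config = TroopConfig(seed=2, n_matrilines=1, matriline_coverage=1.0)
        roster = make_roster(config)
        counts = count_relatives(roster)
        assert all(c == len(roster) - 1 for c in counts.values())

    def test_roster_relative_field_agrees(self, roster):
        counts = count_relatives(roster)
        for ind in roster:
            assert ind.n_relatives == counts[ind.id]
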