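import numpy as np
import pytest

from sdconnectome.io import Connectome
from sdconnectome.richclub import (
    ABSENT,
    FEEDER,
    LOCAL,
    RICH,
    RichClubUndefinedError,
    backbone_network,
    classify_edges,
    connection_strengths,
    identify_hubs,
    normalized_rich_club,
    rich_club_result,
    sign_test_presence_p,
    weighted_rich_club_coefficient,
)
from conftest import random_connectome


def phi_oracle(w: np.ndarray, hub_set) -> float:
    """Exhaustive sort-based weighted rich-club coefficient."""
    n = w.shape[0]
    hubs = set(int(h) for h in hub_set)
    all_w, hub_w = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                all_w.append(w[i, j])
                if i in hubs and j in hubs:
                    hub_w.append(w[i, j])
    if not hub_w:
        raise RichClubUndefinedError
    top = sorted(all_w, reverse=True)[: len(hub_w)]
    return sum(hub_w) / sum(top)


def make_group(rng, n_subjects, n, present_prob):
    """Subjects whose edges appear i.i.d. with per-pair probabilities."""
    subs = []
    for _ in range(n_subjects):
        mask = rng.random((n, n)) < present_prob
        w = np.triu(mask, 1) * rng.integers(1, 20, (n, n))
        w = w + w.T
        subs.append(Connectome(w.astype(float)))
    return subs


class TestSignTestBackbone:
    def test_closed_form_p_values(self):
        # edge in all 10 subjects: p = 0.5^10; in 2: p = 0.25; in 0: p = 1
        np.testing.assert_allclose(
            sign_test_presence_p(np.array([10, 2, 0])), [0.5**10, 0.25, 1.0]
        )

    def test_always_present_edge_retained(self, rng):
        n = 6
        w = np.zeros((n, n))
        w[0, 1] = w[1, 0] = 5
        subs = [Connectome(w) for _ in range(10)]
        bb = backbone_network(subs, alpha=0.05)
        assert bb.adjacency[0, 1] == 1
        assert bb.adjacency.sum() == 2

    def test_rare_edge_rejected(self, rng):
        n = 4
        subs = []
        for k in range(10):
            w = np.zeros((n, n))
            if k < 2:
                w[0, 1] = w[1, 0] = 3
            w[2, 3] = w[3, 2] = 4  # anchor edge present in all
            subs.append(Connectome(w))
        bb = backbone_network(subs, alpha=0.05)
        assert bb.adjacency[0, 1] == 0
        assert bb.adjacency[2, 3] == 1

    def test_monotone_in_alpha(self, rng):
        subs = make_group(rng, 12, 10, rng.uniform(0.2, 1.0, (10, 10)))
        a1 = backbone_network(subs, alpha=0.01).adjacency
        a2 = backbone_network(subs, alpha=0.10).adjacency
        assert np.all(a2[a1 == 1] == 1)

    def test_group_size_validated(self, rng):
        with pytest.raises(ValueError):
            backbone_network([])
        with pytest.raises(ValueError):
            backbone_network([random_connectome(rng, 4)])


class TestHubs:
    def test_star_center_is_only_hub(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = 1
        adj += adj.T
        np.testing.assert_array_equal(identify_hubs(adj), [0])

    def test_regular_graph_degenerate_warns_all_hubs(self):
        adj = np.ones((4, 4)) - np.eye(4)
        with pytest.warns(UserWarning, match="degenerate"):
            hubs = identify_hubs(adj)
        assert hubs.size == 4

    def test_empty_graph_no_hubs(self):
        assert identify_hubs(np.zeros((5, 5))).size == 0


class TestEdgeClassification:
    def test_definition_applied(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[0, 2] = w[2, 3] = 1
        w += w.T
        cls = classify_edges(Connectome(w), np.array([0, 1]))
        assert cls[0, 1] == RICH and cls[0, 2] == FEEDER and cls[2, 3] == LOCAL
        assert cls[1, 3] == ABSENT

    def test_empty_and_full_hub_sets(self, rng):
        conn = random_connectome(rng, 6, density=0.6)
        present = np.triu(conn.weights, 1) > 0
        cls_none = classify_edges(conn, np.array([], dtype=int))
        assert np.all(np.triu(cls_none, 1)[present] == LOCAL)
        cls_all = classify_edges(conn, np.arange(6))
        assert np.all(np.triu(cls_all, 1)[present] == RICH)

    def test_out_of_range_hub_rejected(self, rng):
        with pytest.raises(IndexError):
            classify_edges(random_connectome(rng, 4), np.array([9]))


class TestStrengths:
    def test_hand_example(self):
        w = np.zeros((4, 4))
        w[0, 1], w[0, 2], w[2, 3] = 5, 2, 1
        w += w.T
        conn = Connectome(w)
        cls = classify_edges(conn, np.array([0, 1]))
        s_rich, s_feeder, s_local, r_rf, r_rl = connection_strengths(conn, cls)
        assert (s_rich, s_feeder, s_local) == (5, 2, 1)
        assert r_rf == pytest.approx(2.5)
        assert r_rl == pytest.approx(5.0)

    def test_missing_class_flagged_nan(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 4
        conn = Connectome(w)
        cls = classify_edges(conn, np.array([0, 1]))
        *_, r_rf, r_rl = connection_strengths(conn, cls)
        assert np.isnan(r_rf) and np.isnan(r_rl)

    def test_class_strengths_conserve_total_weight(self, rng):
        for _ in range(10):
            conn = random_connectome(rng, 10, density=0.5)
            hubs = rng.choice(10, size=3, replace=False)
            cls = classify_edges(conn, hubs)
            s = connection_strengths(conn, cls)
            assert sum(s[:3]) == pytest.approx(conn.weights.sum() / 2)


class TestPhi:
    def test_hub_edges_strongest_gives_one(self):
        w = np.zeros((4, 4))
        w[0, 1] = 10  # hub-hub, also the single strongest edge
        w[2, 3] = 2
        w += w.T
        assert weighted_rich_club_coefficient(Connectome(w), [0, 1]) == 1.0

    def test_hand_example(self):
        # hubs {0,1,2} with hub-hub weights {4,4}; strongest two weights {10,4}
        w = np.zeros((4, 4))
        w[0, 1], w[1, 2], w[0, 3] = 4, 4, 10
        w += w.T
        phi = weighted_rich_club_coefficient(Connectome(w), [0, 1, 2])
        assert phi == pytest.approx(8 / 14)

    def test_no_hub_edges_undefined(self):
        w = np.zeros((4, 4))
        w[2, 3] = w[3, 2] = 1
        with pytest.raises(RichClubUndefinedError):
            weighted_rich_club_coefficient(Connectome(w), [0, 1])

    def test_matches_sort_oracle_and_scale_invariance(self, rng):
        for _ in range(20):
            conn = random_connectome(rng, 8, density=0.6)
            hubs = rng.choice(8, size=3, replace=False)
            try:
                expected = phi_oracle(conn.weights, hubs)
            except RichClubUndefinedError:
                with pytest.raises(RichClubUndefinedError):
                    weighted_rich_club_coefficient(conn, hubs)
                continue
            phi = weighted_rich_club_coefficient(conn, hubs)
            assert phi == pytest.approx(expected)
            assert 0 < phi <= 1
            scaled = Connectome(conn.weights * 7.5)
            assert weighted_rich_club_coefficient(scaled, hubs) == pytest.approx(phi)

    def test_hub_set_enlargement_matches_oracle(self, rng):
        conn = random_connectome(rng, 8, density=0.8)
        order = np.argsort(-(conn.weights > 0).sum(axis=1))
        for k in range(2, 6):
            hubs = order[:k]
            assert weighted_rich_club_coefficient(conn, hubs) == pytest.approx(
                phi_oracle(conn.weights, hubs)
            )


class TestNormalizedPhi:
    def test_self_ensemble_gives_one(self, rng):
        conn = random_connectome(rng, 8, density=0.7)
        pn, n_def = normalized_rich_club(conn, np.array([0, 1, 2]), [conn, conn])
        assert pn == pytest.approx(1.0)
        assert n_def == 2

    def test_weight_shuffled_network_is_unorganized(self, rng):
        # Erdos-Renyi-like topology with i.i.d. weights has no weighted rich
        # club: phi_norm should sit near 1 within ensemble error
        from sdconnectome.nulls import matched_ensemble

        conn = random_connectome(rng, 30, density=0.3, max_weight=100)
        hubs = np.argsort(-(conn.weights > 0).sum(axis=1))[:5]
        ens = matched_ensemble(conn, n=100, seed=2)
        phis = []
        for g in ens:
            try:
                phis.append(weighted_rich_club_coefficient(g, hubs))
            except RichClubUndefinedError:
                pass
        pn, _ = normalized_rich_club(conn, hubs, ens)
        # the source network is itself one draw from the unorganized family,
        # so its phi deviates from the null mean on the ensemble-sd scale
        assert abs(pn - 1) < 2 * np.std(phis) / np.mean(phis)

    def test_all_members_undefined_rejected(self, rng):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 3
        w[2, 3] = w[3, 2] = 9
        conn = Connectome(w)
        null = Connectome(np.zeros((4, 4)))
        with pytest.raises(RichClubUndefinedError):
            normalized_rich_club(conn, [0, 1], [null])


def test_rich_club_result_assembles_consistently(rng):
    conn = random_connectome(rng, 10, density=0.6)
    hubs = np.array([0, 3, 7])
    res = rich_club_result(conn, hubs, ensemble=[conn])
    assert res.strength_rich + res.strength_feeder + res.strength_local == pytest.approx(
        conn.weights.sum() / 2
    )
    assert res.phi_norm == pytest.approx(1.0)
    assert res.n_rich_edges == int((np.triu(res.edge_class, 1) == RICH).sum())
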