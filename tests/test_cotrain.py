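"""Co-training tests: kNN primitives against brute-force oracles, the
delta-score, candidate selection, the full loop vs an independent two-player
reference, and pseudo-label imputation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cosoft import (
    BatchTensor,
    PlayerConfig,
    SampleSet,
    apply_label_sparsity,
    cotrain,
    default_minkowski_orders,
    delta_score,
    ensemble_predict,
    flatten,
    impute_labels,
    knn_predict,
    minkowski_distance,
    select_candidate,
)

from _oracles import brute_delta, brute_knn, coreg_reference


def make_sampleset(rng, n, d, labeled=True):
    feats = rng.normal(size=(n, d))
    labels = rng.normal(size=n) if labeled else np.full(n, np.nan)
    origins = np.column_stack([np.zeros(n, dtype=int), np.arange(n)])
    return SampleSet(feats, labels, origins)


class TestMinkowski:
    def test_identity_of_indiscernibles(self, rng):
        x = rng.normal(size=5)
        for p in (1, 2, 3.5, 7):
            assert minkowski_distance(x, x, p) == 0.0

    def test_pythagorean(self):
        assert minkowski_distance([0, 0], [3, 4], 2) == pytest.approx(5.0)

    def test_order_five(self):
        expected = (3**5 + 4**5) ** (1 / 5)
        assert minkowski_distance([0, 0], [3, 4], 5) == pytest.approx(expected, rel=1e-15)

    def test_validation(self):
        with pytest.raises(ValueError):
            minkowski_distance([1, 2], [1, 2, 3], 2)
        with pytest.raises(ValueError):
            minkowski_distance([1], [2], 0.5)

    @settings(deadline=None)
    @given(st.integers(0, 2**32 - 1), st.sampled_from([1.0, 2.0, 3.0, 5.0]))
    def test_symmetry_and_triangle(self, seed, p):
        r = np.random.default_rng(seed)
        a, b, c = r.normal(size=(3, 4))
        dab = minkowski_distance(a, b, p)
        assert dab == pytest.approx(minkowski_distance(b, a, p))
        assert dab <= minkowski_distance(a, c, p) + minkowski_distance(c, b, p) + 1e-12


class TestKnnPredict:
    def test_k1_is_nearest_label(self, rng):
        labeled = make_sampleset(rng, 10, 3)
        q = rng.normal(size=3)
        d = [minkowski_distance(q, f, 2) for f in labeled.features]
        assert knn_predict(labeled, q, 1, 2) == labeled.labels[int(np.argmin(d))]

    def test_k_equals_all_is_global_mean(self, rng):
        labeled = make_sampleset(rng, 6, 2)
        for q in rng.normal(size=(3, 2)):
            assert knn_predict(labeled, q, 6, 2) == pytest.approx(labeled.labels.mean())

    @pytest.mark.parametrize("p", [1, 2, 5])
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_brute_oracle(self, rng, p, k):
        labeled = make_sampleset(rng, 25, 4)
        for q in rng.normal(size=(10, 4)):
            expected = brute_knn(labeled.features, labeled.labels, q, k, p)
            assert knn_predict(labeled, q, k, p) == expected

    def test_k_too_large(self, rng):
        labeled = make_sampleset(rng, 4, 2)
        with pytest.raises(ValueError):
            knn_predict(labeled, np.zeros(2), 5, 2)


class TestDeltaScore:
    def test_distant_candidate_is_exact_zero(self):
        feats = np.array([[0.0], [0.1], [0.2], [0.3]])
        labels = np.array([1.0, 2.0, 3.0, 4.0])
        labeled = SampleSet(feats, labels,
                            np.column_stack([np.zeros(4, dtype=int), np.arange(4)]))
        # candidate so remote it never enters any neighbor list
        assert delta_score(labeled, (np.array([1e6]), 0.0), 2, 2) == 0.0

    def test_matches_hand_computation(self):
        # 4 labeled 1-D points at 0.0/0.4/1.0/1.5 with labels 0/1/3/1, k=2,
        # candidate at 0.9 with pseudo-label 2.0.  Its neighbors are
        # a = {x2=1.0 (d=0.1), x1=0.4 (d=0.5)}.  For x2: 2-NN before =
        # {x2, x3} -> mean 2; the candidate (d=0.1) displaces x3 (d=0.5),
        # after = (3+2)/2 = 2.5, term (3-2.5)^2-(3-2)^2 = -0.75.  For x1:
        # 2-NN before = {x1, x0} (k-th distance 0.4); candidate at d=0.5
        # does not enter, term 0.  Delta = -0.375.
        feats = np.array([[0.0], [0.4], [1.0], [1.5]])
        labels = np.array([0.0, 1.0, 3.0, 1.0])
        labeled = SampleSet(feats, labels,
                            np.column_stack([np.zeros(4, dtype=int), np.arange(4)]))
        expected = (-0.75 + 0.0) / 2
        assert delta_score(labeled, (np.array([0.9]), 2.0), 2, 2) == pytest.approx(
            expected, abs=1e-14
        )

    @pytest.mark.parametrize("p", [1, 2, 5])
    def test_matches_brute_rebuild(self, rng, p):
        labeled = make_sampleset(rng, 30, 3)
        for _ in range(5):
            cand = rng.normal(size=3)
            pseudo = knn_predict(labeled, cand, 4, p)
            got = delta_score(labeled, (cand, pseudo), 4, p)
            want = brute_delta(labeled.features, labeled.labels, cand, pseudo, 4, p)
            assert got == pytest.approx(want, abs=1e-12)


class TestSelectCandidate:
    def _ensemble(self, labeled, pool, config):
        return cotrain(labeled, pool, PlayerConfig(
            n_players=config.n_players,
            minkowski_orders=config.minkowski_orders,
            n_neighbors=config.n_neighbors,
            max_iterations=0,
        ))

    def test_empty_pool_returns_none(self, rng):
        labeled = make_sampleset(rng, 8, 2)
        pool = SampleSet(np.empty((0, 2)), np.empty(0), np.empty((0, 2), dtype=int))
        cfg = PlayerConfig(n_players=2, n_neighbors=3, max_iterations=5)
        ens = self._ensemble(labeled, pool, cfg)
        ens.fitted = True
        assert select_candidate(0, ens, cfg) is None

    def test_agrees_with_literal_delta_argmin(self, rng):
        labeled = make_sampleset(rng, 20, 3)
        pool = make_sampleset(rng, 15, 3, labeled=False)
        cfg = PlayerConfig(n_players=2, n_neighbors=4, max_iterations=5)
        ens = self._ensemble(labeled, pool, cfg)
        for j, p in enumerate(cfg.minkowski_orders):
            deltas = []
            for x in pool.features:
                pseudo = knn_predict(labeled, x, cfg.n_neighbors, p)
                deltas.append(delta_score(labeled, (x, pseudo), cfg.n_neighbors, p))
            deltas = np.array(deltas)
            pick = select_candidate(j, ens, cfg)
            if deltas.min() >= 0:
                assert pick is None
            else:
                idx, pseudo, delta = pick
                assert idx == int(np.argmin(deltas))
                assert delta == pytest.approx(deltas[idx], abs=1e-12)


class TestCotrainLoop:
    def _fixture(self, rng, n_l=12, n_u=15, d=2):
        labeled = make_sampleset(rng, n_l, d)
        pool_feats = rng.normal(size=(n_u, d))
        origins = np.column_stack([np.ones(n_u, dtype=int), np.arange(n_u)])
        pool = SampleSet(pool_feats, np.full(n_u, np.nan), origins)
        return labeled, pool

    def test_matches_two_player_reference(self, rng):
        labeled, pool = self._fixture(rng)
        cfg = PlayerConfig(n_players=2, minkowski_orders=[2.0, 5.0],
                           n_neighbors=3, max_iterations=6)
        ens = cotrain(labeled, pool, cfg)
        ref_log, ref_sets = coreg_reference(
            labeled.features, labeled.labels, labeled.origins,
            pool.features, pool.origins, k=3, orders=(2.0, 5.0), max_iterations=6,
        )
        assert len(ens.log) == len(ref_log) > 0
        for got, want in zip(ens.log, ref_log):
            assert got.iteration == want["iteration"]
            assert got.player == want["player"]
            assert got.origin == want["origin"]
            assert got.pseudo_label == want["pseudo_label"]
            assert got.delta == pytest.approx(want["delta"], abs=1e-12)
        for player, (ref_f, ref_l) in zip(ens.players, ref_sets):
            np.testing.assert_array_equal(player.features, ref_f)
            np.testing.assert_array_equal(player.labels, ref_l)

    def test_empty_pool_zero_iterations(self, rng):
        labeled = make_sampleset(rng, 8, 2)
        pool = SampleSet(np.empty((0, 2)), np.empty(0), np.empty((0, 2), dtype=int))
        ens = cotrain(labeled, pool, PlayerConfig(n_players=2, n_neighbors=3,
                                                  max_iterations=10))
        assert ens.n_iterations == 0 and ens.log == []
        for player in ens.players:
            assert len(player.labels) == len(labeled)

    def test_zero_max_iterations_is_initial_fit(self, rng):
        labeled, pool = self._fixture(rng)
        ens = cotrain(labeled, pool, PlayerConfig(n_players=3, n_neighbors=3,
                                                  max_iterations=0))
        assert ens.n_iterations == 0 and not ens.log
        assert ens.fitted

    def test_growth_and_conservation(self, rng):
        """Each acceptance leaves the pool once and enters n-1 labeled sets,
        never its selector's own set via its own pick."""
        labeled, pool = self._fixture(rng, n_l=15, n_u=20)
        cfg = PlayerConfig(n_players=3, n_neighbors=4, max_iterations=8)
        ens = cotrain(labeled, pool, cfg)
        n_acc = len(ens.log)
        assert len(ens.pool_origins) == len(pool) - n_acc
        total_added = sum(len(p.labels) - len(labeled) for p in ens.players)
        assert total_added == n_acc * (cfg.n_players - 1)
        for rec in ens.log:
            selector = ens.players[rec.player]
            own = {tuple(o) for o in selector.origins}
            others_selected = {
                r.origin for r in ens.log if r.player != rec.player
            }
            if rec.origin not in others_selected:
                assert rec.origin not in own
        for rec in ens.log:
            assert rec.delta < 0

    def test_terminates_within_budget(self, rng):
        labeled, pool = self._fixture(rng, n_l=10, n_u=6)
        big = PlayerConfig(n_players=2, n_neighbors=3, max_iterations=10_000)
        ens = cotrain(labeled, pool, big)
        assert ens.n_iterations < 10_000  # early exit: pool finite

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PlayerConfig(n_players=2, minkowski_orders=[2.0, 2.0])
        with pytest.raises(ValueError):
            PlayerConfig(n_players=2, minkowski_orders=[0.5, 2.0])
        with pytest.raises(ValueError):
            PlayerConfig(n_players=2, minkowski_orders=[1.0, 2.0, 3.0])

    def test_default_orders_sequence(self):
        assert default_minkowski_orders(2) == [2.0, 5.0]
        assert default_minkowski_orders(3) == [1.0, 2.0, 5.0]
        assert default_minkowski_orders(6) == [1.0, 2.0, 5.0, 3.0, 4.0, 6.0]


class TestEnsemblePredict:
    def test_mean_of_player_predictions(self, rng):
        labeled = make_sampleset(rng, 12, 3)
        pool = make_sampleset(rng, 5, 3, labeled=False)
        cfg = PlayerConfig(n_players=3, n_neighbors=3, max_iterations=2)
        ens = cotrain(labeled, pool, cfg)
        q = rng.normal(size=3)
        per_player = []
        for player, p in zip(ens.players, cfg.minkowski_orders):
            ss = SampleSet(player.features, player.labels,
                           np.column_stack([np.zeros(len(player.labels), dtype=int),
                                            np.arange(len(player.labels))]))
            per_player.append(knn_predict(ss, q, cfg.n_neighbors, p))
        assert ensemble_predict(ens, q) == pytest.approx(np.mean(per_player))

    def test_agreeing_players_return_value(self, rng):
        feats = rng.normal(size=(8, 2))
        labeled = SampleSet(feats, np.full(8, 2.5),
                            np.column_stack([np.zeros(8, dtype=int), np.arange(8)]))
        pool = SampleSet(np.empty((0, 2)), np.empty(0), np.empty((0, 2), dtype=int))
        ens = cotrain(labeled, pool, PlayerConfig(n_players=2, n_neighbors=3,
                                                  max_iterations=0))
        assert ensemble_predict(ens, rng.normal(size=2)) == pytest.approx(2.5)

    def test_unfitted_raises(self, rng):
        labeled = make_sampleset(rng, 8, 2)
        pool = make_sampleset(rng, 3, 2, labeled=False)
        ens = cotrain(labeled, pool, PlayerConfig(n_players=2, n_neighbors=3,
                                                  max_iterations=0))
        ens.fitted = False
        with pytest.raises(RuntimeError):
            ensemble_predict(ens, np.zeros(2))


class TestImputeLabels:
    def _cotrained(self, data, k=4):
        samples = flatten(data)
        ens = cotrain(samples.labeled_subset(), samples.unlabeled_subset(),
                      PlayerConfig(n_players=2, n_neighbors=k, max_iterations=5))
        return ens

    def test_full_mask_identity(self, tiny_campaign):
        ens = self._cotrained(apply_label_sparsity(tiny_campaign, 5))
        out = impute_labels(tiny_campaign, ens)
        np.testing.assert_array_equal(out.y, tiny_campaign.y)
        assert (out.label_source == "measured").all()

    def test_single_unlabeled_cell(self, tiny_campaign):
        data = tiny_campaign.copy()
        data.mask[2, 3] = False
        ens = self._cotrained(apply_label_sparsity(tiny_campaign, 5))
        out = impute_labels(data, ens)
        assert out.mask.all()
        assert (out.label_source == "pseudo").sum() == 1
        assert out.label_source[2, 3] == "pseudo"
        # measured labels untouched
        keep = data.mask
        np.testing.assert_array_equal(out.y[keep], data.y[keep])

    def test_pseudo_labels_track_truth_on_noiseless_data(self, noiseless_campaign):
        sparse = apply_label_sparsity(noiseless_campaign, 5)
        ens = self._cotrained(sparse)
        out = impute_labels(sparse, ens)
        held_out = ~sparse.mask
        truth = noiseless_campaign.y[held_out]
        pseudo = out.y[held_out]
        r = np.corrcoef(truth, pseudo)[0, 1]
        assert r > 0.95
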