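"""Rank-correlation accuracy, bootstrap, permutation null and FDR."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facejudge.evaluation import (
    bootstrap_accuracy,
    evaluate_models,
    fdr_adjust,
    permutation_null,
    spearman,
)


def brute_force_spearman(x, y):
    """Independent oracle: manual average ranks, then Pearson by the formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        assert spearman(np.exp(x), x) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert spearman(x[::-1], x) == pytest.approx(-1.0)

    def test_tied_data_matches_brute_force_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 3.0, 3.0]
        y = [5.0, 5.0, 1.0, 4.0, 4.0, 2.0]
        assert spearman(x, y) == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_matches_scipy_on_random_vectors(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.standard_normal(12)
            if np.ptp(x) == 0:
                continue
            assert spearman(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_raises_naming_vector(self):
        with pytest.raises(ValueError, match="y is constant"):
            spearman([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=12, unique=True))
    def test_bounded_by_one(self, xs):
        rng = np.random.default_rng(1)
        ys = rng.permutation(xs)
        assert abs(spearman(xs, ys)) <= 1 + 1e-12


class TestBootstrap:
    def test_perfect_prediction_gives_rho_one_sd_zero(self):
        x = np.arange(10.0)
        mean, sd, ndeg = bootstrap_accuracy(x, x, n_boot=200, seed=0)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_single_image_identity_map_reduces_to_plain_bootstrap(self):
        rng = np.random.default_rng(3)
        pred, act = rng.standard_normal(20), rng.standard_normal(20)
        ids = [f"f{i}" for i in range(20)]
        imap = {f: f"id{i}" for i, f in enumerate(ids)}
        plain = bootstrap_accuracy(pred, act, n_boot=500, seed=11)
        mapped = bootstrap_accuracy(
            pred, act, identity_map=imap, n_boot=500, seed=11, face_ids=ids
        )
        # one image per identity: same resampling distribution
        assert mapped[0] == pytest.approx(plain[0], abs=0.05)

    def test_bootstrap_mean_tracks_full_sample_rho(self):
        rng = np.random.default_rng(5)
        n = 60
        z = rng.standard_normal(n)
        pred = z + rng.standard_normal(n)
        act = z + rng.standard_normal(n)
        full = spearman(pred, act)
        mean, _, _ = bootstrap_accuracy(pred, act, n_boot=10_000, seed=1)
        assert mean == pytest.approx(full, abs=0.05)

    def test_invariant_to_monotone_transform_of_predictions(self):
        rng = np.random.default_rng(9)
        pred, act = rng.standard_normal(30), rng.standard_normal(30)
        a = bootstrap_accuracy(pred, act, n_boot=300, seed=2)
        b = bootstrap_accuracy(np.exp(pred), act, n_boot=300, seed=2)
        assert a[0] == pytest.approx(b[0], abs=1e-12)

    def test_identity_aware_path_draws_one_image_per_identity(self):
        # two identities, each with images carrying opposite signs: the
        # plain bootstrap sees 4 faces, the identity-aware one only 2 per draw
        pred = np.array([1.0, 1.1, 2.0, 2.1, 3.0, 3.1])
        act = np.array([1.0, 5.0, 2.0, 4.0, 3.0, 6.0])
        ids = [f"f{i}" for i in range(6)]
        imap = {"f0": "a", "f1": "a", "f2": "b", "f3": "b", "f4": "c", "f5": "c"}
        mean, _, _ = bootstrap_accuracy(
            pred, act, identity_map=imap, n_boot=400, seed=4, face_ids=ids
        )
        assert -1 <= mean <= 1


class TestPermutation:
    def test_observed_above_all_null_gives_p_zero(self):
        x = np.arange(20.0)
        _, p, _ = permutation_null(x, x + 0.1, n_perm=500, seed=0)
        assert p == 0.0

    def test_exhaustive_null_matches_enumeration_oracle(self):
        pred = np.array([0.3, 1.2, -0.5, 2.0])
        act = np.array([1.0, 2.0, 3.0, 4.0])
        _, p, null = permutation_null(pred, act, exhaustive=True)
        oracle = sorted(
            spearman(pred, np.asarray(perm, float))
            for perm in itertools.permutations(act)
        )
        assert np.allclose(sorted(null), oracle, atol=1e-12)
        observed = spearman(pred, act)
        assert p == pytest.approx(np.mean([v >= observed for v in oracle]))

    def test_threshold_is_95th_percentile_of_null(self):
        rng = np.random.default_rng(2)
        pred, act = rng.standard_normal(25), rng.standard_normal(25)
        thr, _, null = permutation_null(pred, act, n_perm=1000, seed=3)
        assert thr == pytest.approx(np.percentile(null, 95))

    def test_smoothed_p_never_zero(self):
        x = np.arange(15.0)
        _, p, _ = permutation_null(x, x, n_perm=200, seed=0, smoothed=True)
        assert p == pytest.approx(1 / 201, abs=1e-9) or p > 0


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up_case(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_independent_step_up_oracle(self):
        def step_up(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, m * p[i] / rank)
                q[i] = prev
            return q

        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(rng.integers(1, 30))
            assert np.allclose(fdr_adjust(p), step_up(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestEvaluateModels:
    def test_self_prediction_beats_chance_in_sample(self, small_world, small_models):
        w = small_world
        results = evaluate_models(
            small_models,
            w.train_ratings,
            w.train_features["strong"],
            [(a, a, False) for a in w.train_ratings.attributes],
            n_boot=300,
            n_perm=300,
            seed=0,
        )
        for r in results:
            assert r.mean_rho > r.chance_threshold
            assert r.significant

    def test_antonym_flip_recovers_accuracy_on_reversed_scale(self, small_world, small_models):
        import pandas as pd

        from facejudge.tables import RatingTable

        w = small_world
        ts = w.test_sets[0]
        attr = w.train_ratings.attributes[0]
        reversed_ratings = RatingTable(
            pd.DataFrame(
                {f"anti_{attr}": 8.0 - ts.ratings.ratings[attr]},
                index=ts.ratings.ratings.index,
            )
        )
        straight = evaluate_models(
            small_models, ts.ratings, ts.features["strong"],
            [(attr, attr, False)], n_boot=400, n_perm=300, seed=5,
        )[0]
        flipped = evaluate_models(
            small_models, reversed_ratings, ts.features["strong"],
            [(attr, f"anti_{attr}", True)], n_boot=400, n_perm=300, seed=5,
        )[0]
        assert flipped.mean_rho == pytest.approx(straight.mean_rho, abs=0.02)

    def test_missing_model_raises(self, small_world, small_models):
        ts = small_world.test_sets[0]
        with pytest.raises(KeyError):
            evaluate_models(
                small_models, ts.ratings, ts.features["strong"],
                [("nonexistent", "attr_01", False)], n_boot=100, n_perm=100,
            )
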