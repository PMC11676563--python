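"""Evaluation protocol against brute-force oracles: pairwise micro AUROC,
exhaustive confusion-table scans for the sensitivity-at-specificity
operating point, order statistics of the CV/bootstrap matrix."""

import numpy as np
import pytest

from carenet.evaluation import (ScoreFrame, cv_bootstrap,
                                cv_bootstrap_with_scores, micro_auroc,
                                sens_at_spec, subgroup_report, summarize)


def brute_force_auroc(scores, labels):
    """P(score_pos > score_neg) + 0.5 P(tie) over all pos-neg pairs."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=bool).ravel()
    pos, neg = s[y], s[~y]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_sens_at_spec(scores, labels, floor):
    """Enumerate the confusion table at every candidate threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    best = None
    for t in np.unique(s):
        pred = s >= t
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        if spec > floor:
            # max sensitivity; ties resolve to the lowest threshold
            if best is None or sens > best[0] or (sens == best[0] and t < best[2]):
                best = (sens, spec, t)
    return best if best is not None else (0.0, 1.0, float("inf"))


class TestMicroAuroc:
    def test_separable_and_constant(self):
        assert micro_auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert micro_auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_four_pair_example(self):
        # pos {0.9, 0.4}, neg {0.6, 0.2}: 3 of 4 pairs correctly ordered
        assert micro_auroc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_pools_labels_with_equal_visit_weight(self):
        scores = np.array([[0.9, 0.1], [0.2, 0.8]])
        labels = np.array([[1, 0], [0, 1]])
        assert micro_auroc(scores, labels) == 1.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            micro_auroc([0.5, 0.6], [1, 1])

    def test_matches_brute_force_on_random_instances(self, rng):
        """200 random small instances agree with the pairwise oracle to
        1e-12 (ties included)."""
        for _ in range(200):
            n = rng.integers(4, 12)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert micro_auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12)


class TestSensAtSpec:
    def test_separable(self):
        sens, spec, thr = sens_at_spec([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert sens == 1.0 and spec == 1.0
        assert 0.2 < thr <= 0.8

    def test_all_scores_equal_hits_degenerate_branch(self):
        with pytest.warns(UserWarning, match="specificity"):
            sens, spec, thr = sens_at_spec([0.4] * 6, [1, 0, 1, 0, 1, 0])
        assert (sens, spec, thr) == (0.0, 1.0, float("inf"))

    def test_six_point_toy_matches_enumeration(self):
        scores = [0.95, 0.8, 0.7, 0.6, 0.4, 0.1]
        labels = [1, 0, 1, 1, 0, 0]
        got = sens_at_spec(scores, labels, floor=0.5)
        exp = brute_force_sens_at_spec(scores, labels, 0.5)
        assert got == pytest.approx(exp)

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(50):
            n = rng.integers(6, 20)
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            floor = float(rng.choice([0.5, 0.75, 0.9]))
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = sens_at_spec(scores, labels, floor)
            exp = brute_force_sens_at_spec(scores, labels, floor)
            assert got == pytest.approx(exp)

    def test_result_respects_floor(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        sens, spec, thr = sens_at_spec(scores, labels, floor=0.75)
        assert spec > 0.75 or (sens, spec) == (0.0, 1.0)


class TestSummarize:
    def test_known_matrix_order_statistics(self):
        matrix = np.array([0.8] * 50 + [0.9] * 50)
        med, lo, hi = summarize(matrix)
        assert (med, lo, hi) == (pytest.approx(0.85), pytest.approx(0.8),
                                 pytest.approx(0.9))

    def test_single_entry(self):
        assert summarize(np.array([[0.7]])) == (0.7, 0.7, 0.7)

    def test_matches_independent_percentile_routine(self, rng):
        """Linear-interpolation percentiles recomputed by hand."""
        vals = rng.random(100)

        def manual_pct(v, q):
            v = np.sort(v)
            pos = (len(v) - 1) * q / 100
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return v[lo] + (pos - lo) * (v[hi] - v[lo])

        med, lo, hi = summarize(vals)
        assert med == pytest.approx(manual_pct(vals, 50), abs=1e-12)
        assert lo == pytest.approx(manual_pct(vals, 2.5), abs=1e-12)
        assert hi == pytest.approx(manual_pct(vals, 97.5), abs=1e-12)

    def test_ignores_nan_rejects_all_nan(self):
        m = np.array([0.6, np.nan, 0.8])
        assert summarize(m)[0] == pytest.approx(0.7)
        with pytest.raises(ValueError):
            summarize(np.array([np.nan]))


class _PerfectModel:
    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.asarray(X, dtype=float)   # X *is* the truth


class _ConstantModel:
    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.full((len(X), 4), 0.5)


def _random_multilabel(rng, n):
    y = (rng.random((n, 4)) < [0.3, 0.3, 0.3, 0.6]).astype(float)
    y[y.sum(axis=1) == 0, 3] = 1
    return y


class TestCvBootstrap:
    def test_perfect_and_constant_plugins(self, rng):
        y = _random_multilabel(rng, 200)
        m_perfect = cv_bootstrap(y.copy(), y, _PerfectModel, folds=10, boots=10,
                                 seed=0)
        assert m_perfect.shape == (10, 10)
        np.testing.assert_allclose(m_perfect, 1.0)
        m_const = cv_bootstrap(y.copy(), y, _ConstantModel, folds=10, boots=10,
                               seed=0)
        np.testing.assert_allclose(m_const, 0.5)

    def test_boots_one_frac_one_is_plain_cv(self, rng):
        """boots=1, frac=1.0 reduces to plain 10-fold CV: each entry is the
        full held-out fold's micro AUROC."""
        y = _random_multilabel(rng, 150)
        X = np.clip(y + rng.normal(0, 0.8, size=y.shape), 0, 1)

        class Echo:
            def fit(self, X, y):
                return self

            def predict_proba(self, Z):
                return np.asarray(Z)

        matrix, oof = cv_bootstrap_with_scores(X, y, Echo, folds=10, boots=1,
                                               frac=1.0, seed=5)
        assert matrix.shape == (10, 1)
        np.testing.assert_allclose(oof, X)
        assert np.isnan(matrix).sum() == 0

    def test_degenerate_bootstrap_records_nan(self, rng):
        y = np.ones((24, 4))
        y[0, 0] = 0.0   # a single negative in the whole pool
        X = rng.random((24, 4))
        with pytest.warns(UserWarning, match="degenerate"):
            matrix = cv_bootstrap(X, y, _ConstantModel, folds=2, boots=3,
                                  frac=0.9, seed=1)
        assert np.isnan(matrix).any()
        assert np.nanmax(matrix) <= 1.0

    def test_seed_reproducibility(self, rng):
        y = _random_multilabel(rng, 120)
        X = np.clip(y + rng.normal(0, 0.5, size=y.shape), 0, 1)

        class Echo:
            def fit(self, X, y):
                return self

            def predict_proba(self, Z):
                return np.asarray(Z)

        m1 = cv_bootstrap(X, y, Echo, folds=5, boots=4, seed=9)
        m2 = cv_bootstrap(X, y, Echo, folds=5, boots=4, seed=9)
        np.testing.assert_array_equal(m1, m2)


class TestSubgroups:
    def test_planted_heterogeneity(self, rng):
        """Scores informative only in one subgroup: that group's AUROC
        exceeds the other's."""
        n = 400
        y = _random_multilabel(rng, n)
        group_a = np.arange(n) < n // 2
        scores = rng.random((n, 4))
        scores[group_a] = np.clip(y[group_a] + rng.normal(0, 0.2, (n // 2, 4)),
                                  0, 1)
        frame = ScoreFrame(scores=scores, labels=y)
        rep = subgroup_report(frame, {"A": group_a, "B": ~group_a}, seed=0)
        a = rep[rep.group == "A"].auroc.iloc[0]
        b = rep[rep.group == "B"].auroc.iloc[0]
        assert a > b + 0.2

    def test_empty_group_yields_nan_row(self, rng):
        y = _random_multilabel(rng, 50)
        frame = ScoreFrame(scores=rng.random((50, 4)), labels=y)
        rep = subgroup_report(frame, {"none": np.zeros(50, dtype=bool)}, seed=0)
        assert np.isnan(rep.auroc.iloc[0])
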