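"""Pseudo-absence weighting, member fitting, TSS search and committee rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiersdm.grids import GridSpec, RasterLayer, RasterStack
from hiersdm.sdm import (
    EnsembleSettings,
    FittedMember,
    PseudoAbsenceSet,
    _make_learner,
    binarize_ensemble,
    committee_average,
    cutoff_lattice,
    evaluate_binary,
    fit_member,
    pseudo_absence_weight,
    range_filling,
    sample_pseudo_absences,
    select_members,
    split_train_eval,
    weight_pseudo_absences,
)


class TestPseudoAbsenceWeight:
    @pytest.mark.parametrize(
        "p, expected",
        [(1.0, 0.0), (0.0, 1.0), (0.5, 0.5), (0.8, 1.0 / 17.0)],
    )
    def test_inverse_logistic_values(self, p, expected):
        assert pseudo_absence_weight(p) == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_and_bounded(self):
        p = np.linspace(0, 1, 1001)
        w = pseudo_absence_weight(p)
        assert (np.diff(w) < 0).all()
        assert w.min() >= 0 and w.max() <= 1

    def test_complement_symmetry(self):
        """w(p) + w(1-p) = 1 follows from the squared-odds symmetry."""
        p = np.linspace(0.001, 0.999, 999)
        np.testing.assert_allclose(
            pseudo_absence_weight(p) + pseudo_absence_weight(1 - p), 1.0, atol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            pseudo_absence_weight(np.array([0.5, 1.2]))

    def test_weight_layer_attachment(self):
        grid = GridSpec(0, 0, 0.25, 2, 2)
        proj = RasterLayer(grid, "p", np.array([[0.0, 0.5], [0.8, 1.0]]))
        pa = PseudoAbsenceSet(1, [0, 0, 1, 1], [0, 1, 0, 1], np.ones(4))
        weighted = weight_pseudo_absences(pa, proj)
        np.testing.assert_allclose(
            weighted.weights, [1.0, 0.5, 1 / 17, 0.0], atol=1e-12
        )


class TestSamplePseudoAbsences:
    def test_presences_never_sampled_and_exhaustive_case(self):
        grid = GridSpec(0, 0, 0.25, 5, 5)
        region = RasterLayer(grid, "r", np.ones(grid.shape))
        presences = {(0, 0), (1, 1)}
        pa = sample_pseudo_absences(region, 23, presences, seed=1)
        assert len(pa) == 23
        assert not (set(zip(pa.rows.tolist(), pa.cols.tolist())) & presences)
        assert (pa.weights == 1).all()

    def test_shortfall_named_in_error(self):
        grid = GridSpec(0, 0, 0.25, 3, 3)
        region = RasterLayer(grid, "r", np.ones(grid.shape))
        with pytest.raises(ValueError, match="only 9 candidate"):
            sample_pseudo_absences(region, 50, set(), seed=1)

    def test_seed_determinism(self):
        grid = GridSpec(0, 0, 0.25, 10, 10)
        region = RasterLayer(grid, "r", np.ones(grid.shape))
        a = sample_pseudo_absences(region, 30, set(), seed=7)
        b = sample_pseudo_absences(region, 30, set(), seed=7)
        assert np.array_equal(a.rows, b.rows) and np.array_equal(a.cols, b.cols)


class TestSplit:
    def test_exact_fraction_and_disjointness(self):
        (tp, ta), (ep, ea) = split_train_eval(100, 200, 0.7, seed=0)
        assert len(tp) == 70 and len(ep) == 30
        assert len(ta) == 140 and len(ea) == 60
        assert not (set(tp) & set(ep)) and not (set(ta) & set(ea))
        assert set(tp) | set(ep) == set(range(100))

    def test_different_seeds_differ(self):
        parts = {tuple(split_train_eval(50, 50, 0.7, seed=s)[0][0]) for s in range(4)}
        assert len(parts) == 4

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError, match=">= 10 presences"):
            split_train_eval(5, 100)


class TestEvaluateBinary:
    def test_reported_metric_identity(self):
        """A confusion matrix with sens 95.09% / spec 87.63% yields TSS 0.8272,
        matching the published identity TSS = sens + spec - 1."""
        n = 10_000
        scores = np.concatenate([
            np.where(np.arange(n) < 9509, 0.9, 0.1),  # positives
            np.where(np.arange(n) < 8763, 0.1, 0.9),  # negatives
        ])
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        sens, spec, tss, _ = evaluate_binary(scores, labels)
        assert sens == pytest.approx(0.9509, abs=1e-12)
        assert spec == pytest.approx(0.8763, abs=1e-12)
        assert tss == pytest.approx(0.8272, abs=1e-12)
        assert round(tss, 2) == 0.83

    def test_perfect_scores_give_unit_tss(self):
        scores = np.array([1.0, 1.0, 0.0, 0.0])
        labels = np.array([True, True, False, False])
        sens, spec, tss, cut = evaluate_binary(scores, labels)
        assert tss == 1.0 and 0 < cut <= 1

    def test_random_scores_near_zero_tss(self, rng):
        scores = rng.uniform(size=10_000)
        labels = rng.uniform(size=10_000) < 0.5
        _, _, tss, _ = evaluate_binary(scores, labels)
        assert abs(tss) < 0.05

    def test_permutation_invariance(self, rng):
        scores = rng.uniform(size=500)
        labels = rng.uniform(size=500) < 0.4
        perm = rng.permutation(500)
        assert evaluate_binary(scores, labels) == evaluate_binary(scores[perm], labels[perm])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_binary(np.array([0.1, 0.9]), np.array([True, True]))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_confusion_matrix_oracle(self, seed):
        """Vectorized lattice search equals a brute-force confusion-matrix scan."""
        rng = np.random.default_rng(seed)
        n = 200
        scores = np.round(rng.uniform(size=n), 3)
        labels = rng.uniform(size=n) < 0.5
        if labels.all() or not labels.any():
            return
        sens, spec, tss, cut = evaluate_binary(scores, labels)
        best = (-2.0, None)
        for c in cutoff_lattice():
            tp = ((scores >= c) & labels).sum()
            fn = ((scores < c) & labels).sum()
            tn = ((scores < c) & ~labels).sum()
            fp = ((scores >= c) & ~labels).sum()
            t = tp / (tp + fn) + tn / (tn + fp) - 1
            if t > best[0] + 1e-12:
                best = (t, c)
        assert tss == pytest.approx(best[0], abs=1e-12)
        assert cut == pytest.approx(best[1], abs=1e-12)


def _member(tss, order):
    return FittedMember("glm_logistic", 1, order, None, 0.0, 0.0, tss, 0.5)


class TestSelectMembers:
    def test_threshold_selection(self):
        members = [_member(t, i) for i, t in enumerate([0.8, 0.72, 0.5])]
        assert [m.eval_tss for m in select_members(members)] == [0.8, 0.72]

    def test_fallback_top_quantile(self):
        members = [_member(0.01 * i, i) for i in range(60)]  # all < 0.7
        chosen = select_members(members)
        assert len(chosen) == 6  # ceil(0.10 * 60)
        assert min(m.eval_tss for m in chosen) >= 0.54

    def test_never_empty(self):
        assert len(select_members([_member(0.1, 0)])) == 1


class _Stub:
    """Fake fitted model: maps the first feature through a lookup table."""

    def __init__(self, table):
        self.table = table

    def predict_proba(self, X):
        p = np.array([self.table[int(v)] for v in X[:, 0]])
        return np.column_stack([1 - p, p])


def _stub_member(table, cutoff=0.5):
    return FittedMember("glm_logistic", 1, 1, _Stub(table), 1, 1, 1, cutoff)


class TestCommitteeAverage:
    def _stack(self):
        grid = GridSpec(0, 0, 0.25, 1, 3)
        return RasterStack(grid, [RasterLayer(grid, "idx", np.array([[0.0, 1.0, 2.0]]))])

    def test_agreement_and_split_votes(self):
        stack = self._stack()
        m1 = _stub_member({0: 1.0, 1: 1.0, 2: 0.9})
        m2 = _stub_member({0: 1.0, 1: 0.0, 2: 0.1})
        suit, cv = committee_average([m1, m2], stack)
        np.testing.assert_allclose(suit.values[0], [1.0, 0.5, 0.5])
        # (1,0) votes: mean .5, population sd .5, raw CV 1 -> map max -> 1
        np.testing.assert_allclose(cv.values[0], [0.0, 1.0, 1.0])

    def test_suitability_is_vote_fraction(self, rng):
        stack = self._stack()
        members = [
            _stub_member({i: rng.uniform() for i in range(3)}) for _ in range(7)
        ]
        suit, _ = committee_average(members, stack)
        scaled = suit.values[0] * 7
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-12)


class TestBinarizeAndRangeFilling:
    def test_separated_suitability_gives_unit_tss_smallest_cutoff(self):
        grid = GridSpec(0, 0, 0.25, 1, 4)
        suit = RasterLayer(grid, "s", np.array([[1.0, 1.0, 0.0, 0.0]]))
        pa = PseudoAbsenceSet(1, [0, 0], [2, 3], np.ones(2))
        binary, cut, tss, sens, spec = binarize_ensemble(suit, {(0, 0), (0, 1)}, pa)
        assert tss == 1.0 and sens == 1.0 and spec == 1.0
        assert cut == pytest.approx(0.01)
        np.testing.assert_array_equal(binary.values[0], [1, 1, 0, 0])

    def test_uniform_suitability_has_no_skill(self):
        grid = GridSpec(0, 0, 0.25, 1, 4)
        suit = RasterLayer(grid, "s", np.full((1, 4), 0.5))
        pa = PseudoAbsenceSet(1, [0, 0], [2, 3], np.ones(2))
        _, _, tss, _, _ = binarize_ensemble(suit, {(0, 0), (0, 1)}, pa)
        assert tss == pytest.approx(0.0)

    def test_range_filling_counts(self):
        grid = GridSpec(0, 0, 0.25, 1, 10)
        binary = RasterLayer(grid, "b", np.ones((1, 10)))
        presences = {(0, c) for c in range(4)}
        assert range_filling(binary, presences) == pytest.approx(0.4)
        assert range_filling(binary, {(0, 99)}) == 0.0

    def test_empty_predicted_range_is_undefined(self):
        grid = GridSpec(0, 0, 0.25, 1, 3)
        binary = RasterLayer(grid, "b", np.zeros((1, 3)))
        assert range_filling(binary, {(0, 0)}) is None


class TestFitMember:
    def test_separable_data_reaches_unit_tss(self, rng):
        X = rng.normal(size=(300, 2))
        y = (X[:, 0] > 0).astype(float)
        m = fit_member("glm_logistic", X, y, np.ones(300), X, y)
        assert m.eval_tss == 1.0
        assert m.eval_tss == pytest.approx(m.eval_sensitivity + m.eval_specificity - 1)

    def test_null_labels_give_no_skill(self, rng):
        X = rng.normal(size=(1000, 2))
        y = (rng.uniform(size=1000) < 0.5).astype(float)
        m = fit_member("glm_logistic", X, y, np.ones(1000), X, y)
        assert abs(m.eval_tss) < 0.15

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        with pytest.raises(ValueError, match="single class"):
            fit_member("glm_logistic", X, np.ones(50), np.ones(50), X, np.ones(50))

    def test_doubling_weights_leaves_skill_unchanged(self, rng):
        X = rng.normal(size=(400, 2))
        y = (X[:, 0] + 0.5 * rng.normal(size=400) > 0).astype(float)
        w = np.where(y == 1, 1.0, 0.4)
        Xe = rng.normal(size=(400, 2))
        ye = (Xe[:, 0] + 0.5 * rng.normal(size=400) > 0).astype(float)
        m1 = fit_member("glm_logistic", X, y, w, Xe, ye)
        m2 = fit_member("glm_logistic", X, y, 2 * w, Xe, ye)
        assert m1.eval_tss == pytest.approx(m2.eval_tss, abs=0.02)

    @pytest.mark.parametrize("algorithm", ["gam_spline", "fda", "gbm", "maxent_like"])
    def test_all_algorithms_learn_a_simple_signal(self, algorithm, rng):
        settings = EnsembleSettings(gbm_n_estimators=50)
        X = rng.normal(size=(400, 2))
        y = (X[:, 0] > 0).astype(float)
        m = fit_member(algorithm, X, y, np.ones(400), X, y, settings=settings)
        assert m.eval_tss > 0.8
        p = m.model.predict_proba(X)[:, 1]
        assert p.min() >= 0 and p.max() <= 1

    def test_zero_weight_pseudo_absences_have_no_influence(self, rng):
        """Weight-0 pseudo-absences must not move the fitted glm response."""
        Xp = rng.normal(size=(100, 2)) + 1
        Xa = rng.normal(size=(150, 2))
        X = np.vstack([Xp, Xa])
        y = np.concatenate([np.ones(100), np.zeros(150)])
        w = np.concatenate([np.ones(100), np.zeros(50), np.ones(100)])
        keep = np.concatenate([np.ones(100, bool), np.zeros(50, bool), np.ones(100, bool)])
        p1 = _make_learner("glm_logistic", 0, EnsembleSettings())
        p1.set_params(clf__tol=1e-12, clf__max_iter=50_000)
        p1.fit(X, y, clf__sample_weight=w)
        p2 = _make_learner("glm_logistic", 0, EnsembleSettings())
        p2.set_params(clf__tol=1e-12, clf__max_iter=50_000)
        p2.fit(X[keep], y[keep], clf__sample_weight=np.ones(int(keep.sum())))
        T = rng.normal(size=(500, 2))
        np.testing.assert_allclose(
            p1.predict_proba(T)[:, 1], p2.predict_proba(T)[:, 1], atol=1e-6
        )
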