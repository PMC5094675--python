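"""Voting, raw scores, SVM fitting, fold plans, nested CV, and the metric suite."""

import numpy as np
import pytest
from scipy import stats

import ldometa as lm
from ldometa.classify import (
    ConfusionCounts,
    _group_key,
    confusion,
    precision_recall_f,
)
from ldometa.pool import Label


def make_model(w, b=0.0, C=1.0):
    return lm.LinearModel(weights=np.asarray(w, dtype=float), offset=b, C=C)


class TestVoteAndRawScore:
    def test_printed_signature_has_nine_calls(self):
        sig = [int(c) for c in "00011011101010110"]
        assert lm.vote_count(sig) == 9

    @pytest.mark.parametrize("sig,expected", [([0] * 17, 0), ([1] * 17, 17)])
    def test_vote_extremes(self, sig, expected):
        assert lm.vote_count(sig) == expected

    def test_unit_weights_zero_offset_reduces_to_voting(self):
        rng = np.random.default_rng(0)
        model = make_model([1.0] * 17)
        for _ in range(50):
            sig = rng.integers(0, 2, size=17)
            assert lm.raw_score(model, sig) == lm.vote_count(sig)

    def test_hand_dot_product(self):
        model = make_model([0.5, 1.0, -0.25], b=0.2)
        assert lm.raw_score(model, [1, 0, 1]) == pytest.approx(0.05)

    def test_all_zero_signature_scores_minus_offset(self):
        model = make_model([2.0, 3.0], b=0.7)
        assert lm.raw_score(model, [0, 0]) == pytest.approx(-0.7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lm.raw_score(make_model([1.0, 1.0]), [1, 0, 1])


def separable_data(n=200, K=5, seed=0):
    """Labels depend deterministically on bit 1; other bits are noise."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, K))
    y = X[:, 1].copy()
    return X, y


class TestFitLinearSVM:
    def test_separable_data_learned_perfectly(self):
        X, y = separable_data()
        model = lm.fit_linear_svm(X[:150], y[:150], C=1.0, seed=0)
        from ldometa.classify import raw_scores

        pred = (raw_scores(model, X[150:]) >= 0).astype(int)
        assert np.mean(pred == y[150:]) == 1.0
        assert np.argmax(np.abs(model.weights)) == 1

    def test_duplicating_all_rows_changes_nothing(self):
        # on separable data the solution sits at the hard-margin optimum, which
        # does not move when the empirical distribution is replicated
        X, y = separable_data(n=80, seed=1)
        m1 = lm.fit_linear_svm(X, y, C=4.0, seed=0)
        m2 = lm.fit_linear_svm(np.vstack([X, X]), np.concatenate([y, y]), C=4.0, seed=0)
        assert np.allclose(m1.weights, m2.weights, atol=1e-6)
        assert m1.offset == pytest.approx(m2.offset, abs=1e-6)

    def test_permuted_labels_cannot_beat_chance(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(400, 8))
        y = rng.permutation(np.repeat([0, 1], 200))
        model = lm.fit_linear_svm(X[:300], y[:300], C=1.0, seed=0)
        from ldometa.classify import raw_scores

        pred = (raw_scores(model, X[300:]) >= 0).astype(int)
        acc = np.mean(pred == y[300:])
        # exact binomial 99% interval around the majority-class rate (0.5 here)
        lo, hi = stats.binom.interval(0.99, 100, 0.5)
        assert lo / 100 <= acc <= hi / 100

    def test_contract_errors(self):
        X, y = separable_data(n=20)
        with pytest.raises(ValueError):
            lm.fit_linear_svm(X, np.ones(len(y)), C=1.0)
        with pytest.raises(ValueError):
            lm.fit_linear_svm(X, y, C=0.0)
        with pytest.raises(ValueError):
            lm.fit_linear_svm(X, y, C=-2.0)


def pool_from_assignments(pair_labels):
    """Build a LabeledPool whose labeled pairs are exactly `pair_labels`."""
    m = lm.AlgorithmManifest(names=("A1", "A2", "A3"))
    rng = np.random.default_rng(42)
    sigs = {}
    ref_pairs = set()
    for p, is_pos in pair_labels.items():
        sig = rng.integers(0, 2, size=3).astype(np.uint8)
        if not sig.any():
            sig[0] = 1
        sigs[p] = sig
        if is_pos:
            ref_pairs.add(p)
    pool = lm.CandidatePool(species_pair=("q", "t"), manifest=m, signatures=sigs)
    return lm.label_pool(pool, lm.ReferenceLDOSet(pairs=ref_pairs))


class TestMakeFolds:
    def test_symmetric_case_splits_exactly(self):
        labels = {lm.GenePair(f"q{i}", f"t{i}"): True for i in range(100)}
        plan = lm.make_folds(labels, 10, seed=0)
        for fold in range(1, 11):
            assert len(plan.fold_pairs(fold)) == 10

    def test_query_gene_pairs_share_a_fold(self):
        labels = {}
        for i in range(30):
            for j in range(5):
                labels[lm.GenePair(f"q{i}", f"t{i}_{j}")] = j == 0
        plan = lm.make_folds(labels, 5, seed=1)
        for i in range(30):
            folds = {plan.assignment[lm.GenePair(f"q{i}", f"t{i}_{j}")] for j in range(5)}
            assert len(folds) == 1

    def test_deterministic_under_seed(self):
        labels = {lm.GenePair(f"q{i}", f"t{i}"): i % 3 == 0 for i in range(60)}
        p1 = lm.make_folds(labels, 5, seed=9)
        p2 = lm.make_folds(labels, 5, seed=9)
        assert p1.assignment == p2.assignment

    def test_too_few_genes_rejected(self):
        labels = {lm.GenePair(f"q{i}", f"t{i}"): i < 2 for i in range(8)}
        with pytest.raises(ValueError, match="folds"):
            lm.make_folds(labels, 5, seed=0)

    def test_invariants_over_random_draws(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            n_genes = int(rng.integers(150, 250))
            labels = {}
            for i in range(n_genes):
                n_pairs = int(rng.integers(1, 4))
                is_pos = rng.random() < 0.4
                for j in range(n_pairs):
                    # positives are one-per-gene (reference is one-to-one)
                    labels[lm.GenePair(f"q{i}", f"t{i}_{j}")] = is_pos and j == 0
            seed = int(rng.integers(2**31))
            n_folds = 4
            plan = lm.make_folds(labels, n_folds, seed)
            groups = {p: _group_key(p, "forward") for p in labels}
            plan.validate(labels, groups, rel_tol=0.2)
            assert set(plan.assignment) == set(labels)


class TestInnerCV:
    def test_tie_broken_toward_smallest_C(self):
        # perfectly separable: every C reaches accuracy 1, so the smallest wins
        labeled = separable_labeled_pool(30)
        pairs = sorted(labeled.pool.pairs)
        C, accs = lm.inner_cv_select_C(labeled, pairs, C_grid=(0.25, 1.0, 4.0), n_inner=3, seed=0)
        assert accs[0.25] == pytest.approx(1.0)
        assert C == 0.25

    def test_singleton_grid(self):
        labeled = separable_labeled_pool(20)
        pairs = sorted(labeled.pool.pairs)
        C, accs = lm.inner_cv_select_C(labeled, pairs, C_grid=(1.0,), n_inner=3, seed=0)
        assert C == 1.0 and list(accs) == [1.0]

    def test_empty_grid_rejected(self):
        labeled = separable_labeled_pool(20)
        with pytest.raises(ValueError):
            lm.inner_cv_select_C(labeled, sorted(labeled.pool.pairs), C_grid=(), n_inner=3, seed=0)


def separable_labeled_pool(n_genes):
    """Labeled pool where bit 0 equals the class: trivially separable.

    Each query gene contributes its reference pair (positive, signature 11)
    and one known non-LDO (signature 01, same query gene, wrong target).
    """
    m = lm.AlgorithmManifest(names=("A1", "A2"))
    sigs = {}
    ref = set()
    for i in range(n_genes):
        pos = lm.GenePair(f"q{i}", f"t{i}")
        neg = lm.GenePair(f"q{i}", f"u{i}")
        sigs[pos] = np.array([1, 1], dtype=np.uint8)
        sigs[neg] = np.array([0, 1], dtype=np.uint8)
        ref.add(pos)
    pool = lm.CandidatePool(species_pair=("q", "t"), manifest=m, signatures=sigs)
    return lm.label_pool(pool, lm.ReferenceLDOSet(pairs=ref))


@pytest.fixture(scope="module")
def separable_report():
    labeled = separable_labeled_pool(60)
    report = lm.nested_cv(labeled, C_grid=(0.25, 1.0), n_outer=5, n_inner=3, seed=0)
    return labeled.pool.pairs, labeled, report


class TestNestedCV:

    def test_separable_pool_reaches_perfect_f(self, separable_report):
        _, _, report = separable_report
        assert report.aggregate().loc["f", "mean"] == pytest.approx(1.0)

    def test_every_labeled_pair_scored_out_of_fold_once(self, separable_report):
        labels, _, report = separable_report
        assert set(report.oof_scores) == set(labels)

    def test_sem_matches_hand_computation(self, separable_report):
        _, _, report = separable_report
        vals = np.array([f.max_f for f in report.folds])
        expected_sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert report.aggregate().loc["max_f", "sem"] == pytest.approx(expected_sem)

    def test_bit_identical_reports_under_same_seed(self):
        labeled = separable_labeled_pool(45)
        r1 = lm.nested_cv(labeled, C_grid=(1.0,), n_outer=3, n_inner=3, seed=4)
        r2 = lm.nested_cv(labeled, C_grid=(1.0,), n_outer=3, n_inner=3, seed=4)
        assert r1.oof_scores == r2.oof_scores
        assert [vars(f) for f in r1.folds] == [vars(f) for f in r2.folds]


class TestMetrics:
    def test_confusion_enumeration(self):
        c = confusion({"a", "b", "c"}, {"b", "c", "d"})
        assert (c.TP, c.FP, c.FN) == (2, 1, 1)
        c2 = confusion({"a"}, {"a"})
        assert (c2.FP, c2.FN) == (0, 0)
        c3 = confusion(set(), {"a", "b"})
        assert (c3.TP, c3.FN) == (0, 2)

    def test_prf_formulas(self):
        P, R, F = precision_recall_f(ConfusionCounts(TP=2, FP=1, FN=1))
        assert (P, R, F) == (pytest.approx(2 / 3), pytest.approx(2 / 3), pytest.approx(2 / 3))

    def test_fbeta_equals_p_when_p_equals_r(self):
        for p in (0.2, 0.5, 0.9):
            tp = int(p * 100)
            c = ConfusionCounts(TP=tp, FP=100 - tp, FN=100 - tp)
            for beta in (0.125, 1.0, 8.0):
                assert precision_recall_f(c, beta)[2] == pytest.approx(p)

    def test_fbeta_hand_value(self):
        # P=1, R=0.5, beta=0.5 -> (1.25 * 0.5) / (0.25 + 0.5)
        c = ConfusionCounts(TP=1, FP=0, FN=1)
        assert precision_recall_f(c, beta=0.5)[2] == pytest.approx(1.25 * 0.5 / 0.75)

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError):
            precision_recall_f(ConfusionCounts(1, 1, 1), beta=0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, FN=0)


class TestPRCurve:
    def test_two_pair_enumeration(self):
        a, b = lm.GenePair("a", "x"), lm.GenePair("b", "y")
        curve = lm.pr_curve({a: 0.9, b: 0.1}, {a: True, b: False})
        lo = curve[curve.threshold == 0.1].iloc[0]
        hi = curve[curve.threshold == 0.9].iloc[0]
        assert (hi.precision, hi.recall) == (1.0, 1.0)
        assert (lo.precision, lo.recall) == (0.5, 1.0)

    def test_tied_scores_collapse_to_one_point(self):
        a, b = lm.GenePair("a", "x"), lm.GenePair("b", "y")
        curve = lm.pr_curve({a: 0.5, b: 0.5}, {a: True, b: False})
        assert len(curve) == 1

    def test_recall_non_increasing_in_threshold(self):
        rng = np.random.default_rng(2)
        scores = {lm.GenePair(f"g{i}", f"h{i}"): float(rng.random()) for i in range(60)}
        labels = {p: rng.random() < 0.5 for p in scores}
        if not any(labels.values()):
            labels[next(iter(labels))] = True
        curve = lm.pr_curve(scores, labels)
        assert (np.diff(curve.recall.to_numpy()) <= 1e-12).all()

    def test_unpooled_reference_inflates_fn_denominator(self):
        a = lm.GenePair("a", "x")
        curve = lm.pr_curve({a: 1.0}, {a: True}, reference_total=4)
        assert curve.iloc[0].recall == pytest.approx(0.25)


class TestJaccardAndWeights:
    def test_jaccard_values(self):
        assert lm.jaccard({"x", "y"}, {"x", "y"}) == 1.0
        assert lm.jaccard({"x"}, {"y"}) == 0.0
        assert lm.jaccard({"x", "y"}, {"y", "z"}) == pytest.approx(1 / 3)
        with pytest.raises(ValueError):
            lm.jaccard(set(), set())

    def test_weight_correlation(self):
        m1, m2 = make_model([1, 2, 3]), make_model([1, 2, 4])
        expected = stats.pearsonr([1, 2, 3], [1, 2, 4]).statistic
        assert lm.weight_correlation(m1, m2) == pytest.approx(expected)
        assert expected == pytest.approx(0.98198, abs=1e-5)
        assert lm.weight_correlation(m1, m1) == pytest.approx(1.0)
        assert lm.weight_correlation(m1, make_model([-1, -2, -3])) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            lm.weight_correlation(m1, make_model([2, 2, 2]))
        with pytest.raises(ValueError):
            lm.weight_correlation(m1, make_model([1, 2]))
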