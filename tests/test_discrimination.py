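import math

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.linear_model import LinearRegression
from sklearn.metrics import silhouette_score

from metabotype import (
    confusion_metrics,
    fit_pls_lda,
    loo_cross_validate,
    pca_overview,
    regress_against_score,
)
from metabotype.discrimination import (
    PLSLDAClassifier,
    confusion_from_predictions,
    round_half_up,
)
from metabotype.preprocessing import internal_standard_ratio, zscore_normalize


def two_clouds(n=20, p=8, offset=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X[n // 2 :, 0] += offset
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    return X, y


# ----------------------------------------------------------------------
# confusion metrics


@pytest.mark.parametrize(
    "counts, expected",
    [
        # printed prediction-statistics table for the two genotypes
        ((8, 1, 9, 4), dict(recall=0.67, precision=0.89, sensitivity=0.67,
                            specificity=0.90, f_measure=0.76, accuracy=0.77,
                            kappa=0.55)),
        ((9, 4, 8, 1), dict(recall=0.90, precision=0.69, sensitivity=0.90,
                            specificity=0.67, f_measure=0.78, accuracy=0.77,
                            kappa=0.55)),
    ],
)
def test_confusion_metrics_match_printed_table(counts, expected):
    m = confusion_metrics(*counts)
    for name, want in expected.items():
        assert round_half_up(getattr(m, name), 2) == want, name


def test_perfect_prediction_all_ones():
    m = confusion_metrics(10, 0, 10, 0)
    assert m.recall == m.precision == m.specificity == m.accuracy == m.kappa == 1.0


def test_undefined_ratios_flagged_not_zero():
    m = confusion_metrics(0, 0, 10, 0)
    assert math.isnan(m.recall)
    assert "recall" in m.undefined
    assert m.specificity == 1.0


def test_counts_validated():
    with pytest.raises(ValueError):
        confusion_metrics(-1, 0, 1, 0)


# ----------------------------------------------------------------------
# PLS-LDA


def test_separable_clouds_perfect_training_accuracy():
    X, y = two_clouds()
    model = fit_pls_lda(X, y, n_components=5)
    assert (model.predict(X) == y).all()


def test_loo_on_separable_data_is_perfect():
    X, y = two_clouds()
    result = loo_cross_validate(X, y, n_components=5)
    assert result.accuracy == 1.0
    assert result.kappa == 1.0


def test_components_capped_with_warning():
    X, y = two_clouds(n=6, p=3)
    model = fit_pls_lda(X, y, n_components=10)
    assert model.effective_components_ == 3
    assert model.warnings_


def test_loo_rejects_singleton_class():
    X = np.random.default_rng(0).normal(size=(5, 3))
    y = np.array(["A", "A", "A", "A", "B"])
    with pytest.raises(ValueError, match="single sample"):
        loo_cross_validate(X, y)


def test_permuted_labels_give_chance_level_accuracy():
    """LOO accuracy under label permutation sits in the binomial chance band."""
    rng = np.random.default_rng(3)
    n, p = 24, 40
    X = rng.normal(size=(n, p))
    y = np.array(["A", "B"] * (n // 2))
    accs = []
    for _ in range(50):
        perm = rng.permutation(y)
        accs.append(loo_cross_validate(X, perm, n_components=5).accuracy)
    lo, hi = sps.binom.interval(0.95, n, 0.5)
    assert lo / n <= float(np.mean(accs)) <= hi / n


def test_feature_order_and_zero_padding_invariance():
    X, y = two_clouds(offset=3.0, seed=5)
    base = fit_pls_lda(X, y).predict(X)
    rng = np.random.default_rng(1)
    perm = rng.permutation(X.shape[1])
    shuffled = fit_pls_lda(X[:, perm], y).predict(X[:, perm])
    padded = fit_pls_lda(np.hstack([X, np.zeros((len(y), 3))]), y).predict(
        np.hstack([X, np.zeros((len(y), 3))])
    )
    assert (base == shuffled).all()
    assert (base == padded).all()


def test_full_component_pls_matches_least_squares():
    """PLS with all components reproduces OLS fitted responses."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(20, 5))
    y = np.array(["A"] * 10 + ["B"] * 10)
    model = fit_pls_lda(X, y, n_components=5)
    Y = np.stack([(y == c).astype(float) for c in model.classes_], axis=1)
    ols = LinearRegression().fit(X, Y)
    assert np.allclose(model.decision_function(X), ols.predict(X), atol=1e-8)


def test_lda_readout_agrees_on_separable_data():
    X, y = two_clouds()
    a = fit_pls_lda(X, y, readout="argmax").predict(X)
    b = fit_pls_lda(X, y, readout="lda").predict(X)
    assert (a == b).all()


def test_genotype_discrimination_beats_permuted_null(small_cohort):
    """The genotype effect in the synthetic cohort is learnable by LOO PLS-LDA."""
    m = zscore_normalize(small_cohort)
    bio = m.biological()
    X = bio.intensities.to_numpy()
    y = bio.sample_meta["genotype"].to_numpy()
    obs = loo_cross_validate(X, y, n_components=5).accuracy
    rng = np.random.default_rng(11)
    null = [
        loo_cross_validate(X, rng.permutation(y), n_components=5).accuracy
        for _ in range(20)
    ]
    assert obs > np.quantile(null, 0.95)


def test_confusion_from_predictions_totals():
    y = np.array(["A", "A", "B", "B", "B"])
    pred = np.array(["A", "B", "B", "B", "A"])
    res = confusion_from_predictions(y, pred)
    for c, cm in res.per_class.items():
        assert cm.tp + cm.fp + cm.tn + cm.fn == len(y)
    assert res.accuracy == pytest.approx(3 / 5)


# ----------------------------------------------------------------------
# regression against colitis score


def test_exact_linear_single_feature_recovered():
    rng = np.random.default_rng(6)
    x = rng.normal(size=(15, 1))
    scores = 2.0 * x[:, 0] + 1.0
    diag = regress_against_score(x, scores, method="pls", n_components=1)
    assert np.allclose(diag.predicted, diag.observed, atol=1e-6)
    assert diag.q2 > 0.999


def test_noiseless_combination_of_five_features():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(60, 20))
    w = np.zeros(20)
    w[:5] = [1.0, -2.0, 0.5, 3.0, -1.0]
    scores = X @ w
    diag = regress_against_score(X, scores, method="pls", n_components=5)
    assert diag.q2 > 0.9
    assert abs(diag.slope - 1.0) < 0.1


def test_null_scores_give_nonpositive_q2():
    """Scores independent of features: Q² ≤ 0 in expectation, slope ≈ 0."""
    rng = np.random.default_rng(8)
    q2s, slopes = [], []
    for _ in range(50):
        X = rng.normal(size=(16, 10))
        scores = rng.normal(size=16)
        diag = regress_against_score(X, scores, method="pls", n_components=3)
        q2s.append(diag.q2)
        slopes.append(diag.slope)
    assert np.mean(q2s) < 0
    assert abs(np.mean(slopes)) < 0.2


def test_rf_regression_deterministic_given_seed():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(12, 6))
    scores = rng.normal(size=12)
    a = regress_against_score(X, scores, method="rf", n_estimators=30, seed=5)
    b = regress_against_score(X, scores, method="rf", n_estimators=30, seed=5)
    assert np.array_equal(a.predicted, b.predicted)


def test_constant_scores_rejected():
    X = np.random.default_rng(0).normal(size=(6, 3))
    with pytest.raises(ValueError, match="constant"):
        regress_against_score(X, np.ones(6))


# ----------------------------------------------------------------------
# PCA overview


def test_explained_fractions_valid(small_cohort):
    res = pca_overview(zscore_normalize(small_cohort), n_components=5)
    e = res.explained
    assert (np.diff(e) <= 1e-12).all()
    assert e.sum() <= 1.0 + 1e-9


def test_rank_one_data_explained_fully():
    u = np.arange(6, dtype=float)[:, None]
    v = np.array([[1.0, 2.0, 3.0]])
    res = pca_overview(u @ v, n_components=2)
    assert res.explained[0] == pytest.approx(1.0)


def test_pca_sign_convention_deterministic(rng):
    X = rng.normal(size=(15, 6))
    a = pca_overview(X, n_components=3)
    b = pca_overview(X.copy(), n_components=3)
    assert np.allclose(a.coordinates.to_numpy(), b.coordinates.to_numpy())


def test_age_dominates_genotype_in_pca(small_cohort):
    """With age effect on many features, PC1-2 separate age better than genotype."""
    fm = small_cohort.feature_meta
    std_id = fm.index[fm["is_internal_standard"]][0]
    m = internal_standard_ratio(small_cohort.biological(), std_id)
    m = zscore_normalize(m)
    res = pca_overview(m, n_components=2)
    coords = res.coordinates.to_numpy()
    meta = m.sample_meta
    sil_age = silhouette_score(coords, meta["age_group"])
    sil_geno = silhouette_score(coords, meta["genotype"])
    assert sil_age > sil_geno
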