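import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabotype import FeatureMatrix
from metabotype.preprocessing import (
    compute_qc_stats,
    correlation_filter,
    internal_standard_ratio,
    noise_threshold_filter,
    qc_reliability_filter,
    singleton_filter,
    zscore_normalize,
)

from conftest import small_config
from metabotype import generate_cohort


def matrix_from_array(X, qc_rows=0, feature_ids=None):
    n, p = X.shape
    sample_ids = [f"s{i}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j}" for j in range(p)]
    qc = np.zeros(n, bool)
    if qc_rows:
        qc[-qc_rows:] = True
    return FeatureMatrix(
        pd.DataFrame(X, index=sample_ids, columns=feature_ids),
        pd.DataFrame({"qc_flag": qc}, index=sample_ids),
        pd.DataFrame(index=pd.Index(feature_ids)),
    )


# ----------------------------------------------------------------------
# noise threshold


def test_noise_threshold_zero_is_identity(small_cohort):
    out, rep = noise_threshold_filter(small_cohort, 0.0)
    assert out.n_features == small_cohort.n_features
    assert rep.removed == []


def test_noise_threshold_removes_low_max_column():
    X = np.full((4, 3), 2e5)
    X[:, 1] = 5e4  # max below the 1e5 threshold
    m = matrix_from_array(X)
    out, rep = noise_threshold_filter(m, 1e5)
    assert rep.removed == ["f1"]
    assert list(out.feature_ids) == ["f0", "f2"]


def test_noise_threshold_monotone_in_threshold(small_cohort):
    out_low, _ = noise_threshold_filter(small_cohort, 1e5)
    out_high, _ = noise_threshold_filter(small_cohort, 1e6)
    assert out_high.n_features <= out_low.n_features


def test_qc_max_ignored_for_threshold(small_cohort):
    """The max is taken over study samples; QC rows don't rescue a feature."""
    m = small_cohort.copy()
    X = m.intensities.to_numpy().copy()
    j = 0
    X[~m.qc_mask, j] = 10.0
    X[m.qc_mask, j] = 1e9
    m = m.with_intensities(
        pd.DataFrame(X, index=m.sample_ids, columns=m.feature_ids)
    )
    out, rep = noise_threshold_filter(m, 1e5)
    assert m.feature_ids[j] in rep.removed


# ----------------------------------------------------------------------
# QC reliability


def test_identical_qc_intensities_have_zero_rsd():
    X = np.vstack([np.full((3, 2), 5e5), np.full((4, 2), 7e5)])
    m = matrix_from_array(X, qc_rows=4)
    stats = compute_qc_stats(m)
    assert np.allclose(stats.area_rsd, 0.0)
    out, _, rep = qc_reliability_filter(m)
    assert rep.removed == []


def test_half_present_feature_removed_for_presence():
    X = np.ones((6, 2)) * 1e5
    X[2:, 1] = [1e5, 1e5, 0.0, 0.0]  # QC intensities (100k,100k,0,0)
    m = matrix_from_array(X, qc_rows=4)
    stats = compute_qc_stats(m)
    assert stats.qc_presence["f1"] == pytest.approx(0.5)
    out, _, rep = qc_reliability_filter(m, min_presence=0.8)
    assert "f1" in rep.removed


def test_rt_criterion_skipped_without_observations():
    X = np.full((5, 2), 1e5)
    m = matrix_from_array(X, qc_rows=3)
    _, _, rep = qc_reliability_filter(m)
    assert any("RT" in note for note in rep.notes)
    assert rep.params["max_rt_rsd"] is None


def test_rt_criterion_removes_jittery_feature(small_cohort):
    """Noise ions carry inflated RT jitter and fail the 5% RT RSD rule."""
    out, stats, rep = qc_reliability_filter(small_cohort)
    fm = small_cohort.feature_meta
    noise_ids = fm.index[fm["is_noise"]]
    # essentially all noise ions removed, genotype-effect ions kept
    removed = set(rep.removed)
    assert len(noise_ids.intersection(removed)) >= 0.9 * len(noise_ids)
    geno_ids = fm.index[fm["is_genotype_feature"]]
    assert len(geno_ids.intersection(removed)) <= 0.1 * len(geno_ids)


def test_too_few_qc_rows_is_an_error():
    m = matrix_from_array(np.ones((4, 2)), qc_rows=1)
    with pytest.raises(ValueError, match="at least 2 pooled-QC"):
        qc_reliability_filter(m)


# ----------------------------------------------------------------------
# singleton removal


def test_singleton_features_removed():
    X = np.zeros((5, 3))
    X[:, 0] = 1e5          # everywhere
    X[2, 1] = 1e5          # exactly one sample
    m = matrix_from_array(X)
    out, rep = singleton_filter(m)
    assert set(rep.removed) == {"f1", "f2"}


# ----------------------------------------------------------------------
# correlation filter


def test_exact_duplicate_column_removed(rng):
    X = rng.normal(size=(10, 4))
    X[:, 2] = X[:, 0]
    m = matrix_from_array(X)
    out, rep = correlation_filter(m, threshold=0.98)
    assert rep.removed == ["f2"]


def test_threshold_one_with_jitter_is_identity(rng):
    base = rng.normal(size=10)
    X = np.stack([base + rng.normal(scale=0.05, size=10) for _ in range(5)], axis=1)
    m = matrix_from_array(X)
    out, rep = correlation_filter(m, threshold=1.0)
    assert rep.removed == []


def test_retained_set_is_pairwise_below_threshold(rng):
    """Brute-force check: no surviving pair with |r| >= 0.98."""
    base = rng.normal(size=(20, 10))
    # build 50 columns as noisy copies of 10 bases -> many high correlations
    cols = [base[:, j % 10] + rng.normal(scale=0.01 * (1 + j % 3), size=20) for j in range(50)]
    m = matrix_from_array(np.stack(cols, axis=1))
    out, rep = correlation_filter(m, threshold=0.98)
    assert len(rep.removed) > 0
    R = np.corrcoef(out.intensities.to_numpy(), rowvar=False)
    np.fill_diagonal(R, 0.0)
    assert np.abs(R).max() < 0.98


def test_constant_columns_retained_and_noted(rng):
    X = rng.normal(size=(8, 3))
    X[:, 1] = 5.0
    m = matrix_from_array(X)
    out, rep = correlation_filter(m)
    assert "f1" in out.feature_ids
    assert any("constant" in n for n in rep.notes)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=4), st.integers(min_value=0, max_value=9999))
def test_appending_duplicate_of_retained_column_changes_nothing(col, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(12, 5))
    m = matrix_from_array(X)
    out, _ = correlation_filter(m)
    if f"f{col}" not in out.feature_ids:
        return
    X2 = np.column_stack([X, X[:, col]])
    m2 = matrix_from_array(X2, feature_ids=[f"f{j}" for j in range(5)] + ["dup"])
    out2, rep2 = correlation_filter(m2)
    assert "dup" in rep2.removed
    assert list(out2.feature_ids) == list(out.feature_ids)


# ----------------------------------------------------------------------
# z-score normalization


def test_zscore_column_mean_zero_sd_one():
    m = matrix_from_array(np.array([[1.0], [2.0], [3.0]]))
    out = zscore_normalize(m)
    col = out.intensities["f0"]
    assert col.mean() == pytest.approx(0.0, abs=1e-12)
    assert col.std(ddof=0) == pytest.approx(1.0)


def test_zscore_constant_column_flagged_zero():
    X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
    out = zscore_normalize(matrix_from_array(X))
    assert (out.intensities["f1"] == 0).all()
    assert out.feature_meta.loc["f1", "zero_variance"]
    assert not out.feature_meta.loc["f0", "zero_variance"]


def test_zscore_uses_study_samples_only():
    """QC rows are transformed with µ,σ of the study samples."""
    X = np.array([[0.0], [2.0], [100.0]])
    m = matrix_from_array(X, qc_rows=1)
    out = zscore_normalize(m)
    # µ=1, σ=1 from the two study samples; QC row maps to 99
    assert out.intensities["f0"].tolist() == [-1.0, 1.0, 99.0]


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=9999))
def test_zscore_idempotent(seed):
    rng = np.random.default_rng(seed)
    m = matrix_from_array(rng.lognormal(size=(6, 4)))
    once = zscore_normalize(m)
    twice = zscore_normalize(once)
    assert np.allclose(
        once.intensities.to_numpy(), twice.intensities.to_numpy(), atol=1e-10
    )


# ----------------------------------------------------------------------
# internal-standard ratio


def test_standard_column_becomes_ones(small_cohort):
    std_id = small_cohort.feature_meta.index[
        small_cohort.feature_meta["is_internal_standard"]
    ][0]
    out = internal_standard_ratio(small_cohort, std_id)
    assert np.allclose(out.intensities[std_id], 1.0)


def test_ratio_cancels_dilution():
    """Ratioing to one standard collapses another standard's CV below 5%."""
    m = generate_cohort(small_config(dilution_cv=0.3, seed=9))
    fm = m.feature_meta
    std_ids = fm.index[fm["is_internal_standard"]]
    bio = m.biological()
    before = bio.intensities[std_ids[1]]
    assert before.std(ddof=1) / before.mean() > 0.15  # dilution dominates
    out = internal_standard_ratio(bio, std_ids[0])
    after = out.intensities[std_ids[1]]
    assert after.std(ddof=1) / after.mean() < 0.05


def test_uniform_dilution_is_identity():
    X = np.column_stack([np.full(4, 1.0), np.array([1.0, 2.0, 3.0, 4.0])])
    m = matrix_from_array(X)
    out = internal_standard_ratio(m, "f0")
    assert np.allclose(out.intensities.to_numpy(), X)


def test_zero_standard_names_the_sample():
    X = np.array([[1.0, 2.0], [0.0, 3.0]])
    m = matrix_from_array(X)
    with pytest.raises(ValueError, match="s1"):
        internal_standard_ratio(m, "f0")


# ----------------------------------------------------------------------
# chain properties


def test_filter_chain_never_touches_samples(small_cohort):
    m = small_cohort
    m1, _ = noise_threshold_filter(m, 1e5)
    m2, _, _ = qc_reliability_filter(m1)
    m3, _ = correlation_filter(m2)
    for stage in (m1, m2, m3):
        assert list(stage.sample_ids) == list(m.sample_ids)
    assert m3.n_features <= m2.n_features <= m1.n_features <= m.n_features
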