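"""Feature-permutation significance testing via classification cross-entropy.

The procedure identifies mass ions that contribute to class
discrimination. A random-forest classifier is fitted ``n_repeats``
times on the unpermuted data with distinct derived seeds, and the
cross-entropy of its class-probability estimates for the true labels
is recorded each time, giving a baseline mean and sigma. Then, for
each feature in turn, the feature's column is permuted across samples
(a fresh permutation per repeat), the classifier refitted and the
cross-entropy recomputed; the repeat mean is compared with the
baseline. A feature whose mean cross-entropy increase exceeds
``z_crit · sigma`` (default 1.96·σ) is flagged as significant;
one-sided normal p-values p = P(Z > Δ/σ) are reported alongside and
corrected by Storey's q-value method.

Cross-entropy is evaluated on out-of-bag probability estimates by
default (no extra data split, honest error); training-set evaluation
is available via ``eval_on='train'``. Because the permuted mean
averages over repeats, the Δ > 1.96·σ rule is conservative under the
null — its false-positive rate is well below the nominal one-sided
2.5% (see the methods note). The reported p-values therefore use the
standard error of the difference of two repeat means,
se = σ·sqrt(1/R_perm + 1/R_base), which is approximately uniform
under the null and hence valid input for Storey's estimator;
``p_scale='single'`` reproduces the cruder p = P(Z > Δ/σ) instead.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .containers import FeatureMatrix
from .discrimination import _extract_xy

__all__ = [
    "RandomForestSpec",
    "PermutationImportanceResult",
    "classification_cross_entropy",
    "baseline_cross_entropy",
    "permutation_feature_test",
    "storey_qvalues",
    "storey_pi0",
    "benjamini_hochberg",
]

_MAX_SEED = 2**31 - 1


@dataclasses.dataclass
class RandomForestSpec:
    """Random-forest hyperparameters used throughout the test."""

    n_estimators: int = 500
    max_features: str | float = "sqrt"
    max_depth: int | None = None

    def build(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            oob_score=True,
            bootstrap=True,
            random_state=int(seed),
            n_jobs=1,
        )


def classification_cross_entropy(
    prob_matrix, labels, classes=None, eps: float = 1e-15
) -> float:
    """−(1/N)·Σ log p̂(true class), natural log (nats).

    ``prob_matrix`` rows must sum to 1 (within 1e-9); columns follow
    ``classes`` (default: sorted unique labels). Probabilities are
    floored at ``eps`` before the log.
    """
    P = np.asarray(prob_matrix, dtype=float)
    y = np.asarray(labels)
    if P.ndim != 2 or P.shape[0] != len(y):
        raise ValueError("prob_matrix must be (n_samples, n_classes) matching labels")
    sums = P.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError("probability rows must sum to 1 (within 1e-9)")
    if classes is None:
        classes = np.unique(y)
    classes = np.asarray(classes)
    col = {c: j for j, c in enumerate(classes)}
    try:
        idx = np.array([col[c] for c in y])
    except KeyError as e:
        raise ValueError(f"label {e.args[0]!r} not in the class set") from None
    p_true = np.maximum(P[np.arange(len(y)), idx], eps)
    return float(-np.mean(np.log(p_true)))


def _oob_cross_entropy(clf: RandomForestClassifier, y: np.ndarray, eps: float) -> float:
    """Cross-entropy of the fitted forest's out-of-bag probabilities.

    Samples that never fell out of bag (vanishingly rare for >25
    trees) get uniform probabilities.
    """
    P = clf.oob_decision_function_.copy()
    bad = ~np.isfinite(P).all(axis=1) | (P.sum(axis=1) == 0)
    if bad.any():
        P[bad] = 1.0 / P.shape[1]
    P = P / P.sum(axis=1, keepdims=True)
    return classification_cross_entropy(P, y, classes=clf.classes_, eps=eps)


def _train_cross_entropy(clf, X, y, eps: float) -> float:
    return classification_cross_entropy(
        clf.predict_proba(X), y, classes=clf.classes_, eps=eps
    )


def _repeat_ces(
    X: np.ndarray,
    y: np.ndarray,
    rf: RandomForestSpec,
    seeds: np.ndarray,
    eval_on: str,
    eps: float,
) -> np.ndarray:
    ces = np.empty(len(seeds))
    for r, s in enumerate(seeds):
        clf = rf.build(s)
        clf.fit(X, y)
        if eval_on == "oob":
            ces[r] = _oob_cross_entropy(clf, y, eps)
        else:
            ces[r] = _train_cross_entropy(clf, X, y, eps)
    return ces


def baseline_cross_entropy(
    m: FeatureMatrix | np.ndarray,
    labels,
    n_repeats: int = 100,
    seed: int = 0,
    rf: RandomForestSpec | None = None,
    eval_on: str = "oob",
    eps: float = 1e-15,
) -> tuple[float, float]:
    """Mean and sigma of the unpermuted cross-entropy over ``n_repeats`` fits.

    Each repeat refits the forest with a distinct seed derived from
    ``seed``; sigma is the sample standard deviation across repeats.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 (sigma undefined otherwise)")
    X, y = _extract_xy(m, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    spec = rf or RandomForestSpec()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, _MAX_SEED, size=n_repeats)
    ces = _repeat_ces(X, y, spec, seeds, eval_on, eps)
    return float(ces.mean()), float(ces.std(ddof=1))


@dataclasses.dataclass
class PermutationImportanceResult:
    """Outcome of the feature-permutation cross-entropy test.

    ``features`` has one row per feature, sorted by delta descending:
    ``permuted_mean_ce``, ``delta`` (permuted − baseline mean),
    ``significant`` (delta > z_crit·sigma), ``p_value``, ``q_value``.
    """

    baseline_mean_ce: float
    baseline_sigma: float
    features: pd.DataFrame
    n_repeats: int
    z_crit: float
    classifier: RandomForestSpec
    seed: int
    pi0: float
    p_scale: str = "difference"

    def to_dict(self) -> dict:
        return {
            "baseline_mean_ce": self.baseline_mean_ce,
            "baseline_sigma": self.baseline_sigma,
            "n_repeats": self.n_repeats,
            "z_crit": self.z_crit,
            "classifier": dataclasses.asdict(self.classifier),
            "seed": self.seed,
            "pi0": self.pi0,
            "p_scale": self.p_scale,
            "features": self.features.reset_index()
            .rename(columns={"index": "feature_id"})
            .to_dict(orient="records"),
        }


def permutation_feature_test(
    m: FeatureMatrix | np.ndarray,
    labels,
    n_repeats: int = 100,
    z_crit: float = 1.96,
    seed: int = 0,
    rf: RandomForestSpec | None = None,
    eval_on: str = "oob",
    fresh_permutation: bool = True,
    eps: float = 1e-15,
    p_scale: str = "difference",
) -> PermutationImportanceResult:
    """Permute each feature column and test the cross-entropy increase.

    All randomness (repeat seeds and permutations) derives from
    ``seed``; ``fresh_permutation=False`` reuses one permutation per
    feature across repeats instead of drawing a new one each repeat.
    ``p_scale`` selects the denominator of the normal p-value: the
    standard error of the difference of repeat means (``'difference'``,
    default, null-uniform) or the raw baseline sigma (``'single'``,
    conservative).
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 (sigma undefined otherwise)")
    X, y = _extract_xy(m, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    spec = rf or RandomForestSpec()
    feature_ids = (
        m.feature_ids if isinstance(m, FeatureMatrix) else pd.RangeIndex(X.shape[1])
    )
    rng = np.random.default_rng(seed)
    base_seeds = rng.integers(0, _MAX_SEED, size=n_repeats)
    base_ces = _repeat_ces(X, y, spec, base_seeds, eval_on, eps)
    base_mean = float(base_ces.mean())
    sigma = float(base_ces.std(ddof=1))

    n, p = X.shape
    perm_mean = np.empty(p)
    for j in range(p):
        fit_seeds = rng.integers(0, _MAX_SEED, size=n_repeats)
        Xp = X.copy()
        if not fresh_permutation:
            Xp[:, j] = X[rng.permutation(n), j]
        ces = np.empty(n_repeats)
        for r in range(n_repeats):
            if fresh_permutation:
                Xp[:, j] = X[rng.permutation(n), j]
            clf = spec.build(fit_seeds[r])
            clf.fit(Xp, y)
            ces[r] = (
                _oob_cross_entropy(clf, y, eps)
                if eval_on == "oob"
                else _train_cross_entropy(clf, Xp, y, eps)
            )
        perm_mean[j] = ces.mean()

    delta = perm_mean - base_mean
    significant = delta > z_crit * sigma
    if p_scale == "difference":
        se = sigma * np.sqrt(2.0 / n_repeats)
    elif p_scale == "single":
        se = sigma
    else:
        raise ValueError(f"unknown p_scale {p_scale!r}")
    if se > 0:
        p_values = sps.norm.sf(delta / se)
    else:
        p_values = np.where(delta > 0, 0.0, 1.0)
    q_values, pi0 = storey_qvalues(p_values, return_pi0=True)
    features = pd.DataFrame(
        {
            "permuted_mean_ce": perm_mean,
            "delta": delta,
            "significant": significant,
            "p_value": p_values,
            "q_value": q_values,
        },
        index=feature_ids,
    ).sort_values("delta", ascending=False)
    return PermutationImportanceResult(
        baseline_mean_ce=base_mean,
        baseline_sigma=sigma,
        features=features,
        n_repeats=n_repeats,
        z_crit=z_crit,
        classifier=spec,
        seed=seed,
        pi0=pi0,
        p_scale=p_scale,
    )


# ----------------------------------------------------------------------
# multiple-testing corrections


def storey_pi0(
    p_values, lambdas: np.ndarray | None = None
) -> float:
    """Estimate the null proportion π0 from the p-value distribution.

    For fewer than 100 p-values the conservative moment estimate
    min(1, 2·mean(p)) is used. Otherwise π̂0(λ) = #{p > λ}/(m(1−λ)) is
    computed on a λ grid (default 0.05…0.95 step 0.05) and a cubic
    least-squares smoother is extrapolated to λ = 1.
    """
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    m = p.size
    if m == 0:
        return 1.0
    if m < 100:
        return float(min(1.0, 2.0 * p.mean()))
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, 1.0))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def _check_pvalues(p: np.ndarray) -> None:
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")


def storey_qvalues(p_values, pi0: float | None = None, return_pi0: bool = False):
    """Storey q-values: q_j = min over p_i ≥ p_j of π̂0·m·p_i/rank(p_i).

    With ``pi0`` forced to 1 this reduces exactly to Benjamini–Hochberg
    adjusted p-values. Output is clipped to [0, 1] and monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    m = p.size
    if m == 0:
        q = np.empty(0)
        return (q, 1.0) if return_pi0 else q
    if pi0 is None:
        pi0 = storey_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return (q, float(pi0)) if return_pi0 else q


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [0,1])."""
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    if p.size == 0:
        return np.empty(0)
    return multipletests(p, method="fdr_bh")[1]
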