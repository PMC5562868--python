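"""Supervised discrimination of sample classes from metabolite profiles.

PLS-LDA here means: partial least squares regression of the feature
matrix on a one-hot encoding of the class labels (latent variables
extracted by iterative deflation, as in NIPALS), followed by a linear
discriminant read-out of the predicted responses. The default read-out
assigns each sample to the class with the maximal predicted response
(ties broken toward the class listed first in the encoding); an
alternative read-out fitting a linear discriminant on the latent
scores is available via ``readout='lda'``.

Model quality is assessed by leave-one-out cross-validation with full
confusion statistics (per-class TP/FP/TN/FN, recall, precision,
sensitivity, specificity, F-measure, overall accuracy and Cohen's
kappa). With many more features than samples LOO accuracy can be
optimistic; the confusion result carries a warning to that effect.
"""

from __future__ import annotations

import dataclasses
import decimal
import math
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestRegressor

from .containers import FeatureMatrix

__all__ = [
    "PLSLDAClassifier",
    "ConfusionMetrics",
    "ConfusionResult",
    "RegressionDiagnostics",
    "OrdinationResult",
    "fit_pls_lda",
    "loo_cross_validate",
    "confusion_metrics",
    "regress_against_score",
    "pca_overview",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.675 → 0.68), as printed tables use."""
    if not math.isfinite(x):
        return x
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


# ----------------------------------------------------------------------
# PLS-LDA


class PLSLDAClassifier:
    """PLS regression on one-hot classes with a discriminant read-out.

    Parameters
    ----------
    n_components
        Number of latent variables. Capped at min(n_samples − 1,
        n_features); a cap is recorded in ``warnings_``.
    readout
        ``'argmax'`` (default): predict the class whose one-hot
        response estimate is maximal. ``'lda'``: fit a linear
        discriminant on the latent scores and predict with it.

    The fit is fully deterministic.
    """

    def __init__(self, n_components: int = 5, readout: Literal["argmax", "lda"] = "argmax"):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if readout not in ("argmax", "lda"):
            raise ValueError(f"unknown readout {readout!r}")
        self.n_components = n_components
        self.readout = readout

    # -- sklearn-style API -------------------------------------------------
    def fit(self, X, y) -> "PLSLDAClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        # class order = order of first appearance; ties in the read-out
        # resolve toward the earlier class
        self.classes_ = pd.unique(pd.Series(y))
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.warnings_: list[str] = []
        k = min(self.n_components, X.shape[0] - 1, X.shape[1])
        if k < self.n_components:
            self.warnings_.append(
                f"n_components reduced from {self.n_components} to {k} "
                f"for n={X.shape[0]}, p={X.shape[1]}"
            )
        self.effective_components_ = k
        Y = np.stack([(y == c).astype(float) for c in self.classes_], axis=1)
        self.pls_ = PLSRegression(n_components=k, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns when y residual is tiny
            self.pls_.fit(X, Y)
        if self.readout == "lda":
            scores = self.pls_.transform(X)
            self.lda_ = LinearDiscriminantAnalysis()
            self.lda_.fit(scores, y)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Predicted one-hot responses, columns ordered as ``classes_``."""
        return self.pls_.predict(np.asarray(X, dtype=float))

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.readout == "lda":
            return self.lda_.predict(self.pls_.transform(X))
        resp = self.decision_function(X)
        # argmax returns the first maximum: ties go to the earlier class
        return self.classes_[np.argmax(resp, axis=1)]

    # -- model internals ---------------------------------------------------
    @property
    def x_weights_(self) -> np.ndarray:
        return self.pls_.x_weights_

    @property
    def x_loadings_(self) -> np.ndarray:
        return self.pls_.x_loadings_

    @property
    def y_loadings_(self) -> np.ndarray:
        return self.pls_.y_loadings_

    @property
    def x_scores_(self) -> np.ndarray:
        return self.pls_.x_scores_


def _extract_xy(
    m: FeatureMatrix | np.ndarray | pd.DataFrame, labels
) -> tuple[np.ndarray, np.ndarray]:
    """Pull (X, y) out of a FeatureMatrix (QC rows excluded) or array."""
    if isinstance(m, FeatureMatrix):
        bio = ~m.qc_mask
        X = m.intensities.loc[bio].to_numpy(dtype=float)
        if isinstance(labels, str):
            y = m.sample_meta.loc[bio, labels].to_numpy()
        else:
            y = np.asarray(labels)[bio] if len(labels) == m.n_samples else np.asarray(labels)
    else:
        X = np.asarray(m, dtype=float)
        y = np.asarray(labels)
    if X.shape[0] != len(y):
        raise ValueError("labels length does not match sample count")
    return X, y


def fit_pls_lda(
    m: FeatureMatrix | np.ndarray,
    labels,
    n_components: int = 5,
    readout: Literal["argmax", "lda"] = "argmax",
) -> PLSLDAClassifier:
    """Fit a PLS-LDA model on the study samples (QC rows excluded)."""
    X, y = _extract_xy(m, labels)
    return PLSLDAClassifier(n_components=n_components, readout=readout).fit(X, y)


# ----------------------------------------------------------------------
# confusion statistics


_UNDEFINED = float("nan")


@dataclasses.dataclass
class ConfusionMetrics:
    """Binary (one-vs-rest) confusion counts and their derived rates.

    Ratios with a zero denominator are NaN and listed in ``undefined``
    rather than silently set to 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    recall: float
    precision: float
    sensitivity: float
    specificity: float
    f_measure: float
    accuracy: float
    kappa: float
    undefined: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Derive all confusion statistics from binary counts.

    recall = sensitivity = TP/(TP+FN); precision = TP/(TP+FP);
    specificity = TN/(TN+FP); F = 2·precision·recall/(precision+recall);
    accuracy = (TP+TN)/n; Cohen's kappa = (p_o − p_e)/(1 − p_e) with
    p_o the observed agreement and p_e the chance agreement from the
    marginals of the 2×2 table.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion table")
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return _UNDEFINED
        return num / den

    recall = ratio(tp, tp + fn, "recall")
    precision = ratio(tp, tp + fp, "precision")
    sensitivity = recall
    if "recall" in undefined:
        undefined.append("sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    if math.isnan(recall) or math.isnan(precision) or precision + recall == 0:
        undefined.append("f_measure")
        f_measure = _UNDEFINED
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / n
    # chance agreement from the 2x2 marginals
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
    if p_e == 1.0:
        undefined.append("kappa")
        kappa = _UNDEFINED
    else:
        kappa = (accuracy - p_e) / (1.0 - p_e)
    return ConfusionMetrics(
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
        recall=recall, precision=precision, sensitivity=sensitivity,
        specificity=specificity, f_measure=f_measure, accuracy=accuracy,
        kappa=kappa, undefined=undefined,
    )


@dataclasses.dataclass
class ConfusionResult:
    """Multi-class confusion summary from cross-validated predictions."""

    per_class: dict[str, ConfusionMetrics]
    accuracy: float
    kappa: float
    n: int
    warnings: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": {str(c): m.to_dict() for c, m in self.per_class.items()},
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "n": self.n,
            "warnings": self.warnings,
        }


def _multiclass_kappa(y_true: np.ndarray, y_pred: np.ndarray, classes) -> float:
    n = len(y_true)
    p_o = float(np.mean(y_true == y_pred))
    p_e = sum(
        (np.sum(y_true == c) / n) * (np.sum(y_pred == c) / n) for c in classes
    )
    if p_e == 1.0:
        return _UNDEFINED
    return (p_o - p_e) / (1.0 - p_e)


def confusion_from_predictions(y_true, y_pred, classes=None) -> ConfusionResult:
    """Aggregate per-class one-vs-rest confusion statistics."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = pd.unique(pd.Series(np.concatenate([y_true, y_pred])))
    per_class = {}
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        tn = int(np.sum((y_true != c) & (y_pred != c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        per_class[c] = confusion_metrics(tp, fp, tn, fn)
    return ConfusionResult(
        per_class=per_class,
        accuracy=float(np.mean(y_true == y_pred)),
        kappa=_multiclass_kappa(y_true, y_pred, classes),
        n=len(y_true),
    )


def loo_cross_validate(
    m: FeatureMatrix | np.ndarray,
    labels,
    n_components: int = 5,
    readout: Literal["argmax", "lda"] = "argmax",
) -> ConfusionResult:
    """Leave-one-out cross-validated PLS-LDA confusion statistics.

    Each sample is predicted by a model refit on all other samples;
    predictions are aggregated into per-class confusion counts and
    global accuracy / Cohen's kappa.
    """
    X, y = _extract_xy(m, labels)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        bad = classes[counts < 2].tolist()
        raise ValueError(
            f"class(es) {bad} have a single sample; the LOO fold holding it out "
            "would be untrainable"
        )
    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = PLSLDAClassifier(n_components=n_components, readout=readout)
        model.fit(X[mask], y[mask])
        preds[i] = model.predict(X[i : i + 1])[0]
    result = confusion_from_predictions(y, preds, pd.unique(pd.Series(y)))
    if X.shape[1] > 10 * n:
        result.warnings.append(
            "features greatly outnumber samples; leave-one-out estimates "
            "do not rule out over-fitting"
        )
    return result


# ----------------------------------------------------------------------
# regression against a continuous (colitis) score


@dataclasses.dataclass
class RegressionDiagnostics:
    """Cross-validated predictions of a continuous score plus summaries.

    ``slope``/``intercept`` describe the least-squares fit of predicted
    on observed (identity line = perfect calibration); ``q2`` is the
    cross-validated R², ≤ 1, negative when the model predicts worse
    than the mean.
    """

    observed: np.ndarray
    predicted: np.ndarray
    slope: float
    intercept: float
    q2: float
    method: str

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.tolist(),
            "predicted": self.predicted.tolist(),
            "slope": self.slope,
            "intercept": self.intercept,
            "q2": self.q2,
            "method": self.method,
        }


def regress_against_score(
    m: FeatureMatrix | np.ndarray,
    scores=None,
    method: Literal["pls", "rf"] = "pls",
    n_components: int = 5,
    n_estimators: int = 500,
    seed: int = 0,
) -> RegressionDiagnostics:
    """Leave-one-out regression of a continuous score on the features.

    ``scores`` may be a sample_meta column name (default
    ``'colitis_score'`` for a FeatureMatrix); samples with undefined
    scores are excluded. The random-forest branch is deterministic
    given ``seed``.
    """
    if isinstance(m, FeatureMatrix):
        if scores is None:
            scores = "colitis_score"
        X, y = _extract_xy(m, scores)
    else:
        X = np.asarray(m, dtype=float)
        y = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    X, y = X[ok], y[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 samples with defined scores")
    if np.ptp(y) == 0:
        raise ValueError("scores are constant; regression undefined")

    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if method == "pls":
            k = min(n_components, mask.sum() - 1, X.shape[1])
            reg = PLSRegression(n_components=k, scale=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reg.fit(X[mask], y[mask])
            preds[i] = float(np.ravel(reg.predict(X[i : i + 1]))[0])
        elif method == "rf":
            reg = RandomForestRegressor(
                n_estimators=n_estimators, max_features="sqrt", random_state=seed
            )
            reg.fit(X[mask], y[mask])
            preds[i] = float(reg.predict(X[i : i + 1])[0])
        else:
            raise ValueError(f"unknown method {method!r}")

    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - ss_res / ss_tot
    slope, intercept = np.polyfit(y, preds, 1)
    return RegressionDiagnostics(
        observed=y, predicted=preds, slope=float(slope),
        intercept=float(intercept), q2=q2, method=method,
    )


# ----------------------------------------------------------------------
# PCA overview


@dataclasses.dataclass
class OrdinationResult:
    """Sample coordinates on ordination axes with explained variance."""

    coordinates: pd.DataFrame  # samples × axes
    explained: np.ndarray  # fraction of total variance per axis
    negative_eigenvalues: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0)
    )

    def to_dict(self) -> dict:
        return {
            "coordinates": self.coordinates.to_dict(orient="index"),
            "explained": self.explained.tolist(),
            "negative_eigenvalues": self.negative_eigenvalues.tolist(),
        }


def pca_overview(
    m: FeatureMatrix | np.ndarray,
    n_components: int = 2,
    scale: bool = False,
    include_qc: bool = False,
) -> OrdinationResult:
    """Principal components of the (centered) feature table.

    Components are sorted by descending explained variance; the sign
    convention makes each component's largest-magnitude loading
    positive, so results are deterministic.
    """
    if isinstance(m, FeatureMatrix):
        keep = np.ones(m.n_samples, bool) if include_qc else ~m.qc_mask
        X = m.intensities.loc[keep].to_numpy(dtype=float)
        index = m.sample_ids[keep]
    else:
        X = np.asarray(m, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    k = min(n_components, X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=index, columns=[f"PC{j + 1}" for j in range(k)]
        ),
        explained=pca.explained_variance_ratio_.copy(),
    )
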