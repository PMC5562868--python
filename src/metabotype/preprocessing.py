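"""Reliability filtering and normalization of aligned feature tables.

The canonical chain, mirroring common untargeted LC-MS practice, is

    noise threshold → pooled-QC reliability → singleton removal →
    correlation filter → Z-score normalization

with optional internal-standard ratio normalization before Z-scoring.
Filters only ever remove feature columns; sample rows are never
reordered or dropped. Every filter returns a :class:`FilterReport`
so a pipeline run can record exactly what was removed and why.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import FeatureMatrix

__all__ = [
    "FilterReport",
    "QCStats",
    "noise_threshold_filter",
    "compute_qc_stats",
    "qc_reliability_filter",
    "singleton_filter",
    "correlation_filter",
    "zscore_normalize",
    "internal_standard_ratio",
]


@dataclasses.dataclass
class FilterReport:
    """Record of one feature-filtering step."""

    name: str
    params: dict
    n_in: int
    n_out: int
    removed: list[str]
    notes: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - len(self.removed):
            raise ValueError("inconsistent filter report: n_out != n_in - |removed|")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class QCStats:
    """Per-feature reproducibility statistics over pooled-QC injections.

    ``area_rsd``/``rt_rsd`` are sd/mean (dimensionless); NaN where the
    QC mean is zero (flagged via ``area_rsd_defined``).
    """

    table: pd.DataFrame  # columns: qc_presence, area_rsd, area_rsd_defined, rt_rsd

    @property
    def qc_presence(self) -> pd.Series:
        return self.table["qc_presence"]

    @property
    def area_rsd(self) -> pd.Series:
        return self.table["area_rsd"]

    @property
    def rt_rsd(self) -> pd.Series:
        return self.table["rt_rsd"]


def _rsd(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """sd/mean per column with a defined-mask; NaN where mean == 0."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    defined = mean != 0
    rsd = np.full(values.shape[1], np.nan)
    rsd[defined] = sd[defined] / mean[defined]
    return rsd, defined


def noise_threshold_filter(
    m: FeatureMatrix, threshold: float = 100_000.0
) -> tuple[FeatureMatrix, FilterReport]:
    """Drop features whose maximum intensity over study samples < threshold.

    The threshold is in raw intensity units (the instrument's noise
    floor; 100 000 in the default acquisition, 1 000 000 for the
    stricter re-processing).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    bio = m.intensities.loc[~m.qc_mask]
    max_int = bio.max(axis=0)
    removed = m.feature_ids[(max_int < threshold).to_numpy()].tolist()
    out = m.drop_features(removed)
    report = FilterReport(
        name="noise_threshold",
        params={"threshold": threshold},
        n_in=m.n_features,
        n_out=out.n_features,
        removed=removed,
    )
    return out, report


def compute_qc_stats(
    m: FeatureMatrix,
    rt_obs: pd.DataFrame | None = None,
    detection_floor: float = 0.0,
) -> QCStats:
    """QC presence fraction and peak-area / RT RSDs for every feature."""
    qc_rows = m.intensities.loc[m.qc_mask]
    if qc_rows.shape[0] < 2:
        raise ValueError(
            "QC statistics require at least 2 pooled-QC injections "
            f"(got {qc_rows.shape[0]}); flag QC rows via sample_meta['qc_flag']"
        )
    vals = qc_rows.to_numpy(dtype=float)
    presence = (vals > detection_floor).mean(axis=0)
    area_rsd, defined = _rsd(vals)
    rt_rsd = np.full(m.n_features, np.nan)
    if rt_obs is None and m.rt_obs is not None:
        rt_obs = m.rt_obs
    if rt_obs is not None:
        rt_vals = rt_obs.loc[m.sample_ids[m.qc_mask], m.feature_ids].to_numpy(float)
        rt_rsd, _ = _rsd(rt_vals)
    table = pd.DataFrame(
        {
            "qc_presence": presence,
            "area_rsd": area_rsd,
            "area_rsd_defined": defined,
            "rt_rsd": rt_rsd,
        },
        index=m.feature_ids,
    )
    return QCStats(table)


def qc_reliability_filter(
    m: FeatureMatrix,
    min_presence: float = 0.80,
    max_area_rsd: float = 0.30,
    max_rt_rsd: float = 0.05,
    rt_obs: pd.DataFrame | None = None,
    detection_floor: float = 0.0,
) -> tuple[FeatureMatrix, QCStats, FilterReport]:
    """Keep features reproducible across the pooled-QC injections.

    A feature passes when it is detected in at least ``min_presence``
    of the QC injections, its QC peak-area RSD is defined and at most
    ``max_area_rsd``, and (when per-sample retention times are
    available) its QC RT RSD is at most ``max_rt_rsd``. The RT
    criterion is skipped, and the report says so, when no RT
    observations exist.
    """
    stats = compute_qc_stats(m, rt_obs=rt_obs, detection_floor=detection_floor)
    t = stats.table
    keep = (t["qc_presence"] >= min_presence) & t["area_rsd_defined"] & (
        t["area_rsd"] <= max_area_rsd
    )
    notes = []
    have_rt = t["rt_rsd"].notna().any()
    if have_rt:
        keep &= t["rt_rsd"] <= max_rt_rsd
    else:
        notes.append("RT RSD criterion skipped: no per-sample RT observations supplied")
    removed = m.feature_ids[~keep.to_numpy()].tolist()
    out = m.drop_features(removed)
    report = FilterReport(
        name="qc_reliability",
        params={
            "min_presence": min_presence,
            "max_area_rsd": max_area_rsd,
            "max_rt_rsd": max_rt_rsd if have_rt else None,
        },
        n_in=m.n_features,
        n_out=out.n_features,
        removed=removed,
        notes=notes,
    )
    return out, stats, report


def singleton_filter(
    m: FeatureMatrix, detection_floor: float = 0.0
) -> tuple[FeatureMatrix, FilterReport]:
    """Drop features detected in at most one study (non-QC) sample."""
    bio = m.intensities.loc[~m.qc_mask]
    n_detected = (bio.to_numpy(float) > detection_floor).sum(axis=0)
    removed = m.feature_ids[n_detected <= 1].tolist()
    out = m.drop_features(removed)
    report = FilterReport(
        name="singleton",
        params={"detection_floor": detection_floor},
        n_in=m.n_features,
        n_out=out.n_features,
        removed=removed,
    )
    return out, report


def correlation_filter(
    m: FeatureMatrix,
    threshold: float = 0.98,
    method: Literal["pearson", "spearman"] = "pearson",
    keep: Literal["first", "variance"] = "first",
) -> tuple[FeatureMatrix, FilterReport]:
    """Greedy removal of highly inter-correlated features.

    Features are scanned in column order (or descending variance when
    ``keep='variance'``); each retained feature eliminates all
    later-scanned features whose absolute correlation with it reaches
    ``threshold``. The retained set therefore contains no pair with
    |r| >= threshold. Constant (zero-variance) columns have undefined
    correlations; they are treated as uncorrelated with everything and
    retained, which the report notes.
    """
    if m.n_samples < 2:
        raise ValueError("correlation filter requires at least 2 samples")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    X = m.intensities.to_numpy(dtype=float)
    if method == "spearman":
        X = sps.rankdata(X, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    sd = X.std(axis=0)
    constant = sd == 0
    Xc = X - X.mean(axis=0)
    denom = np.where(constant, 1.0, sd * np.sqrt(X.shape[0]))
    Z = Xc / denom  # unit-norm columns; constant ones are all-zero

    p = m.n_features
    if keep == "variance":
        order = np.argsort(-m.intensities.to_numpy(float).var(axis=0), kind="stable")
    elif keep == "first":
        order = np.arange(p)
    else:
        raise ValueError(f"unknown keep rule {keep!r}")

    alive = np.ones(p, dtype=bool)
    for pos, j in enumerate(order):
        if not alive[j] or constant[j]:
            continue
        later = order[pos + 1 :]
        later = later[alive[later] & ~constant[later]]
        if later.size == 0:
            continue
        r = Z[:, later].T @ Z[:, j]
        alive[later[np.abs(r) >= threshold - 1e-12]] = False

    removed = m.feature_ids[~alive].tolist()
    out = m.drop_features(removed)
    notes = []
    if constant.any():
        notes.append(
            f"{int(constant.sum())} constant column(s) treated as uncorrelated and retained"
        )
    report = FilterReport(
        name="correlation",
        params={"threshold": threshold, "method": method, "keep": keep},
        n_in=m.n_features,
        n_out=out.n_features,
        removed=removed,
        notes=notes,
    )
    return out, report


def zscore_normalize(m: FeatureMatrix) -> FeatureMatrix:
    """Z = (x − µ)/σ per feature, with µ, σ from the study samples.

    σ uses the population (n) denominator, the unit-variance scaling
    convention of the multivariate-analysis software the workflow
    follows. QC rows are transformed with the same µ and σ so they stay
    comparable. Zero-variance columns map to all-zero and are flagged
    in ``feature_meta['zero_variance']``.
    """
    if (~m.qc_mask).sum() < 2:
        raise ValueError("z-scoring requires at least 2 study samples")
    bio = m.intensities.loc[~m.qc_mask].to_numpy(dtype=float)
    mu = bio.mean(axis=0)
    sigma = bio.std(axis=0, ddof=0)
    flagged = sigma == 0
    safe_sigma = np.where(flagged, 1.0, sigma)
    z = (m.intensities.to_numpy(dtype=float) - mu) / safe_sigma
    z[:, flagged] = 0.0
    out = m.with_intensities(
        pd.DataFrame(z, index=m.sample_ids, columns=m.feature_ids)
    )
    out.feature_meta = out.feature_meta.copy()
    out.feature_meta["zero_variance"] = flagged
    return out


def internal_standard_ratio(m: FeatureMatrix, standard_feature_id: str) -> FeatureMatrix:
    """Divide every feature by the internal standard's intensity per sample.

    Ratio normalization against an endogenous internal standard (e.g.
    creatine or histidine in urine) cancels per-sample dilution. The
    standard column itself becomes all ones.
    """
    if standard_feature_id not in m.feature_ids:
        raise KeyError(f"internal standard {standard_feature_id!r} not in feature table")
    std = m.intensities[standard_feature_id].to_numpy(dtype=float)
    bad = np.flatnonzero(~(std > 0))
    if bad.size:
        names = m.sample_ids[bad].tolist()
        raise ValueError(
            f"internal standard {standard_feature_id!r} non-positive in sample(s) "
            f"{names[:5]}; ratio normalization undefined"
        )
    ratio = m.intensities.to_numpy(dtype=float) / std[:, None]
    return m.with_intensities(
        pd.DataFrame(ratio, index=m.sample_ids, columns=m.feature_ids)
    )
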