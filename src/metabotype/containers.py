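"""Core in-memory containers for aligned LC-MS feature tables.

A :class:`FeatureMatrix` bundles three aligned pandas DataFrames: a
samples × features intensity table, per-sample metadata (genotype,
age group, pooled-QC flag, colitis score), and per-feature metadata
(m/z, retention time, ionisation mode, acquisition window). The same
container also carries pathway-abundance count tables, where the
metabolite-specific metadata columns are simply absent.

On disk a FeatureMatrix is a triplet of UTF-8 CSV files with period
decimal separators: ``intensities.csv``, ``sample_metadata.csv`` and
``feature_metadata.csv`` (plus an optional ``rt_observations.csv``
holding per-sample retention times when available).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "FeatureMatrixError",
    "read_feature_matrix",
    "write_feature_matrix",
]

#: Acquisition m/z range of the instrument method (Da).
MZ_RANGE = (60.0, 1250.0)
#: Chromatographic run length (minutes).
RT_RANGE = (0.0, 23.5)

INTENSITIES_FILE = "intensities.csv"
SAMPLE_META_FILE = "sample_metadata.csv"
FEATURE_META_FILE = "feature_metadata.csv"
RT_OBS_FILE = "rt_observations.csv"


class FeatureMatrixError(ValueError):
    """Raised when a feature matrix violates its structural invariants."""


@dataclasses.dataclass
class FeatureMatrix:
    """Aligned samples × features intensity table with metadata.

    Parameters
    ----------
    intensities
        Non-negative intensity matrix; index = sample ids, columns =
        feature ids.
    sample_meta
        One row per sample, indexed identically to ``intensities``.
        Recognised columns: ``genotype`` (WT/KO/QC), ``age_group``
        (6/18 or NA), ``qc_flag`` (bool), ``colitis_score``.
    feature_meta
        One row per feature, indexed like the intensity columns.
        Recognised columns: ``mz`` (Da), ``rt`` (minutes), ``mode``
        (pos/neg), ``window``, ``is_internal_standard``.
    rt_obs
        Optional per-sample observed retention times (same shape as
        ``intensities``); aligned export tables usually lack these.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    rt_obs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    # structure
    def validate(self) -> None:
        """Check index alignment, uniqueness and metadata ranges."""
        ints = self.intensities
        if not ints.index.equals(self.sample_meta.index):
            missing = ints.index.difference(self.sample_meta.index).tolist()
            extra = self.sample_meta.index.difference(ints.index).tolist()
            raise FeatureMatrixError(
                "sample ids of intensities and sample_meta disagree; "
                f"missing from metadata: {missing[:5]}, unmatched metadata rows: {extra[:5]}"
            )
        if not ints.columns.equals(self.feature_meta.index):
            missing = ints.columns.difference(self.feature_meta.index).tolist()
            extra = self.feature_meta.index.difference(ints.columns).tolist()
            raise FeatureMatrixError(
                "feature ids of intensities and feature_meta disagree; "
                f"missing from metadata: {missing[:5]}, unmatched metadata rows: {extra[:5]}"
            )
        if ints.index.has_duplicates:
            dups = ints.index[ints.index.duplicated()].unique().tolist()
            raise FeatureMatrixError(f"duplicate sample ids: {dups[:5]}")
        if ints.columns.has_duplicates:
            dups = ints.columns[ints.columns.duplicated()].unique().tolist()
            raise FeatureMatrixError(f"duplicate feature ids: {dups[:5]}")
        vals = ints.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FeatureMatrixError(
                "intensities are not numeric; if the file uses ',' as the decimal "
                "separator re-export it with '.' (C locale)"
            )
        if "mz" in self.feature_meta.columns:
            mz = self.feature_meta["mz"].dropna()
            if ((mz < MZ_RANGE[0]) | (mz > MZ_RANGE[1])).any():
                bad = mz[(mz < MZ_RANGE[0]) | (mz > MZ_RANGE[1])].index.tolist()
                raise FeatureMatrixError(f"m/z outside {MZ_RANGE} for features {bad[:5]}")
        if "rt" in self.feature_meta.columns:
            rt = self.feature_meta["rt"].dropna()
            if ((rt < RT_RANGE[0]) | (rt > RT_RANGE[1])).any():
                bad = rt[(rt < RT_RANGE[0]) | (rt > RT_RANGE[1])].index.tolist()
                raise FeatureMatrixError(f"RT outside {RT_RANGE} min for features {bad[:5]}")
        if self.rt_obs is not None:
            if not (
                self.rt_obs.index.equals(ints.index)
                and self.rt_obs.columns.equals(ints.columns)
            ):
                raise FeatureMatrixError("rt_obs is not aligned with intensities")

    # ------------------------------------------------------------------
    # convenience accessors
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def qc_mask(self) -> np.ndarray:
        """Boolean array marking pooled-QC injections (False if unflagged)."""
        if "qc_flag" in self.sample_meta.columns:
            return self.sample_meta["qc_flag"].astype(bool).to_numpy()
        return np.zeros(self.n_samples, dtype=bool)

    def qc(self) -> "FeatureMatrix":
        """The pooled-QC injections only."""
        return self.subset_samples(self.sample_ids[self.qc_mask])

    def biological(self) -> "FeatureMatrix":
        """The study (non-QC) samples only."""
        return self.subset_samples(self.sample_ids[~self.qc_mask])

    def subset_samples(self, ids) -> "FeatureMatrix":
        ids = pd.Index(ids)
        return FeatureMatrix(
            self.intensities.loc[ids],
            self.sample_meta.loc[ids],
            self.feature_meta,
            None if self.rt_obs is None else self.rt_obs.loc[ids],
        )

    def subset_features(self, ids) -> "FeatureMatrix":
        ids = pd.Index(ids)
        return FeatureMatrix(
            self.intensities.loc[:, ids],
            self.sample_meta,
            self.feature_meta.loc[ids],
            None if self.rt_obs is None else self.rt_obs.loc[:, ids],
        )

    def drop_features(self, ids) -> "FeatureMatrix":
        keep = self.feature_ids.difference(pd.Index(ids), sort=False)
        # difference() can reorder; preserve original column order
        keep = self.feature_ids[self.feature_ids.isin(keep)]
        return self.subset_features(keep)

    def with_intensities(self, values: pd.DataFrame) -> "FeatureMatrix":
        """Same metadata, new intensity values (indexes must match)."""
        return FeatureMatrix(values, self.sample_meta, self.feature_meta, self.rt_obs)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.intensities.copy(),
            self.sample_meta.copy(),
            self.feature_meta.copy(),
            None if self.rt_obs is None else self.rt_obs.copy(),
        )


# ----------------------------------------------------------------------
# CSV triplet I/O


def write_feature_matrix(m: FeatureMatrix, directory: str | Path) -> dict[str, Path]:
    """Write the CSV triplet (plus optional RT observations) to *directory*.

    Returns the mapping of logical name → written path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": directory / INTENSITIES_FILE,
        "sample_meta": directory / SAMPLE_META_FILE,
        "feature_meta": directory / FEATURE_META_FILE,
    }
    m.intensities.to_csv(paths["intensities"], index_label="sample_id")
    m.sample_meta.to_csv(paths["sample_meta"], index_label="sample_id")
    m.feature_meta.to_csv(paths["feature_meta"], index_label="feature_id")
    if m.rt_obs is not None:
        paths["rt_obs"] = directory / RT_OBS_FILE
        m.rt_obs.to_csv(paths["rt_obs"], index_label="sample_id")
    return paths


def _read_numeric_table(path: Path, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        sample = df[non_numeric[0]].astype(str).iloc[0]
        hint = ""
        if "," in sample:
            hint = (
                "; values contain ',' — the file appears to use a comma decimal "
                "separator, re-export with '.' (C locale)"
            )
        raise FeatureMatrixError(
            f"{path.name}: non-numeric values in columns {non_numeric[:5]}{hint}"
        )
    return df


def read_feature_matrix(directory: str | Path) -> FeatureMatrix:
    """Read and validate a FeatureMatrix from its CSV triplet.

    Raises :class:`FeatureMatrixError` naming the offending ids on any
    mismatch between the three files.
    """
    directory = Path(directory)
    ints_path = directory / INTENSITIES_FILE
    smeta_path = directory / SAMPLE_META_FILE
    fmeta_path = directory / FEATURE_META_FILE
    for p in (ints_path, smeta_path, fmeta_path):
        if not p.exists():
            raise FeatureMatrixError(f"missing required file {p}")
    intensities = _read_numeric_table(ints_path, "sample_id")
    # age_group legitimately holds the literal string "NA" (QC rows);
    # read metadata verbatim, then restore typed columns explicitly
    sample_meta = pd.read_csv(smeta_path, index_col=0, keep_default_na=False, na_values=[""])
    if "qc_flag" in sample_meta.columns:
        sample_meta["qc_flag"] = sample_meta["qc_flag"].astype(str).str.lower().eq("true")
    if "colitis_score" in sample_meta.columns:
        sample_meta["colitis_score"] = pd.to_numeric(
            sample_meta["colitis_score"], errors="coerce"
        )
    feature_meta = pd.read_csv(fmeta_path, index_col=0)
    for df in (intensities, sample_meta, feature_meta):
        df.index.name = None
        df.columns.name = None
    rt_obs = None
    rt_path = directory / RT_OBS_FILE
    if rt_path.exists():
        rt_obs = _read_numeric_table(rt_path, "sample_id")
        rt_obs.index.name = None
        rt_obs.columns.name = None
    # align metadata to the intensity table's order when ids agree as sets
    if set(sample_meta.index) == set(intensities.index):
        sample_meta = sample_meta.loc[intensities.index]
    if set(feature_meta.index) == set(intensities.columns):
        feature_meta = feature_meta.loc[intensities.columns]
    if rt_obs is not None and set(rt_obs.index) == set(intensities.index):
        rt_obs = rt_obs.loc[intensities.index, :]
    return FeatureMatrix(intensities, sample_meta, feature_meta, rt_obs)
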