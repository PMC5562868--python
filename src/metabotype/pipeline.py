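"""End-to-end pipeline runs: configuration, staging, manifest.

A :class:`PipelineConfig` captures every stage toggle and parameter
(unknown keys are rejected, and every stochastic stage has an explicit
seed). :func:`run_pipeline` executes

    noise threshold → pooled-QC reliability → singleton removal →
    correlation filter → [internal-standard ratio] → Z-score →
    requested analyses (PCA, PLS-LDA LOO, score regression,
    permutation importance)

writing JSON reports plus a :class:`RunManifest` that suffices to
re-run the pipeline identically. Reports are written with sorted keys
and fixed float formatting, so two runs of one config are
byte-identical; the manifest additionally carries a wall-clock
timestamp, which is the only field that differs between runs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Any, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .containers import FeatureMatrix, read_feature_matrix, write_feature_matrix
from .discrimination import loo_cross_validate, pca_overview, regress_against_score
from .permutation import RandomForestSpec, permutation_feature_test
from .preprocessing import (
    FilterReport,
    correlation_filter,
    internal_standard_ratio,
    noise_threshold_filter,
    qc_reliability_filter,
    singleton_filter,
    zscore_normalize,
)
from .simulate import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "write_json"]


class PipelineConfig(BaseModel):
    """Full parameterization of a pipeline run. Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # input: a CSV-triplet directory, or a synthetic cohort
    input_dir: str | None = None
    synthetic: dict[str, Any] | None = None

    # preprocessing chain
    noise_threshold: float | None = 100_000.0
    qc_filter: bool = True
    qc_min_presence: float = 0.80
    qc_max_area_rsd: float = 0.30
    qc_max_rt_rsd: float = 0.05
    singleton_removal: bool = True
    correlation_threshold: float | None = 0.98
    internal_standard: str | None = None
    zscore: bool = True

    # analyses
    pca: bool = True
    pca_components: int = 2
    discriminate: bool = True
    labels_column: str | None = "genotype"
    n_components: int = 5
    regress: bool = False
    score_column: str = "colitis_score"
    regress_method: Literal["pls", "rf"] = "pls"
    regress_seed: int = 0
    permtest: bool = False
    permtest_repeats: int = 100
    permtest_z_crit: float = 1.96
    permtest_seed: int = 0
    rf_trees: int = 500

    out_dir: str = Field(default="pipeline_out")

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_dir or synthetic must be given")
        if (self.discriminate or self.permtest) and not self.labels_column:
            raise ValueError(
                "discriminate/permtest require labels_column to be set"
            )
        return self


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-run a pipeline bit-identically."""

    config: dict
    version: str
    filter_chain: list[dict]
    input_checksums: dict[str, str]
    seeds: dict[str, int]
    timestamp: str
    outputs: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, no locale dependence)."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured pipeline and write all artifacts.

    Input files are never mutated; every artifact goes to
    ``config.out_dir``. Stage errors propagate annotated with the
    stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    seeds: dict[str, int] = {}

    if config.input_dir is not None:
        m = read_feature_matrix(config.input_dir)
        for p in sorted(Path(config.input_dir).glob("*.csv")):
            checksums[p.name] = _sha256(p)
    else:
        cohort_cfg = CohortConfig(**config.synthetic)
        seeds["synthetic"] = cohort_cfg.seed
        m = generate_cohort(cohort_cfg)
        write_feature_matrix(m, out / "synthetic_input")

    chain: list[FilterReport] = []

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    if config.noise_threshold is not None:
        m, rep = stage("noise_threshold", noise_threshold_filter, m, config.noise_threshold)
        chain.append(rep)
    if config.qc_filter:
        m, _, rep = stage(
            "qc_reliability",
            qc_reliability_filter,
            m,
            min_presence=config.qc_min_presence,
            max_area_rsd=config.qc_max_area_rsd,
            max_rt_rsd=config.qc_max_rt_rsd,
        )
        chain.append(rep)
    if config.singleton_removal:
        m, rep = stage("singleton", singleton_filter, m)
        chain.append(rep)
    if config.correlation_threshold is not None:
        m, rep = stage(
            "correlation", correlation_filter, m, threshold=config.correlation_threshold
        )
        chain.append(rep)
    if config.internal_standard is not None:
        m = stage("internal_standard", internal_standard_ratio, m, config.internal_standard)
    if config.zscore:
        m = stage("zscore", zscore_normalize, m)

    outputs: list[str] = []
    write_json([r.to_dict() for r in chain], out / "filter_report.json")
    outputs.append("filter_report.json")

    # QC rows informed the filters; analyses run on study samples only
    if config.pca:
        ord_res = stage("pca", pca_overview, m, n_components=config.pca_components)
        write_json(ord_res.to_dict(), out / "pca.json")
        outputs.append("pca.json")
    if config.discriminate:
        conf = stage(
            "discriminate",
            loo_cross_validate,
            m,
            config.labels_column,
            n_components=config.n_components,
        )
        write_json(conf.to_dict(), out / "confusion.json")
        outputs.append("confusion.json")
    if config.regress:
        seeds["regress"] = config.regress_seed
        diag = stage(
            "regress",
            regress_against_score,
            m,
            config.score_column,
            method=config.regress_method,
            seed=config.regress_seed,
        )
        write_json(diag.to_dict(), out / "regression.json")
        outputs.append("regression.json")
    if config.permtest:
        seeds["permtest"] = config.permtest_seed
        res = stage(
            "permtest",
            permutation_feature_test,
            m,
            config.labels_column,
            n_repeats=config.permtest_repeats,
            z_crit=config.permtest_z_crit,
            seed=config.permtest_seed,
            rf=RandomForestSpec(n_estimators=config.rf_trees),
        )
        write_json(res.to_dict(), out / "permutation.json")
        outputs.append("permutation.json")

    manifest = RunManifest(
        config=config.model_dump(),
        version=__version__,
        filter_chain=[r.to_dict() for r in chain],
        input_checksums=checksums,
        seeds=seeds,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=sorted(outputs),
    )
    write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
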