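"""Synthetic LC-MS cohorts and pathway-abundance tables.

The generator emulates the statistical structure of an untargeted
urinary-metabolomics study of colitis-prone knockout (KO) mice and
wild-type (WT) littermates sampled at two ages (6 and 18 weeks), with
repeated pooled-QC injections:

* per-feature log-normal intensities with baselines spanning roughly
  three orders of magnitude;
* a dominant multiplicative *age* effect on a large feature subset and
  a weaker *genotype* effect confined to a smaller subset (ground
  truth recorded in the feature metadata);
* a per-sample log-normal *dilution* scalar multiplying every feature,
  making internal-standard ratio normalization consequential;
* internal-standard ions with tiny biological variance, untouched by
  the group effects but carried along by dilution;
* low-intensity noise ions hovering around the noise threshold with
  erratic dropout, so that intensity thresholding and pooled-QC
  reliability filtering both have real work to do;
* pooled-QC rows equal to the feature-wise mean of the study samples
  perturbed by low-variance technical noise (noise ions excepted —
  they stay irreproducible in the QCs, as real noise ions are).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, RT_RANGE

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "generate_pathway_table",
    "generate_marker_classes",
]

#: Acquisition windows: (label, ionisation mode, m/z low, m/z high).
ACQUISITION_WINDOWS = (
    ("pos_60_200", "pos", 60.0, 200.0),
    ("pos_140_1250", "pos", 140.0, 1250.0),
    ("neg_60_200", "neg", 60.0, 200.0),
    ("neg_140_1250", "neg", 140.0, 1250.0),
)

_GROUP_RE = re.compile(r"^(WT|KO)(6|18)$")


def _lognormal_sigma(cv: float) -> float:
    """Log-space sigma of a log-normal variate with the given CV."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclasses.dataclass
class CohortConfig:
    """Parameters of the simulated cohort.

    Defaults mirror the study design: group sizes 18/18/17/12 for
    WT-6wk / KO-6wk / WT-18wk / KO-18wk, 3129 aligned mass ions over
    four acquisition windows, and eight pooled-QC injections.
    """

    n_per_group: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"WT6": 18, "KO6": 18, "WT18": 17, "KO18": 12}
    )
    n_qc: int = 8
    n_features: int = 3129
    n_genotype_features: int = 150
    genotype_effect: float = 1.5
    n_age_features: int = 800
    age_effect: float = 2.0
    n_internal_standards: int = 2
    dilution_cv: float = 0.3
    noise_feature_fraction: float = 0.15
    noise_level: float = 100_000.0
    rt_jitter_sd: float = 0.02  # minutes, QC-grade RT reproducibility
    noise_rt_jitter_mult: float = 20.0
    qc_technical_cv: float = 0.05
    qc_noise_dropout: float = 0.5
    colitis_score_range: tuple[float, float] = (4.0, 12.0)
    colitis_coupling: float = 0.0
    emit_rt_observations: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for label in self.n_per_group:
            if not _GROUP_RE.match(label):
                raise ValueError(
                    f"group label {label!r} must be genotype WT/KO + age 6/18 (e.g. 'WT6')"
                )
        if sorted(self.n_per_group) != sorted(["WT6", "KO6", "WT18", "KO18"]):
            raise ValueError("groups must be exactly the cross of {WT,KO} x {6,18}")
        counts = [
            self.n_qc,
            self.n_features,
            self.n_genotype_features,
            self.n_age_features,
            self.n_internal_standards,
            *self.n_per_group.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0.0 <= self.noise_feature_fraction <= 1.0:
            raise ValueError("noise_feature_fraction must lie in [0, 1]")
        if self.genotype_effect <= 0 or self.age_effect <= 0:
            raise ValueError("effect fold-changes must be positive")
        if self.dilution_cv < 0 or self.qc_technical_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        n_noise = round(self.noise_feature_fraction * self.n_features)
        n_signal = self.n_features - n_noise - self.n_internal_standards
        if self.n_genotype_features > self.n_features:
            raise ValueError("n_genotype_features exceeds n_features")
        if self.n_genotype_features > n_signal or self.n_age_features > n_signal:
            raise ValueError(
                "effect feature counts exceed the number of non-noise, "
                f"non-standard features ({n_signal})"
            )

    @property
    def n_biological(self) -> int:
        return sum(self.n_per_group.values())


def generate_cohort(config: CohortConfig | None = None) -> FeatureMatrix:
    """Simulate an aligned LC-MS feature matrix for the configured cohort.

    Ground-truth feature roles are recorded in ``feature_meta`` columns
    ``is_genotype_feature``, ``is_age_feature``, ``is_noise`` and
    ``is_internal_standard``; they never leak into the intensities when
    the corresponding effect is 1.0.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_features
    n_bio = cfg.n_biological

    # ---- feature annotations -------------------------------------------------
    feature_ids = [f"F{j + 1:05d}" for j in range(p)]
    win_idx = rng.integers(0, len(ACQUISITION_WINDOWS), size=p)
    mz = np.empty(p)
    mode = np.empty(p, dtype=object)
    window = np.empty(p, dtype=object)
    for k, (label, m, lo, hi) in enumerate(ACQUISITION_WINDOWS):
        sel = win_idx == k
        mz[sel] = rng.uniform(lo, hi, size=sel.sum())
        mode[sel] = m
        window[sel] = label
    rt = rng.uniform(0.3, 23.0, size=p)

    # ---- feature roles -------------------------------------------------------
    n_noise = round(cfg.noise_feature_fraction * p)
    roles = rng.permutation(p)
    is_is = np.zeros(p, dtype=bool)
    is_is[roles[: cfg.n_internal_standards]] = True
    is_noise = np.zeros(p, dtype=bool)
    is_noise[roles[cfg.n_internal_standards : cfg.n_internal_standards + n_noise]] = True
    signal_idx = roles[cfg.n_internal_standards + n_noise :]
    is_geno = np.zeros(p, dtype=bool)
    is_geno[rng.choice(signal_idx, size=cfg.n_genotype_features, replace=False)] = True
    is_age = np.zeros(p, dtype=bool)
    is_age[rng.choice(signal_idx, size=cfg.n_age_features, replace=False)] = True

    # ---- intensity model (natural-log space) ---------------------------------
    log_base = np.log(10.0) * rng.uniform(5.3, 8.0, size=p)
    log_base[is_noise] = rng.normal(
        np.log(cfg.noise_level) - 0.25, 0.45, size=is_noise.sum()
    )
    log_base[is_is] = np.log(1e7)
    log_sd = rng.uniform(0.2, 0.6, size=p)
    log_sd[is_noise] = 0.6
    # internal standards track dilution only: near-zero biological variance
    log_sd[is_is] = 0.02

    # ---- biological samples --------------------------------------------------
    sample_ids: list[str] = []
    genotype: list[str] = []
    age_group: list[str] = []
    # canonical group order: output must not depend on dict key order
    group_order = ["WT6", "KO6", "WT18", "KO18"]
    for label, n in ((g, cfg.n_per_group[g]) for g in group_order):
        g, a = _GROUP_RE.match(label).groups()
        for i in range(n):
            sample_ids.append(f"{label}_{i + 1:02d}")
            genotype.append(g)
            age_group.append(a)
    genotype_arr = np.array(genotype)
    age_arr = np.array(age_group)

    log_int = log_base + rng.normal(0.0, 1.0, size=(n_bio, p)) * log_sd
    ko = (genotype_arr == "KO")[:, None]
    old = (age_arr == "18")[:, None]
    log_int += np.log(cfg.genotype_effect) * (ko & is_geno[None, :])
    log_int += np.log(cfg.age_effect) * (old & is_age[None, :])

    # per-sample dilution: multiplies every feature, standards included
    sig_d = _lognormal_sigma(cfg.dilution_cv)
    dilution = rng.lognormal(-0.5 * sig_d**2, sig_d, size=n_bio)
    log_int += np.log(dilution)[:, None]
    intensities_bio = np.exp(log_int)

    # noise ions: erratic detection in study samples as well
    noise_cols = np.flatnonzero(is_noise)
    dropout_bio = rng.random((n_bio, noise_cols.size)) < 0.5
    intensities_bio[:, noise_cols] = np.where(
        dropout_bio, 0.0, intensities_bio[:, noise_cols]
    )

    # ---- pooled-QC injections ------------------------------------------------
    pooled = intensities_bio.mean(axis=0)
    sig_t = _lognormal_sigma(cfg.qc_technical_cv)
    qc = pooled[None, :] * rng.lognormal(
        -0.5 * sig_t**2, sig_t, size=(cfg.n_qc, p)
    )
    if noise_cols.size:
        sig_n = _lognormal_sigma(0.6)
        qc_noise = pooled[noise_cols][None, :] * rng.lognormal(
            -0.5 * sig_n**2, sig_n, size=(cfg.n_qc, noise_cols.size)
        )
        dropout_qc = rng.random((cfg.n_qc, noise_cols.size)) < cfg.qc_noise_dropout
        qc[:, noise_cols] = np.where(dropout_qc, 0.0, qc_noise)

    qc_ids = [f"QC_{i + 1:02d}" for i in range(cfg.n_qc)]

    # ---- colitis scores ------------------------------------------------------
    score = np.zeros(n_bio)
    ko18 = (genotype_arr == "KO") & (age_arr == "18")
    lo, hi = cfg.colitis_score_range
    score[ko18] = rng.uniform(lo, hi, size=ko18.sum())
    if cfg.colitis_coupling != 0.0 and is_geno.any() and ko18.any():
        summary = np.log(np.maximum(intensities_bio[:, is_geno], 1.0)).mean(axis=1)
        z = (summary - summary[ko18].mean()) / max(summary[ko18].std(), 1e-12)
        score[ko18] = np.maximum(score[ko18] + cfg.colitis_coupling * z[ko18], 0.0)

    # ---- assemble ------------------------------------------------------------
    all_ids = sample_ids + qc_ids
    intensities = pd.DataFrame(
        np.vstack([intensities_bio, qc]), index=all_ids, columns=feature_ids
    )
    sample_meta = pd.DataFrame(
        {
            "genotype": genotype + ["QC"] * cfg.n_qc,
            "age_group": age_group + ["NA"] * cfg.n_qc,
            "qc_flag": [False] * n_bio + [True] * cfg.n_qc,
            "colitis_score": np.concatenate([score, np.full(cfg.n_qc, np.nan)]),
        },
        index=all_ids,
    )
    feature_meta = pd.DataFrame(
        {
            "mz": mz,
            "rt": rt,
            "mode": mode,
            "window": window,
            "is_internal_standard": is_is,
            "is_genotype_feature": is_geno,
            "is_age_feature": is_age,
            "is_noise": is_noise,
        },
        index=feature_ids,
    )

    rt_obs = None
    if cfg.emit_rt_observations:
        jitter_sd = np.full(p, cfg.rt_jitter_sd)
        jitter_sd[is_noise] *= cfg.noise_rt_jitter_mult
        observed = rt[None, :] + rng.normal(0.0, 1.0, size=(len(all_ids), p)) * jitter_sd
        observed = np.clip(observed, RT_RANGE[0], RT_RANGE[1])
        rt_obs = pd.DataFrame(observed, index=all_ids, columns=feature_ids)

    return FeatureMatrix(intensities, sample_meta, feature_meta, rt_obs)


def generate_marker_classes(
    n_classes: int = 10,
    per_class: int = 8,
    n_features: int = 60,
    effect: float = 4.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A benchmark with one uniquely informative marker feature per class.

    Sample classes c0…c{k−1}; feature j is shifted by ``effect`` for
    class j's samples and is standard normal elsewhere; features
    k…n_features−1 are pure noise. Each marker therefore carries
    information no other feature duplicates, which is the regime where
    permutation importance has per-feature power — redundant markers
    mask one another (permuting one leaves the rest carrying the
    signal) and are not individually recoverable by design.

    Returns ``(X, y)``; the markers are columns ``0…n_classes−1``.
    """
    if n_classes < 2 or per_class < 1 or n_features < n_classes:
        raise ValueError("need >= 2 classes and n_features >= n_classes")
    rng = np.random.default_rng(seed)
    n = n_classes * per_class
    X = rng.normal(size=(n, n_features))
    y = np.repeat([f"c{i}" for i in range(n_classes)], per_class)
    for j in range(n_classes):
        X[j * per_class : (j + 1) * per_class, j] += effect
    return X, y


def generate_pathway_table(
    n_samples: int,
    n_pathways: int,
    group_shift: float = 0.0,
    seed: int = 0,
    depth: int = 20_000,
    shifted_fraction: float = 0.2,
) -> FeatureMatrix:
    """Simulate a samples × pathways abundance count table with two groups.

    Rows are multinomial draws of comparable depth from group-specific
    pathway proportions. Group B (the second half of the samples)
    multiplies a ``shifted_fraction`` subset of the pathway weights by
    ``exp(±group_shift)`` with alternating signs, producing a
    compositional location effect whose magnitude grows with
    ``group_shift``; ``group_shift = 0`` is an exact null.
    """
    if n_samples <= 0 or n_pathways <= 0:
        raise ValueError("n_samples and n_pathways must be positive")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, 1.0, size=n_pathways)
    n_shift = max(1, round(shifted_fraction * n_pathways))
    shifted = rng.choice(n_pathways, size=n_shift, replace=False)
    signs = np.where(np.arange(n_shift) % 2 == 0, 1.0, -1.0)
    w_b = base.copy()
    w_b[shifted] *= np.exp(group_shift * signs)

    n_a = n_samples // 2
    p_a = base / base.sum()
    p_b = w_b / w_b.sum()
    depths = rng.poisson(depth, size=n_samples)
    counts = np.empty((n_samples, n_pathways), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(depths[i], p_a if i < n_a else p_b)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    pathway_ids = [f"ko{j + 1:05d}" for j in range(n_pathways)]
    is_shifted = np.zeros(n_pathways, dtype=bool)
    is_shifted[shifted] = True
    return FeatureMatrix(
        pd.DataFrame(counts, index=sample_ids, columns=pathway_ids),
        pd.DataFrame(
            {"group": ["A"] * n_a + ["B"] * (n_samples - n_a)}, index=sample_ids
        ),
        pd.DataFrame({"is_shifted": is_shifted}, index=pathway_ids),
    )
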