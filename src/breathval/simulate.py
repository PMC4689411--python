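"""Synthetic breath-VOC cohorts with known ground truth.

The generator emulates the statistical structure of a two-laboratory
breath-biomarker study: a large panel of candidate mass ions of which only a
small minority carry disease signal, duplicate chromatograms per subject
analyzed at two laboratories with correlated intensities, and cancer /
cancer-free group sizes on the scale of a clinical cohort.

Model
-----
Ion abundances are log-normal.  Per subject, each ion's latent
log-intensity is drawn ``Normal(baseline_log_mean, log_sd_subject)``;
informative ions get their mean shifted by ``±delta`` in cancer subjects,
with ``delta = sigma_total * sqrt(2) * Phi^{-1}(target_auc)`` where
``sigma_total**2 = log_sd_subject**2 + log_sd_lab**2`` is the variance of
an observed log intensity, so the theoretical per-laboratory C-statistic
``Phi(delta / (sigma_total * sqrt(2)))`` equals ``target_auc`` exactly — a
closed-form oracle for recovery tests.
Each laboratory observes the latent vector plus independent
``Normal(0, log_sd_lab)`` replicate noise (optionally a systematic per-lab
log offset), exponentiated to intensities; the internal-standard record is
appended at a fixed retention time.  The implied between-laboratory Pearson
correlation of log intensities is
``log_sd_subject**2 / (log_sd_subject**2 + log_sd_lab**2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import PreprocessConfig
from .errors import ConsistencyError, ValidationError
from .ion_table import FeatureKey, IonTable

#: lab-replicate log-intensity correlation matching the concordance the
#: duplicate-assay design is expected to achieve
DEFAULT_REPLICATE_CORRELATION = 0.88


def lab_sd_for_correlation(rho: float, log_sd_subject: float) -> float:
    """Replicate (laboratory) log-SD giving between-lab correlation ``rho``."""
    if not (0.0 < rho < 1.0):
        raise ValidationError("correlation must lie in (0, 1)")
    return log_sd_subject * sqrt(1.0 / rho - 1.0)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator parameters.

    Defaults reproduce the study conditions: 95 tissue-confirmed cancer
    subjects vs 81 CT-negative controls in the model-building phase, a
    1,000-ion candidate panel (a down-scaled stand-in for the full
    ~70,000-ion chromatographic panel), 50 informative ions of modest
    accuracy (theoretical C-statistic 0.70), and replicate noise tuned to a
    between-laboratory log-intensity correlation of 0.88.
    """

    n_cancer: int = 95
    n_control: int = 81
    n_segments: int = 200
    ions_per_segment: int = 5
    n_informative: int = 50
    target_auc: float = 0.70
    log_sd_subject: float = 1.0
    log_sd_lab: float = field(
        default=lab_sd_for_correlation(DEFAULT_REPLICATE_CORRELATION, 1.0))
    baseline_log_mean: float = 9.2
    is_intensity: float = 1.0e6
    is_rt: float = 700.0
    mz_range: tuple[int, int] = (30, 250)
    informative_mz: tuple[int, ...] | None = None
    lab_bias_log: float = 0.0
    phase: str = "model_building"
    subject_prefix: str | None = None
    site: str = "site1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 1 or self.n_control < 1:
            raise ValidationError("both group sizes must be >= 1")
        if self.n_segments < 1 or self.ions_per_segment < 1:
            raise ValidationError("panel dimensions must be >= 1")
        if self.n_informative > self.n_features:
            raise ValidationError(
                "n_informative exceeds the number of candidate ions")
        if not (0.5 < self.target_auc < 1.0):
            raise ValidationError(
                "target_auc must lie strictly between 0.5 and 1 "
                "(informative ions must beat chance)")
        if self.log_sd_subject <= 0 or self.log_sd_lab <= 0:
            raise ValidationError("log-scale SDs must be positive")
        if self.is_intensity <= 0:
            raise ValidationError("is_intensity must be positive")
        lo, hi = self.mz_range
        n_mz = hi - lo + 1 - (1 if lo <= 95 <= hi else 0)
        if self.ions_per_segment > n_mz:
            raise ValidationError("ions_per_segment exceeds available m/z")

    @property
    def n_features(self) -> int:
        return self.n_segments * self.ions_per_segment

    @property
    def total_log_sd(self) -> float:
        """SD of an observed single-laboratory log intensity."""
        return sqrt(self.log_sd_subject ** 2 + self.log_sd_lab ** 2)

    @property
    def delta(self) -> float:
        """Log-mean shift of informative ions in cancer subjects.

        Calibrated against the *observed* log-intensity SD (subject plus
        replicate noise) so that the theoretical per-laboratory AUC of an
        informative ion, ``Phi(delta / (sigma_total * sqrt(2)))``, equals
        ``target_auc`` exactly.
        """
        return self.total_log_sd * sqrt(2.0) * norm.ppf(self.target_auc)

    @property
    def replicate_correlation(self) -> float:
        """Theoretical lab-A vs lab-B Pearson correlation of log intensity."""
        vs = self.log_sd_subject ** 2
        return vs / (vs + self.log_sd_lab ** 2)


@dataclass(frozen=True)
class GroundTruth:
    """Panel layout and injected signal of a simulated cohort.

    ``features`` fixes the (segment, m/z) identity and within-run retention
    time of every candidate ion so that an independently simulated blinded
    cohort aligns feature-for-feature with the training cohort.
    """

    features: tuple[FeatureKey, ...]
    rts: np.ndarray
    informative_index: np.ndarray
    directions: np.ndarray
    delta: float
    theoretical_auc: float

    @property
    def informative_features(self) -> list[FeatureKey]:
        return [self.features[i] for i in self.informative_index]

    def to_frame(self) -> pd.DataFrame:
        keys = self.informative_features
        return pd.DataFrame({
            "segment": [k.segment for k in keys],
            "mz": [k.mz for k in keys],
            "direction": self.directions.astype(int),
            "theoretical_auc": self.theoretical_auc,
        })


def _panel_layout(config: SimConfig, rng: np.random.Generator):
    lo, hi = config.mz_range
    mz_pool = np.array([m for m in range(lo, hi + 1) if m != 95])
    features: list[FeatureKey] = []
    rts = np.empty(config.n_features)
    w = 5.0
    for seg in range(config.n_segments):
        mzs = np.sort(rng.choice(mz_pool, size=config.ions_per_segment,
                                 replace=False))
        offs = rng.uniform(0.0, w, size=config.ions_per_segment)
        for j, (m, o) in enumerate(zip(mzs, offs)):
            idx = seg * config.ions_per_segment + j
            features.append(FeatureKey(seg, int(m)))
            rts[idx] = seg * w + o
    return tuple(features), rts


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    features, rts = _panel_layout(config, rng)
    if config.informative_mz is not None:
        candidates = np.array([i for i, k in enumerate(features)
                               if k.mz in set(config.informative_mz)])
        if candidates.size < config.n_informative:
            raise ValidationError(
                "not enough features at the requested informative m/z values")
    else:
        candidates = np.arange(len(features))
    informative = np.sort(rng.choice(candidates, size=config.n_informative,
                                     replace=False))
    directions = rng.choice([-1.0, 1.0], size=config.n_informative)
    return GroundTruth(features, rts, informative, directions,
                       config.delta, config.target_auc)


def _subject_table(meta: dict, truth: GroundTruth,
                   log_intensity: np.ndarray, config: SimConfig) -> IonTable:
    rt = np.append(truth.rts, config.is_rt)
    mz = np.append(np.array([k.mz for k in truth.features]), 95)
    intensity = np.append(np.exp(log_intensity), config.is_intensity)
    return IonTable(sample_id=meta["sample_id"], rt=rt, mz=mz,
                    intensity=intensity, config=PreprocessConfig())


def _simulate(config: SimConfig, truth: GroundTruth,
              rng: np.random.Generator, prefix: str):
    n = config.n_cancer + config.n_control
    cancer = np.zeros(n, dtype=bool)
    cancer[:config.n_cancer] = True

    latent = rng.normal(config.baseline_log_mean, config.log_sd_subject,
                        size=(n, config.n_features))
    shift = np.zeros(config.n_features)
    shift[truth.informative_index] = truth.directions * truth.delta
    latent[cancer] += shift

    age = np.clip(np.where(cancer, rng.normal(67.7, 10.7, n),
                           rng.normal(61.8, 7.2, n)), 30, 95).round(1)
    pack = np.clip(np.where(cancer, rng.normal(48.5, 28.0, n),
                            rng.normal(42.1, 16.9, n)), 0, None).round(1)
    sex = rng.choice(["M", "F"], size=n)

    meta_rows, tables = [], {"A": [], "B": []}
    for lab, bias in (("A", 0.0), ("B", config.lab_bias_log)):
        noise = rng.normal(0.0, config.log_sd_lab,
                           size=(n, config.n_features))
        logs = latent + noise + bias
        for i in range(n):
            subject = f"{prefix}{i:04d}"
            row = {
                "sample_id": f"{subject}_{lab}",
                "subject_id": subject,
                "group": 3 if cancer[i] else 1,
                "cancer_status": "positive" if cancer[i] else "negative",
                "lab": lab,
                "site": config.site,
                "phase": config.phase,
                "sample_kind": "breath",
                "age": age[i],
                "pack_years": pack[i],
                "sex": sex[i],
            }
            meta_rows.append(row)
            tables[lab].append(_subject_table(row, truth, logs[i], config))
    meta = pd.DataFrame(meta_rows)
    return meta, tables["A"], tables["B"]


def simulate_cohort(config: SimConfig):
    """Simulate a model-building cohort.

    Returns ``(meta, tables_A, tables_B, truth)``: the sample-metadata
    table (two rows per subject, one per laboratory), the raw — not yet
    normalized — ion tables of each laboratory, and the ground truth.
    Identical configs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    prefix = config.subject_prefix or "MB"
    meta, a, b = _simulate(config, truth, rng, prefix)
    return meta, a, b, truth


def simulate_blinded_cohort(config: SimConfig, truth: GroundTruth):
    """Simulate an independent validation cohort sharing ``truth``.

    New subjects are drawn from the same distributions (same panel layout,
    informative ions and effect sizes); the phase is forced to
    ``model_testing`` and subject ids are disjoint from the training
    cohort's by prefix.
    """
    if len(truth.features) != config.n_features:
        raise ConsistencyError(
            f"truth has {len(truth.features)} features but config implies "
            f"{config.n_features}")
    if truth.informative_index.size and \
            truth.informative_index.max() >= config.n_features:
        raise ConsistencyError("truth informative index out of range")
    config = replace(config, phase="model_testing")
    # decorrelate from the training stream even when the seed is reused
    rng = np.random.default_rng((config.seed, 1))
    prefix = config.subject_prefix or "MT"
    meta, a, b = _simulate(config, truth, rng, prefix)
    return meta, a, b, truth
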