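"""Evaluation of discriminant-function predictions.

Three views of a set of DF values: (1) sensitivity and specificity as
functions of the DF cutoff, with the crossover operating point — the cutoff
maximizing sensitivity + specificity, where the two step curves intersect —
and the C-statistic of the DF itself; (2) inter-laboratory concordance of
replicate DF values (Pearson r with a Fisher-z confidence interval); and
(3) a blinded-validation report that audits, via a parameter hash, that the
frozen predictor was not touched between fitting and unblinding.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import atanh, sqrt, tanh

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import (
    BlindingViolationError,
    DegenerateInputError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)
from .ion_table import FeatureMatrix
from .screen import cstat


@dataclass(frozen=True)
class PerfCurve:
    """Sensitivity/specificity over a DF-cutoff grid, with crossover & AUC.

    The grid holds every distinct observed DF value plus 0; positivity is
    strict (``DF > cutoff``), so sensitivity is non-increasing and
    specificity non-decreasing along the grid.  ``crossover`` is
    ``(df*, sens*, spec*)`` at the cutoff maximizing sens + spec (ties to
    the smallest cutoff); ``auc`` is the oriented Mann-Whitney C-statistic
    of DF for cancer vs cancer-free.
    """

    cutoffs: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    crossover: tuple[float, float, float]
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "df_cutoff": self.cutoffs,
            "sensitivity": self.sens,
            "specificity": self.spec,
        })

    def roc_points(self) -> pd.DataFrame:
        """(1 - specificity, sensitivity) pairs of the same grid."""
        return pd.DataFrame({
            "fpr": 1.0 - self.spec,
            "tpr": self.sens,
        })


def perf_curve(dfs, labels) -> PerfCurve:
    """Performance of DF values against binary cancer labels.

    Both classes must be present; callers are expected to have excluded
    samples with unknown cancer status beforehand.
    """
    dfs = np.asarray(dfs, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if dfs.shape != labels.shape:
        raise ValidationError("dfs and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be present")

    cutoffs = np.unique(np.concatenate(([0.0], dfs)))
    pos = dfs[labels]
    neg = dfs[~labels]
    # strict positivity: positive iff DF > cutoff
    sens = (pos[None, :] > cutoffs[:, None]).mean(axis=1)
    spec = (neg[None, :] <= cutoffs[:, None]).mean(axis=1)

    total = sens + spec
    best = int(np.argmax(total))  # argmax returns the first (smallest cutoff)
    crossover = (float(cutoffs[best]), float(sens[best]), float(spec[best]))
    auc, _ = cstat(dfs, labels)
    return PerfCurve(cutoffs, sens, spec, crossover, auc)


@dataclass(frozen=True)
class ConcordanceResult:
    """Between-laboratory agreement of replicate DF values per subject."""

    pairs: pd.DataFrame  # columns subject_id, df_A, df_B
    r: float
    ci95: tuple[float, float]
    n: int
    n_dropped: int


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = atanh(r)
    se = 1.0 / sqrt(n - 3)
    zcrit = norm.ppf(0.5 + level / 2.0)
    return (tanh(z - zcrit * se), tanh(z + zcrit * se))


def interlab_concordance(dfs_a: pd.Series, dfs_b: pd.Series,
                         meta: pd.DataFrame) -> ConcordanceResult:
    """Pearson correlation of subject-matched replicate DF values.

    ``dfs_a`` / ``dfs_b`` are DF series indexed by sample_id from the two
    laboratories; ``meta`` maps sample ids to subjects.  Subjects missing a
    DF from either laboratory are dropped and counted.
    """
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    sub_a = {sid: m.loc[sid, "subject_id"] for sid in dfs_a.index
             if sid in m.index}
    sub_b = {sid: m.loc[sid, "subject_id"] for sid in dfs_b.index
             if sid in m.index}
    by_subject_a = {subj: dfs_a[sid] for sid, subj in sub_a.items()}
    by_subject_b = {subj: dfs_b[sid] for sid, subj in sub_b.items()}
    subjects = sorted(set(by_subject_a) & set(by_subject_b))
    n_dropped = len(set(by_subject_a) | set(by_subject_b)) - len(subjects)
    if len(subjects) < 3:
        raise InsufficientDataError(
            f"need >= 3 paired subjects, found {len(subjects)}")
    a = np.array([by_subject_a[s] for s in subjects], dtype=float)
    b = np.array([by_subject_b[s] for s in subjects], dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError(
            "zero variance in one laboratory's DF values")
    r = float(np.corrcoef(a, b)[0, 1])
    pairs = pd.DataFrame({"subject_id": subjects, "df_A": a, "df_B": b})
    return ConcordanceResult(pairs, r, _fisher_ci(r, len(subjects)),
                             len(subjects), n_dropped)


def blinded_report(results, fm_by_lab: dict[str, FeatureMatrix],
                   meta: pd.DataFrame) -> dict:
    """Blinded-validation report for a frozen predictor.

    Predicts DF values per laboratory first, then unblinds: per-lab
    sensitivity, specificity and C-statistic at each lab's crossover DF
    cutoff, plus between-laboratory concordance.  Samples with unknown
    cancer status receive DF values but are excluded from the performance
    metrics.  The predictor's parameter hash is checked before and after
    prediction; a mismatch with the hash frozen at fit time raises
    :class:`BlindingViolationError`.
    """
    if results.parameter_hash() != results.frozen_hash:
        raise BlindingViolationError(
            "model parameters changed since fitting")

    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    dfs_by_lab = {lab: results.predict(fm)
                  for lab, fm in sorted(fm_by_lab.items())}
    if results.parameter_hash() != results.frozen_hash:
        raise BlindingViolationError(
            "model parameters changed during prediction")

    report: dict = {"model_hash": results.frozen_hash, "labs": {}}
    for lab, dfs in dfs_by_lab.items():
        status = m.loc[dfs.index, "cancer_status"]
        known = status.isin(["positive", "negative"]).to_numpy()
        labels = (status == "positive").to_numpy()[known]
        curve = perf_curve(dfs.to_numpy()[known], labels)
        df_star, sens, spec = curve.crossover
        report["labs"][lab] = {
            "n": int(known.sum()),
            "df_cutoff": df_star,
            "sensitivity": sens,
            "specificity": spec,
            "c_statistic": curve.auc,
        }
    if len(dfs_by_lab) == 2:
        (_, da), (_, db) = sorted(dfs_by_lab.items())
        conc = interlab_concordance(da, db, meta)
        report["concordance"] = {
            "r": conc.r, "ci95": list(conc.ci95), "n": conc.n,
            "n_dropped": conc.n_dropped,
        }
    return report
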