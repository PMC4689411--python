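"""Weighted digital analysis (WDA): a weighted-voting discriminant model.

WDA turns each selected marker ion into a binary vote: a sample votes
"cancer" on a rule when ``sign * (value - cutoff) > 0`` (strict), and the
votes are summed with per-rule weights to give the sample's discriminant
function (DF).  The three rule ingredients are fixed at fit time from the
training data: the *sign* is the marker's orientation (elevated or
depressed in cancer), the *weight* its oriented C-statistic, and the
*cutoff* the intensity threshold maximizing Youden's J (sensitivity +
specificity - 1) for that single rule, searched over midpoints of
consecutive distinct observed values.  The DF is compared against a DF
cutoff to call a sample positive, again with strict inequality.

The model/results split follows the usual statistical-modeling idiom:
:class:`WDAModel` holds data and configuration, ``fit()`` returns a frozen
:class:`WDAResults` that predicts, summarizes, and serializes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .ion_table import FeatureKey, FeatureMatrix
from .screen import MarkerScore, ScreenResult


@dataclass(frozen=True)
class WDAConfig:
    """Fit-time conventions for WDA rules.

    ``weight_mode``: "c" uses the oriented C-statistic as the vote weight
    (default), "2c-1" uses the rescaled Gini-style weight.
    ``cutoff_criterion``: "youden" maximizes sensitivity + specificity - 1
    (default), "accuracy" maximizes the fraction correctly classified.
    Ties always break toward the smaller cutoff.
    """

    weight_mode: str = "c"
    cutoff_criterion: str = "youden"

    def __post_init__(self) -> None:
        if self.weight_mode not in ("c", "2c-1"):
            raise ValidationError("weight_mode must be 'c' or '2c-1'")
        if self.cutoff_criterion not in ("youden", "accuracy"):
            raise ValidationError(
                "cutoff_criterion must be 'youden' or 'accuracy'")


@dataclass(frozen=True)
class WDARule:
    """One marker's vote: fires when ``sign * (x - cutoff) > 0``."""

    feature: FeatureKey
    cutoff: float
    sign: int
    weight: float

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValidationError("sign must be +1 or -1")
        if self.cutoff < 0:
            raise ValidationError("cutoff must be nonnegative")
        if self.weight < 0:
            raise ValidationError("weight must be nonnegative")


def _best_cutoff(values: np.ndarray, labels: np.ndarray, sign: int,
                 criterion: str) -> tuple[float, float]:
    """Exhaustive single-rule threshold search.

    Candidates are midpoints of consecutive distinct observed values;
    returns ``(cutoff, score)`` where score is Youden's J or accuracy of
    the rule ``sign * (x - cutoff) > 0`` predicting cancer.  Ties break
    toward the smaller cutoff.  A constant feature has no midpoints: its
    single value is returned (the rule never fires) with score 0 and a
    warning.
    """
    distinct = np.unique(values)
    if distinct.size < 2:
        warnings.warn(
            "constant feature: rule can never discriminate", stacklevel=3)
        return float(distinct[0]), 0.0
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best_c, best_score = None, -np.inf
    for c in candidates:
        pred = sign * (values - c) > 0
        tp = np.count_nonzero(pred & labels)
        tn = np.count_nonzero(~pred & ~labels)
        if criterion == "youden":
            score = tp / n_pos + tn / n_neg - 1.0
        else:
            score = (tp + tn) / labels.size
        if score > best_score:
            best_c, best_score = float(c), float(score)
    return best_c, best_score


class WDAModel:
    """WDA model specification: training matrix, labels, selected markers.

    Parameters
    ----------
    fm
        Training feature matrix (internal-standard normalized, binned).
    labels
        Binary cancer indicator aligned with ``fm`` rows (or a Series
        indexed by sample_id; rows not covered are dropped).
    selected
        Marker features to build rules from, e.g. ``ScreenResult.selected``.
    scores
        The per-feature screening scores supplying orientation and weight;
        a :class:`ScreenResult` is accepted directly.
    """

    def __init__(self, fm: FeatureMatrix, labels,
                 selected: Sequence[FeatureKey],
                 scores: Sequence[MarkerScore] | ScreenResult,
                 config: WDAConfig | None = None) -> None:
        if isinstance(scores, ScreenResult):
            scores = scores.scores
        if len(selected) == 0:
            raise ValidationError("empty marker selection")
        score_by_feature = {s.feature: s for s in scores}
        missing = [k for k in selected if k not in score_by_feature]
        if missing:
            raise ValidationError(f"selected features without scores: "
                                  f"{missing[:5]}")
        absent = set(selected) - set(fm.features)
        if absent:
            raise ValidationError(
                f"selected features absent from matrix: "
                f"{sorted(absent)[:5]}")

        if isinstance(labels, pd.Series):
            common = [s for s in fm.sample_ids if s in labels.index]
            fm = fm.subset(common)
            labels = labels.loc[common].to_numpy()
        labels = np.asarray(labels, dtype=bool)
        if labels.size != fm.n_samples:
            raise ValidationError("labels length must match sample count")
        if labels.all() or not labels.any():
            raise DegenerateInputError("training labels are single-class")

        self.fm = fm
        self.labels = labels
        self.selected = list(selected)
        self.score_by_feature = score_by_feature
        self.config = config or WDAConfig()

    def fit(self) -> "WDAResults":
        """Fit one rule per selected marker and freeze the predictor."""
        rules = []
        for key in self.selected:
            score = self.score_by_feature[key]
            values = self.fm.values_for(key)
            cutoff, _ = _best_cutoff(values, self.labels, score.orientation,
                                     self.config.cutoff_criterion)
            weight = score.c_correct if self.config.weight_mode == "c" \
                else 2.0 * score.c_correct - 1.0
            rules.append(WDARule(key, cutoff, score.orientation, weight))
        results = WDAResults(rules=rules, config=self.config)
        results._attach_training_summary(self.fm, self.labels)
        return results


@dataclass
class WDAResults:
    """A fitted WDA predictor: frozen rules plus training diagnostics."""

    rules: list[WDARule]
    config: WDAConfig = field(default_factory=WDAConfig)
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        feats = [r.feature for r in self.rules]
        if len(set(feats)) != len(feats):
            raise ValidationError("duplicate features across rules")
        self.frozen_hash = self.parameter_hash()

    # -- identity -----------------------------------------------------------

    def parameter_hash(self) -> str:
        """SHA-256 over the canonical rule parameters (blinding audit)."""
        canonical = json.dumps(
            [[r.feature.segment, r.feature.mz, r.cutoff, r.sign, r.weight]
             for r in self.rules],
            sort_keys=True,
        )
        return hashlib.sha256(canonical.encode()).hexdigest()

    @property
    def k(self) -> int:
        return len(self.rules)

    @property
    def max_df(self) -> float:
        return float(sum(r.weight for r in self.rules))

    # -- prediction ---------------------------------------------------------

    def predict(self, fm: FeatureMatrix) -> pd.Series:
        """Discriminant-function value per sample.

        ``DF = sum over rules of weight * 1[sign * (x - cutoff) > 0]``,
        strict inequality; a feature absent from the matrix contributes
        value 0.  Only intensities are consulted — never metadata — so
        prediction on blinded samples cannot leak labels.
        """
        df = np.zeros(fm.n_samples)
        for r in self.rules:
            x = fm.values_for(r.feature)
            df += r.weight * (r.sign * (x - r.cutoff) > 0)
        return pd.Series(df, index=fm.sample_ids, name="df")

    def classify(self, dfs: pd.Series, df_cutoff: float) -> pd.Series:
        """Binary call per sample: positive iff ``DF > df_cutoff``."""
        if df_cutoff < 0:
            raise ValidationError("df_cutoff must be nonnegative")
        return (dfs > df_cutoff).astype(int)

    # -- diagnostics --------------------------------------------------------

    def _attach_training_summary(self, fm: FeatureMatrix,
                                 labels: np.ndarray) -> None:
        from .validation import perf_curve  # lazy: avoid import cycle

        dfs = self.predict(fm)
        curve = perf_curve(dfs.to_numpy(), labels)
        self.training_summary = {
            "n_cancer": int(labels.sum()),
            "n_control": int(labels.size - labels.sum()),
            "c_statistic": curve.auc,
            "df_cutoff": curve.crossover[0],
            "sensitivity": curve.crossover[1],
            "specificity": curve.crossover[2],
        }

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        ts = self.training_summary
        lines = [
            "Weighted Digital Analysis Results",
            "=" * 54,
            f"Rules (markers):        {self.k}",
            f"Max attainable DF:      {self.max_df:.2f}",
            f"Weight mode:            {self.config.weight_mode}",
            f"Cutoff criterion:       {self.config.cutoff_criterion}",
        ]
        if ts:
            lines += [
                f"Training cancer/ctrl:   {ts['n_cancer']}/{ts['n_control']}",
                f"Training C-statistic:   {ts['c_statistic']:.3f}",
                f"Optimal DF cutoff:      {ts['df_cutoff']:.2f}",
                f"Sens/spec at cutoff:    {100 * ts['sensitivity']:.1f}% / "
                f"{100 * ts['specificity']:.1f}%",
            ]
        lines.append("-" * 54)
        lines.append(f"{'feature':>14} {'cutoff':>12} {'sign':>5} "
                     f"{'weight':>7}")
        shown = self.rules[:10]
        for r in shown:
            lines.append(f"{r.feature.column:>14} {r.cutoff:>12.5g} "
                         f"{r.sign:>+5d} {r.weight:>7.3f}")
        if self.k > len(shown):
            lines.append(f"... {self.k - len(shown)} more rules")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str) -> None:
        payload = {
            "rules": [
                {"segment": r.feature.segment, "mz": r.feature.mz,
                 "cutoff": r.cutoff, "sign": r.sign, "weight": r.weight}
                for r in self.rules
            ],
            "config": {"weight_mode": self.config.weight_mode,
                       "cutoff_criterion": self.config.cutoff_criterion},
            "training_summary": self.training_summary,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "WDAResults":
        with open(path) as fh:
            payload = json.load(fh)
        rules = [
            WDARule(FeatureKey(d["segment"], d["mz"]), d["cutoff"],
                    d["sign"], d["weight"])
            for d in payload["rules"]
        ]
        return cls(rules=rules, config=WDAConfig(**payload["config"]),
                   training_summary=payload.get("training_summary", {}))


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_wda(fm: FeatureMatrix, labels, selected: Sequence[FeatureKey],
            scores: Sequence[MarkerScore] | ScreenResult,
            config: WDAConfig | None = None) -> WDAResults:
    """Fit a WDA predictor (functional form of ``WDAModel(...).fit()``)."""
    return WDAModel(fm, labels, selected, scores, config).fit()


def predict_df(results: WDAResults, fm: FeatureMatrix) -> pd.Series:
    """DF value per sample of ``fm`` under a fitted predictor."""
    return results.predict(fm)


def classify(dfs: pd.Series, df_cutoff: float) -> pd.Series:
    """Positive iff DF strictly exceeds the cutoff."""
    if df_cutoff < 0:
        raise ValidationError("df_cutoff must be nonnegative")
    return (pd.Series(dfs) > df_cutoff).astype(int)
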