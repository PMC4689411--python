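"""Monte-Carlo C-statistic screening of candidate mass-ion biomarkers.

Every (segment, m/z) feature is scored by its C-statistic — the area under
the ROC curve, computed as the Mann-Whitney concordance probability with
midrank tie handling — for tissue-confirmed cancer versus CT-negative
controls, folded to [0.5, 1] with an orientation sign.  The null behavior
of the whole panel is estimated by Monte-Carlo random assignment: the
subject labels are shuffled (class sizes preserved, one shuffle shared by
all features per replicate) and the C-statistics recomputed, by default 40
times.  Counting, on a C-value grid, how many features exceed each value
under correct versus random assignment yields two declining curves; the
point where the random-assignment curve reaches zero is the non-randomness
cutoff, and features whose correct-assignment C-statistic clears it are
declared better-than-random markers, of which the top K by C-statistic are
kept for the classifier.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateInputError, ValidationError
from .ion_table import FeatureKey, FeatureMatrix

DEFAULT_N_PERM = 40
DEFAULT_K = 500
DEFAULT_GRID_STEP = 0.01


def _auc_from_rank_sums(rank_sum_pos: np.ndarray, n_pos: int,
                        n_neg: int) -> np.ndarray:
    """AUC of 'positive class has higher values' from positive-rank sums."""
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def cstat(values: Sequence[float], labels: Sequence[int]) -> tuple[float, int]:
    """Oriented C-statistic of one feature.

    Computes the Mann-Whitney concordance probability ``a`` that a cancer
    sample has the higher intensity (ties count one half, via midranks) and
    folds it: returns ``(max(a, 1 - a), +1 if a >= 0.5 else -1)``.

    Raises
    ------
    DegenerateInputError
        If only one class is present.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be non-empty")
    ranks = rankdata(values)
    a = float(_auc_from_rank_sums(ranks[labels].sum(), n_pos, n_neg))
    return (a, 1) if a >= 0.5 else (1.0 - a, -1)


@dataclass(frozen=True)
class MarkerScore:
    """Per-feature screening result: oriented C plus its permutation draws."""

    feature: FeatureKey
    c_correct: float
    orientation: int
    c_random: np.ndarray

    def __post_init__(self) -> None:
        if not (0.5 - 1e-12 <= self.c_correct <= 1.0 + 1e-12):
            raise ValidationError("oriented C-statistic outside [0.5, 1]")


def monte_carlo_screen(fm: FeatureMatrix, labels: Sequence[int],
                       n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                       fold_random: bool = True,
                       groups: Sequence | None = None) -> list[MarkerScore]:
    """Score every feature under correct and random label assignment.

    Each of the ``n_perm`` Monte-Carlo replicates randomly reassigns the
    *subjects* to the two diagnosis groups once (preserving group sizes)
    and applies that same assignment to all features, preserving
    inter-feature correlation under the null.  ``groups`` gives the
    subject id of each row; rows sharing a subject (duplicate samples from
    two laboratories) keep a common label under permutation, exactly as a
    random assignment of diagnoses to subjects would.  When ``groups`` is
    omitted every row is its own subject.  ``fold_random`` controls
    whether permuted C-statistics are folded to [0.5, 1] like the
    correct-assignment ones (the default) or kept raw.
    """
    if n_perm < 2:
        raise ValidationError("n_perm must be >= 2 (SD undefined below)")
    labels = np.asarray(labels, dtype=bool)
    if labels.size != fm.n_samples:
        raise ValidationError("labels length must match sample count")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be non-empty")

    if groups is None:
        group_ids = np.arange(labels.size)
    else:
        group_ids = np.asarray(groups)
        if group_ids.size != labels.size:
            raise ValidationError("groups length must match sample count")
    uniq, inverse = np.unique(group_ids, return_inverse=True)
    group_labels = np.full(uniq.size, -1, dtype=int)
    for row, g in enumerate(inverse):
        if group_labels[g] == -1:
            group_labels[g] = int(labels[row])
        elif group_labels[g] != int(labels[row]):
            raise ValidationError(
                "a subject's duplicate samples carry different labels")

    X = fm.data.to_numpy(dtype=float)
    ranks = rankdata(X, axis=0)  # midranks per feature

    rng = np.random.default_rng(seed)
    assign = np.empty((n_perm + 1, labels.size), dtype=float)
    assign[0] = labels
    for p in range(n_perm):
        assign[p + 1] = rng.permutation(group_labels)[inverse]

    rank_sums = assign @ ranks                      # (n_perm+1, n_features)
    # class sizes can differ per permutation when subjects have unequal
    # numbers of duplicate rows
    npos_vec = assign.sum(axis=1, keepdims=True)
    nneg_vec = labels.size - npos_vec
    auc = (rank_sums - npos_vec * (npos_vec + 1) / 2.0) / (npos_vec * nneg_vec)
    correct = auc[0]
    random = auc[1:]

    orientation = np.where(correct >= 0.5, 1, -1)
    c_correct = np.where(correct >= 0.5, correct, 1.0 - correct)
    c_random = np.where(random >= 0.5, random, 1.0 - random) \
        if fold_random else random

    return [
        MarkerScore(feature=key, c_correct=float(c_correct[j]),
                    orientation=int(orientation[j]),
                    c_random=c_random[:, j].copy())
        for j, key in enumerate(fm.features)
    ]


@dataclass(frozen=True)
class ScreenCurves:
    """Correct- vs random-assignment count curves on a C-value grid.

    ``count_correct[i]`` is the number of features whose oriented
    C-statistic is at least ``grid[i]``; ``mean_count_random`` /
    ``sd_count_random`` summarize the same count across the Monte-Carlo
    replicates.  ``cutoff_c`` is the smallest grid value where the mean
    random count is exactly zero (no permutation produced a C that large);
    ``n_selected`` is the correct-assignment count there, and
    ``sigma_separation`` the curve separation in random-count SDs at the
    largest grid point at or below the cutoff where that SD is positive.
    """

    grid: np.ndarray
    count_correct: np.ndarray
    mean_count_random: np.ndarray
    sd_count_random: np.ndarray
    cutoff_c: float
    n_selected: int
    sigma_separation: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "c": self.grid,
            "count_correct": self.count_correct,
            "mean_count_random": self.mean_count_random,
            "sd_count_random": self.sd_count_random,
        })


def build_curves(scores: Sequence[MarkerScore],
                 grid_step: float = DEFAULT_GRID_STEP) -> ScreenCurves:
    """Build the count curves and locate the non-randomness cutoff."""
    if len(scores) == 0:
        raise ValidationError("no scores given")
    n_steps = int(round(0.5 / grid_step))
    grid = 0.5 + grid_step * np.arange(n_steps + 1)
    grid = np.round(grid, 12)

    c_correct = np.sort(np.array([s.c_correct for s in scores]))
    c_random = np.stack([s.c_random for s in scores], axis=1)  # (P, F)
    n_perm = c_random.shape[0]

    count_correct = len(c_correct) - np.searchsorted(
        c_correct, grid, side="left")
    counts_random = np.empty((n_perm, grid.size))
    for p in range(n_perm):
        row = np.sort(c_random[p])
        counts_random[p] = row.size - np.searchsorted(row, grid, side="left")
    mean_random = counts_random.mean(axis=0)
    sd_random = counts_random.std(axis=0, ddof=0)

    zero = np.flatnonzero(mean_random == 0)
    if zero.size:
        cut_idx = int(zero[0])
    else:
        cut_idx = grid.size - 1
        warnings.warn(
            "random-assignment curve never reaches zero on the grid; "
            "using the maximum grid value as cutoff", stacklevel=2)
    cutoff_c = float(grid[cut_idx])
    n_selected = int(count_correct[cut_idx])

    positive_sd = np.flatnonzero(sd_random[:cut_idx + 1] > 0)
    if positive_sd.size:
        j = int(positive_sd[-1])
        sigma = float(
            (count_correct[j] - mean_random[j]) / sd_random[j])
    else:
        sigma = float("nan")
    return ScreenCurves(grid, count_correct.astype(int), mean_random,
                        sd_random, cutoff_c, n_selected, sigma)


def select_top_k(scores: Sequence[MarkerScore], curves: ScreenCurves,
                 k: int = DEFAULT_K) -> list[FeatureKey]:
    """Top-K better-than-random features.

    Features with oriented C at or above the cutoff, ordered by descending
    C then ascending (segment, m/z) for a deterministic tie-break,
    truncated to ``k``.
    """
    eligible = [s for s in scores if s.c_correct >= curves.cutoff_c]
    eligible.sort(key=lambda s: (-s.c_correct, s.feature.segment,
                                 s.feature.mz))
    return [s.feature for s in eligible[:k]]


@dataclass(frozen=True)
class ScreenResult:
    """Full screening output: per-feature scores, curves, and selection."""

    scores: list[MarkerScore]
    curves: ScreenCurves
    selected: list[FeatureKey]
    k: int
    n_perm: int
    seed: int

    def score_for(self, key: FeatureKey) -> MarkerScore:
        for s in self.scores:
            if s.feature == key:
                return s
        raise KeyError(key)

    def to_json(self, path: str) -> None:
        payload = {
            "k": self.k,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "cutoff_c": self.curves.cutoff_c,
            "n_selected": self.curves.n_selected,
            "sigma_separation": self.curves.sigma_separation,
            "grid": self.curves.grid.tolist(),
            "count_correct": self.curves.count_correct.tolist(),
            "mean_count_random": self.curves.mean_count_random.tolist(),
            "sd_count_random": self.curves.sd_count_random.tolist(),
            "selected": [[k.segment, k.mz] for k in self.selected],
            "scores": [
                {
                    "segment": s.feature.segment,
                    "mz": s.feature.mz,
                    "c_correct": s.c_correct,
                    "orientation": s.orientation,
                    "c_random": s.c_random.tolist(),
                }
                for s in self.scores
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "ScreenResult":
        with open(path) as fh:
            payload = json.load(fh)
        scores = [
            MarkerScore(FeatureKey(d["segment"], d["mz"]), d["c_correct"],
                        d["orientation"], np.array(d["c_random"]))
            for d in payload["scores"]
        ]
        curves = ScreenCurves(
            np.array(payload["grid"]),
            np.array(payload["count_correct"], dtype=int),
            np.array(payload["mean_count_random"]),
            np.array(payload["sd_count_random"]),
            payload["cutoff_c"], payload["n_selected"],
            payload["sigma_separation"],
        )
        selected = [FeatureKey(s, m) for s, m in payload["selected"]]
        return cls(scores, curves, selected, payload["k"],
                   payload["n_perm"], payload["seed"])


def screen_features(fm: FeatureMatrix, labels: Sequence[int],
                    n_perm: int = DEFAULT_N_PERM, k: int = DEFAULT_K,
                    seed: int = 0, grid_step: float = DEFAULT_GRID_STEP,
                    fold_random: bool = True,
                    groups: Sequence | None = None) -> ScreenResult:
    """Run the full screen: score, build curves, select top-K."""
    scores = monte_carlo_screen(fm, labels, n_perm=n_perm, seed=seed,
                                fold_random=fold_random, groups=groups)
    curves = build_curves(scores, grid_step=grid_step)
    selected = select_top_k(scores, curves, k=k)
    return ScreenResult(scores, curves, selected, k, n_perm, seed)


def screening_labels(meta: pd.DataFrame) -> pd.Series:
    """Binary screening labels from metadata, indexed by sample_id.

    The biomarker comparison is tissue-confirmed cancer (group 3,
    cancer-positive) versus CT-negative controls (group 1,
    cancer-negative), restricted to model-building-phase breath samples;
    all other samples — other groups, room air, unknown status, blinded
    phase — are excluded from screening and flow through to prediction
    only.
    """
    breath = meta[(meta["sample_kind"] == "breath")
                  & (meta["phase"] == "model_building")]
    cancer = (breath["group"].astype(int) == 3) & \
        (breath["cancer_status"] == "positive")
    control = (breath["group"].astype(int) == 1) & \
        (breath["cancer_status"] == "negative")
    sel = breath[cancer | control]
    return pd.Series(
        (sel["group"].astype(int) == 3).astype(int).to_numpy(),
        index=sel["sample_id"].to_numpy(),
    )
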