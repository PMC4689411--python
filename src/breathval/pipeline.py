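"""End-to-end convenience layer tying the pipeline stages together.

These helpers chain normalization → binning → screening → WDA fitting →
blinded evaluation, in the two-phase design: markers and the predictor are
frozen on the model-building cohort, then applied unchanged to an
independent model-testing cohort whose labels are only consulted when the
report is unblinded.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import pandas as pd

from .config import PreprocessConfig
from .ion_table import FeatureMatrix, IonTable, bin_to_features, \
    normalize_table
from .screen import ScreenResult, screen_features, screening_labels
from .simulate import SimConfig, simulate_blinded_cohort, simulate_cohort
from .validation import blinded_report
from .wda import WDAResults, fit_wda


def build_feature_matrix(tables: Sequence[IonTable],
                         meta: pd.DataFrame | None = None,
                         config: PreprocessConfig | None = None
                         ) -> FeatureMatrix:
    """Normalize raw ion tables to the internal standard and bin them."""
    config = config or PreprocessConfig()
    normalized = [normalize_table(t, config) for t in tables]
    return bin_to_features(normalized, meta, config)


def discover_markers(fm: FeatureMatrix, meta: pd.DataFrame,
                     n_perm: int = 40, k: int = 500, seed: int = 0
                     ) -> tuple[ScreenResult, WDAResults]:
    """Screen markers and fit the WDA predictor on the screening samples.

    Screening and fitting both use only the tissue-confirmed-cancer vs
    CT-negative-control samples; other samples flow through to prediction
    only.
    """
    labels = screening_labels(meta)
    fm_train = fm.subset([s for s in fm.sample_ids if s in labels.index])
    y = labels.loc[fm_train.sample_ids].to_numpy()
    subjects = meta.set_index("sample_id").loc[
        fm_train.sample_ids, "subject_id"].to_numpy()
    screen = screen_features(fm_train, y, n_perm=n_perm, k=k, seed=seed,
                             groups=subjects)
    results = fit_wda(fm_train, y, screen.selected, screen)
    return screen, results


def study_replicate(config: SimConfig, n_test_cancer: int = 73,
                    n_test_control: int = 68, n_perm: int = 40,
                    k: int = 500) -> dict:
    """One full simulated study: build, freeze, blind-test, unblind.

    Simulates a model-building cohort under ``config``, screens and fits
    on it, simulates an independent model-testing cohort with the paper's
    blinded group sizes sharing the same ground truth, and evaluates the
    frozen predictor per laboratory.

    Returns a dict with the screen, the fitted results, planted-marker
    recovery, and the blinded report (per-lab C-statistic and operating
    point, inter-laboratory concordance).
    """
    meta, ta, tb, truth = simulate_cohort(config)
    fm = build_feature_matrix(ta + tb, meta)
    screen, results = discover_markers(fm, meta, n_perm=n_perm, k=k,
                                       seed=config.seed)

    informative = set(truth.informative_features)
    recovered = informative & set(screen.selected)
    recovery = len(recovered) / len(informative) if informative else \
        float("nan")

    test_config = replace(config, n_cancer=n_test_cancer,
                          n_control=n_test_control)
    meta_t, ta_t, tb_t, _ = simulate_blinded_cohort(test_config, truth)
    fm_a = build_feature_matrix(ta_t, meta_t)
    fm_b = build_feature_matrix(tb_t, meta_t)
    report = blinded_report(results, {"A": fm_a, "B": fm_b}, meta_t)
    c_stats = [lab["c_statistic"] for lab in report["labs"].values()]

    return {
        "truth": truth,
        "screen": screen,
        "results": results,
        "recovery": recovery,
        "n_selected": screen.curves.n_selected,
        "cutoff_c": screen.curves.cutoff_c,
        "sigma_separation": screen.curves.sigma_separation,
        "blinded_report": report,
        "blinded_c": sum(c_stats) / len(c_stats),
        "concordance_r": report.get("concordance", {}).get("r"),
    }
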