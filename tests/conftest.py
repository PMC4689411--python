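import numpy as np
import pandas as pd
import pytest

import breathval as bv


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated two-lab cohort with planted markers, preprocessed."""
    cfg = bv.SimConfig(n_cancer=40, n_control=40, n_segments=40,
                       ions_per_segment=5, n_informative=20,
                       target_auc=0.80, seed=11)
    meta, tables_a, tables_b, truth = bv.simulate_cohort(cfg)
    fm = bv.build_feature_matrix(tables_a + tables_b, meta)
    labels = bv.screening_labels(meta)
    y = labels.loc[fm.sample_ids].to_numpy()
    subjects = meta.set_index("sample_id").loc[
        fm.sample_ids, "subject_id"].to_numpy()
    return {
        "config": cfg,
        "meta": meta,
        "tables_a": tables_a,
        "tables_b": tables_b,
        "truth": truth,
        "fm": fm,
        "y": y,
        "subjects": subjects,
    }


@pytest.fixture
def write_ion_csv(tmp_path):
    """Write rows of (sample_id, rt, mz, intensity) to a CSV and return it."""

    def _write(rows, name="ions.csv", columns=None):
        path = tmp_path / name
        cols = columns or ["sample_id", "rt", "mz", "intensity"]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        return str(path)

    return _write


def make_feature_matrix(values, feature_names, sample_ids=None,
                        meta=None):
    """Build a FeatureMatrix directly from an array (test helper)."""
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=sample_ids, columns=feature_names)
    return bv.FeatureMatrix(data, meta)
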