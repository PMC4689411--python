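"""Ion-table reading, internal-standard normalization, and binning."""

import numpy as np
import pandas as pd
import pytest

import breathval as bv
from breathval.errors import (
    ConsistencyError,
    FormatError,
    MissingInternalStandardError,
    StateError,
    ValidationError,
)

from conftest import make_feature_matrix


def test_read_locates_internal_standard(write_ion_csv):
    path = write_ion_csv([
        ("s1", 100.0, 95, 1e6),
        ("s1", 100.0, 43, 2e5),
        ("s1", 500.0, 57, 1e4),
    ])
    t = bv.read_ion_table(path)
    assert t.is_record.intensity == 1e6
    assert t.is_record.mz == 95
    assert len(t) == 3


def test_fractional_mz_rounds_half_up(write_ion_csv):
    path = write_ion_csv([
        ("s1", 100.0, 95, 1e6),
        ("s1", 200.0, 56.6, 5.0),
        ("s1", 300.0, 56.5, 5.0),
        ("s1", 400.0, 56.4, 5.0),
    ])
    t = bv.read_ion_table(path)
    assert list(t.mz) == [95, 57, 57, 56]


def test_is_search_window_restricts_candidates(write_ion_csv):
    # the larger mz-95 peak lies outside the window and must be ignored
    path = write_ion_csv([
        ("s1", 50.0, 95, 9e9),
        ("s1", 700.0, 95, 1e6),
    ])
    cfg = bv.PreprocessConfig(is_rt_window=(600.0, 800.0))
    t = bv.read_ion_table(path, cfg)
    assert t.is_record.rt == 700.0
    cfg_bad = bv.PreprocessConfig(is_rt_window=(900.0, 1000.0))
    with pytest.raises(MissingInternalStandardError):
        bv.read_ion_table(path, cfg_bad)


@pytest.mark.parametrize("rows,columns,err", [
    ([("s1", 1.0, 95)], ["sample_id", "rt", "mz"], FormatError),
    ([("s1", 100.0, 43, 2e5)], None, MissingInternalStandardError),
    ([("s1", 100.0, 95, 1e6), ("s1", 1.0, 43, -2.0)], None, ValidationError),
])
def test_read_rejects_malformed_tables(write_ion_csv, rows, columns, err):
    path = write_ion_csv(rows, columns=columns)
    with pytest.raises(err):
        bv.read_ion_table(path)


def test_write_read_round_trip(tmp_path, small_cohort):
    t = small_cohort["tables_a"][0]
    path = str(tmp_path / "rt.csv")
    bv.write_ion_table(t, path)
    back = bv.read_ion_table(path)
    assert back.sample_id == t.sample_id
    np.testing.assert_array_equal(back.rt, t.rt)
    np.testing.assert_array_equal(back.mz, t.mz)
    np.testing.assert_array_equal(back.intensity, t.intensity)


def test_normalize_divides_by_internal_standard(write_ion_csv):
    path = write_ion_csv([
        ("s1", 100.0, 95, 1e6),
        ("s1", 100.0, 43, 2e5),
    ])
    n = bv.normalize_table(bv.read_ion_table(path))
    assert n.is_record.intensity == 1.0
    assert n.intensity[1] == pytest.approx(0.2)
    assert n.is_normalized


def test_normalize_rescales_retention_times(write_ion_csv):
    path = write_ion_csv([
        ("s1", 1000.0, 95, 1e6),
        ("s1", 500.0, 43, 2e5),
    ])
    cfg = bv.PreprocessConfig(reference_is_rt=1100.0)
    n = bv.normalize_table(bv.read_ion_table(path, cfg), cfg)
    assert n.rt[1] == pytest.approx(550.0)
    assert n.is_record.rt == pytest.approx(1100.0)


def test_normalize_is_idempotent(write_ion_csv):
    path = write_ion_csv([
        ("s1", 1100.0, 95, 1e6),
        ("s1", 500.0, 43, 2e5),
    ])
    cfg = bv.PreprocessConfig(reference_is_rt=1100.0)
    once = bv.normalize_table(bv.read_ion_table(path, cfg), cfg)
    twice = bv.normalize_table(once, cfg)
    np.testing.assert_array_equal(once.rt, twice.rt)
    np.testing.assert_array_equal(once.intensity, twice.intensity)


def test_zero_intensity_internal_standard_rejected():
    with pytest.raises(MissingInternalStandardError):
        bv.IonTable("s1", rt=[100.0], mz=[95], intensity=[0.0])


def test_binning_segment_assignment_and_summation():
    t = bv.IonTable(
        "s1",
        rt=[700.0, 1502.0, 1505.0, 1503.0],
        mz=[95, 43, 43, 43],
        intensity=[1.0, 0.1, 0.4, 0.2],
    )
    fm = bv.bin_to_features([t])
    cols = set(fm.data.columns)
    # floor(1502/5) = 300 (half-open), 1505 starts segment 301
    assert {"seg300_mz43", "seg301_mz43"} <= cols
    assert fm.data.loc["s1", "seg300_mz43"] == pytest.approx(0.3)
    assert fm.data.loc["s1", "seg301_mz43"] == pytest.approx(0.4)


def test_binning_rejects_unnormalized_tables():
    t = bv.IonTable("s1", rt=[700.0], mz=[95], intensity=[1e6])
    with pytest.raises(StateError):
        bv.bin_to_features([t])


def test_binning_conserves_total_intensity(small_cohort):
    t = bv.normalize_table(small_cohort["tables_a"][0])
    fm = bv.bin_to_features([t])
    assert fm.data.loc[t.sample_id].sum() == pytest.approx(
        t.intensity.sum())


def test_normalization_invariant_to_global_intensity_scale(small_cohort):
    t = small_cohort["tables_a"][0]
    scaled = bv.IonTable(t.sample_id, t.rt, t.mz, t.intensity * 7.5)
    fm1 = bv.bin_to_features([bv.normalize_table(t)])
    fm2 = bv.bin_to_features([bv.normalize_table(scaled)])
    pd.testing.assert_frame_equal(fm1.data, fm2.data)


def test_min_prevalence_drops_rare_features():
    t1 = bv.IonTable("s1", rt=[700.0, 10.0], mz=[95, 43],
                     intensity=[1.0, 0.5])
    t2 = bv.IonTable("s2", rt=[700.0], mz=[95], intensity=[1.0])
    cfg = bv.PreprocessConfig(min_prevalence=0.6)
    fm = bv.bin_to_features([t1, t2], config=cfg)
    # mz-43 feature present in 1/2 samples < 0.6 -> dropped; IS kept (2/2)
    assert "seg2_mz43" not in fm.data.columns
    assert "seg140_mz95" in fm.data.columns


def _meta_frame(**overrides):
    base = pd.DataFrame({
        "sample_id": ["a_A", "a_B", "b_A"],
        "subject_id": ["a", "a", "b"],
        "group": [3, 3, 1],
        "cancer_status": ["positive", "positive", "negative"],
        "lab": ["A", "B", "A"],
        "site": ["s", "s", "s"],
        "phase": ["model_building"] * 3,
        "sample_kind": ["breath"] * 3,
        "age": [60.0, 60.0, 55.0],
        "pack_years": [30.0, 30.0, 20.0],
        "sex": ["M", "M", "F"],
    })
    for col, vals in overrides.items():
        base[col] = vals
    return base


def test_metadata_validates_clean_table():
    out = bv.validate_metadata(_meta_frame())
    assert len(out) == 3


@pytest.mark.parametrize("overrides", [
    {"sample_id": ["a_A", "a_A", "b_A"]},                  # duplicate id
    {"group": [2, 2, 1]},                                  # positive in grp 2
    {"phase": ["model_building", "model_testing",
               "model_building"]},                         # both phases
    {"lab": ["A", "C", "A"]},                              # unknown lab
    {"lab": ["A", "A", "A"]},                              # dup subject/lab
    {"age": [60.0, 60.0, -1.0]},                           # negative age
])
def test_metadata_rejects_invariant_violations(overrides):
    with pytest.raises(ValidationError):
        bv.validate_metadata(_meta_frame(**overrides))


def test_feature_matrix_csv_round_trip(tmp_path, small_cohort):
    fm = small_cohort["fm"]
    path = str(tmp_path / "fm.csv")
    fm.to_csv(path)
    back = bv.FeatureMatrix.read_csv(path)
    pd.testing.assert_frame_equal(back.data, fm.data)


def test_export_marker_map_midpoints(small_cohort):
    fm = small_cohort["fm"]
    screen = bv.screen_features(fm, small_cohort["y"], seed=1,
                                groups=small_cohort["subjects"])
    table = bv.export_marker_map(fm, screen)
    assert list(table.columns) == ["rt_midpoint_s", "mz", "c_statistic"]
    for row, key in zip(table.itertuples(index=False), screen.selected):
        assert row.rt_midpoint_s == key.segment * 5 + 2.5
        assert row.mz == key.mz


def test_export_marker_map_empty_selection(small_cohort):
    fm = small_cohort["fm"]
    screen = bv.screen_features(fm, small_cohort["y"], seed=1,
                                groups=small_cohort["subjects"])
    empty = bv.ScreenResult(screen.scores, screen.curves, [], screen.k,
                            screen.n_perm, screen.seed)
    assert len(bv.export_marker_map(fm, empty)) == 0


def test_export_marker_map_detects_feature_mismatch(small_cohort):
    fm = small_cohort["fm"]
    screen = bv.screen_features(fm, small_cohort["y"], seed=1,
                                groups=small_cohort["subjects"])
    bogus = bv.ScreenResult(screen.scores, screen.curves,
                            [bv.FeatureKey(99999, 999)], screen.k,
                            screen.n_perm, screen.seed)
    with pytest.raises(ConsistencyError):
        bv.export_marker_map(fm, bogus)


def test_marker_map_recovers_alkane_like_mz_clusters():
    """Markers planted at the alkane fragment masses 43 and 57 dominate
    the exported marker map, matching the generator's ground truth."""
    cfg = bv.SimConfig(n_cancer=40, n_control=40, n_segments=60,
                       ions_per_segment=10, mz_range=(30, 60),
                       n_informative=25, target_auc=0.85,
                       informative_mz=(43, 57), seed=21)
    meta, ta, tb, truth = bv.simulate_cohort(cfg)
    fm = bv.build_feature_matrix(ta + tb, meta)
    labels = bv.screening_labels(meta)
    y = labels.loc[fm.sample_ids].to_numpy()
    subjects = meta.set_index("sample_id").loc[
        fm.sample_ids, "subject_id"].to_numpy()
    screen = bv.screen_features(fm, y, seed=21, groups=subjects)
    table = bv.export_marker_map(fm, screen)
    assert len(table) > 0
    frac_alkane = table["mz"].isin([43, 57]).mean()
    assert frac_alkane >= 0.8
    truly_informative = set(truth.informative_features)
    hits = sum(k in truly_informative for k in screen.selected)
    assert hits / len(screen.selected) >= 0.8
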