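"""Aligned GC-MS ion tables: reading, validation, normalization, binning.

The pipeline consumes the long-form output of chromatogram alignment
software (one row per detected ion: retention time in seconds, unit-mass
m/z, intensity) — it does not do peak detection itself.  Every chromatogram
carries a bromofluorobenzene internal standard whose m/z-95 ion anchors two
normalizations: intensities are expressed as ratios to the internal
standard's intensity, and retention times may be rescaled so the internal
standard elutes at a common reference time.  Normalized tables are then
binned into (retention-time segment, m/z) features to form the
samples-by-features matrix that all downstream statistics operate on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .config import PreprocessConfig
from .errors import (
    ConsistencyError,
    FormatError,
    MissingInternalStandardError,
    StateError,
    ValidationError,
)

ION_TABLE_COLUMNS = ["sample_id", "rt", "mz", "intensity"]
META_COLUMNS = [
    "sample_id", "subject_id", "group", "cancer_status", "lab", "site",
    "phase", "sample_kind", "age", "pack_years", "sex",
]

_FEATURE_RE = re.compile(r"^seg(\d+)_mz(\d+)$")


def _float_repr(v) -> str:
    """Shortest decimal text that round-trips to the same float64."""
    return repr(float(v))


class IonRecord(NamedTuple):
    """One aligned ion: retention time (s), unit-mass m/z, intensity."""

    rt: float
    mz: int
    intensity: float


class FeatureKey(NamedTuple):
    """A binned feature: retention-time segment index and unit-mass m/z.

    Segment ``k`` covers the half-open interval
    ``[k * width, (k + 1) * width)`` seconds.
    """

    segment: int
    mz: int

    @property
    def column(self) -> str:
        return f"seg{self.segment}_mz{self.mz}"

    @classmethod
    def from_column(cls, name: str) -> "FeatureKey":
        m = _FEATURE_RE.match(name)
        if m is None:
            raise FormatError(f"not a feature column name: {name!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    def rt_midpoint(self, segment_width_s: float = 5.0) -> float:
        return self.segment * segment_width_s + segment_width_s / 2.0


def round_half_up_mz(mz: np.ndarray | float) -> np.ndarray | int:
    """Round fractional m/z to unit mass, halves away from zero upward."""
    out = np.floor(np.asarray(mz, dtype=float) + 0.5).astype(int)
    return out if out.ndim else int(out)


@dataclass
class IonTable:
    """All aligned ions of one chromatogram, with its internal standard.

    Intensities and retention times are stored as parallel numpy arrays.
    The internal-standard record is the maximum-intensity record at the
    configured IS m/z inside the configured retention-time window; a table
    without one is rejected at construction.
    """

    sample_id: str
    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    config: PreprocessConfig = field(default_factory=PreprocessConfig)
    _is_index: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.mz = np.asarray(self.mz, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.rt.shape == self.mz.shape == self.intensity.shape):
            raise ValidationError("rt, mz, intensity must have equal length")
        if self.rt.size == 0:
            raise ValidationError(f"{self.sample_id}: empty ion table")
        if np.any(self.rt < 0):
            raise ValidationError(f"{self.sample_id}: negative retention time")
        if np.any(self.mz < 1):
            raise ValidationError(f"{self.sample_id}: m/z below 1")
        if np.any(self.intensity < 0):
            raise ValidationError(f"{self.sample_id}: negative intensity")
        self._is_index = self._locate_internal_standard()

    def _locate_internal_standard(self) -> int:
        lo, hi = self.config.is_rt_window
        cand = np.flatnonzero(
            (self.mz == self.config.is_mz) & (self.rt >= lo) & (self.rt <= hi)
        )
        if cand.size == 0:
            raise MissingInternalStandardError(
                f"{self.sample_id}: no m/z {self.config.is_mz} record in "
                f"retention-time window [{lo}, {hi}]"
            )
        idx = int(cand[np.argmax(self.intensity[cand])])
        if self.intensity[idx] <= 0:
            raise MissingInternalStandardError(
                f"{self.sample_id}: internal-standard intensity is zero"
            )
        return idx

    @property
    def is_record(self) -> IonRecord:
        i = self._is_index
        return IonRecord(float(self.rt[i]), int(self.mz[i]),
                         float(self.intensity[i]))

    @property
    def is_normalized(self) -> bool:
        return np.isclose(self.is_record.intensity, 1.0)

    def __len__(self) -> int:
        return int(self.rt.size)

    def records(self) -> Iterator[IonRecord]:
        for r, m, i in zip(self.rt, self.mz, self.intensity):
            yield IonRecord(float(r), int(m), float(i))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "rt": self.rt,
                "mz": self.mz,
                "intensity": self.intensity,
            }
        )


def _table_from_frame(sample_id: str, df: pd.DataFrame,
                      config: PreprocessConfig) -> IonTable:
    return IonTable(
        sample_id=str(sample_id),
        rt=df["rt"].to_numpy(dtype=float),
        mz=round_half_up_mz(df["mz"].to_numpy(dtype=float)),
        intensity=df["intensity"].to_numpy(dtype=float),
        config=config,
    )


def read_ion_tables(path: str,
                    config: PreprocessConfig | None = None) -> list[IonTable]:
    """Read a long-form ion-table CSV (possibly pooled over samples).

    Returns one validated :class:`IonTable` per distinct ``sample_id``,
    in order of first appearance. Fractional m/z values are rounded half-up
    to unit mass.
    """
    config = config or PreprocessConfig()
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    tables = []
    for sid in df["sample_id"].drop_duplicates():
        tables.append(_table_from_frame(sid, df[df["sample_id"] == sid], config))
    return tables


def read_ion_table(path: str,
                   config: PreprocessConfig | None = None) -> IonTable:
    """Read a single-sample ion-table CSV; error if the file pools samples."""
    tables = read_ion_tables(path, config)
    if len(tables) != 1:
        raise FormatError(
            f"{path}: expected one sample_id, found {len(tables)}"
        )
    return tables[0]


def write_ion_table(table: IonTable | Sequence[IonTable], path: str) -> None:
    """Write one or several ion tables to a long-form CSV."""
    tables = [table] if isinstance(table, IonTable) else list(table)
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
        path, index=False, float_format=_float_repr  # shortest exact round-trip
    )


def normalize_table(t: IonTable,
                    config: PreprocessConfig | None = None) -> IonTable:
    """Normalize a table to its internal standard.

    Every intensity is divided by the internal standard's intensity (so the
    IS record itself becomes exactly 1) and, when the config sets a
    reference IS retention time, all retention times are rescaled by
    ``reference_is_rt / observed_is_rt`` — a single-anchor linear alignment.
    """
    config = config or t.config
    is_rec = t.is_record
    rt = t.rt
    if config.reference_is_rt is not None:
        rt = rt * (config.reference_is_rt / is_rec.rt)
    return IonTable(
        sample_id=t.sample_id,
        rt=rt,
        mz=t.mz,
        intensity=t.intensity / is_rec.intensity,
        config=config,
    )


# ---------------------------------------------------------------------------
# Sample metadata


VALID_GROUPS = {1, 2, 3, 4}
VALID_STATUS = {"positive", "negative", "unknown"}
VALID_LABS = {"A", "B"}
VALID_PHASES = {"model_building", "model_testing"}
VALID_KINDS = {"breath", "room_air"}
VALID_SEX = {"M", "F", ""}


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table against the cohort invariants.

    Checks: required columns; enum-valued fields; unique sample ids; at most
    one sample per (subject, lab, sample kind); cancer-positive status only
    in the screening-CT and tissue-diagnosis groups (1 and 3); no subject in
    both study phases.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns {missing}")
    meta = meta.copy()
    meta["group"] = meta["group"].astype(int)
    for col in ("sample_id", "subject_id", "cancer_status", "lab", "site",
                "phase", "sample_kind"):
        meta[col] = meta[col].astype(str)
    meta["sex"] = meta["sex"].fillna("").astype(str)

    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    if not set(meta["group"]) <= VALID_GROUPS:
        raise ValidationError("group must be 1-4")
    for col, valid in (("cancer_status", VALID_STATUS), ("lab", VALID_LABS),
                       ("phase", VALID_PHASES), ("sample_kind", VALID_KINDS),
                       ("sex", VALID_SEX)):
        bad = set(meta[col]) - valid
        if bad:
            raise ValidationError(f"invalid {col} values: {sorted(bad)}")
    dup = meta.duplicated(subset=["subject_id", "lab", "sample_kind"])
    if dup.any():
        raise ValidationError(
            "a subject has more than one sample per lab per sample kind"
        )
    pos = meta[meta["cancer_status"] == "positive"]
    if not set(pos["group"]) <= {1, 3}:
        raise ValidationError("cancer-positive status outside groups 1 and 3")
    phases_per_subject = meta.groupby("subject_id")["phase"].nunique()
    if (phases_per_subject > 1).any():
        raise ValidationError("a subject appears in both study phases")
    for col in ("age", "pack_years"):
        vals = pd.to_numeric(meta[col], errors="coerce")
        if (vals.dropna() < 0).any():
            raise ValidationError(f"negative {col}")
        meta[col] = vals
    return meta


def read_sample_metadata(path: str) -> pd.DataFrame:
    """Read and validate the sample-metadata CSV (empty string = missing)."""
    meta = pd.read_csv(path, keep_default_na=False,
                       na_values={"age": [""], "pack_years": [""]})
    return validate_metadata(meta)


def write_sample_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature matrix


@dataclass
class FeatureMatrix:
    """Samples-by-features matrix of internal-standard-normalized intensities.

    ``data`` is indexed by sample_id with one column per
    (segment, m/z) feature, named ``seg<k>_mz<m>``; a feature absent from a
    sample's chromatogram has value exactly 0 (absence of signal).  ``meta``
    is the validated sample-metadata table aligned to the rows.
    """

    data: pd.DataFrame
    meta: pd.DataFrame | None = None
    segment_width_s: float = 5.0

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("feature matrix has negative values")
        for name in self.data.columns:
            FeatureKey.from_column(name)
        if self.meta is not None:
            meta = self.meta.set_index("sample_id") \
                if "sample_id" in self.meta.columns else self.meta
            missing = set(self.data.index) - set(meta.index)
            if missing:
                raise ConsistencyError(
                    f"samples without metadata: {sorted(missing)[:5]}"
                )
            self.meta = (meta.loc[self.data.index]
                         .rename_axis("sample_id").reset_index())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[FeatureKey]:
        return [FeatureKey.from_column(c) for c in self.data.columns]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values_for(self, key: FeatureKey) -> np.ndarray:
        """Per-sample values of one feature; zeros if the feature is absent."""
        if key.column in self.data.columns:
            return self.data[key.column].to_numpy(dtype=float)
        return np.zeros(self.n_samples)

    def subset(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        meta = None
        if self.meta is not None:
            keep = self.meta["sample_id"].isin(sample_ids)
            meta = self.meta[keep].reset_index(drop=True)
        return FeatureMatrix(self.data.loc[list(sample_ids)], meta,
                             self.segment_width_s)

    def to_csv(self, path: str) -> None:
        out = self.data.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False, float_format=_float_repr)

    @classmethod
    def read_csv(cls, path: str, meta: pd.DataFrame | None = None,
                 segment_width_s: float = 5.0) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        if "sample_id" not in df.columns:
            raise FormatError(f"{path}: missing sample_id column")
        df = df.set_index(df["sample_id"].astype(str)).drop(
            columns="sample_id")
        df.index.name = None
        return cls(df, meta, segment_width_s)


def bin_to_features(tables: Sequence[IonTable],
                    meta: pd.DataFrame | None = None,
                    config: PreprocessConfig | None = None) -> FeatureMatrix:
    """Bin normalized ion tables into the (segment, m/z) feature matrix.

    Each record lands in segment ``floor(rt / width)`` (half-open bins);
    multiple records of one (sample, segment, m/z) are summed — ion current
    is additive.  Features non-zero in fewer than ``min_prevalence`` of the
    samples are dropped.  Tables must be internal-standard normalized.
    """
    config = config or PreprocessConfig()
    if len(tables) == 0:
        raise ValidationError("no ion tables given")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id among ion tables")
    frames = []
    for t in tables:
        if not t.is_normalized:
            raise StateError(
                f"{t.sample_id}: table not normalized (IS intensity != 1)"
            )
        seg = np.floor(t.rt / config.segment_width_s).astype(int)
        frames.append(pd.DataFrame({
            "sample_id": t.sample_id, "segment": seg, "mz": t.mz,
            "intensity": t.intensity,
        }))
    long = pd.concat(frames, ignore_index=True)
    wide = (
        long.groupby(["sample_id", "segment", "mz"], sort=True)["intensity"]
        .sum()
        .unstack(["segment", "mz"], fill_value=0.0)
    )
    wide = wide.reindex(ids)  # preserve input sample order
    wide.index.name = None
    wide = wide.loc[:, sorted(wide.columns)]
    wide.columns = [FeatureKey(int(s), int(m)).column
                    for s, m in wide.columns]
    if config.min_prevalence > 0:
        prevalence = (wide > 0).mean(axis=0)
        wide = wide.loc[:, prevalence >= config.min_prevalence]
    return FeatureMatrix(wide, meta, config.segment_width_s)


def export_marker_map(fm: FeatureMatrix, screen) -> pd.DataFrame:
    """Tabulate selected markers as (retention-time midpoint, m/z, C).

    Produces the scatter-ready table behind the marker-cluster view:
    vertical stripes are co-eluting fragment ions of one parent VOC,
    horizontal stripes at m/z 43 and 57 are alkane-series fragments.
    """
    scored = {s.feature: s.c_correct for s in screen.scores}
    fm_features = set(fm.features)
    rows = []
    for key in screen.selected:
        if key not in fm_features or key not in scored:
            raise ConsistencyError(
                f"selected feature {key} not present in matrix/scores"
            )
        rows.append({
            "rt_midpoint_s": key.rt_midpoint(fm.segment_width_s),
            "mz": key.mz,
            "c_statistic": scored[key],
        })
    return pd.DataFrame(rows, columns=["rt_midpoint_s", "mz", "c_statistic"])
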