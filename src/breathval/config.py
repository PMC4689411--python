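"""Preprocessing configuration.

Holds the handful of knobs that control ion-table normalization and
retention-time binning. Values mirror the assay conventions: the
bromofluorobenzene internal standard is tracked through its m/z-95 ion and
chromatograms are binned into 5-second retention-time segments.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration for reading, normalizing and binning ion tables.

    Parameters
    ----------
    segment_width_s
        Width of a retention-time segment in seconds (default 5).
    is_mz
        Unit mass of the internal-standard ion (default 95,
        bromofluorobenzene).
    reference_is_rt
        Reference retention time (seconds) of the internal standard.  When
        set, each table's retention times are rescaled by
        ``reference_is_rt / observed_is_rt`` during normalization; when
        ``None`` retention times are left on the observed scale.
    min_prevalence
        Features present (non-zero) in fewer than this fraction of samples
        are dropped during binning.  Default 0: keep everything.
    is_rt_window
        ``(lo, hi)`` retention-time window (seconds) searched for the
        internal-standard record; default the whole run.
    """

    segment_width_s: float = 5.0
    is_mz: int = 95
    reference_is_rt: float | None = None
    min_prevalence: float = 0.0
    is_rt_window: tuple[float, float] = (0.0, math.inf)

    def __post_init__(self) -> None:
        if self.segment_width_s <= 0:
            raise ValidationError("segment_width_s must be positive")
        if not (0.0 <= self.min_prevalence <= 1.0):
            raise ValidationError("min_prevalence must lie in [0, 1]")
        lo, hi = self.is_rt_window
        if lo < 0 or hi < lo:
            raise ValidationError("is_rt_window must satisfy 0 <= lo <= hi")

    @classmethod
    def from_yaml(cls, path: str) -> "PreprocessConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "is_rt_window" in raw:
            raw["is_rt_window"] = tuple(raw["is_rt_window"])
        return cls(**raw)
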