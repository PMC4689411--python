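"""Analytic model of combining two diagnostic tests in a screened population.

Two binary tests A and B with known sensitivity and specificity are
combined under one of two rules, assuming conditional independence of the
tests given disease status:

* ``BOTH_POSITIVE`` (series): disease called only when both tests are
  positive — sensitivity ``sensA * sensB``, specificity
  ``1 - (1 - specA) * (1 - specB)``; specificity rises.
* ``EITHER_POSITIVE`` (parallel): disease called when either test is
  positive — sensitivity ``1 - (1 - sensA) * (1 - sensB)``, specificity
  ``specA * specB``; sensitivity rises.

Predictive values at a disease prevalence follow Bayes' rule:
``PPV = sens * prev / (sens * prev + (1 - spec) * (1 - prev))`` and
``NPV = spec * (1 - prev) / (spec * (1 - prev) + (1 - sens) * prev)``.
Expected true/false positive/negative counts among ``n`` screened people
are the corresponding cell probabilities times ``n``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ValidationError


class CombinationRule(str, enum.Enum):
    BOTH_POSITIVE = "BOTH_POSITIVE"
    EITHER_POSITIVE = "EITHER_POSITIVE"


@dataclass(frozen=True)
class TestProfile:
    """A diagnostic test summarized by its sensitivity and specificity."""

    name: str
    sens: float
    spec: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sens <= 1.0 and 0.0 <= self.spec <= 1.0):
            raise ValidationError("sens and spec must lie in [0, 1]")


def combine(a: TestProfile, b: TestProfile,
            rule: CombinationRule | str) -> TestProfile:
    """Sensitivity/specificity of two conditionally independent tests."""
    rule = CombinationRule(rule)
    if rule is CombinationRule.BOTH_POSITIVE:
        sens = a.sens * b.sens
        spec = 1.0 - (1.0 - a.spec) * (1.0 - b.spec)
    else:
        sens = 1.0 - (1.0 - a.sens) * (1.0 - b.sens)
        spec = a.spec * b.spec
    return TestProfile(f"{a.name}+{b.name}[{rule.value}]", sens, spec)


def _check_prevalence(prevalence: float) -> None:
    if not (0.0 < prevalence < 1.0):
        raise ValidationError("prevalence must lie strictly in (0, 1)")


def ppv(t: TestProfile, prevalence: float) -> float:
    """Positive predictive value at the given disease prevalence."""
    _check_prevalence(prevalence)
    num = t.sens * prevalence
    return num / (num + (1.0 - t.spec) * (1.0 - prevalence))


def npv(t: TestProfile, prevalence: float) -> float:
    """Negative predictive value at the given disease prevalence."""
    _check_prevalence(prevalence)
    num = t.spec * (1.0 - prevalence)
    return num / (num + (1.0 - t.sens) * prevalence)


def population_counts(t: TestProfile, prevalence: float,
                      n_screened: float) -> dict:
    """Expected TP/FN/TN/FP among ``n_screened`` people.

    Exact (unrounded) values under ``exact``; nearest-integer display
    values under ``rounded``.  The four exact counts sum to ``n_screened``.
    """
    _check_prevalence(prevalence)
    if n_screened < 1:
        raise ValidationError("n_screened must be >= 1")
    exact = {
        "TP": t.sens * prevalence * n_screened,
        "FN": (1.0 - t.sens) * prevalence * n_screened,
        "FP": (1.0 - t.spec) * (1.0 - prevalence) * n_screened,
        "TN": t.spec * (1.0 - prevalence) * n_screened,
    }
    return {
        "exact": exact,
        "rounded": {k: int(round(v)) for k, v in exact.items()},
    }


@dataclass(frozen=True)
class CombinedOutcome:
    """Full outcome of combining two tests at a prevalence and cohort size."""

    rule: CombinationRule
    profile: TestProfile
    prevalence: float
    n_screened: float
    ppv: float
    npv: float
    counts: dict


def combined_outcome(a: TestProfile, b: TestProfile,
                     rule: CombinationRule | str, prevalence: float,
                     n_screened: float = 1_000_000) -> CombinedOutcome:
    """Combine two tests and evaluate the screened-population outcome."""
    rule = CombinationRule(rule)
    profile = combine(a, b, rule)
    return CombinedOutcome(
        rule=rule,
        profile=profile,
        prevalence=prevalence,
        n_screened=n_screened,
        ppv=ppv(profile, prevalence),
        npv=npv(profile, prevalence),
        counts=population_counts(profile, prevalence, n_screened),
    )
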