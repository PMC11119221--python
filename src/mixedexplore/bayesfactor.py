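"""Bayes-factor arithmetic for cross-validating criterion-based nominations.

Two nominated models are compared through their log Bayes factors against a
common baseline (conventionally the null model): the evidence statistic is
``2·(ln BF_A0 − ln BF_B0)``, interpreted on the Kass–Raftery scale, where
``2·ln BF ≥ 2`` is positive evidence and ``≥ 10`` very strong evidence.

When bridge-sampling BFs are unavailable, the Schwarz (BIC) approximation
``ln BF(model vs baseline) ≈ (BIC_baseline − BIC_model) / 2`` — valid under
unit-information priors and large N — turns any exploration table into
approximate Bayes factors.  Because the map is a monotone transform of BIC,
rankings by approximate BF and by BIC coincide exactly; the approximation
adds interpretability (evidence categories), not a new ordering.  All logs
are natural; the "2·log BF" convention is applied only at reporting time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BFComparison",
    "approx_log_bf_from_bic",
    "compare_nominations",
    "interpret_2logbf",
    "two_log_bf_diff",
]

#: Kass–Raftery bands on |2·ln BF|: upper edge -> label.
_BANDS = ((2.0, "weak"), (6.0, "positive"), (10.0, "strong"),
          (math.inf, "very strong"))


@dataclass(frozen=True)
class BFComparison:
    """Evidence comparison of model A vs model B through a shared baseline."""

    label_a: str
    label_b: str
    log_bf_a0: float
    log_bf_b0: float

    @property
    def two_log_bf_diff(self) -> float:
        return two_log_bf_diff(self.log_bf_a0, self.log_bf_b0)

    @property
    def category(self) -> str:
        return interpret_2logbf(self.two_log_bf_diff)

    @property
    def favored(self) -> str:
        d = self.two_log_bf_diff
        if d == 0:
            return "neither"
        return self.label_a if d > 0 else self.label_b


def two_log_bf_diff(log_bf_a0: float, log_bf_b0: float) -> float:
    """``2·(ln BF_A0 − ln BF_B0)``: evidence for A over B via a common baseline."""
    if not (math.isfinite(log_bf_a0) and math.isfinite(log_bf_b0)):
        raise ValueError("log Bayes factors must be finite")
    return 2.0 * (log_bf_a0 - log_bf_b0)


def interpret_2logbf(value: float) -> str:
    """Kass–Raftery evidence category for a 2·ln BF difference.

    The category depends on |value| only — [0,2) weak (not worth more than
    a bare mention), [2,6) positive, [6,10) strong, ≥10 very strong — with
    the *direction* of support carried by the sign, reported separately.
    """
    if not math.isfinite(value):
        raise ValueError("2logBF value must be finite")
    mag = abs(value)
    for edge, label in _BANDS:
        if mag < edge:
            return label
    raise AssertionError("unreachable")


def approx_log_bf_from_bic(bic_model: float, bic_baseline: float) -> float:
    """Schwarz approximation: ``ln BF ≈ (BIC_baseline − BIC_model) / 2``.

    Both BICs must come from fits on identical observations; mixing row
    sets makes the criteria, and hence the approximation, meaningless.
    """
    if not (math.isfinite(bic_model) and math.isfinite(bic_baseline)):
        raise ValueError("BIC values must be finite")
    return (bic_baseline - bic_model) / 2.0


def compare_nominations(
    labeled_bics: dict[str, float], baseline_label: str
) -> list[BFComparison]:
    """Pairwise evidence comparisons of all models vs ``baseline_label``.

    Returns one :class:`BFComparison` per unordered pair of non-baseline
    models, each built from the BIC-approximated log BFs vs the baseline.
    """
    if baseline_label not in labeled_bics:
        raise KeyError(f"baseline {baseline_label!r} not among models")
    base = labeled_bics[baseline_label]
    log_bfs = {
        lab: approx_log_bf_from_bic(bic, base)
        for lab, bic in labeled_bics.items()
        if lab != baseline_label
    }
    labels = list(log_bfs)
    return [
        BFComparison(a, b, log_bfs[a], log_bfs[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    ]
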