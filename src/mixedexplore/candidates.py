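"""Exhaustive enumeration of admissible candidate mixed models.

Given a full model with ``f`` free fixed effects, ``s`` of them eligible as
random slopes over a single grouping factor, the admissible candidates are:

1. every subset of the free fixed effects (plus all forced covariates),
   with no random part — ``2^f`` models;
2. if a group is present, the same subsets with a random intercept —
   another ``2^f`` models;
3. for every fixed subset ``S``, every nonempty subset of the slope-eligible
   members of ``S`` as correlated random slopes (always with a random
   intercept).

A random slope is only admissible when its fixed effect is in the model,
and slopes never appear without the intercept.  Summing stratum 3 over
subsets gives ``2^(f-s)·3^s − 2^f`` models (each slope-eligible predictor is
independently absent / fixed-only / fixed+slope), hence the closed-form
total ``2^f + 2^(f-s)·3^s`` with a group and ``2^f`` without.

The enumeration order is stratified — fixed-only, random-intercept,
random-slope — and within each stratum subsets are ordered by increasing
size, ties broken by declaration order, so output is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

from .formula import FormulaError, ModelFormula

__all__ = [
    "CandidateSet",
    "TooManyCandidatesError",
    "count_candidates",
    "enumerate_candidates",
]

#: Enumeration refuses (without ``force=True``) above this many candidates;
#: the model space grows exponentially in the number of free predictors.
DEFAULT_CANDIDATE_CEILING = 10_000

STRATUM_FIXED = "fixed_only"
STRATUM_INTERCEPT = "random_intercept"
STRATUM_SLOPE = "random_slope"


class TooManyCandidatesError(RuntimeError):
    """Candidate space exceeds the safety ceiling and no override was given."""


@dataclass(frozen=True)
class CandidateSet:
    """Ordered candidate models with their stratum labels."""

    candidates: tuple[ModelFormula, ...]
    strata: tuple[str, ...]
    full_spec: ModelFormula

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self) -> Iterator[ModelFormula]:
        return iter(self.candidates)

    def rendered(self) -> list[str]:
        return [m.render() for m in self.candidates]


def count_candidates(f: int, s: int, has_group: bool = True) -> int:
    """Closed-form size of the candidate space.

    ``f`` free fixed predictors, ``s`` of them slope-eligible.  Returns
    ``2^f`` without a grouping variable, otherwise ``2^f + 2^(f-s)·3^s``.
    """
    if not (isinstance(f, int) and isinstance(s, int)):
        raise TypeError("f and s must be integers")
    if f < 0 or s < 0:
        raise ValueError("f and s must be nonnegative")
    if s > f:
        raise ValueError(f"slope candidates ({s}) cannot exceed free predictors ({f})")
    if not has_group:
        return 2**f
    return 2**f + 2 ** (f - s) * 3**s


def _ordered_subsets(terms: tuple[str, ...]) -> Iterator[tuple[str, ...]]:
    """Subsets by increasing size; within a size, lexicographic by position."""
    for r in range(len(terms) + 1):
        yield from combinations(terms, r)


def enumerate_candidates(
    full: ModelFormula,
    ceiling: int = DEFAULT_CANDIDATE_CEILING,
    force: bool = False,
) -> CandidateSet:
    """Generate every admissible candidate implied by the full model.

    ``full`` carries the free fixed effects, forced covariates, grouping
    variable and the slope-eligible terms (its ``random_slopes``).  Raises
    :class:`TooManyCandidatesError` when the space exceeds ``ceiling``
    unless ``force`` is set.
    """
    if set(full.random_slopes) & set(full.forced):
        raise FormulaError("forced covariates cannot be random-slope candidates")
    f = len(full.fixed_free)
    s = len(full.random_slopes)
    total = count_candidates(f, s, has_group=full.group is not None)
    if total > ceiling and not force:
        raise TooManyCandidatesError(
            f"{total} candidate models exceed the ceiling of {ceiling}; "
            "the space grows exponentially with free predictors — restrict "
            "the model (more forced terms, fewer slope candidates) or "
            "override the ceiling to proceed"
        )

    slope_pool = set(full.random_slopes)

    def _sub(fixed_subset: tuple[str, ...], **rand) -> ModelFormula:
        order = tuple(
            t for t in full.term_order if t in fixed_subset or t in full.forced
        )
        return ModelFormula(
            response=full.response,
            fixed_free=fixed_subset,
            forced=full.forced,
            term_order=order,
            **rand,
        )

    models: list[ModelFormula] = []
    strata: list[str] = []

    for subset in _ordered_subsets(full.fixed_free):
        models.append(_sub(subset))
        strata.append(STRATUM_FIXED)

    if full.group is not None:
        for subset in _ordered_subsets(full.fixed_free):
            models.append(
                _sub(subset, group=full.group, has_random_intercept=True)
            )
            strata.append(STRATUM_INTERCEPT)
        for subset in _ordered_subsets(full.fixed_free):
            eligible = tuple(t for t in subset if t in slope_pool)
            for r in range(1, len(eligible) + 1):
                for sl in combinations(eligible, r):
                    models.append(
                        _sub(
                            subset,
                            group=full.group,
                            has_random_intercept=True,
                            random_slopes=sl,
                        )
                    )
                    strata.append(STRATUM_SLOPE)

    assert len(models) == total, "enumeration disagrees with closed form"
    rendered = [m.render() for m in models]
    assert len(set(rendered)) == len(rendered), "duplicate candidates"
    return CandidateSet(tuple(models), tuple(strata), full)
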