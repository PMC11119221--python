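"""Structured mixed-model formulas.

A :class:`ModelFormula` describes one candidate linear mixed model in the
restricted grammar this package explores: an additive fixed part
``y ~ t1 + t2 + ...`` over plain column names, optionally followed by a
single random part ``(1 | g)`` or ``(1 + s1 + ... | g)`` over one grouping
factor.  Interactions, transformations, nested or crossed grouping factors
are deliberately rejected: the exhaustive enumerator only ever needs
additive terms and one group.

Fixed terms are split into *free* terms (the predictors the enumerator
toggles on and off) and *forced* terms (covariates that every candidate
must contain, e.g. a demographics block).  Random slopes always come with a
random intercept and must have their fixed effect present in the model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "FormulaError",
    "ModelFormula",
    "parse_formula",
    "render_formula",
]


class FormulaError(ValueError):
    """Raised for malformed formulas or inadmissible model structures."""


_NAME_RE = re.compile(r"^[A-Za-z_.][A-Za-z0-9_.]*$")


@dataclass(frozen=True)
class ModelFormula:
    """One candidate model: fixed part, forced covariates, random part.

    Parameters
    ----------
    response:
        Outcome column name.
    fixed_free:
        Free fixed-effect terms, in declaration order.  These are the
        terms the candidate enumerator varies.
    forced:
        Always-included covariate terms, in declaration order; disjoint
        from ``fixed_free``.
    group:
        Grouping column for the random part, or ``None`` for a pure
        fixed-effects model.
    has_random_intercept:
        Whether the model carries a group-level intercept deviation.
    random_slopes:
        Terms with group-level slope deviations; each must appear in
        ``fixed_free`` and implies a random intercept.
    term_order:
        Rendering order of all fixed terms (free and forced interleaved as
        declared in the source formula).  Defaults to free terms followed
        by forced terms.
    """

    response: str
    fixed_free: tuple[str, ...] = ()
    forced: tuple[str, ...] = ()
    group: str | None = None
    has_random_intercept: bool = False
    random_slopes: tuple[str, ...] = field(default=())
    term_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_free", tuple(self.fixed_free))
        object.__setattr__(self, "forced", tuple(self.forced))
        object.__setattr__(self, "random_slopes", tuple(self.random_slopes))
        if not self.term_order:
            object.__setattr__(
                self, "term_order", self.fixed_free + self.forced
            )
        else:
            object.__setattr__(self, "term_order", tuple(self.term_order))
        self._validate()

    def _validate(self) -> None:
        for name in (self.response, *self.fixed_free, *self.forced):
            if not _NAME_RE.match(name):
                raise FormulaError(f"invalid column name: {name!r}")
        all_fixed = self.fixed_free + self.forced
        if len(set(all_fixed)) != len(all_fixed):
            raise FormulaError(f"duplicate terms in fixed part: {all_fixed}")
        if self.response in all_fixed:
            raise FormulaError(
                f"response {self.response!r} also appears as a predictor"
            )
        if self.random_slopes and not self.has_random_intercept:
            raise FormulaError(
                "random slopes without a random intercept are inadmissible"
            )
        if len(set(self.random_slopes)) != len(self.random_slopes):
            raise FormulaError(f"duplicate random slopes: {self.random_slopes}")
        missing = [s for s in self.random_slopes if s not in self.fixed_free]
        if missing:
            raise FormulaError(
                f"random slope(s) {missing} lack a matching free fixed effect"
            )
        if self.group is None:
            if self.has_random_intercept or self.random_slopes:
                raise FormulaError("random part requires a grouping variable")
        else:
            if not _NAME_RE.match(self.group):
                raise FormulaError(f"invalid group name: {self.group!r}")
            if self.group in all_fixed or self.group == self.response:
                raise FormulaError(
                    f"group {self.group!r} may not also be a model term"
                )
        if sorted(self.term_order) != sorted(self.fixed_free + self.forced):
            raise FormulaError(
                "term_order must be a permutation of the fixed terms"
            )

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        """All fixed terms in declaration (rendering) order."""
        return self.term_order

    @property
    def q(self) -> int:
        """Random-effect dimension: 0, or 1 + number of slopes."""
        if not self.has_random_intercept:
            return 0
        return 1 + len(self.random_slopes)

    @property
    def columns(self) -> tuple[str, ...]:
        """Every data column the model references."""
        cols = (self.response, *self.fixed_terms)
        if self.group is not None:
            cols = cols + (self.group,)
        return cols

    def render(self) -> str:
        return render_formula(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _split_terms(rhs: str) -> list[str]:
    terms = [t.strip() for t in rhs.split("+")]
    if any(not t for t in terms):
        raise FormulaError(f"empty term in formula right-hand side: {rhs!r}")
    return terms


def parse_formula(
    text: str,
    group: str | None = None,
    slopes: list[str] | tuple[str, ...] = (),
    forced: list[str] | tuple[str, ...] = (),
) -> ModelFormula:
    """Parse a full-model specification into a :class:`ModelFormula`.

    ``text`` is an additive Wilkinson formula ``"Y ~ X1 + X2 + X3"``; it
    may alternatively embed the random part directly, e.g.
    ``"Y ~ X1 + X2 + X3 + (1 + X1 + X2 | G)"``, in which case ``group``
    and ``slopes`` must not also be given.  ``slopes`` names the random
    slope candidates over ``group``; ``forced`` names terms of ``text``
    that every candidate must keep.  Free fixed effects are the remaining
    terms.
    """
    if text.count("~") != 1:
        raise FormulaError(f"formula must contain exactly one '~': {text!r}")
    lhs, rhs = (side.strip() for side in text.split("~"))
    if not lhs:
        raise FormulaError("missing response on left-hand side")

    rand_match = re.search(r"\(([^)|]*)\|([^)]*)\)", rhs)
    slopes = list(slopes)
    if rand_match:
        if group is not None or slopes:
            raise FormulaError(
                "random part given both inline and via group=/slopes= arguments"
            )
        inner = _split_terms(rand_match.group(1))
        if inner[0] != "1":
            raise FormulaError(
                f"random part must start with '1' (intercept): {rand_match.group(0)!r}"
            )
        slopes = inner[1:]
        group = rand_match.group(2).strip()
        rhs = (rhs[: rand_match.start()] + rhs[rand_match.end() :]).strip(" +")
    if "(" in rhs or ")" in rhs or "|" in rhs:
        raise FormulaError(f"unparseable random part in {rhs!r}")
    if "*" in rhs or ":" in rhs:
        raise FormulaError("interaction terms are not supported")

    terms = _split_terms(rhs)
    if len(set(terms)) != len(terms):
        raise FormulaError(f"duplicate terms in formula: {terms}")
    terms = [t for t in terms if t != "1"]  # explicit intercept marker
    forced = list(forced)
    for f in forced:
        if f not in terms:
            raise FormulaError(f"forced term {f!r} is not a term of the formula")
    for s in slopes:
        if s not in terms:
            raise FormulaError(f"random slope {s!r} is not a term of the formula")
        if s in forced:
            raise FormulaError(f"forced covariate {s!r} cannot be a random slope")
    fixed_free = tuple(t for t in terms if t not in forced)
    return ModelFormula(
        response=lhs,
        fixed_free=fixed_free,
        forced=tuple(forced),
        group=group,
        has_random_intercept=group is not None,
        random_slopes=tuple(slopes),
        term_order=tuple(terms),
    )


def render_formula(m: ModelFormula) -> str:
    """Canonical string form, e.g. ``"Y ~ X1 + X2 + X3 + (1 + X1 + X2 | G)"``.

    Fixed terms appear in declaration order (free, then forced); the random
    part, when present, is rendered last.  ``parse_formula(render_formula(m))``
    recovers ``m`` when the same ``forced`` list is supplied.
    """
    rhs_terms = list(m.fixed_terms) or ["1"]
    out = f"{m.response} ~ " + " + ".join(rhs_terms)
    if m.has_random_intercept:
        rand = " + ".join(["1", *m.random_slopes])
        out += f" + ({rand} | {m.group})"
    return out
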