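"""Enumerate every admissible candidate model from one full model.

The full model has two free predictors (X1, X2, both eligible as random
slopes over the grouping variable G) and one forced covariate (X3) that
every candidate must keep.  The admissible space stratifies into
fixed-effects-only models, random-intercept models, and random-slope
models; its size has the closed form 2^f + 2^(f-s)·3^s.
"""

from mixedexplore import count_candidates, enumerate_candidates, parse_formula

full = parse_formula("Y ~ X1 + X2 + X3", group="G", slopes=["X1", "X2"],
                     forced=["X3"])
cs = enumerate_candidates(full)

print(f"full model : {full.render()}")
print(f"candidates : {len(cs)} (closed form: {count_candidates(2, 2)})\n")
for stratum, model in zip(cs.strata, cs.candidates):
    print(f"  [{stratum:16s}] {model.render()}")

print("\nLarger spaces grow exponentially with free predictors:")
for f in (4, 7):
    print(f"  {f} free predictors, all slope-eligible -> "
          f"{count_candidates(f, f)} candidate models")
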