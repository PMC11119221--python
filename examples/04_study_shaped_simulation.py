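"""Simulate datasets shaped like the three multi-country survey studies.

Each shape mirrors one study's model layout — number of free predictors,
forced demographic covariates, and country count — with small per-group
sizes so a full sweep stays fast.  The candidate-space size depends only
on the layout: 13, 97 and 2315 models respectively.
"""

import mixedexplore as mx

for shape in ("blackburn", "ntontis", "han"):
    spec = mx.study_shaped_spec(shape, group_size=20, seed=1)
    data = mx.simulate_dataset(spec)
    space = mx.count_candidates(len(spec.free_terms), len(spec.free_terms))
    print(f"{shape:10s}: {len(spec.free_terms)} free + "
          f"{len(spec.forced_terms)} forced predictors, "
          f"{spec.n_groups} groups, {len(data)} simulated rows, "
          f"{space} candidate models")

print("\nfull model for the smallest shape:")
print(" ", mx.study_shaped_spec("blackburn").full_model().render())
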