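"""Genotype basics: eye placement geometry, validation, seeded mutation.

Eyes sit on the equator of the spherical body, uniformly spread over the
placement range and bilaterally symmetric about the forward heading.
"""

import numpy as np

from eyevo.genome import (MutationMask, compute_eye_placements, mutate,
                          primitive_genotype, validate_genotype)

for n, span in [(3, 90.0), (3, 20.0), (7, 135.0)]:
    placements = compute_eye_placements(n, span)
    print(f"{n} eyes over {span:5.1f} deg -> longitudes "
          f"{[float(round(p, 1)) for p in placements]}")
# The first two lines reproduce the canonical worked examples: the
# outermost eyes sit at +/- half the placement range.

g = primitive_genotype()
print("\nancestral agent:", g.morph)
ok, violations = validate_genotype(g)
print("valid:", ok)

# Morphology-only evolution mutates eye count, resolution, and placement.
rng = np.random.default_rng(0)
mask = MutationMask.morphology(res_axis="width-only")
for step in range(10):
    g = mutate(g, mask, rng)
print("after 10 morphological mutations:", g.morph)
print("still valid:", validate_genotype(g)[0])
# Mutation is closed over the valid set: bounds are clamped and overlapping
# eye layouts are repaired, so every lineage stays physically realizable.
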