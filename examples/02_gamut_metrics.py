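"""Colour-gamut metrics: hull volume, overlap and chromatic loci.

Measures the colour space occupied by the males and females of a small
synthetic avifauna, both as convex-hull volume and as occupied 0.022-edge
grid cells (chromatic loci).
"""

from avigamut import (AvifaunaConfig, aggregate_species_sex,
                      build_sensitivity_set, gen_avifauna, hull_overlap,
                      hull_volume, model_set, rasterize_loci,
                      shared_unique_loci, volume_fraction)

sset, _ = gen_avifauna(AvifaunaConfig(seed=4))
points = aggregate_species_sex(model_set(sset, build_sensitivity_set("U")))
males = points[points.sex == "male"]
females = points[points.sex == "female"]

hm, hf = hull_volume(males), hull_volume(females)
print(f"male hull volume   {hm.volume:.5f} "
      f"({100 * volume_fraction(hm.volume):.1f}% of the full tetrahedron)")
print(f"female hull volume {hf.volume:.5f} "
      f"({100 * volume_fraction(hf.volume):.1f}% of the full tetrahedron)")

ov = hull_overlap(females, males)
print(f"hull overlap: {100 * ov.frac_of_a:.1f}% of female volume, "
      f"{100 * ov.frac_of_b:.1f}% of male volume")

lm, lf = rasterize_loci(males), rasterize_loci(females)
part = shared_unique_loci(lf, lm)
print(f"chromatic loci: males {lm.n_occupied}, females {lf.n_occupied}; "
      f"{100 * part.frac_shared:.0f}% of the union shared, "
      f"{100 * part.frac_only_b:.0f}% male-only, "
      f"{100 * part.frac_only_a:.0f}% female-only")
# Males typically occupy more colour space than females because ornamental
# (carotenoid/structural) patches are male-biased in the generator, the
# synthetic analogue of sexual dichromatism.
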