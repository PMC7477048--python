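"""Extract IBSI-style radiomic features from a textured lesion.

A necrotic-core phantom (cool centre, hot rim) is delineated and ~100
features across ten families are computed with fixed 0.25-SUV bins.
"""

from petfactor import delineate, extract_all, volume_filter
from petfactor.simulate import PhantomSpec, generate_phantom

spec = PhantomSpec(texture_model="necrotic_core", suv_lesion_mean=10.0,
                   suv_core=2.0, noise_sd=0.1, seed=7)
volume, _ = generate_phantom(spec)
mask = volume_filter(delineate(volume, (16, 16, 16)), volume.spacing_mm)

fv = extract_all(volume, mask)
print(f"extracted {len(fv.values)} features "
      f"({len(fv.degenerate)} degenerate), config {fv.config_hash}")

show = [
    "morph/sphericity", "stat/coefficient_of_variation",
    "ih/max_histogram_gradient", "glcm/contrast",
    "glrlm/long_run_low_grey_level_emphasis",
    "glszm/zone_size_nonuniformity", "ngtdm/busyness",
    "ngldm/high_dependence_high_grey_level_emphasis", "moran/morans_i",
]
for name in show:
    print(f"  {name:46s} = {fv.values[name]:10.4f}")
print(
    "The necrotic core shows up as texture heterogeneity: a large "
    "histogram gradient and high GLCM contrast from the cool-centre / "
    "hot-rim transition that the PSF blur spreads over several voxels."
)
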