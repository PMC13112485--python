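"""Extract the 16-descriptor feature vector from phantom MRI images.

Generates one healthy and one tumor phantom (256x256 grayscale) and
prints their feature vectors side by side. Healthy phantoms are built
brighter and more finely textured, so intensity_mean and glcm_contrast —
the two strongest discriminators on real brain MRI — are visibly higher
for the healthy image.
"""

from rdbpso.features import FEATURE_NAMES, extract_features
from rdbpso.synthetic import PhantomSimConfig, simulate_phantoms

images, labels = simulate_phantoms(PhantomSimConfig(n_healthy=1, n_tumor=1, seed=0))
healthy, tumor = (extract_features(img) for img in images)

print(f"{'feature':<22}{'healthy':>12}{'tumor':>12}")
for name, h, t in zip(FEATURE_NAMES, healthy, tumor):
    print(f"{name:<22}{h:>12.4f}{t:>12.4f}")
print("\nA positive healthy-tumor gap in intensity_mean and glcm_contrast "
      "mirrors the discriminative structure of the real dataset.")
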