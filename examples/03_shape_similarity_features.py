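"""Shape-similarity features against the nucleus shape library.

Builds an 80+80 aligned shape library from a synthetic pool, then scores
query nuclei against every library entry with the four overlap
coefficients (Dice, Jaccard, precision, recall): 4 x 160 = 640 features.
"""

import nucmorph as nm

pool, _ = nm.generate_dataset(100, seed=42)
library = nm.library_from_patches(pool, n_per_class=80, seed=42)

queries, _ = nm.generate_dataset(1, seed=5)  # one normal + one HCC nucleus
print(f"library size        : {len(library)} ({library.class_counts})")

for patch in queries:
    aligned, _ = nm.align(patch.mask)
    vec = nm.shape_feature_vector(aligned, library)
    ji = vec[[c for c in vec.index if c.startswith("JI.")]]
    mean_ji = {
        label: ji[[f"JI.{i}" for i, l in zip(library.ids, library.labels)
                   if l == label]].mean()
        for label in ("normal", "HCC")
    }
    print(f"{patch.label:>7} query: {len(vec)} dims; "
          f"mean JI vs normal {mean_ji['normal']:.3f}, "
          f"vs HCC {mean_ji['HCC']:.3f}, "
          f"gap {mean_ji['normal'] - mean_ji['HCC']:+.3f}")
# A smooth, regular normal query overlaps the library uniformly better
# than an irregular HCC query does; the classifier separates the classes
# on the full 160-dimensional overlap pattern, not on any single mean.
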