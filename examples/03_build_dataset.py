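"""Assemble the labeled dataset from per-column mean spectra.

Per variety-day image, the retained column means are split into 40
consecutive sets and each set is averaged into one labeled sample — the
reduction that turns ~1,800 columns into 40 samples per variety-day.
"""

from vinehsi import (SceneConfig, SegmentationParams, assemble, build_samples,
                     make_signatures, render_scene, segment_cube,
                     to_absorbance, to_reflectance)

n_varieties, n_days, n_sets = 3, 2, 40
signatures = make_signatures(n_varieties, n_bands=120, separation=0.5, seed=3)

parts = []
for v, sig in enumerate(signatures):
    for day in range(n_days):
        config = SceneConfig(n_columns=90, n_rows=80, n_bands=120,
                             noise_sd=5.0, seed=100 * v + day)
        scene = render_scene(config, sig)
        cube = to_absorbance(to_reflectance(scene.cube, scene.refs))
        means, _, _ = segment_cube(cube, sig.absorbance, SegmentationParams())
        parts.append(build_samples(means, n_sets, sig.variety_id, day))

table = assemble(parts)
print(f"dataset: {table.n_samples} samples x {table.n_bands} bands")
print(f"per-variety counts: {table.class_counts()}")
print(f"({n_varieties} varieties x {n_days} days x {n_sets} sets = "
      f"{n_varieties * n_days * n_sets} rows; at full study scale "
      "30 x 2 x 40 = 2,400)")
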