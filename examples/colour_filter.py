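"""Exclude a minority contaminant population by colour.

Renders 20 yellow colonies plus 2 red contaminants, fits the normal
colour model to the non-split detections, and shows that a likelihood
cutoff removes exactly the contaminants.
"""

import numpy as np

from pycfu import PipelineConfig, count_image
from pycfu.postfilter import filter_by_likelihood, fit_colour_model
from pycfu.synthetic import random_plate, render_scene

spec = random_plate(22, seed=4100, minority=2,
                    pair_fraction=0.0, triple_fraction=0.0)
image, truth = render_scene(spec)

config = PipelineConfig()
config.roi.auto_petri = True
result = count_image(image, config)
print(f"detected: {result.summary.count} objects")

medians = np.array([[r.median_r, r.median_g, r.median_b]
                    for r in result.records])
model = fit_colour_model(medians, [r.cluster_size for r in result.records])
print(f"colour model: mean relative intensities {np.round(model.mean, 3)} "
      f"(fitted on {model.n_fit} non-split objects)")

excluded = filter_by_likelihood(medians, model, cutoff=1e-5)
print(f"excluded at cutoff 1e-5: {int(excluded.sum())} objects")
for i in np.flatnonzero(excluded):
    r = result.records[i]
    print(f"  outlier at ({r.x:.0f}, {r.y:.0f}): "
          f"medians ({r.median_r:.0f}, {r.median_g:.0f}, {r.median_b:.0f})")
# The two excluded objects are the red contaminants: their relative
# green intensity is far outside the yellow population's normal model.
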