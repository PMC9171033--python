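"""Match every vertex of one instance to the next and check the scores.

Uses a small synthetic pair so it runs in seconds.  The correlation score is
1.0 for a perfect local match and decreases with deformation and noise; the
matched indices recover the generator's ground-truth identity map.
"""
import numpy as np

import osteomap as om
from osteomap.synthetic import TemplateParams

template = om.make_template_mandible(TemplateParams(n_vertices=220), seed=1)
scenario = om.GrowthScenario(n_instances=4, noise_sigma=0.1, seed=1)
data = om.grow_series(template, scenario)

m = om.build_correspondence(data.series[0], data.series[1])
exact = (m.target_index == np.arange(m.n_source)).mean()

print(f"matched {m.n_source} vertices of T1 onto T2")
print(f"scores: min {m.score.min():.4f}, median {np.median(m.score):.4f}, "
      f"max {m.score.max():.4f}")
print(f"agreement with ground-truth correspondence: {100 * exact:.1f}%")
print("\nScores near 1 mean each vertex neighborhood aligns rigidly onto "
      "its counterpart; the identity agreement confirms the matcher tracks "
      "the same material points through growth and noise.")
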