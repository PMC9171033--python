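"""Landmark-based validation: propagate landmarks and score them by RMSE.

Snaps the template's 17 anatomical landmarks to the first-instance mesh,
propagates them through the correspondence chain, and scores the propagated
positions against the generator's noiseless truth — the same protocol used
to validate the method against manually identified gold-standard landmarks.
"""
import numpy as np

import osteomap as om
from osteomap.synthetic import TemplateParams

template = om.make_template_mandible(TemplateParams(n_vertices=220), seed=9)
scenario = om.GrowthScenario(n_instances=5, noise_sigma=0.1, seed=9)
data = om.grow_series(template, scenario)

maps = [om.build_correspondence(data.series[i], data.series[i + 1])
        for i in range(len(data.series) - 1)]
est = om.propagate_landmarks(template.landmarks, data.series, maps)

# gold standard: the same landmarks tracked on the noiseless meshes
gold = om.propagate_landmarks(template.landmarks, data.noiseless, data.maps)

report = om.position_rmse([est], [gold])
print("landmark position RMSE (mm) per instance:")
cols = [c for c in report.columns if c.startswith("T")]
print(report.loc["Mean", cols].round(3).to_string())
print(f"\nworst single landmark/instance: "
      f"{report.loc[template.landmarks.names, cols].to_numpy().max():.3f} mm")
print("Sub-voxel RMSE (< 0.4 mm) indicates the correspondence chain tracks "
      "anatomical points at the accuracy of the imaging itself.")
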