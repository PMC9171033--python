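"""Full pipeline on a small series: correspondence -> spline growth rates.

Recovers per-vertex growth rates (%/month) with anterior/posterior,
superior/inferior, medial/lateral components, and compares the region means
against the generator's ground truth.
"""
import numpy as np

import osteomap as om
from osteomap.synthetic import TemplateParams

template = om.make_template_mandible(TemplateParams(n_vertices=220), seed=5)
scenario = om.GrowthScenario(n_instances=6, noise_sigma=0.1, seed=5)
data = om.grow_series(template, scenario)

maps = [om.build_correspondence(data.series[i], data.series[i + 1])
        for i in range(len(data.series) - 1)]
field = om.compute_growth_field(data.series, maps)

print("recovered vs true region-mean total rate at T2 (%/month):")
rec = om.region_summary(field, template.labels, directions=("total",))
tru = om.region_summary(data.truth, template.labels, directions=("total",))
for region in sorted(rec.region.unique()):
    r = rec[(rec.region == region) & (rec.instance == 2)]["mean"].iloc[0]
    t = tru[(tru.region == region) & (tru.instance == 2)]["mean"].iloc[0]
    print(f"  {region:18s} recovered {r:5.2f}   true {t:5.2f}")

s = field.ap + field.si + field.ml
print(f"\ndirectional components sum to the total rate "
      f"(max deviation {np.abs(s - field.total).max():.2e} %/month) — "
      "the squared-cosine decomposition is conservative by construction.")
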