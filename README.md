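# osteomap

Per-vertex growth mapping for longitudinal bone-surface models.

When the same growing bone is imaged repeatedly — e.g. monthly CBCT scans of
a juvenile mandible reconstructed as triangulated surface models — the
classical analysis reduces each scan to a handful of inter-landmark
distances.  osteomap instead tracks **every vertex** of the surface through
the series and maps the continuous, non-uniform pattern of growth:

1. **Correspondence.**  For each vertex *j* of the model at instance *Tᵢ*,
   the matching vertex on the model at *Tᵢ₊₁* maximizes the correlation
   coefficient

   f = cov(Q_{i,j}, Q_{i+1,j}) / (σ_{i,j} σ_{i+1,j})

   between the local vertex neighborhoods *Q* (radius *r*), subject to a
   local rigid constraint P_{i+1,j} = R_i P_{i,j} + **v**_i.  The search is a
   global ICP pre-alignment followed by a discrete candidate search with a
   local Kabsch refinement per candidate.
2. **Rates.**  For every mesh edge (pair of adjacent vertices) the monthly
   morphological change is the relative length increase
   g_i = 100·(L(T_{i+1}) − L(T_i))/L(T_i) in %/month; a least-squares cubic
   smoothing spline is fitted to the cumulative change and its gradient at
   *Tᵢ* is the instantaneous rate.  Per-vertex rates average the incident
   edges and are decomposed into anterior/posterior, superior/inferior and
   medial/lateral components by squared direction cosines.
3. **Summaries and validation.**  Rates are averaged over the six standard
   mandibular regions (condyle, posterior/anterior ramus,
   posterior/middle/anterior corpus), exported as color-mapped PLY models
   and report tables, and validated by the RMSE of propagated anatomical
   landmarks against a gold standard.

A synthetic generator builds watertight mandible-like templates with known
growth fields, landmarks and region labels, so the whole pipeline is
testable without any scan data.

## Worked example

```python
import numpy as np
import osteomap as om

template = om.make_template_mandible(seed=42)       # 653-vertex mandible
scenario = om.GrowthScenario(seed=42)               # 12 monthly instances
data = om.grow_series(template, scenario)           # meshes + ground truth

maps = [om.build_correspondence(data.series[i], data.series[i + 1])
        for i in range(11)]
field = om.compute_growth_field(data.series, maps)

summ = om.region_summary(field, template.labels, directions=("total",))
print(summ[summ.instance == 2][["region", "mean"]])
```

prints (n = vertices per region; %/month at the first interval):

```
               region      mean
              condyle  1.767216
      posterior_ramus  1.749033
       anterior_ramus  0.905694
     posterior_corpus  0.635361
        middle_corpus  0.347307
      anterior_corpus  0.488917
```

i.e. the condyle and posterior ramus grow fastest (~1.8 %/month) and the
corpus regions slowest (~0.3–0.6 %/month) — the recovered field reproduces
the scenario's regional gradient from mesh geometry alone.  The
`examples/` scripts walk through each capability (synthesis,
correspondence, rates, landmark validation) and print what the numbers
mean.

A thin CLI wraps the library for shell use:

```bash
osteomap synth --seed 42 -o series/                    # synthetic series
osteomap correspond --source series/T01.ply --target series/T02.ply -o map.csv
osteomap run --config pipeline.yaml                    # full pipeline
```

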