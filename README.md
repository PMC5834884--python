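# synquant

3D synapse quantification for volume electron microscopy.

Quantitative synaptology asks whether a condition — here, early
Alzheimer's disease in medial temporal cortex — changes the number,
size, type balance or spatial arrangement of cortical synapses. FIB/SEM
imaging yields aligned stacks of neuropil (5 nm/pixel in plane, 20 nm
sections) in which every synaptic junction can be reconstructed in 3D,
classified as asymmetric (AS, excitatory) or symmetric (SS, inhibitory),
and reduced to a synaptic apposition surface (SAS) — the open surface
apposed between the pre- and post-synaptic densities. `synquant`
implements the complete downstream analysis of such segmented material:

* **Stereology** — Cavalieri point-count volume fractions of neurons,
  glia, vessels and neuropil on semithin sections
  (`V_n = 100 − (V_neu + V_g + V_bv)`), tissue-shrinkage correction by
  the area factor p² (a d-dimensional measure is divided by
  `p²^(d/2)`), fixation-artifact discounting, and cortical-thickness
  summaries.
* **Unbiased counting** — the 3D unbiased brick (three inclusion, three
  exclusion faces with extension planes) applied to whole reconstructed
  junctions; densities `N_v = n / V_counting` per stack, aggregated
  stack → case → group.
* **SAS morphometry** — area, boundary perimeter, and the curvature
  statistic `1 − projected_area/area` (0 flat, 0.5 hemisphere), with
  log-normal size fits and group × type summaries.
* **Spatial statistics** — 3D G, F and K functions with border and
  translation edge corrections, CSR (homogeneous Poisson) references,
  100-simulation pointwise envelopes, nearest-neighbour summaries, and
  the hard-core "dead space" of the G function.
* **Group comparison** — two-sided Mann-Whitney U on per-case values
  (cases, never stacks, are the independent unit) and two-sample KS on
  pooled SAS size distributions.
* **Synthetic studies** — a generator producing hard-core synapse
  positions, spherical-cap SAS meshes with controllable area and
  curvature, artifact masks with analytic volume, and semithin label
  images with exact ground truth, at the documented default study
  conditions.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

```python
import numpy as np
from synquant import synthgen, spatial, counting, stereology, morphometry
from synquant.geometry import Window3D

# --- a stack of hard-core synapses at 0.51 per μm³ ---------------------
w = Window3D(extents=(10_000.0, 10_000.0, 10_000.0))   # 10 μm cube, nm
pattern = synthgen.simulate_hardcore_pattern(0.51, 250.0, w, seed=1)
print(pattern.n)                        # 510  (= round(0.51 × 1000 μm³))

g = spatial.g_function(pattern)
print(round(spatial.dead_space_radius(g), 1))   # 503.9  (≈ 2 × 250 nm)

env = spatial.csr_envelope(pattern, "G", n_sim=100, seed=2)
print(env.verdict)                      # departs from CSR
                                        # (hard core < CSR at small r)

# --- densities with artifact and shrinkage corrections -----------------
vol, _ = stereology.discount_artifacts(500.0, 0.10 * 500.0)  # 10% artifacts
vol = stereology.correct_measurement(vol, 0.933, dimension=3)
est = counting.density_estimate(n_as=239, n_ss=11, counting_volume_um3=vol)
print(round(est.density_total, 3), round(est.pct_as, 1))   # 0.501 95.6

# --- a SAS and its curvature statistic ---------------------------------
mesh = synthgen.synthesize_sas_mesh(area=117_800.0, curvature=0.049, seed=3)
f = morphometry.sas_features(mesh)
print(round(f.area_nm2), round(f.curvature, 3))            # 117800 0.05
```

The full pipeline — synthetic study generation, stereology, counting,
morphometry, spatial statistics and the comparison table — runs in one
call:

```python
from synquant.pipeline import StudyConfig, run_pipeline
report = run_pipeline(StudyConfig(seed=1))
print(report["groups"][["group", "density_total_mean", "pct_as_mean"]])
#      group  density_total_mean  pct_as_mean
#    control               0.554        95.79
#    disease               0.359        92.21
```

or from the shell:

```sh
synquant simulate --out study/ --seed 1     # centroid CSV + PLY meshes
synquant report --out report/ --seed 1      # full pipeline report
synquant spatial --centroids study/centroids.csv \
    --window-nm 5000 5000 5000 --out spatial/
```

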