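# edlimaging

Noninvasive imaging of cardiac activation times from body-surface potential
maps (BSPMs) with the **equivalent dipole layer** (EDL) source model, and a
synthetic, fully reproducible assessment of how myocardial anisotropy
degrades the reconstruction.

## The problem

The electric sources of the QRS complex are distributed current dipoles
`J(r) = -Σ_i ∇φ_h(r)` throughout the ventricular wall, where `Σ_i` is the
intracellular conductivity tensor (longitudinal along the muscle fibers) and
`φ_h` the transmembrane potential (TMP). When the intra- and extracellular
anisotropy ratios are equal, these volume sources are equivalent to a dipole
layer on the closed myocardial surface `S_h` (epicardium *and* endocardium)
whose strength tracks the TMP. Treating the TMP as a step parameterized by
the local activation time `τ(r)`, the body-surface potential is

    φ(r*, t) = ∫_{S_h} H(t − τ(r)) A(r, r*) dS(r)

with `H` the Heaviside step and `A(r, r*)` the transfer function of an
infinitesimal "on" source, computed with the boundary element method (BEM)
in an inhomogeneous torso (thorax 0.2, lungs 0.04, blood 0.6, myocardial
bulk 0.2 S/m). The layer strength is `σ_i/(σ_i+σ_e)` times the TMP
amplitude (0.25 × 100 mV with the default conductivities). The inverse
problem — find `τ` on `S_h` from 120-electrode BSPMs — is solved in two
steps:

1. **Fastest route algorithm (FRA).** Every surface node is tried as an
   ectopic focus; its activation map follows from shortest paths with
   distinct surface and transmural velocities. Candidates are ranked by the
   correlation between their EDL-predicted and the measured BSPM; within the
   top 2% the smallest relative difference wins. Sinus rhythm uses a greedy
   multi-focus ensemble ("first come, first served").
2. **Regularized Levenberg–Marquardt refinement** of `τ`, minimizing
   `‖Φ_EDL(τ) − Φ_meas‖² + λ‖Lτ‖²` with the surface Laplacian `L` as a
   second-order Tikhonov penalty.

Real inputs (MRI-derived geometry, monodomain simulations) are replaced by
first-class synthetic generators: a biventricular wall geometry with a
rule-based helix fiber field, anisotropic graph-eikonal wavefront
propagation as ground truth, and the volumetric-dipole forward model above
to produce "measured" BSPMs with 20 µV Gaussian noise — so the inverse is
confronted with data from a *different, richer* model, except in explicit
inverse-crime controls.

## Worked example

```python
import numpy as np
from edlimaging import (ConductivitySetup, StudyConfig, build_study_context,
                        run_study)

cfg = StudyConfig(scenarios=("lv_free_endo",), cases=("isotropic",), seed=1)
ctx = build_study_context(cfg)       # geometry, BEM, transfer, FRA maps
table, records = run_study(cfg, ctx)
print(table[["scenario", "case", "rms_at", "cor_at", "dist_mm"]])
```

This simulates an ectopic beat on the left-ventricular endocardial free
wall, inverts the noisy BSPM and prints

```
       scenario       case    rms_at    cor_at  dist_mm
0  lv_free_endo  isotropic  7.003807  0.985331  7.99609
```

i.e. the activation map is recovered to 7.0 ms RMS with correlation 0.99,
and the reconstructed focus lies 8 mm from the true stimulation site
(mesh spacing is ~5.5 mm). Across all eight ectopic scenarios in the
isotropic case the median focus error is ~12 mm; with unequal anisotropy
ratios (intracellular 9 vs extracellular 3) the mean error roughly doubles,
while the equal-ratio case sits in between — the ordering the EDL
equivalence theorem predicts.

The command-line interface exposes the same pipeline:

```bash
edlstudy run --config study.yaml --out results/
edlstudy build-geometry --out geometry/
edlstudy simulate --scenario lv_free_endo --case unequal --out bspm.h5
edlstudy invert --bspm bspm.h5 --transfer geometry/transfer.h5 --lambda 1e-3
```

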