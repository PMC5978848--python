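# Methods

This note documents the models implemented in `edlimaging`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate. Units throughout: mm, ms, S/m, mV; 0-based vertex
indices; outward-oriented faces.

## Synthetic geometry

The default ventricular geometry is a biventricular wall built by marching
cubes over an implicit shape: a truncated left-ventricular ellipsoid
(epicardial semi-axes 34 × 32 × 55 mm, 10 mm free wall), a crescent-shaped
right-ventricular cavity separated by a ~9 mm septum, and sealed basal caps.
Its closed boundary has three genus-0 components — the epicardial shell and
two endocardial cavity surfaces — oriented outward from the *myocardium*
(cavity faces point into the blood pool), so the total signed volume is the
wall volume. At the default 5.5 mm grid the surface carries ~1450 nodes,
matching the scale at which the inverse method is normally discretized
(~1500 ventricular nodes). A cheap single-chamber thick-walled ellipsoid
("shell", icosphere-based) is provided for unit tests. Surface nodes are
classified endo/epi/septal; septal nodes are endocardial nodes within 16 mm
of the opposite cavity.

Fibers follow a rule-based helix: the fiber lies in the plane of the local
circumferential direction and the long axis, with the helix angle varying
linearly from +60° at the endocardium to −60° at the epicardium. The
transmural coordinate is the normalized distance between the endo- and
epicardial vertex sets.

The torso is an ellipsoid (semi-axes 170 × 115 × 280 mm) containing two
lung ellipsoids and the heart; 120 electrodes are Fibonacci-distributed
torso vertices. Compartment conductivities: thorax 0.2, lungs 0.04, blood
0.6, myocardial bulk 0.2 S/m (the sum of the isotropic intra- and
extracellular values, 0.05 + 0.15).

## Conductivity cases and ground-truth propagation

Three intracellular/extracellular setups are studied (S/m):

| case      | σ_i,l | σ_i,t | σ_e,l | σ_e,t | ratios (i, e) |
|-----------|-------|-------|-------|-------|----------------|
| isotropic | 0.05  | 0.05  | 0.15  | 0.15  | 1, 1           |
| equal     | 0.15  | 0.05  | 0.45  | 0.15  | 3, 3           |
| unequal   | 0.45  | 0.05  | 0.45  | 0.15  | 9, 3           |

Ground-truth activation is computed by a graph-eikonal solver: Dijkstra on
a dense neighborhood graph (radius 1.82 × spacing ≈ the 26-neighborhood)
over a ~2.5 mm volumetric wall sampling, with edge speed
`v(e) = v_t √(1 + (k² − 1) cos²θ)`, θ the angle to the local fiber. The
transversal velocity default is v_t = 0.6 mm/ms (0.6 m/s, physiological).
The velocity ratio k derives from the monodomain *effective* conductivity
σ_i σ_e/(σ_i + σ_e) per direction — k = 1 (isotropic), √3 (equal), √6
(unequal). Using the intracellular ratio alone (k = 3 for the unequal case)
would overstate longitudinal speed and compress the unequal-case QRS to
~70 ms, distorting cross-case RMS comparisons; the harmonic-mean rule is
what a monodomain solver actually implements. Discretization error of the
graph-eikonal metric is bounded by the neighborhood's angular resolution
(up to ~13% on worst-case directions; exact along grid axes and diagonals).

Scenarios: sinus rhythm is imitated by four endocardial early sites (two
septal near the apex, one high LV endocardial, one RV endocardial; onsets
0, 5, 10, 15 ms) standing in for a Purkinje activation profile; the eight
ectopic scenarios are septal left/right, LV free-wall endo/epi, RV
free-wall endo/epi and basal left/right near the septum, each a single
spherical stimulus (3 mm radius) placed by the transmural pairing of its
surface node.

## Forward models

**Volumetric-dipole ("measured") forward.** The TMP template is a logistic
upstroke (width 2 ms, amplitude 100 mV, rest −80 mV) composed with the
ground-truth activation. Gradients on the wall sampling use moving least
squares over the 12 nearest neighbors; dipole moments are
`−Σ_i ∇φ_h ΔV` with `Σ_i = σ_i,t I + (σ_i,l − σ_i,t) f fᵀ`. Electrode
potentials follow from a precomputed BEM lead field; 20 µV (0.02 mV)
Gaussian noise is added, then all maps are re-referenced to zero mean over
electrodes at every sample.

**BEM.** Linear collocation with exact (van Oosterom–Strackee) triangle
solid angles, one-third vertex lumping and diagonal terms fixed by the
requirement that a constant potential solves the source-free system; the
singular system is deflated by pinning the mean torso potential. Surfaces
with zero conductivity jump carry no unknowns — in particular the
ventricular source surface itself (0.2 | 0.2), so the EDL is never
evaluated at its own collocation points. The blood-compartment boundaries
are inset 1.5 mm into the cavities from the endocardial source surface for
the same reason. A uniform closed layer then produces an exactly null
exterior field (machine precision), and a central/eccentric dipole in a
homogeneous sphere is reproduced to ≤0.1% relative RMS at a 2562-node mesh.
Anisotropic *bulk* conduction cannot be represented by a surface BEM; all
anisotropy lives in the sources and the wavefront shape. The equal-ratio
case therefore satisfies the dipole-layer equivalence only approximately,
and cross-case comparisons are interpreted as trends, not absolute errors.

**EDL forward.** `Φ(e, t) = Σ_j A[e, j] h(t − τ_j)` with `A` the transfer
matrix (electrodes × surface nodes, zero-mean columns, scale
0.25 × 100 mV) and `h` the normalized upstroke; a sharp Heaviside variant
is used wherever no derivative is needed.

## Inverse procedure

**FRA.** Candidate activation maps are exact shortest paths on the surface
mesh graph plus transmural links; defaults v_surface = 0.8, v_transmural =
0.4 mm/ms. Transmural links pair each endocardial node with the nearest
node on a *different* boundary component — for free-wall nodes the nearest
epicardial node, for septal nodes the opposite septal face — so every link
crosses about one wall thickness and none tunnels through a cavity.
Ranking uses the Pearson correlation of the flattened predicted-vs-measured
matrices (sharp-step predictions, evaluated by cumulative sums of transfer
columns in activation order); the top 2% by correlation are short-listed
and the smallest relative difference wins, ties resolving to lower RD then
lower node index. The second-best estimate is the best-ranked candidate at
least 30 mm from the primary focus.

**Multifocal (sinus) estimate.** Greedy "first come, first served": start
from the best single focus; repeatedly apply the best of (a) adding a
(node, onset) pair, onsets −15…25 ms in 5 ms steps, or (b) delaying the
whole ensemble and inserting a new earliest focus; stop below a 0.005
correlation gain or at 6 foci; finally prune foci whose removal costs less
than the gain tolerance. The moves beyond plain addition exist because the
min-combination is monotone: a first pick that is not the earliest true
focus could otherwise never be repaired.

**Optimization.** Levenberg–Marquardt on
`‖Φ_EDL(τ) − Φ_meas‖² + λ‖Lτ‖²`, with `L` the symmetric umbrella Laplacian
(A − D; rows sum to zero, annihilates constants). The Jacobian is analytic
and separable — `JᵀJ = (AᵀA) ∘ (H′H′ᵀ)` — which keeps an iteration at one
Cholesky solve. The upstroke width anneals 2 → 1 ms (sharp steps have
vanishing gradients); the damping parameter adapts by factor 4/3 on
reject/accept; caps: 200 iterations (60 in study runs), relative objective
tolerance 1e-6. The target λ is approached through λ/100 and λ/10 warm-up
stages: cold starts at full smoothing lock the solution into the initial
estimate's basin. The study default λ = 1e-3 was frozen once from an
L-curve sweep (1e-6…1e-1) on a pilot isotropic scenario; `lam="auto"`
performs the warm-started L-curve (corner by maximum log-log curvature) per
inversion.

## Evaluation

RMS/COR/RD between simulated and reconstructed activation times
(node-wise, unweighted) and between measured and EDL-predicted BSPMs; the
recovered focus is the node of minimal reconstructed activation, its error
the Euclidean distance to the true stimulus (geodesic distance is also
reported); "DIFF 1st" is the reconstructed-minus-true earliest activation
time. Early-activation sites are local minima with topographic persistence
of at least 5 ms (basins flooded in activation order), thinned to a 10 mm
geodesic separation; a flat map is flagged degenerate and only thinned.
`run_study` crosses the 9 scenarios with the 3 conductivity cases, applies
the second-best rescue (keep the lower-residual of the two refinements)
when a near-tied alternative exists (ΔCOR < 0.03), and emits a CSV report
plus JSON summary, all derived from a single seed.

## Problem sizes and defaults

Default study: ~1450 surface nodes, ~6800 wall samples, ~1500 BEM unknowns,
120 electrodes, 1 ms sampling. One ectopic inversion (ranking + refinement
with rescue) takes ~10 s on one CPU; the full 27-cell study roughly half an
hour with the multifocal sinus cells dominating. The acceptance script and
the long-running tests use the same geometry with two-scenario/five-seed
subsets for the anisotropy trend; subset membership (septal + LV free wall,
with RV covered by the localization check) was fixed once for regional
coverage.

## Known limitations

- The surrogate truth is an eikonal wavefront, not ionic-model
  electrophysiology: no rate-dependence, heterogeneity, or repolarization;
  conduction velocities are homogeneous per case.
- The BEM conductor is isotropic; the equal-ratio case is only
  approximately EDL-equivalent here (see above).
- At ~5 mm surface resolution the endo/epi discrimination of the recovered
  focus is fragile: the FRA initial estimates classify the wall side
  correctly in most scenarios, but the nonlinear refinement can move the
  earliest node across a thin right-ventricular or basal wall without
  changing the data misfit appreciably (endocardial transfer columns are
  weakened by the conductive blood pool, and the reconstructed first
  activation is systematically late). Typical isotropic-case counts are
  5–6 of 8 correct; treat per-focus wall-side calls on this synthetic
  geometry as indicative only.
- The multifocal greedy recovers well-separated foci to ~one mesh edge but
  may retain one spurious focus and misassign relative onsets by ~5–10 ms;
  the refinement stage, not the estimate, carries the timing accuracy.
- Absolute RMS values depend on the per-case depolarization duration
  (71–175 ms across cases) and on the surrogate's velocity scale; only the
  cross-case ordering is interpreted.
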