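"""Ground-truth activation by anisotropic wavefront propagation.

Synthetic-data stage 1: activation times for sinus rhythm and paired
endo/epicardial ectopic foci are produced by a graph-eikonal solver (exact
Dijkstra on a dense neighborhood graph over the volumetric wall sampling).
Conduction is faster along the local fiber direction: an edge of vector e
costs |e| / v(e) with

    v(e) = v_t * sqrt(1 + (k^2 - 1) * cos^2(theta)),

where theta is the angle between the edge and the fiber, v_t the transversal
velocity (mm/ms) and k >= 1 the longitudinal/transversal velocity ratio.
With k derived from sqrt of the intracellular conductivity ratio this
emulates monodomain propagation under the three conductivity cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .geometry import FiberField, GeometryError, MyocardialSampling, Ventricle


@dataclass
class StimulusSet:
    """Stimulation seeds: (position mm, onset ms, radius mm) triples."""

    positions: np.ndarray
    onsets: np.ndarray
    radii: np.ndarray
    scenario: str = "ectopic"

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.onsets = np.atleast_1d(np.asarray(self.onsets, float))
        self.radii = np.atleast_1d(np.asarray(self.radii, float))
        if np.any(self.radii <= 0) or np.any(self.onsets < 0):
            raise ValueError("radii must be positive and onsets non-negative")
        if self.scenario != "sinus" and len(self.positions) != 1:
            raise ValueError("ectopic scenarios have exactly one seed")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class VolumeActivation:
    """Activation times (ms) on the wall sampling and their restriction to
    the ventricular surface nodes (the gold standard for evaluation)."""

    tau_vol: np.ndarray
    tau_surf: np.ndarray
    stimuli: StimulusSet | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.tau_vol))
                and np.all(np.isfinite(self.tau_surf))):
            raise ValueError("activation must be finite everywhere (full capture)")
        if self.tau_vol.min() < 0 or self.tau_surf.min() < 0:
            raise ValueError("activation times must be non-negative")


def neighborhood_graph(points: np.ndarray, spacing: float,
                       reach: float = 1.82) -> np.ndarray:
    """Edge list (i, j) of the dense volumetric neighborhood graph.

    ``reach * spacing`` captures the 26-neighborhood of a regular grid
    (diagonal distance sqrt(3) ~ 1.73 spacings).
    """
    pairs = cKDTree(points).query_pairs(r=reach * spacing, output_type="ndarray")
    if len(pairs) == 0:
        raise GeometryError("sampling too sparse: no neighborhood edges")
    return pairs


def edge_costs(points: np.ndarray, fibers: FiberField, pairs: np.ndarray,
               v_t: float, k: float) -> np.ndarray:
    """Anisotropic travel time (ms) of each edge."""
    if k < 1:
        raise ValueError("velocity ratio k must be >= 1")
    if v_t <= 0:
        raise ValueError("transversal velocity must be positive")
    e = points[pairs[:, 1]] - points[pairs[:, 0]]
    elen = np.linalg.norm(e, axis=1)
    f1 = fibers.directions[pairs[:, 0]]
    f2 = fibers.directions[pairs[:, 1]]
    # fibers are axes (sign-free): align the pair before averaging
    sgn = np.sign(np.einsum('ij,ij->i', f1, f2))
    sgn[sgn == 0] = 1.0
    fm = f1 + f2 * sgn[:, None]
    fm /= np.maximum(np.linalg.norm(fm, axis=1, keepdims=True), 1e-12)
    cos2 = (np.einsum('ij,ij->i', e, fm) / np.maximum(elen, 1e-12)) ** 2
    v = v_t * np.sqrt(1.0 + (k * k - 1.0) * np.clip(cos2, 0.0, 1.0))
    return elen / v


def anisotropic_activation(sampling: MyocardialSampling, fibers: FiberField,
                           v_t: float, k: float,
                           stimuli: StimulusSet) -> VolumeActivation:
    """Propagate activation from the stimuli through the wall sampling.

    tau(p) = min over seeds of (onset + anisotropic travel time), realized
    as a single Dijkstra run from a virtual super-source connected to every
    seed node with its onset as edge cost.
    """
    pts = sampling.points
    n = len(pts)
    pairs = neighborhood_graph(pts, sampling.spacing)
    cost = edge_costs(pts, fibers, pairs, v_t, k)

    tree = cKDTree(pts)
    rows, cols, data = [], [], []
    for s, (pos, onset, radius) in enumerate(zip(stimuli.positions,
                                                 stimuli.onsets,
                                                 stimuli.radii)):
        seeds = tree.query_ball_point(pos, r=radius)
        if not seeds:
            seeds = [int(tree.query(pos)[1])]
        d_seed = np.linalg.norm(pts[seeds] - pos, axis=1)
        if d_seed.min() > 3.0 * sampling.spacing:
            raise GeometryError(f"stimulus {s} lies outside the wall sampling")
        rows += [n] * len(seeds)
        cols += list(seeds)
        data += [onset + 1e-12] * len(seeds)  # strictly positive edge

    g = coo_matrix(
        (np.concatenate([cost, cost, np.asarray(data)]),
         (np.concatenate([pairs[:, 0], pairs[:, 1], np.asarray(rows)]),
          np.concatenate([pairs[:, 1], pairs[:, 0], np.asarray(cols)]))),
        shape=(n + 1, n + 1)).tocsr()
    tau = dijkstra(g, directed=True, indices=n)[:n]
    if not np.all(np.isfinite(tau)):
        bad = np.where(~np.isfinite(tau))[0]
        raise GeometryError(f"{len(bad)} sampling points unreachable, e.g. "
                            f"indices {bad[:5].tolist()}")
    tau_surf = tau[sampling.surface_to_sample]
    return VolumeActivation(tau, tau_surf, stimuli,
                            meta=dict(v_t=v_t, k=k,
                                      scenario=stimuli.scenario))


# --------------------------------------------------------------------------
# stimulus catalogues
# --------------------------------------------------------------------------

#: onset staggering of the sinus early sites (ms)
SINUS_ONSETS = (0.0, 5.0, 10.0, 15.0)


def _seed_point(sampling: MyocardialSampling, node: int) -> np.ndarray:
    """Wall sampling point adjacent to a surface node (seed inside the wall)."""
    return sampling.points[sampling.surface_to_sample[node]]


def _pick(vertices, cand_ids, score):
    if len(cand_ids) == 0:
        raise GeometryError("no surface nodes in the requested class")
    return int(cand_ids[np.argmax(score(vertices[cand_ids]))])


def sinus_stimuli(sampling: MyocardialSampling, vertices: np.ndarray,
                  n_sites: int = 4, radius: float = 3.0) -> StimulusSet:
    """Endocardial early-activation profile standing in for the Purkinje
    system: by default two septal sites near the apex, one high left
    ventricular endocardial site and one right ventricular endocardial
    site, with staggered onsets.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    cls, side = sampling.node_class, sampling.node_side
    z0 = vertices[:, 2].min()
    septal = np.where(cls == "septal")[0]
    lv_endo = np.where((cls == "endo") & (side == "lv"))[0]
    rv_endo = np.where((cls == "endo") & (side == "rv"))[0]
    nodes = []
    if len(septal) and len(rv_endo) and len(lv_endo):
        sep_lv = septal[side[septal] == "lv"]
        sep_rv = septal[side[septal] == "rv"]

        def spread(cand, score0):
            """Pick from cand by score, then by separation from chosen."""
            if len(nodes) == 0:
                return _pick(vertices, cand, score0)
            chosen = vertices[nodes]
            return _pick(vertices, cand, lambda v: np.min(np.linalg.norm(
                v[:, None, :] - chosen[None, :, :], axis=-1), axis=1))

        nodes.append(_pick(vertices, sep_lv if len(sep_lv) else septal,
                           lambda v: -v[:, 2]))
        nodes.append(spread(sep_rv if len(sep_rv) else septal, None))
        nodes.append(_pick(vertices, lv_endo, lambda v: v[:, 2]))
        nodes.append(spread(rv_endo, None))
    else:  # single-chamber shell: spread endocardial sites apart
        endo = np.where(cls != "epi")[0]
        chosen = [int(endo[np.argmin(vertices[endo, 2])])]
        for _ in range(3):
            d = np.min(np.linalg.norm(
                vertices[endo][:, None, :] - vertices[chosen][None, :, :],
                axis=-1), axis=1)
            chosen.append(int(endo[np.argmax(d)]))
        nodes = chosen
    nodes = nodes[:n_sites]
    while len(nodes) < n_sites:  # more sites: farthest-point fill-in
        endo = np.where(cls != "epi")[0]
        d = np.min(np.linalg.norm(
            vertices[endo][:, None, :] - vertices[nodes][None, :, :],
            axis=-1), axis=1)
        nodes.append(int(endo[np.argmax(d)]))
    pos = np.array([_seed_point(sampling, j) for j in nodes])
    onsets = np.resize(np.asarray(SINUS_ONSETS), len(nodes))
    return StimulusSet(pos, onsets, np.full(len(nodes), radius), "sinus")


def ectopic_pair(sampling: MyocardialSampling, vertices: np.ndarray,
                 node: int, radius: float = 3.0,
                 label: str = "ectopic") -> tuple[StimulusSet, StimulusSet]:
    """Paired stimuli on opposite sides of the wall at one location.

    For a free-wall node the pair is (endocardial, epicardial) along the
    transmural direction; for a septal node it is the two opposite septal
    faces.  Returns two single-seed stimulus sets.
    """
    cls, side = sampling.node_class, sampling.node_side
    v0 = vertices[node]
    if cls[node] == "septal":
        other = np.where((cls == "septal") & (side != side[node]))[0]
        if len(other) == 0:
            raise GeometryError("no opposite septal face present")
        mate = int(other[np.argmin(np.linalg.norm(vertices[other] - v0,
                                                  axis=1))])
    else:
        target = "epi" if cls[node] == "endo" else "endo"
        other = np.where(cls == target)[0]
        mate = int(other[np.argmin(np.linalg.norm(vertices[other] - v0,
                                                  axis=1))])
        if cls[node] == "epi":
            node, mate = mate, node
    a = StimulusSet(_seed_point(sampling, node), [0.0], [radius],
                    f"{label}_a")
    b = StimulusSet(_seed_point(sampling, mate), [0.0], [radius],
                    f"{label}_b")
    return a, b


def ectopic_catalogue(ventricle: Ventricle,
                      radius: float = 3.0) -> list[dict]:
    """The default set of eight ectopic scenarios: septal left/right, left
    ventricular free wall endo/epi, right ventricular free wall endo/epi,
    and basal left/right near the septum.

    Each entry carries the stimulus set, the seeding surface node, its
    true endo/epi/septal class and a scenario label.
    """
    smp, v = ventricle.sampling, ventricle.surface.vertices
    cls, side = smp.node_class, smp.node_side
    zmax = v[:, 2].max()

    def pick(mask, score):
        ids = np.where(mask)[0]
        if len(ids) == 0:
            raise GeometryError("geometry lacks nodes for the focus catalogue")
        return int(ids[np.argmax(score(v[ids]))])

    mid = lambda vv: -np.abs(vv[:, 2] - np.median(v[:, 2]))  # noqa: E731
    entries = []
    sep_l = pick((cls == "septal") & (side == "lv"), mid)
    sep_r = pick((cls == "septal") & (side == "rv"), mid)
    lv_endo = pick((cls == "endo") & (side == "lv"), lambda vv: vv[:, 0] + mid(vv))
    rv_endo = pick((cls == "endo") & (side == "rv"), lambda vv: -vv[:, 0] + mid(vv))
    base_l = pick((cls != "epi") & (side == "lv"), lambda vv: vv[:, 2])
    base_r = pick((cls != "epi") & (side == "rv"), lambda vv: vv[:, 2])

    def add(label, node, want="endo"):
        a, b = ectopic_pair(smp, v, node, radius, label)
        stim, seed_node = (a, node)
        if want == "epi":
            # the epicardial member of the transmural pair
            epi_ids = np.where(cls == "epi")[0]
            seed_node = int(epi_ids[np.argmin(np.linalg.norm(
                v[epi_ids] - b.positions[0], axis=1))])
            stim = b
        entries.append(dict(label=label, stimuli=stim, node=seed_node,
                            true_class=str(cls[seed_node]),
                            position=v[seed_node].copy()))

    add("septal_lv", sep_l)
    add("septal_rv", sep_r)
    add("lv_free_endo", lv_endo)
    add("lv_free_epi", lv_endo, want="epi")
    add("rv_free_endo", rv_endo)
    add("rv_free_epi", rv_endo, want="epi")
    add("base_lv", base_l)
    add("base_rv", base_r)
    for e in entries:
        e["stimuli"] = StimulusSet(e["stimuli"].positions,
                                   e["stimuli"].onsets,
                                   e["stimuli"].radii, e["label"])
    return entries
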