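"""Synthetic torso/heart geometry for activation-time imaging.

Builds the triangulated compartment surfaces of an inhomogeneous volume
conductor (thorax, lungs, intracavitary blood, ventricular myocardium), a
rule-based myocardial fiber field, a volumetric sampling of the ventricular
wall, electrode positions, the surface Laplacian used for regularization and
the geodesic graph used by the fastest-route algorithm.

Conventions: lengths in mm, conductivities in S/m, 0-based vertex indices,
outward-oriented faces.  The ventricular source surface is oriented outward
from the *myocardium*: the epicardial component has positive signed volume,
endocardial (cavity) components negative, and the total signed volume equals
the wall volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import trimesh
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage import measure


class GeometryError(ValueError):
    """Invalid or degenerate geometry (open surface, nesting violation, ...)."""


# --------------------------------------------------------------------------
# basic mesh primitives
# --------------------------------------------------------------------------

def triangle_solid_angles(points: np.ndarray, vertices: np.ndarray,
                          faces: np.ndarray, chunk: int = 2_000_000) -> np.ndarray:
    """Signed solid angle of each triangle as seen from each point.

    Uses the van Oosterom & Strackee closed form, which is exact for plane
    triangles.  The sign follows the face orientation: a closed outward
    surface subtends +4*pi at interior points and 0 at exterior points.

    Returns an array of shape ``(len(points), len(faces))``.
    """
    points = np.asarray(points, dtype=float)
    out = np.empty((len(points), len(faces)))
    # chunk over observation points so the (P, F, 3) temporaries stay small
    step = max(1, int(chunk // max(len(faces), 1)))
    tri = vertices[faces]  # (F, 3, 3)
    for s in range(0, len(points), step):
        p = points[s:s + step]
        r = tri[None, :, :, :] - p[:, None, None, :]        # (p, F, 3, 3)
        n = np.linalg.norm(r, axis=-1)                       # (p, F, 3)
        r1, r2, r3 = r[..., 0, :], r[..., 1, :], r[..., 2, :]
        n1, n2, n3 = n[..., 0], n[..., 1], n[..., 2]
        num = np.einsum('...i,...i->...', r1, np.cross(r2, r3))
        den = (n1 * n2 * n3 + np.einsum('...i,...i->...', r1, r2) * n3
               + np.einsum('...i,...i->...', r1, r3) * n2
               + np.einsum('...i,...i->...', r2, r3) * n1)
        out[s:s + step] = 2.0 * np.arctan2(num, den)
    return out


def winding_fraction(points: np.ndarray, vertices: np.ndarray,
                     faces: np.ndarray) -> np.ndarray:
    """Total solid angle / 4*pi at each point: ~1 inside, ~0 outside."""
    return triangle_solid_angles(points, vertices, faces).sum(axis=1) / (4 * np.pi)


@dataclass
class TriangleSurface:
    """A closed, consistently oriented triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array, coordinates in mm.
    faces : (m, 3) int array of vertex index triples, outward oriented.
    label : compartment name.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.vertices
        e1 = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        e2 = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        cr = np.cross(e1, e2)
        area2 = np.linalg.norm(cr, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = cr / area2[:, None]
        return normals, area2 / 2.0

    def area(self) -> float:
        return float(self.face_normals_areas()[1].sum())

    def signed_volume(self) -> float:
        v = self.vertices[self.faces]
        return float(np.einsum('ij,ij->i', v[:, 0],
                               np.cross(v[:, 1], v[:, 2])).sum() / 6.0)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric area patch per vertex (one third of adjacent faces)."""
        _, a = self.face_normals_areas()
        out = np.zeros(self.n_vertices)
        np.add.at(out, self.faces.ravel(), np.repeat(a / 3.0, 3))
        return out

    def vertex_normals(self) -> np.ndarray:
        n, a = self.face_normals_areas()
        out = np.zeros_like(self.vertices)
        np.add.at(out, self.faces.ravel(), np.repeat(n * a[:, None], 3, axis=0))
        nrm = np.linalg.norm(out, axis=1, keepdims=True)
        return out / np.maximum(nrm, 1e-300)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, shape (k, 2)."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + len(self.faces)

    def is_closed(self) -> bool:
        """Every directed edge appears exactly once (closed + orientable)."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        fwd = {(a, b) for a, b in e.tolist()}
        if len(fwd) != len(e):
            return False
        return all((b, a) in fwd for a, b in fwd)

    def validate(self, require_positive_volume: bool = True) -> None:
        if not self.is_closed():
            raise GeometryError(f"surface {self.label!r} is not a closed "
                                "orientable manifold")
        _, areas = self.face_normals_areas()
        if np.any(areas <= 1e-12):
            raise GeometryError(f"surface {self.label!r} has degenerate faces")
        if require_positive_volume and self.signed_volume() <= 0:
            raise GeometryError(f"surface {self.label!r} has non-positive "
                                "enclosed volume (orientation?)")

    def flipped(self) -> "TriangleSurface":
        return TriangleSurface(self.vertices.copy(),
                               self.faces[:, [0, 2, 1]].copy(), self.label)

    def components(self) -> list[np.ndarray]:
        """Vertex index sets of connected components."""
        e = self.edges()
        adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                         shape=(self.n_vertices, self.n_vertices))
        n, lab = connected_components(adj, directed=False)
        return [np.where(lab == i)[0] for i in range(n)]

    def submesh(self, vertex_ids: np.ndarray, label: str = "") -> "TriangleSurface":
        mask = np.zeros(self.n_vertices, bool)
        mask[vertex_ids] = True
        fmask = mask[self.faces].all(axis=1)
        remap = -np.ones(self.n_vertices, np.int64)
        remap[vertex_ids] = np.arange(len(vertex_ids))
        return TriangleSurface(self.vertices[vertex_ids],
                               remap[self.faces[fmask]], label or self.label)

    def contains(self, points: np.ndarray, tol: float = 0.25) -> np.ndarray:
        return np.abs(winding_fraction(points, self.vertices, self.faces)) > tol


# --------------------------------------------------------------------------
# conductivity setups (intra/extracellular tensors of the myocardium)
# --------------------------------------------------------------------------

#: default bulk conductivities of the volume-conductor compartments, S/m
BULK_CONDUCTIVITY = {"thorax": 0.2, "lungs": 0.04, "blood": 0.6, "heart": 0.2}


@dataclass(frozen=True)
class ConductivitySetup:
    """Longitudinal/transversal intra- and extracellular conductivities (S/m).

    ``isotropic``  : sigma_i = 0.05, sigma_e = 0.15 in all directions.
    ``equal``      : both domains have anisotropy ratio 3.
    ``unequal``    : extracellular ratio 3, intracellular ratio 9.

    The isotropic/equal/unequal transversal values coincide, so the three
    cases differ only in the longitudinal components.
    """

    case: str
    sigma_i_l: float
    sigma_i_t: float
    sigma_e_l: float
    sigma_e_t: float

    def __post_init__(self) -> None:
        if min(self.sigma_i_l, self.sigma_i_t, self.sigma_e_l, self.sigma_e_t) <= 0:
            raise ValueError("conductivities must be positive")
        ri = self.sigma_i_l / self.sigma_i_t
        re = self.sigma_e_l / self.sigma_e_t
        expected = {"isotropic": (1.0, 1.0), "equal": (3.0, 3.0),
                    "unequal": (9.0, 3.0)}
        if self.case in expected and not np.allclose((ri, re), expected[self.case]):
            raise ValueError(f"anisotropy ratios ({ri:g}, {re:g}) inconsistent "
                             f"with case {self.case!r}")

    @property
    def jump_factor(self) -> float:
        """Fractional TMP jump of the dipole layer, sigma_i / (sigma_i + sigma_e).

        Evaluated with the transversal (= isotropic-case) values.
        """
        return self.sigma_i_t / (self.sigma_i_t + self.sigma_e_t)

    @property
    def velocity_ratio(self) -> float:
        """Longitudinal/transversal conduction velocity ratio.

        Monodomain propagation speed scales with the square root of the
        effective (harmonic-mean) monodomain conductivity
        sigma_i * sigma_e / (sigma_i + sigma_e) per direction: k = 1 for the
        isotropic case, sqrt(3) for equal anisotropy ratios and sqrt(6) for
        the unequal case.
        """
        eff_l = self.sigma_i_l * self.sigma_e_l / (self.sigma_i_l
                                                   + self.sigma_e_l)
        eff_t = self.sigma_i_t * self.sigma_e_t / (self.sigma_i_t
                                                   + self.sigma_e_t)
        return float(np.sqrt(eff_l / eff_t))

    @classmethod
    def preset(cls, case: str) -> "ConductivitySetup":
        table = {
            "isotropic": (0.05, 0.05, 0.15, 0.15),
            "equal": (0.15, 0.05, 0.45, 0.15),
            "unequal": (0.45, 0.05, 0.45, 0.15),
        }
        if case not in table:
            raise ValueError(f"unknown conductivity case {case!r}")
        return cls(case, *table[case])


@dataclass
class FiberField:
    """Unit fiber directions sampled at volumetric positions.

    ``depth`` is the normalized transmural coordinate in [0, 1]
    (0 = endocardium, 1 = epicardium).
    """

    positions: np.ndarray
    directions: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        nrm = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(nrm, 1.0, atol=1e-9):
            raise ValueError("fiber directions must be unit vectors")


@dataclass
class MyocardialSampling:
    """Volumetric point cloud of the ventricular wall.

    Carries per-point fiber directions and volume elements, the mapping
    between wall samples and surface nodes, and the endo/epi/septal
    classification of the surface nodes.
    """

    points: np.ndarray               # (n, 3) mm
    fibers: FiberField
    dv: np.ndarray                   # (n,) mm^3
    nearest_surface_node: np.ndarray  # (n,) surface node index
    surface_to_sample: np.ndarray     # (n_surf,) sampling index per surface node
    node_class: np.ndarray            # (n_surf,) strings: 'endo'|'epi'|'septal'
    node_side: np.ndarray             # (n_surf,) strings: 'lv'|'rv'|'epi'
    spacing: float

    def __post_init__(self) -> None:
        if np.any(self.dv <= 0):
            raise ValueError("volume elements must be positive")
        if not set(np.unique(self.node_class)) <= {"endo", "epi", "septal"}:
            raise ValueError("node classes must partition into endo/epi/septal")


@dataclass
class Ventricle:
    """Bundle returned by :func:`build_ventricle` (unpacks as a 3-tuple)."""

    surface: TriangleSurface
    fibers: FiberField
    sampling: MyocardialSampling
    blood_surfaces: list[TriangleSurface] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __iter__(self) -> Iterator:
        return iter((self.surface, self.fibers, self.sampling))


@dataclass
class VolumeConductorModel:
    """Nested closed compartments with isotropic bulk conductivities.

    ``compartments`` is an ordered outside-in list of
    (surface, conductivity inside, conductivity outside); outside the
    outermost surface the conductivity is 0.  ``heart_index`` points at the
    ventricular source surface.
    """

    compartments: list[tuple[TriangleSurface, float, float]]
    electrodes: np.ndarray
    electrode_nodes: np.ndarray
    heart_index: int
    ventricle: Ventricle | None = None

    @property
    def torso(self) -> TriangleSurface:
        return self.compartments[0][0]

    @property
    def heart_surface(self) -> TriangleSurface:
        return self.compartments[self.heart_index][0]

    def validate(self) -> None:
        torso, s_in, s_out = self.compartments[0]
        if s_out != 0.0:
            raise GeometryError("conductivity outside the torso must be 0")
        for surf, si, so in self.compartments:
            surf.validate()
            if si <= 0 or (so < 0):
                raise GeometryError("conductivities must be positive inside")
        for surf, _, _ in self.compartments[1:]:
            frac = winding_fraction(surf.vertices, torso.vertices, torso.faces)
            if not np.all(frac > 0.5):
                raise GeometryError(f"compartment {surf.label!r} not strictly "
                                    "inside the torso")
        d, _ = cKDTree(self.torso.vertices).query(self.electrodes)
        if np.max(d) > 1e-6:
            raise GeometryError("electrodes must lie on the torso surface")


# --------------------------------------------------------------------------
# implicit shapes and meshing helpers
# --------------------------------------------------------------------------

def _ellipsoid_mesh(semiaxes, center, subdivisions: int, label: str) -> TriangleSurface:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    v = ico.vertices * np.asarray(semiaxes) + np.asarray(center)
    return TriangleSurface(v, np.asarray(ico.faces), label)


def _ellipsoid_value(pts, center, semi):
    q = (pts - np.asarray(center)) / np.asarray(semi)
    return 1.0 - np.einsum('...i,...i->...', q, q)


def _biventricular_implicit(params: dict):
    """Return F(pts): >0 inside the myocardial wall, and the cavity implicits."""
    p = params

    def f_epi(pts):
        e = np.maximum(_ellipsoid_value(pts, p["lv_center"], p["lv_epi"]),
                       _ellipsoid_value(pts, p["rv_center"], p["rv_epi"]))
        return np.minimum(e, (p["z_base"] - pts[..., 2]) / p["lv_epi"][2])

    def f_lv_cavity(pts, inset=0.0):
        semi = np.asarray(p["lv_cavity"]) - inset
        e = _ellipsoid_value(pts, p["lv_center"], semi)
        return np.minimum(e, (p["z_cap"] - inset - pts[..., 2]) / semi[2])

    def f_rv_cavity(pts, inset=0.0):
        semi = np.asarray(p["rv_cavity"]) - inset
        e = _ellipsoid_value(pts, p["rv_cavity_center"], semi)
        keep = -_ellipsoid_value(pts, p["lv_center"],
                                 np.asarray(p["lv_cavity"]) + p["septum"] + inset)
        return np.minimum(np.minimum(e, keep),
                          (p["z_cap"] - inset - pts[..., 2]) / semi[2])

    def f_wall(pts):
        return np.minimum(f_epi(pts),
                          np.minimum(-f_lv_cavity(pts), -f_rv_cavity(pts)))

    return f_wall, f_epi, f_lv_cavity, f_rv_cavity


def _marching_cubes_surface(f, bounds, spacing: float, label: str,
                            smooth_iters: int = 8) -> TriangleSurface:
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    ax = [np.arange(lo[i], hi[i] + spacing, spacing) for i in range(3)]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    vol = f(grid)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0,
                                                spacing=(spacing,) * 3)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if smooth_iters:
        trimesh.smoothing.filter_taubin(mesh, lamb=0.5, nu=0.53,
                                        iterations=smooth_iters)
    if not mesh.is_watertight:
        raise GeometryError(f"marching-cubes surface {label!r} is not closed; "
                            "refine the resolution or relax the shape parameters")
    surf = TriangleSurface(np.asarray(mesh.vertices),
                           np.asarray(mesh.faces), label)
    if surf.signed_volume() < 0:  # orient outward from the enclosed region
        surf = surf.flipped()
    return surf


_DEF_BIV = dict(
    lv_center=(0.0, 0.0, 0.0),
    rv_center=(-20.0, 0.0, 5.0),
    rv_cavity_center=(-24.0, 0.0, 5.0),
    z_base=18.0,
    z_cap=10.0,
    septum=9.0,
)


def _fiber_directions(points: np.ndarray, depth: np.ndarray,
                      rotation_deg: float) -> np.ndarray:
    """Rule-based helix fibers: angle varies linearly with wall depth.

    The fiber lies in the plane spanned by the local circumferential
    direction (about the long axis, z) and the long axis itself; the helix
    angle goes from +rotation/2 at the endocardium to -rotation/2 at the
    epicardium.
    """
    xy = points[:, :2]
    r = np.linalg.norm(xy, axis=1)
    circ = np.zeros_like(points)
    ok = r > 1e-6
    circ[ok, 0] = -xy[ok, 1] / r[ok]
    circ[ok, 1] = xy[ok, 0] / r[ok]
    circ[~ok] = (1.0, 0.0, 0.0)  # on-axis fallback
    alpha = np.deg2rad(rotation_deg) * (0.5 - depth)
    fib = circ * np.cos(alpha)[:, None]
    fib[:, 2] += np.sin(alpha)
    return fib / np.linalg.norm(fib, axis=1, keepdims=True)


def _classify_and_sample(surface: TriangleSurface, f_wall, cavity_infos,
                         bounds, sample_spacing: float,
                         fiber_rotation: float) -> tuple[FiberField, MyocardialSampling]:
    """Shared tail of build_ventricle: sampling, fibers, classification.

    ``cavity_infos`` is a list of (component vertex ids, side label).
    """
    comps = surface.components()
    vols = []
    for ids in comps:
        vols.append(abs(surface.submesh(ids).signed_volume()))
    epi_comp = comps[int(np.argmax(vols))]
    is_epi_node = np.zeros(surface.n_vertices, bool)
    is_epi_node[epi_comp] = True

    node_class = np.where(is_epi_node, "epi", "endo").astype(object)
    node_side = np.where(is_epi_node, "epi", "lv").astype(object)
    endo_sets = []
    for ids, side in cavity_infos:
        node_side[ids] = side
        endo_sets.append(ids)
    # septal endo nodes: close to the opposite cavity's vertex set
    if len(endo_sets) == 2:
        for a, b in ((0, 1), (1, 0)):
            d, _ = cKDTree(surface.vertices[endo_sets[b]]).query(
                surface.vertices[endo_sets[a]])
            node_class[endo_sets[a][d < 16.0]] = "septal"
    node_class = node_class.astype("U8")
    node_side = node_side.astype("U4")

    # volumetric sampling on a regular grid restricted to the wall interior
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    ax = [np.arange(lo[i] + sample_spacing / 2, hi[i], sample_spacing)
          for i in range(3)]
    pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts[f_wall(pts) > 0]
    dsurf, _ = cKDTree(surface.vertices).query(pts)
    pts = pts[dsurf > 0.30 * sample_spacing]
    if len(pts) < 50:
        raise GeometryError("wall sampling too sparse; decrease sample spacing")

    endo_ids = np.where(~is_epi_node)[0]
    epi_ids = np.where(is_epi_node)[0]
    d_endo, _ = cKDTree(surface.vertices[endo_ids]).query(pts)
    d_epi, _ = cKDTree(surface.vertices[epi_ids]).query(pts)
    depth = d_endo / (d_endo + d_epi)

    fibers = FiberField(pts, _fiber_directions(pts, depth, fiber_rotation), depth)

    _, nearest_node = cKDTree(surface.vertices).query(pts)
    surf_to_sample = cKDTree(pts).query(surface.vertices)[1]
    sampling = MyocardialSampling(
        points=pts, fibers=fibers,
        dv=np.full(len(pts), sample_spacing ** 3),
        nearest_surface_node=nearest_node,
        surface_to_sample=surf_to_sample,
        node_class=node_class, node_side=node_side,
        spacing=sample_spacing)
    return fibers, sampling


def build_ventricle(kind: str = "biventricular", *,
                    long_axis: float = 55.0, short_axis: float = 33.0,
                    wall_thickness: float = 10.0, resolution: float = 5.5,
                    sample_spacing: float = 2.5,
                    fiber_rotation: float = 120.0,
                    blood_inset: float = 1.5) -> Ventricle:
    """Build a synthetic ventricular geometry.

    Parameters
    ----------
    kind : 'biventricular' (default study geometry: LV + crescent RV sharing
        a septal wall) or 'shell' (single-chamber thick-walled ellipsoid used
        by cheap unit tests).
    long_axis, short_axis : epicardial semi-axes in mm (apex-base, lateral).
    wall_thickness : LV free-wall thickness in mm; must be < short_axis.
    resolution : target mesh edge length / marching-cubes grid spacing (mm).
    sample_spacing : spacing of the volumetric wall sampling (mm).
    fiber_rotation : total helix-angle rotation endo -> epi in degrees.
    blood_inset : inset of the blood compartment boundary from the
        endocardium (mm), keeping the source surface off the BEM surfaces.

    Returns a :class:`Ventricle`; iterating it yields
    ``(surface, fibers, sampling)``.
    """
    if wall_thickness >= short_axis:
        raise GeometryError("wall thickness must be smaller than the short axis")

    if kind == "shell":
        return _build_shell(long_axis, short_axis, wall_thickness, resolution,
                            sample_spacing, fiber_rotation, blood_inset)
    if kind != "biventricular":
        raise ValueError(f"unknown ventricle kind {kind!r}")

    w = wall_thickness
    p = dict(_DEF_BIV)
    p["lv_epi"] = (short_axis + 1.0, short_axis - 1.0, long_axis)
    p["lv_cavity"] = (short_axis + 1.0 - w, short_axis - 1.0 - w, long_axis - w)
    p["rv_epi"] = (short_axis + 5.0, short_axis - 5.0, long_axis - 7.0)
    p["rv_cavity"] = (short_axis - 7.0, short_axis - 14.0, long_axis - 19.0)
    f_wall, f_epi, f_lv, f_rv = _biventricular_implicit(p)

    lo = (p["rv_center"][0] - p["rv_epi"][0] - 6, -short_axis - 8,
          -long_axis - 8)
    hi = (p["lv_epi"][0] + 6, short_axis + 8, p["z_base"] + 6)
    bounds = (lo, hi)

    surface = _marching_cubes_surface(f_wall, bounds, resolution, "ventricle",
                                      smooth_iters=8)
    comps = surface.components()
    # drop spurious marching-cubes bubbles (tiny enclosed volume)
    cvols = [abs(surface.submesh(ids).signed_volume()) for ids in comps]
    keep = [ids for ids, cv in zip(comps, cvols) if cv > 0.01 * max(cvols)]
    if len(keep) != len(comps):
        surface = surface.submesh(np.concatenate(keep), "ventricle")
        comps = surface.components()
    if len(comps) != 3:
        raise GeometryError(
            f"expected 3 boundary components (epi + 2 cavities), got "
            f"{len(comps)}; the wall is fused or pierced at this resolution")
    if surface.n_vertices < 200:
        raise GeometryError("resolution too coarse: fewer than 200 surface nodes")
    # orient: epi outward (+V), cavities toward the cavity (-V as seen from wall)
    vols = [surface.submesh(ids).signed_volume() for ids in comps]
    epi_i = int(np.argmax(np.abs(vols)))
    new_faces = []
    cavity_infos = []
    for i, ids in enumerate(comps):
        mask = np.isin(surface.faces, ids).all(axis=1)
        fc = surface.faces[mask]
        want_positive = i == epi_i
        if (vols[i] > 0) != want_positive:
            fc = fc[:, [0, 2, 1]]
        new_faces.append(fc)
        if i != epi_i:
            side = "lv" if abs(np.mean(surface.vertices[ids, 0]
                                       - p["lv_center"][0])) < \
                           abs(np.mean(surface.vertices[ids, 0]
                                       - p["rv_cavity_center"][0])) else "rv"
            cavity_infos.append((ids, side))
    surface = TriangleSurface(surface.vertices, np.concatenate(new_faces),
                              "ventricle")
    surface.validate()

    fibers, sampling = _classify_and_sample(surface, f_wall, cavity_infos,
                                            bounds, sample_spacing,
                                            fiber_rotation)

    blood = []
    for name, f_cav in (("blood_lv", f_lv), ("blood_rv", f_rv)):
        s = _marching_cubes_surface(lambda q, fc=f_cav: fc(q, inset=blood_inset),
                                    bounds, resolution, name, smooth_iters=8)
        s.validate()
        blood.append(s)

    params = dict(kind=kind, long_axis=long_axis, short_axis=short_axis,
                  wall_thickness=wall_thickness, resolution=resolution,
                  sample_spacing=sample_spacing, fiber_rotation=fiber_rotation,
                  blood_inset=blood_inset, **p)
    return Ventricle(surface, fibers, sampling, blood, params)


def _subdiv_for(resolution: float, radius: float) -> int:
    # icosahedron edge ~ 1.05 R, halved per subdivision
    n = int(np.clip(np.round(np.log2(1.05 * radius / max(resolution, 1e-6))),
                    1, 6))
    return n


def _build_shell(long_axis, short_axis, w, resolution, sample_spacing,
                 fiber_rotation, blood_inset) -> Ventricle:
    epi_semi = np.array([short_axis, short_axis, long_axis])
    endo_semi = epi_semi - w
    sub = _subdiv_for(resolution, float(np.mean(epi_semi)))
    epi = _ellipsoid_mesh(epi_semi, (0, 0, 0), sub, "epi")
    endo = _ellipsoid_mesh(endo_semi, (0, 0, 0),
                           max(sub - 1, 1), "endo").flipped()
    n_epi = epi.n_vertices
    surface = TriangleSurface(
        np.vstack([epi.vertices, endo.vertices]),
        np.vstack([epi.faces, endo.faces + n_epi]), "ventricle")
    if surface.n_vertices < 200:
        raise GeometryError("resolution too coarse: fewer than 200 surface nodes")
    surface.validate()

    def f_wall(pts):
        return np.minimum(_ellipsoid_value(pts, (0, 0, 0), epi_semi),
                          -_ellipsoid_value(pts, (0, 0, 0), endo_semi))

    bounds = (-epi_semi - 4, epi_semi + 4)
    endo_ids = np.arange(n_epi, surface.n_vertices)
    fibers, sampling = _classify_and_sample(surface, f_wall,
                                            [(endo_ids, "lv")], bounds,
                                            sample_spacing, fiber_rotation)
    blood = [_ellipsoid_mesh(endo_semi - blood_inset, (0, 0, 0),
                             max(sub - 1, 1), "blood_lv")]
    params = dict(kind="shell", long_axis=long_axis, short_axis=short_axis,
                  wall_thickness=w, resolution=resolution,
                  sample_spacing=sample_spacing,
                  fiber_rotation=fiber_rotation, blood_inset=blood_inset)
    return Ventricle(surface, fibers, sampling, blood, params)


# --------------------------------------------------------------------------
# torso assembly
# --------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def place_electrodes(torso: TriangleSurface, n: int = 120) -> np.ndarray:
    """Quasi-uniform electrode layout: snap Fibonacci-sphere directions to
    the nearest distinct torso vertices.  Returns vertex indices."""
    center = torso.vertices.mean(axis=0)
    scale = (torso.vertices - center).std(axis=0)
    probes = _fibonacci_directions(max(3 * n, 256)) * scale * 1.5 + center
    _, idx = cKDTree(torso.vertices).query(probes)
    chosen: list[int] = []
    seen: set[int] = set()
    for j in idx:
        if j not in seen:
            seen.add(int(j))
            chosen.append(int(j))
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise GeometryError("torso mesh too coarse to place the electrodes")
    return np.asarray(chosen)


def build_torso(ventricle: Ventricle, *,
                torso_semiaxes: Sequence[float] = (170.0, 115.0, 280.0),
                heart_center: Sequence[float] = (35.0, 40.0, 55.0),
                include_lungs: bool = True,
                n_electrodes: int = 120,
                torso_subdivisions: int = 3,
                conductivities: dict | None = None) -> VolumeConductorModel:
    """Assemble the inhomogeneous volume conductor around a built ventricle.

    Compartments (outside-in): thorax (0.2 S/m), lungs (0.04), ventricular
    myocardium as bulk 0.2 (intra + extracellular isotropic sum), blood
    cavities (0.6).  Electrodes are ``n_electrodes`` quasi-uniform torso
    vertices.
    """
    cond = dict(BULK_CONDUCTIVITY)
    if conductivities:
        cond.update(conductivities)
    hc = np.asarray(heart_center, float)

    def shift(surf: TriangleSurface, label=None) -> TriangleSurface:
        return TriangleSurface(surf.vertices + hc, surf.faces.copy(),
                               label or surf.label)

    torso = _ellipsoid_mesh(torso_semiaxes, (0, 0, 0), torso_subdivisions,
                            "thorax")
    comps: list[tuple[TriangleSurface, float, float]] = [
        (torso, cond["thorax"], 0.0)]
    if include_lungs:
        lung_r = _ellipsoid_mesh((45, 55, 140), (-95, -30, 20), 2, "lung_right")
        lung_l = _ellipsoid_mesh((45, 55, 140), (95, -30, 20), 2, "lung_left")
        comps += [(lung_r, cond["lungs"], cond["thorax"]),
                  (lung_l, cond["lungs"], cond["thorax"])]

    heart = shift(ventricle.surface)
    heart_index = len(comps)
    comps.append((heart, cond["heart"], cond["thorax"]))
    for b in ventricle.blood_surfaces:
        comps.append((shift(b), cond["blood"], cond["heart"]))

    # shift the ventricle bundle into torso coordinates as well
    vent = Ventricle(
        surface=heart,
        fibers=FiberField(ventricle.fibers.positions + hc,
                          ventricle.fibers.directions.copy(),
                          ventricle.fibers.depth.copy()),
        sampling=dataclasses.replace(
            ventricle.sampling,
            points=ventricle.sampling.points + hc,
            fibers=FiberField(ventricle.fibers.positions + hc,
                              ventricle.fibers.directions.copy(),
                              ventricle.fibers.depth.copy())),
        blood_surfaces=[shift(b) for b in ventricle.blood_surfaces],
        params=dict(ventricle.params, heart_center=tuple(hc)))

    e_nodes = place_electrodes(torso, n_electrodes)
    vcm = VolumeConductorModel(comps, torso.vertices[e_nodes], e_nodes,
                               heart_index, vent)
    vcm.validate()
    _check_disjoint(vcm)
    return vcm


def _check_disjoint(vcm: VolumeConductorModel, margin: float = 2.0) -> None:
    inner = [c[0] for c in vcm.compartments[1:]]
    blood_labels = {s.label for s in (vcm.ventricle.blood_surfaces
                                      if vcm.ventricle else [])}
    for i in range(len(inner)):
        for j in range(i + 1, len(inner)):
            a, b = inner[i], inner[j]
            if a.label in blood_labels or b.label in blood_labels:
                continue  # blood is nested inside the heart surface
            d, _ = cKDTree(a.vertices).query(b.vertices)
            if d.min() < margin:
                raise GeometryError(
                    f"compartments {a.label!r} and {b.label!r} are closer "
                    f"than {margin} mm")


# --------------------------------------------------------------------------
# surface Laplacian and geodesic graph
# --------------------------------------------------------------------------

def surface_laplacian(surface: TriangleSurface) -> csr_matrix:
    """Symmetric umbrella Laplacian L = A - D on the surface graph.

    Rows sum to zero, so L annihilates constant fields; the operator is used
    as the second-order Tikhonov penalty on activation times.
    """
    if not surface.is_closed():
        raise GeometryError("surface Laplacian requires a closed manifold mesh")
    e = surface.edges()
    n = surface.n_vertices
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    a = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    from scipy.sparse import diags
    return (a - diags(deg)).tocsr()


@dataclass
class GeodesicGraph:
    """Weighted surface graph for fastest-route activation maps.

    ``lengths`` holds Euclidean edge lengths (mm) over mesh edges plus the
    transmural endo->epi pairing edges, which are flagged in ``transmural``
    so a distinct propagation velocity can be applied.
    """

    n: int
    lengths: csr_matrix
    transmural: csr_matrix

    def travel_times(self, v_surface: float, v_transmural: float) -> csr_matrix:
        """Edge traversal times (ms) given the two velocities (mm/ms)."""
        if v_surface <= 0 or v_transmural <= 0:
            raise ValueError("velocities must be positive")
        tm = self.transmural.multiply(self.lengths)
        surf = self.lengths - tm
        return (surf / v_surface + tm / v_transmural).tocsr()


def transmural_pairs(surface: TriangleSurface,
                     sampling: MyocardialSampling) -> np.ndarray:
    """Transmural links through the wall: each endocardial node is paired
    with its nearest node on a different boundary component.

    For free-wall nodes that is the nearest epicardial node; for septal
    nodes it is the opposite septal face, so the edge length is always about
    one wall thickness and never tunnels through a blood cavity.
    """
    comps = surface.components()
    comp_of = np.empty(surface.n_vertices, np.int64)
    for c, ids in enumerate(comps):
        comp_of[ids] = c
    endo = np.where(sampling.node_class != "epi")[0]
    out = []
    for i in endo:
        other = np.where(comp_of != comp_of[i])[0]
        d = np.linalg.norm(surface.vertices[other] - surface.vertices[i],
                           axis=1)
        out.append((i, other[np.argmin(d)]))
    return np.asarray(out, np.int64)


def geodesic_graph(surface: TriangleSurface,
                   pairs: np.ndarray) -> GeodesicGraph:
    """Build the FRA graph: mesh edges plus flagged transmural edges."""
    e = surface.edges()
    v = surface.vertices
    n = surface.n_vertices
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)

    def sym(idx, w):
        rows = np.concatenate([idx[:, 0], idx[:, 1]])
        cols = np.concatenate([idx[:, 1], idx[:, 0]])
        return coo_matrix((np.concatenate([w, w]), (rows, cols)),
                          shape=(n, n)).tocsr()

    surf_len = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
    tm_len = np.linalg.norm(v[pairs[:, 0]] - v[pairs[:, 1]], axis=1)
    lengths = sym(np.vstack([e, pairs]), np.concatenate([surf_len, tm_len]))
    tmask = sym(pairs, np.ones(len(pairs)))
    tmask.data = np.minimum(tmask.data, 1.0)
    ncomp, _ = connected_components(lengths, directed=False)
    if ncomp != 1:
        raise GeometryError(f"geodesic graph is disconnected ({ncomp} parts); "
                            "missing transmural links?")
    return GeodesicGraph(n, lengths, tmask)
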