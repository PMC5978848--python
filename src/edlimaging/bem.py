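"""Boundary-element solver for the inhomogeneous isotropic torso.

Solves the surface-potential integral equation of a piecewise-homogeneous
volume conductor by linear collocation with analytically integrated (van
Oosterom & Strackee) triangle solid angles, one-third vertex lumping, and
diagonal terms fixed by the constant-potential consistency condition (a
constant potential with no sources must solve the homogeneous system).  The
singular system is deflated to pin the potential reference; all reported
potentials are additionally zero-mean referenced across the electrodes.

Only surfaces with a nonzero conductivity jump carry unknowns.  In the
default model the ventricular (source) surface has equal bulk conductivity
on both sides, so the equivalent-dipole-layer source is never evaluated at
its own collocation points; the blood-compartment boundaries are inset from
the endocardium for the same reason.

Unit bookkeeping: lengths mm, conductivities S/m, dipole-layer strengths mV
(transmembrane voltage of the layer), volumetric dipole moments
sigma * grad(TMP) * dV in (S/m)*(mV/mm)*mm^3; with these choices potentials
come out in mV with no extra conversion constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.sparse import coo_matrix
from scipy.spatial import cKDTree

from .geometry import (
    TriangleSurface,
    VolumeConductorModel,
    triangle_solid_angles,
)

FOUR_PI = 4.0 * np.pi


class BEMError(RuntimeError):
    """Assembly or solve failure (singular system, source on a surface, ...)."""


@dataclass
class DipoleSet:
    """Volumetric current dipoles: positions (mm) and moments.

    Moments are ``sigma * grad(phi_h) * dV`` vectors; see the module
    docstring for units.
    """

    positions: np.ndarray
    moments: np.ndarray
    compartment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.moments = np.atleast_2d(np.asarray(self.moments, float))
        if self.positions.shape != self.moments.shape:
            raise ValueError("positions and moments must have the same shape")
        if not np.all(np.isfinite(self.moments)):
            raise ValueError("dipole moments must be finite")


@dataclass
class TransferMatrix:
    """EDL transfer operator: electrode potentials per unit layer strength.

    ``matrix`` has shape (electrodes, ventricular surface nodes), is
    zero-mean referenced across electrodes, and includes the barycentric
    area weighting of each node's patch (through lumped solid angles) and
    the ``scale`` = jump factor x TMP amplitude.
    """

    matrix: np.ndarray
    electrodes: np.ndarray
    scale: float
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[1]

    def closure_defect(self) -> float:
        """max |A @ 1| relative to the largest column norm.

        A uniform closed dipole layer is invisible outside the heart, so
        this should be at the rounding level.
        """
        resid = np.abs(self.matrix @ np.ones(self.n_nodes)).max()
        return float(resid / np.linalg.norm(self.matrix, axis=0).max())


def _lumping_matrix(surface: TriangleSurface) -> coo_matrix:
    """Sparse (faces x vertices) matrix assigning 1/3 of each face to its
    vertices (linear-collocation lumping of the solid-angle integrals)."""
    f = surface.faces
    rows = np.repeat(np.arange(len(f)), 3)
    return coo_matrix((np.full(f.size, 1.0 / 3.0), (rows, f.ravel())),
                      shape=(len(f), surface.n_vertices)).tocsr()


def _lumped_solid_angles(points: np.ndarray,
                         surface: TriangleSurface) -> np.ndarray:
    """(points x surface nodes) lumped solid-angle matrix.

    Entries for a point coinciding with a triangle vertex evaluate to zero
    (the closed form degenerates to atan2(0, 0)); callers repair those rows
    through closure constraints.
    """
    om = triangle_solid_angles(points, surface.vertices, surface.faces)
    return om @ _lumping_matrix(surface)


class BEMSolver:
    """Assembled, factorized BEM system; reusable for many right-hand sides."""

    def __init__(self, vcm: VolumeConductorModel,
                 deflation_scale: float | None = None):
        vcm.validate()
        self.vcm = vcm
        self.surfaces: list[tuple[TriangleSurface, float, float]] = []
        for surf, s_in, s_out in vcm.compartments:
            if s_in != s_out:  # zero-jump surfaces carry no unknowns
                self.surfaces.append((surf, s_in, s_out))
        if not self.surfaces:
            raise BEMError("no conductivity jumps: nothing to solve")
        self.offsets = np.cumsum([0] + [s[0].n_vertices for s in self.surfaces])
        self.points = np.vstack([s[0].vertices for s in self.surfaces])
        n = len(self.points)

        m = np.zeros((n, n))
        for li, (surf, s_in, s_out) in enumerate(self.surfaces):
            b = _lumped_solid_angles(self.points, surf)
            sl = slice(self.offsets[li], self.offsets[li + 1])
            m[:, sl] -= (s_in - s_out) / FOUR_PI * b
        np.fill_diagonal(m, 0.0)
        np.fill_diagonal(m, -m.sum(axis=1))  # constants in the nullspace

        # deflation: fix the reference by pinning the mean over torso nodes
        n_t = self.surfaces[0][0].n_vertices
        c = deflation_scale or float(np.abs(np.diag(m)).mean())
        defl = np.zeros(n)
        defl[:n_t] = c / n_t
        m += defl[None, :]
        try:
            self._lu = lu_factor(m)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise BEMError(f"singular BEM system after deflation: {exc}") from exc
        cond_probe = np.abs(np.diag(m)).max() / max(np.abs(np.diag(m)).min(),
                                                    1e-300)
        self.diagnostics = {"n_unknowns": n, "diag_ratio": float(cond_probe)}
        self._surface_tree = cKDTree(self.points)
        self._x_elec: np.ndarray | None = None

        # electrode nodes live on the torso surface, which comes first
        self.electrode_rows = np.asarray(vcm.electrode_nodes)
        self.sigma_heart = vcm.compartments[vcm.heart_index][1]

    # -- basic solves --------------------------------------------------------

    def solve(self, g: np.ndarray) -> np.ndarray:
        """Surface potentials for right-hand side g (can be a matrix of
        columns)."""
        return lu_solve(self._lu, g)

    @property
    def electrode_influence(self) -> np.ndarray:
        """(n_unknowns x n_electrodes) reciprocity solves: columns e satisfy
        M^T x_e = delta_e, so electrode potentials are x_e . g."""
        if self._x_elec is None:
            rhs = np.zeros((len(self.points), len(self.electrode_rows)))
            rhs[self.electrode_rows, np.arange(rhs.shape[1])] = 1.0
            self._x_elec = lu_solve(self._lu, rhs, trans=1)
        return self._x_elec

    # -- volumetric dipole sources -------------------------------------------

    def _dipole_kernel(self, positions: np.ndarray) -> np.ndarray:
        """(n_unknowns, n_dipoles, 3) source-term kernel m . K -> g."""
        r = self.points[:, None, :] - positions[None, :, :]
        d = np.linalg.norm(r, axis=-1)
        return r / (FOUR_PI * d[..., None] ** 3)

    def _check_clearance(self, positions: np.ndarray, tol: float) -> None:
        d, _ = self._surface_tree.query(positions)
        if np.any(d < tol):
            k = int(np.argmin(d))
            raise BEMError(f"dipole {k} is {d[k]:.3f} mm from a conductivity "
                           f"interface (tolerance {tol} mm)")

    def dipole_potential(self, dipoles: DipoleSet,
                         tol: float = 0.5) -> np.ndarray:
        """Zero-mean electrode potentials (mV) of a set of interior dipoles."""
        self._check_clearance(dipoles.positions, tol)
        k = self._dipole_kernel(dipoles.positions)
        g = np.einsum('npk,pk->n', k, dipoles.moments)
        phi = self.solve(g)[self.electrode_rows]
        return phi - phi.mean()

    def dipole_leadfield(self, positions: np.ndarray, tol: float = 0.5,
                         chunk: int = 1500) -> np.ndarray:
        """(electrodes, points, 3) lead field, zero-mean referenced.

        Precomputes electrode potentials per unit dipole moment so forward
        simulations over many time samples reduce to one tensor contraction.
        """
        positions = np.asarray(positions, float)
        self._check_clearance(positions, tol)
        x = self.electrode_influence  # (n, E)
        out = np.empty((x.shape[1], len(positions), 3))
        for s in range(0, len(positions), chunk):
            k = self._dipole_kernel(positions[s:s + chunk])
            out[:, s:s + chunk] = np.einsum('ne,npk->epk', x, k)
        out -= out.mean(axis=0, keepdims=True)
        return out

    # -- equivalent dipole layer ---------------------------------------------

    def edl_source_matrix(self, heart: TriangleSurface) -> np.ndarray:
        """Right-hand-side matrix G: column j is the BEM source term of a
        unit-strength (1 mV) dipole layer on node j's barycentric patch.

        The layer is oriented along the myocardium-outward normals; a unit
        uniform layer over the closed surface therefore produces an exactly
        zero source term at every collocation point (all of which lie
        strictly outside the myocardial wall), which the solid-angle closure
        delivers at rounding precision.
        """
        g = (self.sigma_heart / FOUR_PI) * _lumped_solid_angles(self.points,
                                                                heart)
        return g

    def edl_transfer(self, heart: TriangleSurface | None = None, *,
                     jump_factor: float = 0.25, v_amp: float = 100.0,
                     meta: dict | None = None) -> TransferMatrix:
        """Assemble the EDL transfer matrix A (electrodes x heart nodes).

        ``A[:, j]`` is the zero-mean electrode potential pattern of node j's
        'on' source, scaled by ``jump_factor * v_amp`` (the potential jump
        of the activation wavefront times the TMP amplitude).
        """
        if heart is None:
            heart = self.vcm.heart_surface
        else:
            ref = self.vcm.heart_surface
            if heart.n_vertices != ref.n_vertices or not np.allclose(
                    heart.vertices, ref.vertices):
                raise BEMError("transfer surface is not the ventricular "
                               "compartment boundary of this conductor")
        g = self.edl_source_matrix(heart)
        a = self.electrode_influence.T @ g
        a -= a.mean(axis=0, keepdims=True)
        a *= jump_factor * v_amp
        info = dict(jump_factor=jump_factor, v_amp=v_amp,
                    n_heart_nodes=heart.n_vertices,
                    n_electrodes=len(self.electrode_rows))
        info.update(meta or {})
        return TransferMatrix(a, self.vcm.electrodes.copy(),
                              jump_factor * v_amp, info)


def assemble_bem(vcm: VolumeConductorModel) -> BEMSolver:
    """Assemble and factorize the BEM system for a volume conductor."""
    return BEMSolver(vcm)


def dipole_potential(solver: BEMSolver, dipoles: DipoleSet) -> np.ndarray:
    return solver.dipole_potential(dipoles)


def edl_transfer(solver: BEMSolver, heart: TriangleSurface | None = None,
                 **kw) -> TransferMatrix:
    return solver.edl_transfer(heart, **kw)
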