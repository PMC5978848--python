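"""Volumetric wavefront dipoles (the "measured" BSPM generator) and the EDL
forward map.

Stage 2 of the synthetic data path evaluates the distributed current-dipole
density J = -Sigma_i * grad(phi_h) on the wall sampling, where Sigma_i is
the intracellular conductivity tensor (longitudinal along the local fiber)
and phi_h the transmembrane potential template composed with the activation
times; electrode potentials follow from the BEM lead field, and calibrated
Gaussian noise is added.  The same module provides the fast EDL forward map
used inside the inverse procedure: electrode potentials as the transfer
matrix applied to the (smoothed) step of the activation times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.spatial import cKDTree

from .bem import BEMSolver, DipoleSet, TransferMatrix
from .geometry import ConductivitySetup, FiberField, MyocardialSampling, Ventricle
from .propagation import StimulusSet, VolumeActivation, anisotropic_activation


@dataclass(frozen=True)
class TMPTemplate:
    """Transmembrane potential upstroke template.

    ``value(t, tau)`` rises from ``rest`` to ``rest + amplitude`` (mV) around
    the activation time tau; ``width`` (ms) is the 12%-88% rise interval of
    the logistic upstroke.  ``width = 0`` gives the Heaviside step used in
    the sharp (sampling-faithful) variant.
    """

    rest: float = -80.0
    amplitude: float = 100.0
    width: float = 2.0

    def upstroke(self, x: np.ndarray) -> np.ndarray:
        """Normalized step in [0, 1] as a function of t - tau."""
        x = np.asarray(x, float)
        if self.width == 0.0:
            return np.where(x > 0, 1.0, np.where(x < 0, 0.0, 0.5))
        z = np.clip(4.0 * x / self.width, -60.0, 60.0)
        return 1.0 / (1.0 + np.exp(-z))

    def upstroke_deriv(self, x: np.ndarray) -> np.ndarray:
        if self.width == 0.0:
            raise ValueError("the Heaviside template has no usable derivative")
        s = self.upstroke(x)
        return (4.0 / self.width) * s * (1.0 - s)

    def value(self, t: np.ndarray, tau: np.ndarray) -> np.ndarray:
        return self.rest + self.amplitude * self.upstroke(np.asarray(t) - tau)


DEFAULT_TEMPLATE = TMPTemplate()
SHARP_TEMPLATE = TMPTemplate(width=0.0)

#: default transversal conduction velocity of the truth propagation, mm/ms
DEFAULT_VT = 0.6


@dataclass
class BSPM:
    """Body-surface potential map: electrodes x time samples, in mV."""

    potentials: np.ndarray
    times: np.ndarray
    dt: float = 1.0
    zero_mean: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, float)
        self.times = np.asarray(self.times, float)
        if self.potentials.shape[1] != len(self.times):
            raise ValueError("time axis mismatch")

    def rereference(self) -> "BSPM":
        p = self.potentials - self.potentials.mean(axis=0, keepdims=True)
        return replace(self, potentials=p, zero_mean=True)


# --------------------------------------------------------------------------
# moving-least-squares gradients on the wall sampling
# --------------------------------------------------------------------------

def gradient_operator(sampling: MyocardialSampling,
                      n_neighbors: int = 12) -> tuple[csr_matrix, ...]:
    """Sparse (Gx, Gy, Gz) estimating field gradients at each wall sample by
    local least squares over its nearest neighbors.  Cached on the sampling."""
    cached = getattr(sampling, "_grad_op", None)
    if cached is not None and cached[0] == n_neighbors:
        return cached[1]
    pts = sampling.points
    n = len(pts)
    k = min(n_neighbors + 1, n)
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k)
    # complete tied neighbor shells: truncating inside an equidistant shell
    # (ubiquitous on grid samplings) biases the gradients directionally
    nb_lists = tree.query_ball_point(pts, dist[:, -1] * (1 + 1e-9))
    rows, cols, vals = [], [], [[], [], []]
    for i in range(n):
        nb = np.asarray([j for j in nb_lists[i] if j != i])
        x = pts[nb] - pts[i]
        if np.linalg.matrix_rank(x, tol=1e-8) < 3:
            raise ValueError(f"sample {i}: fewer than 4 non-coplanar "
                             "neighbors for gradient estimation")
        p = np.linalg.pinv(x)  # (3, len(nb))
        rows.append(np.full(len(nb) + 1, i))
        cols.append(np.concatenate([nb, [i]]))
        for d in range(3):
            vals[d].append(np.concatenate([p[d], [-p[d].sum()]]))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    ops = tuple(coo_matrix((np.concatenate(vals[d]), (rows, cols)),
                           shape=(n, n)).tocsr() for d in range(3))
    sampling._grad_op = (n_neighbors, ops)
    return ops


def wavefront_dipoles(activation: VolumeActivation,
                      sampling: MyocardialSampling, fibers: FiberField,
                      setup: ConductivitySetup,
                      template: TMPTemplate = DEFAULT_TEMPLATE,
                      t: float | np.ndarray = 0.0) -> DipoleSet:
    """Distributed current dipoles -Sigma_i grad(phi_h) dV at time t.

    For an array of times, moments have shape (n, 3, len(t)) and a DipoleSet
    is not constructed; use :func:`dipole_moments` directly in that case.
    """
    m = dipole_moments(activation, sampling, fibers, setup, template,
                       np.atleast_1d(np.asarray(t, float)))
    if m.shape[-1] != 1:
        raise ValueError("wavefront_dipoles takes a scalar time")
    return DipoleSet(sampling.points, m[..., 0])


def dipole_moments(activation: VolumeActivation,
                   sampling: MyocardialSampling, fibers: FiberField,
                   setup: ConductivitySetup, template: TMPTemplate,
                   times: np.ndarray) -> np.ndarray:
    """(n_samples, 3, n_times) dipole moments of the propagating wavefront."""
    if template.width == 0.0:
        raise ValueError("volumetric sources need a differentiable template")
    gx, gy, gz = gradient_operator(sampling)
    tau = activation.tau_vol
    phi = template.value(times[None, :], tau[:, None])   # (n, T)
    grad = np.stack([gx @ phi, gy @ phi, gz @ phi], axis=1)  # (n, 3, T)
    f = fibers.directions
    along = np.einsum('nk,nkt->nt', f, grad)
    sig_t, sig_l = setup.sigma_i_t, setup.sigma_i_l
    m = sig_t * grad + (sig_l - sig_t) * f[:, :, None] * along[:, None, :]
    return -m * sampling.dv[:, None, None]


# --------------------------------------------------------------------------
# forward simulation
# --------------------------------------------------------------------------

def simulation_times(activation: VolumeActivation, template: TMPTemplate,
                     dt: float = 1.0) -> np.ndarray:
    pad = 3.0 * max(template.width, 1.0)
    t1 = float(np.ceil(activation.tau_vol.max() + pad))
    return np.arange(0.0, t1 + dt / 2, dt)


def simulate_measured_bspm(solver: BEMSolver, ventricle: Ventricle,
                           stimuli: StimulusSet | VolumeActivation,
                           setup: ConductivitySetup, *,
                           template: TMPTemplate = DEFAULT_TEMPLATE,
                           v_t: float = DEFAULT_VT,
                           noise_sd: float = 0.02, seed: int = 0,
                           dt: float = 1.0,
                           leadfield: np.ndarray | None = None) -> BSPM:
    """Forward-simulate the "measured" BSPM of a scenario.

    Propagates activation anisotropically (velocity ratio from the setup's
    intracellular tensor), evaluates the volumetric wavefront dipoles at
    every sample, maps them to the electrodes through the BEM lead field and
    adds calibrated Gaussian noise.  The ground-truth activation is attached
    to ``meta['activation']``.
    """
    smp, fib = ventricle.sampling, ventricle.fibers
    if isinstance(stimuli, VolumeActivation):
        activation = stimuli
    else:
        activation = anisotropic_activation(smp, fib, v_t,
                                            setup.velocity_ratio, stimuli)
    times = simulation_times(activation, template, dt)
    moments = dipole_moments(activation, smp, fib, setup, template, times)
    if leadfield is None:
        leadfield = solver.dipole_leadfield(smp.points)
    pot = np.einsum('epk,pkt->et', leadfield, moments, optimize=True)
    pot -= pot.mean(axis=0, keepdims=True)
    bspm = BSPM(pot, times, dt=dt,
                meta=dict(case=setup.case, scenario=activation.meta.get(
                    "scenario", ""), seed=seed, noise_sd=noise_sd,
                    activation=activation))
    if noise_sd > 0:
        bspm = add_noise(bspm, sd=noise_sd, seed=seed)
    return bspm


def edl_forward(transfer: TransferMatrix, tau: np.ndarray,
                template: TMPTemplate = DEFAULT_TEMPLATE,
                times: np.ndarray | None = None,
                dt: float = 1.0) -> BSPM:
    """EDL forward map: BSPM(e, t) = sum_j A[e, j] * step(t - tau_j).

    Columns of the transfer matrix are zero-mean, so the result is
    zero-mean referenced by construction.
    """
    tau = np.asarray(tau, float)
    if tau.shape[0] != transfer.n_nodes:
        raise ValueError("activation map does not match the transfer matrix")
    if times is None:
        pad = 3.0 * max(template.width, 1.0)
        times = np.arange(0.0, np.ceil(tau.max() + pad) + dt / 2, dt)
    h = template.upstroke(times[None, :] - tau[:, None])   # (n, T)
    return BSPM(transfer.matrix @ h, times, dt=dt,
                meta=dict(kind="edl_forward"))


def add_noise(bspm: BSPM, sd: float = 0.02, seed: int = 0) -> BSPM:
    """Additive Gaussian electrode noise (sd in mV; 0.02 mV = 20 uV),
    re-referenced to zero mean afterwards.  Seed-reproducible."""
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return bspm
    rng = np.random.default_rng(seed)
    noisy = bspm.potentials + rng.normal(0.0, sd, bspm.potentials.shape)
    out = replace(bspm, potentials=noisy,
                  meta=dict(bspm.meta, noise_sd=sd, noise_seed=seed))
    return out.rereference()
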