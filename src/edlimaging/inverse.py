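"""EDL inverse procedure: fastest-route initial estimate + regularized
Levenberg-Marquardt refinement of activation times.

The fastest route algorithm (FRA) treats every ventricular surface node as a
candidate ectopic focus, computes its activation map by shortest paths with
distinct surface and transmural velocities, ranks the candidates by the
Pearson correlation between their EDL-predicted and the measured BSPM, and
selects, within the top 2% by correlation, the candidate with the smallest
relative difference.  Sinus rhythm is handled by a greedy multi-focus
extension ("first come, first served").  The selected map initializes a
Levenberg-Marquardt minimization of

    || Phi_EDL(tau) - Phi_meas ||_F^2 + lambda * || L tau ||^2

with the surface Laplacian L as second-order Tikhonov penalty and an
analytic Jacobian from the smoothed upstroke template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .bem import TransferMatrix
from .geometry import GeodesicGraph
from .sources import BSPM, TMPTemplate

#: default fastest-route propagation velocities (mm/ms)
V_SURFACE = 0.8
V_TRANSMURAL = 0.4

#: FRA selection: fraction of candidates kept by correlation
TOP_FRACTION = 0.02

#: multifocal greedy-search constants
MULTIFOCAL_GAIN_TOL = 0.005
MULTIFOCAL_MAX_FOCI = 6
#: candidate onsets relative to the first focus; negative values let the
#: greedy place a focus earlier than its first pick
MULTIFOCAL_ONSETS = np.arange(-15.0, 26.0, 5.0)


@dataclass
class InitialEstimate:
    """FRA candidate ranking and the selected initial activation map."""

    node: int
    tau: np.ndarray
    cor: float
    rd: float
    rank: int
    table: pd.DataFrame
    foci: list[tuple[int, float]] = field(default_factory=list)
    tau_maps: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.foci:
            self.foci = [(self.node, 0.0)]


@dataclass
class InverseResult:
    """Output of the nonlinear activation-time optimization."""

    tau: np.ndarray
    lam: float
    iterations: int
    residual_norm: float
    penalty: float
    converged: bool
    initial: InitialEstimate | None = None
    objective_history: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.residual_norm) and np.isfinite(self.penalty)):
            raise ValueError("non-finite residual or penalty")


# --------------------------------------------------------------------------
# fastest route algorithm
# --------------------------------------------------------------------------

def fra_candidates(graph: GeodesicGraph, v_surface: float = V_SURFACE,
                   v_transmural: float = V_TRANSMURAL) -> np.ndarray:
    """All-pairs activation maps: row f is the activation map (ms) obtained
    when node f is the focus.  Exact single-source shortest paths."""
    w = graph.travel_times(v_surface, v_transmural)
    return dijkstra(w, directed=False)


def _score_maps(transfer: TransferMatrix, template: TMPTemplate,
                measured: BSPM, maps: np.ndarray,
                chunk: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Flattened-matrix Pearson correlation and relative difference of the
    EDL BSPMs of many activation maps against the measured BSPM.

    For the sharp (Heaviside) template the predicted BSPM of a map is a
    cumulative sum of transfer columns in activation order, which avoids
    materializing the (candidates x nodes x times) step tensor.
    """
    y = measured.potentials.astype(np.float64)
    times = measured.times
    e, t = y.shape
    m = e * t
    ysum, ynorm2 = float(y.sum()), float((y * y).sum())
    yvar = ynorm2 - ysum ** 2 / m
    if yvar <= 0:
        raise ValueError("measured BSPM has zero variance")
    maps = np.atleast_2d(maps)
    cor = np.empty(len(maps))
    rd = np.empty(len(maps))
    a32 = transfer.matrix.astype(np.float32)
    sharp = template.width == 0.0
    for s in range(0, len(maps), chunk):
        tm = maps[s:s + chunk]
        c = len(tm)
        if sharp:
            order = np.argsort(tm, axis=1)
            tau_sorted = np.take_along_axis(tm, order, axis=1)
            # cumulative electrode pattern after each activation event
            cum = np.cumsum(a32[:, order], axis=-1)          # (e, c, n)
            k = np.empty((c, t), np.int64)
            for i in range(c):  # count of nodes with tau < t
                k[i] = np.searchsorted(tau_sorted[i], times, side="left")
            p = np.where(k[None, :, :] > 0,
                         np.take_along_axis(
                             cum, np.maximum(k - 1, 0)[None, :, :], axis=-1),
                         np.float32(0.0))
        else:
            h = template.upstroke(times[None, None, :]
                                  - tm[:, :, None]).astype(np.float32)
            p = (a32 @ h.transpose(1, 0, 2).reshape(tm.shape[1], c * t)
                 ).reshape(e, c, t)
        p = p.transpose(1, 0, 2).reshape(c, m).astype(np.float64)
        psum = p.sum(axis=1)
        pnorm2 = np.einsum('ij,ij->i', p, p)
        pdoty = p @ y.reshape(m)
        pvar = np.maximum(pnorm2 - psum ** 2 / m, 1e-30)
        cor[s:s + chunk] = (pdoty - psum * ysum / m) / np.sqrt(pvar * yvar)
        rd[s:s + chunk] = np.sqrt(np.maximum(ynorm2 - 2 * pdoty + pnorm2, 0)
                                  ) / np.sqrt(ynorm2)
    return cor, rd


def rank_candidates(tau_maps: np.ndarray, transfer: TransferMatrix,
                    template: TMPTemplate, measured: BSPM,
                    top_fraction: float = TOP_FRACTION) -> InitialEstimate:
    """Rank every candidate focus and select the initial estimate.

    The candidates within the top ``top_fraction`` by correlation are
    short-listed and the one with the smallest relative difference wins;
    remaining ties break toward the lower node index.
    """
    cor, rd = _score_maps(transfer, template, measured, tau_maps)
    n = len(tau_maps)
    order = np.lexsort((np.arange(n), rd, -cor))  # cor desc, rd asc, index asc
    k = max(1, int(np.ceil(top_fraction * n))) if n >= 50 else 1
    short = order[:k]
    best = short[np.lexsort((short, rd[short]))][0]
    table = pd.DataFrame({"node": order, "cor": cor[order], "rd": rd[order]})
    rank = int(np.where(order == best)[0][0])
    return InitialEstimate(int(best), tau_maps[best].copy(), float(cor[best]),
                           float(rd[best]), rank, table, tau_maps=tau_maps)


def second_best(estimate: InitialEstimate, positions: np.ndarray,
                min_separation: float = 30.0) -> InitialEstimate | None:
    """Best-ranked alternative focus at least ``min_separation`` mm away
    from the primary one; ``None`` when no candidate qualifies."""
    if estimate.tau_maps is None:
        raise ValueError("candidate table lacks the activation maps")
    p0 = positions[estimate.node]
    tab = estimate.table
    for rank, row in enumerate(tab.itertuples(index=False)):
        node = int(row.node)
        if np.linalg.norm(positions[node] - p0) >= min_separation:
            return InitialEstimate(node, estimate.tau_maps[node].copy(),
                                   float(row.cor), float(row.rd), rank,
                                   tab, tau_maps=estimate.tau_maps)
    return None


def multifocal_sinus_estimate(tau_maps: np.ndarray, transfer: TransferMatrix,
                              template: TMPTemplate, measured: BSPM, *,
                              max_foci: int = MULTIFOCAL_MAX_FOCI,
                              gain_tol: float = MULTIFOCAL_GAIN_TOL,
                              top_k: int | None = None,
                              onsets: np.ndarray = MULTIFOCAL_ONSETS
                              ) -> InitialEstimate:
    """Greedy multi-focus estimate: first come, first served.

    Starting from the best single focus, repeatedly add the (focus, onset)
    pair whose combined map tau(j) = min_f (onset_f + tau_f(j)) maximally
    increases the correlation; stop when the gain drops below ``gain_tol``
    or ``max_foci`` is reached, then prune foci whose removal costs less
    than ``gain_tol`` (the greedy first pick can end up redundant once
    better foci join the ensemble).  By default every surface node is an
    addition candidate; ``top_k`` restricts the pool to the best single-
    focus nodes as a cheaper approximation.
    """
    base = rank_candidates(tau_maps, transfer, template, measured)
    cand = base.table["node"].to_numpy()
    if top_k is not None:
        cand = cand[:top_k]
    foci = [(base.node, 0.0)]
    cor = base.cor

    def combined(fs):
        return np.min([o + tau_maps[f] for f, o in fs], axis=0)

    def prune():
        """Drop foci whose removal costs less than gain_tol; an early pick
        can end up redundant (or harmful) once better foci join."""
        nonlocal cor
        while len(foci) > 1:
            trials = np.array([combined([g for g in foci if g is not f])
                               for f in foci])
            cors, _ = _score_maps(transfer, template, measured, trials)
            j = int(np.argmax(cors))
            if cors[j] < cor - gain_tol:
                break
            cor = max(cor, float(cors[j]))
            foci.pop(j)

    shifts = [float(s) for s in onsets if s > 0]
    while len(foci) < max_foci:
        tau = combined(foci)
        best = (cor + gain_tol, None)
        # plain additions at every candidate onset ...
        for o in onsets:
            trial = np.minimum(tau[None, :], float(o) + tau_maps[cand])
            cors, _ = _score_maps(transfer, template, measured, trial)
            j = int(np.argmax(cors))
            if cors[j] >= best[0]:
                best = (float(cors[j]), ("add", int(cand[j]), float(o)))
        # ... and shift-and-add moves: delay the whole ensemble by s and
        # put the new focus first (the greedy base need not be the
        # earliest true focus)
        for s in shifts:
            trial = np.minimum(tau[None, :] + s, tau_maps[cand])
            cors, _ = _score_maps(transfer, template, measured, trial)
            j = int(np.argmax(cors))
            if cors[j] >= best[0]:
                best = (float(cors[j]), ("shift", int(cand[j]), s))
        if best[1] is None:
            break
        cor, (kind, f, o) = best
        if kind == "add":
            foci.append((f, o))
        else:
            foci = [(g, og + o) for g, og in foci] + [(f, 0.0)]
        prune()
    prune()

    tau = combined(foci)
    cor_f, rd = _score_maps(transfer, template, measured, tau[None, :])
    return InitialEstimate(base.node, tau, float(cor_f[0]), float(rd[0]),
                           base.rank, base.table, foci=foci,
                           tau_maps=tau_maps)


# --------------------------------------------------------------------------
# Levenberg-Marquardt refinement
# --------------------------------------------------------------------------

def _lm_stage(a: np.ndarray, ata: np.ndarray, y: np.ndarray,
              times: np.ndarray, tau0: np.ndarray, lam: float,
              ltl, width: float, max_iter: int, tol: float
              ) -> tuple[np.ndarray, list[float], bool, int]:
    """One Levenberg-Marquardt run at fixed template width.

    Exploits the separable Jacobian J[(e,t), j] = -A[e, j] h'(t - tau_j):
    J^T J = (A^T A) o (H' H'^T) and J^T r = -sum_t H' o (A^T R)."""
    tmpl = TMPTemplate(width=width)
    tau = tau0.copy()
    n = len(tau)
    lo, hi = times.min() - 3 * width, times.max() + 3 * width

    def objective(tv):
        p = a @ tmpl.upstroke(times[None, :] - tv[:, None]) - y
        reg = ltl @ tv
        return float((p * p).sum() + lam * float(tv @ reg)), p

    f, p = objective(tau)
    history = [f]
    mu = 1e-3
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        hp = tmpl.upstroke_deriv(times[None, :] - tau[:, None])  # (n, T)
        jtj = ata * (hp @ hp.T)
        grad = -np.einsum('nt,nt->n', hp, a.T @ p) + lam * (ltl @ tau)
        hess = jtj + lam * ltl
        d = np.diag(hess).copy()
        d[d <= 0] = max(d.max(), 1e-12) * 1e-9
        accepted = False
        for _ in range(12):
            try:
                step = np.linalg.solve(hess + mu * np.diag(d), -grad)
            except np.linalg.LinAlgError:
                mu *= 4.0
                continue
            trial = np.clip(tau + step, lo, hi)
            f_new, p_new = objective(trial)
            if f_new <= f:
                accepted = True
                break
            mu *= 4.0
        if not accepted:
            break
        rel = (f - f_new) / max(f, 1e-300)
        tau, f, p = trial, f_new, p_new
        history.append(f)
        mu = max(mu / 3.0, 1e-12)
        if rel < tol:
            converged = True
            break
    return tau, history, converged, it


def optimize_activation(initial: InitialEstimate | np.ndarray,
                        transfer: TransferMatrix, template: TMPTemplate,
                        measured: BSPM, lam: float,
                        laplacian: csr_matrix, *,
                        widths: tuple[float, ...] = (2.0, 1.0),
                        max_iter: int = 200, tol: float = 1e-6,
                        warmup: bool = True) -> InverseResult:
    """Refine an initial activation map by regularized Levenberg-Marquardt.

    ``widths`` anneals the upstroke width of the Jacobian template (sharp
    steps have vanishing gradients); the iteration cap and the relative
    objective tolerance apply to the total across stages.  With ``warmup``
    the target penalty weight is approached through two lighter stages
    (lambda/100, lambda/10), which keeps the smoothness penalty from locking
    the solution into the initial estimate's basin.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    est = initial if isinstance(initial, InitialEstimate) else None
    tau = (initial.tau if est is not None else np.asarray(initial, float)
           ).astype(float)
    if not np.all(np.isfinite(tau)):
        raise ValueError("initial activation map must be finite")
    a = transfer.matrix
    ata = a.T @ a
    ltl = (laplacian.T @ laplacian).tocsr()
    ltl_dense = ltl.toarray()
    y = measured.potentials
    times = measured.times

    schedule: list[tuple[float, float, int]] = []
    if warmup and lam > 0:
        schedule += [(lam / 100.0, widths[0], max_iter // 5),
                     (lam / 10.0, widths[0], max_iter // 5)]
    for w in widths:
        schedule.append((lam, w, max_iter))  # budgets capped globally below

    history: list[float] = []
    converged = False
    total_it = 0
    for lam_i, w, budget in schedule:
        budget = min(budget, max_iter - total_it)
        if budget <= 0:
            break
        tau, h, converged, it = _lm_stage(a, ata, y, times, tau, lam_i,
                                          ltl_dense, w, budget, tol)
        history += h
        total_it += it
    p = a @ TMPTemplate(width=widths[-1]).upstroke(
        times[None, :] - tau[:, None]) - y
    pen = float(tau @ (ltl @ tau))
    return InverseResult(tau, lam, total_it, float(np.linalg.norm(p)), pen,
                         converged, est, np.asarray(history))


def regularization_path(initial, transfer, template, measured, laplacian,
                        lam_grid: np.ndarray | None = None, **kw
                        ) -> tuple[InverseResult, list[InverseResult]]:
    """L-curve selection of the regularization weight.

    Solves the problem over an ascending lambda grid with warm starts and
    returns the corner solution (maximum curvature of the log-log L-curve)
    plus the whole path.
    """
    if lam_grid is None:
        lam_grid = np.logspace(-6, -1, 6)
    lam_grid = np.sort(np.asarray(lam_grid, float))
    results = []
    start = initial
    for lam in lam_grid:
        res = optimize_activation(start, transfer, template, measured,
                                  float(lam), laplacian, **kw)
        if isinstance(initial, InitialEstimate):
            res.initial = initial
        results.append(res)
        start = res.tau.copy()  # warm start along the path
    rho = np.log10(np.maximum([r.residual_norm for r in results], 1e-300))
    eta = np.log10(np.maximum([np.sqrt(r.penalty) for r in results], 1e-300))
    if len(results) >= 3:
        curv = np.abs(np.gradient(np.gradient(eta, rho), rho))
        pick = int(np.argmax(curv[1:-1])) + 1
    else:
        pick = 0
    return results[pick], results
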