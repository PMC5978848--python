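"""Quality measures and study orchestration.

Implements the comparison measures used to score reconstructions (RMS,
Pearson correlation and relative difference between simulated and
reconstructed activation times and BSPMs, focus localization distance,
early-activation-site detection) and `run_study`, which reproduces the full
design: three myocardial conductivity cases (isotropic / equal / unequal
anisotropy ratio) crossed with nine activation scenarios (sinus rhythm and
eight paired ectopic foci), inverted with and without the second-best
initial-estimate rescue, reported as a Table-2-style CSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.stats import pearsonr

from .bem import BEMSolver, TransferMatrix
from .geometry import (
    ConductivitySetup,
    GeodesicGraph,
    TriangleSurface,
    Ventricle,
    build_torso,
    build_ventricle,
    geodesic_graph,
    surface_laplacian,
    transmural_pairs,
)
from .inverse import (
    InitialEstimate,
    InverseResult,
    V_SURFACE,
    V_TRANSMURAL,
    fra_candidates,
    multifocal_sinus_estimate,
    optimize_activation,
    rank_candidates,
    regularization_path,
    second_best,
)
from .propagation import VolumeActivation, ectopic_catalogue, sinus_stimuli
from .sources import (
    BSPM,
    DEFAULT_VT,
    TMPTemplate,
    edl_forward,
    simulate_measured_bspm,
)


# --------------------------------------------------------------------------
# scalar quality measures
# --------------------------------------------------------------------------

def rd(sim: np.ndarray, rec: np.ndarray) -> float:
    """Relative difference: ||sim - rec||_F / ||sim||_F."""
    sim = np.asarray(sim, float)
    rec = np.asarray(rec, float)
    if sim.shape != rec.shape:
        raise ValueError("shape mismatch")
    nrm = np.linalg.norm(sim)
    if nrm == 0:
        raise ValueError("reference signal has zero norm")
    return float(np.linalg.norm(sim - rec) / nrm)


def cor(sim: np.ndarray, rec: np.ndarray) -> float:
    """Pearson correlation of the flattened values."""
    sim = np.asarray(sim, float).ravel()
    rec = np.asarray(rec, float).ravel()
    if sim.std() == 0 or rec.std() == 0:
        raise ValueError("zero-variance input")
    return float(pearsonr(sim, rec).statistic)


def rms(sim_tau: np.ndarray, rec_tau: np.ndarray) -> float:
    """Root-mean-square activation-time difference (ms)."""
    sim_tau = np.asarray(sim_tau, float)
    rec_tau = np.asarray(rec_tau, float)
    return float(np.sqrt(np.mean((sim_tau - rec_tau) ** 2)))


def focus_distance(true_position: np.ndarray, tau_hat: np.ndarray,
                   surface: TriangleSurface,
                   true_onset: float = 0.0) -> tuple[float, float, int, bool]:
    """Localization error of the recovered focus.

    Returns (Euclidean distance mm, first-activation difference ms,
    recovered node, tie flag).  The recovered focus is the node of minimal
    reconstructed activation; exact ties resolve to the lowest index.
    """
    tau_hat = np.asarray(tau_hat, float)
    if not np.all(np.isfinite(tau_hat)):
        raise ValueError("activation map must be finite")
    node = int(np.argmin(tau_hat))
    tie = bool(np.sum(tau_hat == tau_hat[node]) > 1)
    dist = float(np.linalg.norm(surface.vertices[node]
                                - np.asarray(true_position, float)))
    return dist, float(tau_hat[node] - true_onset), node, tie


@dataclass
class EarlySites:
    nodes: np.ndarray
    taus: np.ndarray
    degenerate: bool = False

    def __len__(self) -> int:
        return len(self.nodes)


def early_sites(tau: np.ndarray, graph: GeodesicGraph,
                suppression_radius: float = 10.0,
                window: float = 5.0) -> EarlySites:
    """Detect early-activation sites.

    A site is a local minimum of the activation map whose basin is at least
    ``window`` ms deep before it merges into a deeper basin (topographic
    persistence, computed by flooding the surface graph in order of
    increasing activation); sites are then greedily thinned so no two lie
    within the geodesic suppression radius.  A map that is flat over most of
    the surface is flagged degenerate and simply thinned by distance.
    """
    tau = np.asarray(tau, float)
    if not np.all(np.isfinite(tau)):
        raise ValueError("activation map must be finite")
    adj = graph.lengths
    indptr, indices = adj.indptr, adj.indices
    order = np.argsort(tau, kind="stable")
    degenerate = bool(np.ptp(tau) < 1e-12)

    if degenerate:
        candidates = order
    else:
        # union-find flooding: track each basin's minimum
        parent = np.arange(graph.n)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        active = np.zeros(graph.n, bool)
        basin_min = np.arange(graph.n)
        sites = []
        for i in order:
            active[i] = True
            for j in indices[indptr[i]:indptr[i + 1]]:
                if not active[j]:
                    continue
                ri, rj = find(i), find(j)
                if ri == rj:
                    continue
                # the shallower basin dies at height tau[i]
                mi, mj = basin_min[ri], basin_min[rj]
                deep, shallow = (ri, rj) if tau[mi] <= tau[mj] else (rj, ri)
                dead_min = basin_min[shallow]
                if tau[i] - tau[dead_min] >= window:
                    sites.append(int(dead_min))
                parent[shallow] = deep
                basin_min[deep] = mi if tau[mi] <= tau[mj] else mj
        sites.append(int(basin_min[find(order[0])]))  # global minimum
        candidates = np.asarray(sorted(set(sites), key=lambda k: tau[k]))

    dist_from = dijkstra(adj, directed=False, indices=candidates,
                         limit=suppression_radius * 1.001)
    accepted: list[int] = []
    acc_rows: list[int] = []
    for k, i in enumerate(candidates):
        if any(dist_from[r, i] <= suppression_radius or
               dist_from[k, j] <= suppression_radius
               for r, j in zip(acc_rows, accepted)):
            continue
        accepted.append(int(i))
        acc_rows.append(k)
    accepted = np.asarray(sorted(accepted, key=lambda j: (tau[j], j)))
    return EarlySites(accepted, tau[accepted], degenerate)


# --------------------------------------------------------------------------
# per-scenario evaluation
# --------------------------------------------------------------------------

#: Table-style report columns, in the conventional order
RECORD_COLUMNS = ["scenario", "case", "lambda", "rms_at", "cor_at", "rd_at",
                  "cor_bspm", "rd_bspm", "dist_mm", "diff_first_ms",
                  "n_early_sites", "dist_geodesic_mm", "true_class",
                  "recovered_class", "class_match", "second_best_used",
                  "iterations", "converged"]


@dataclass
class EvaluationRecord:
    scenario: str
    case: str
    lam: float
    rms_at: float
    cor_at: float
    rd_at: float
    cor_bspm: float
    rd_bspm: float
    dist_mm: float
    diff_first_ms: float
    early: EarlySites | None = None
    dist_geodesic_mm: float = np.nan
    true_class: str = ""
    recovered_class: str = ""
    second_best_used: bool = False
    iterations: int = 0
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.cor_at <= 1.0 + 1e-9):
            raise ValueError("COR out of range")
        for v, name in ((self.rd_at, "RD"), (self.rms_at, "RMS")):
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_row(self) -> dict:
        return {
            "scenario": self.scenario, "case": self.case, "lambda": self.lam,
            "rms_at": self.rms_at, "cor_at": self.cor_at, "rd_at": self.rd_at,
            "cor_bspm": self.cor_bspm, "rd_bspm": self.rd_bspm,
            "dist_mm": self.dist_mm, "diff_first_ms": self.diff_first_ms,
            "n_early_sites": (len(self.early) if self.early is not None
                              else 0),
            "dist_geodesic_mm": self.dist_geodesic_mm,
            "true_class": self.true_class,
            "recovered_class": self.recovered_class,
            "class_match": (self.true_class == self.recovered_class
                            if self.true_class else np.nan),
            "second_best_used": self.second_best_used,
            "iterations": self.iterations, "converged": self.converged,
        }


def evaluate_scenario(truth: VolumeActivation, result: InverseResult,
                      measured: BSPM, transfer: TransferMatrix,
                      ventricle: Ventricle, graph: GeodesicGraph, *,
                      scenario: str = "", case: str = "",
                      true_position: np.ndarray | None = None,
                      true_onset: float = 0.0, true_class: str = "",
                      eval_width: float = 1.0,
                      second_best_used: bool = False) -> EvaluationRecord:
    """Score one reconstruction against the gold standard."""
    tau_true, tau_hat = truth.tau_surf, result.tau
    pred = edl_forward(transfer, tau_hat, TMPTemplate(width=eval_width),
                       times=measured.times)
    rec = EvaluationRecord(
        scenario=scenario, case=case, lam=result.lam,
        rms_at=rms(tau_true, tau_hat),
        cor_at=cor(tau_true, tau_hat),
        rd_at=rd(tau_true, tau_hat),
        cor_bspm=cor(measured.potentials, pred.potentials),
        rd_bspm=rd(measured.potentials, pred.potentials),
        dist_mm=np.nan, diff_first_ms=np.nan,
        early=early_sites(tau_hat, graph),
        second_best_used=second_best_used,
        iterations=result.iterations, converged=result.converged)
    if true_position is not None:
        dist, diff, node, _ = focus_distance(true_position, tau_hat,
                                             ventricle.surface, true_onset)
        rec.dist_mm, rec.diff_first_ms = dist, diff
        cls = ventricle.sampling.node_class
        rec.true_class = true_class
        rec.recovered_class = str(cls[node])
        true_node = int(np.argmin(np.linalg.norm(
            ventricle.surface.vertices - true_position, axis=1)))
        geo = dijkstra(graph.lengths, directed=False, indices=node)
        rec.dist_geodesic_mm = float(geo[true_node])
    return rec


# --------------------------------------------------------------------------
# study orchestration
# --------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Complete description of a study run; fully seed-reproducible."""

    # geometry
    kind: str = "biventricular"
    resolution: float = 5.5
    sample_spacing: float = 2.5
    wall_thickness: float = 10.0
    long_axis: float = 55.0
    short_axis: float = 33.0
    # design
    cases: tuple[str, ...] = ("isotropic", "equal", "unequal")
    scenarios: str | tuple[str, ...] = "all"   # 'all' = sinus + 8 ectopic
    v_t: float = DEFAULT_VT
    noise_sd: float = 0.02
    seed: int = 0
    # generator: 'volumetric' (Eq.-1 dipoles) or 'edl' (inverse-crime control)
    generator: str = "volumetric"
    # inverse
    lam: float | str = 1e-3
    rank_width: float = 0.0   # FRA ranking uses the sharp Heaviside step
    lam_grid: tuple[float, ...] = tuple(np.logspace(-6, -1, 6))
    v_surface: float = V_SURFACE
    v_transmural: float = V_TRANSMURAL
    use_second_best: bool = True
    min_separation: float = 30.0
    rescue_cor_margin: float = 0.03
    widths: tuple[float, ...] = (2.0, 1.0)
    max_iter: int = 60
    tol: float = 1e-6
    template_width: float = 2.0
    v_amp: float = 100.0

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("cases", "lam_grid", "widths"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        if isinstance(cfg.scenarios, list):
            cfg.scenarios = tuple(cfg.scenarios)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class StudyContext:
    """Geometry, BEM operators and FRA maps shared across study cells."""

    config: StudyConfig
    ventricle: Ventricle
    vcm: object
    solver: BEMSolver
    transfer: TransferMatrix
    graph: GeodesicGraph
    laplacian: object
    tau_maps: np.ndarray
    leadfield: np.ndarray | None
    template: TMPTemplate


def build_study_context(config: StudyConfig) -> StudyContext:
    vent0 = build_ventricle(kind=config.kind, resolution=config.resolution,
                            sample_spacing=config.sample_spacing,
                            wall_thickness=config.wall_thickness,
                            long_axis=config.long_axis,
                            short_axis=config.short_axis)
    vcm = build_torso(vent0)
    vent = vcm.ventricle
    solver = BEMSolver(vcm)
    setup0 = ConductivitySetup.preset("isotropic")
    transfer = solver.edl_transfer(jump_factor=setup0.jump_factor,
                                   v_amp=config.v_amp)
    graph = geodesic_graph(vent.surface,
                           transmural_pairs(vent.surface, vent.sampling))
    lap = surface_laplacian(vent.surface)
    tau_maps = fra_candidates(graph, config.v_surface, config.v_transmural)
    lead = None
    if config.generator == "volumetric":
        lead = solver.dipole_leadfield(vent.sampling.points)
    template = TMPTemplate(width=config.template_width, amplitude=config.v_amp)
    return StudyContext(config, vent, vcm, solver, transfer, graph, lap,
                        tau_maps, lead, template)


def _study_scenarios(ctx: StudyContext) -> list[dict]:
    vent = ctx.ventricle
    wanted = ctx.config.scenarios
    entries = []
    if wanted == "all" or "sinus" in wanted:
        entries.append(dict(label="sinus",
                            stimuli=sinus_stimuli(vent.sampling,
                                                  vent.surface.vertices),
                            node=None, true_class="", position=None))
    if wanted == "all" or set(wanted) - {"sinus"}:
        entries += ectopic_catalogue(vent)
    if wanted != "all":
        entries = [e for e in entries if e["label"] in wanted]
        missing = set(wanted) - {e["label"] for e in entries}
        if missing:
            raise ValueError(f"unknown scenarios: {sorted(missing)}")
    return entries


def _fra_truth(ctx: StudyContext, entry: dict) -> VolumeActivation:
    """Inverse-crime ground truth: the FRA model's own activation map."""
    vent = ctx.ventricle
    if entry["label"] == "sinus":
        stim = entry["stimuli"]
        nodes = [int(np.argmin(np.linalg.norm(
            vent.surface.vertices - p, axis=1))) for p in stim.positions]
        tau = np.min([o + ctx.tau_maps[n]
                      for n, o in zip(nodes, stim.onsets)], axis=0)
    else:
        tau = ctx.tau_maps[entry["node"]].copy()
    vol = tau[ctx.ventricle.sampling.nearest_surface_node]
    va = VolumeActivation(vol, tau)
    va.meta["scenario"] = entry["label"]
    return va


def _invert_cell(ctx: StudyContext, measured: BSPM,
                 sinus: bool) -> tuple[InverseResult, bool, InitialEstimate]:
    cfg = ctx.config
    rank_template = TMPTemplate(width=cfg.rank_width)
    if sinus:
        est = multifocal_sinus_estimate(ctx.tau_maps, ctx.transfer,
                                        rank_template, measured)
    else:
        est = rank_candidates(ctx.tau_maps, ctx.transfer, rank_template,
                              measured)
    kw = dict(widths=cfg.widths, max_iter=cfg.max_iter, tol=cfg.tol)

    def solve(e0, lam):
        if lam == "auto":
            res, _ = regularization_path(e0, ctx.transfer, ctx.template,
                                         measured, ctx.laplacian,
                                         np.asarray(cfg.lam_grid), **kw)
            return res
        return optimize_activation(e0, ctx.transfer, ctx.template, measured,
                                   float(lam), ctx.laplacian, **kw)

    res = solve(est, cfg.lam)
    used_second = False
    if cfg.use_second_best and not sinus:
        alt = second_best(est, ctx.ventricle.surface.vertices,
                          cfg.min_separation)
        if alt is not None and est.cor - alt.cor < cfg.rescue_cor_margin:
            res_alt = solve(alt, res.lam)
            if res_alt.residual_norm < res.residual_norm:
                res, used_second = res_alt, True
    return res, used_second, est


def run_study(config: StudyConfig | dict,
              ctx: StudyContext | None = None
              ) -> tuple[pd.DataFrame, list[EvaluationRecord]]:
    """Run the full design and return (report table, evaluation records).

    Per scenario x conductivity case: forward-simulate the measured BSPM,
    invert it (multifocal estimate for sinus, single-focus otherwise, with
    optional second-best rescue) and evaluate.  Failures are recorded per
    cell and the run continues.
    """
    if isinstance(config, dict):
        config = StudyConfig.from_dict(config)
    if ctx is None:
        ctx = build_study_context(config)
    entries = _study_scenarios(ctx)
    rows, records = [], []
    for si, entry in enumerate(entries):
        for ci, case in enumerate(config.cases):
            cell_seed = (config.seed * 8191 + si * 37 + ci) % (2 ** 31 - 1)
            try:
                setup = ConductivitySetup.preset(case)
                if config.generator == "edl":
                    truth = _fra_truth(ctx, entry)
                    measured = edl_forward(ctx.transfer, truth.tau_surf,
                                           ctx.template)
                    if config.noise_sd > 0:
                        from .sources import add_noise
                        measured = add_noise(measured, config.noise_sd,
                                             cell_seed)
                else:
                    measured = simulate_measured_bspm(
                        ctx.solver, ctx.ventricle, entry["stimuli"], setup,
                        template=ctx.template, v_t=config.v_t,
                        noise_sd=config.noise_sd, seed=cell_seed,
                        leadfield=ctx.leadfield)
                    truth = measured.meta["activation"]
                res, used2, est = _invert_cell(ctx, measured,
                                               entry["label"] == "sinus")
                rec = evaluate_scenario(
                    truth, res, measured, ctx.transfer, ctx.ventricle,
                    ctx.graph, scenario=entry["label"], case=case,
                    true_position=entry["position"],
                    true_class=entry["true_class"],
                    eval_width=config.widths[-1],
                    second_best_used=used2)
                rec.extra["initial_cor"] = est.cor
                records.append(rec)
                rows.append(rec.as_row())
            except Exception as exc:  # noqa: BLE001 - keep the run alive
                rows.append({"scenario": entry["label"], "case": case,
                             "error": f"{type(exc).__name__}: {exc}"})
    table = pd.DataFrame(rows)
    lead = [c for c in RECORD_COLUMNS if c in table.columns]
    rest = [c for c in table.columns if c not in lead]
    return table[lead + rest], records
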