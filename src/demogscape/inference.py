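"""SFS composite-likelihood inference: Monte-Carlo expected spectra, ECM-style
cyclic maximization, AIC model selection, and 1-D profile recovery.

The likelihood is the multinomial composite likelihood over polymorphic joint
SFS entries, log10 L = sum_ij O_ij log10 p_ij, where p is the simulated,
probability-normalized expected spectrum. "ECM" here means cyclic conditional
maximization: each free parameter in turn is optimized in one dimension
(golden section, log scale for sizes and rates) with the others held fixed,
re-using common random numbers within a cycle so the Monte-Carlo surface is
smooth in the parameter being moved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._core import branch_sfs, sim_path_stats
from .coalescent import (DemographicModel, branch_sfs_mc, locus_seeds,
                         simulate_dataset)
from .scenarios import ScenarioSpec, build_scenario
from .stats import JointSFS

__all__ = [
    "LikelihoodResult",
    "ModelSelectionTable",
    "ProfileResult",
    "expected_sfs_mc",
    "composite_loglik",
    "aic",
    "maximize_likelihood",
    "model_select",
    "profile_recover",
    "profile_suite",
    "reweighted_sfs_grid",
    "reweight_supported",
]

_GOLDEN = (math.sqrt(5) - 1) / 2


@dataclass
class LikelihoodResult:
    log10_lik: float
    params: dict[str, float]
    n_free: int
    n_sims_per_eval: int
    seed: int


@dataclass
class ModelSelectionTable:
    """Per-scenario best fits ranked by AIC (rank 1 has delta-AIC 0)."""

    rows: list[dict] = field(default_factory=list)
    failed: list[int] = field(default_factory=list)

    def finalize(self) -> None:
        self.rows.sort(key=lambda r: r["aic"])
        best = self.rows[0]["aic"] if self.rows else float("nan")
        for rank, r in enumerate(self.rows, start=1):
            r["delta_aic"] = r["aic"] - best
            r["rank"] = rank

    @property
    def best_scenario_id(self) -> int:
        return self.rows[0]["scenario_id"]


@dataclass
class ProfileResult:
    param: str
    grid: np.ndarray
    log10_lik: np.ndarray
    estimate: float
    at_boundary: bool


def _subseeds(seed: int, n: int) -> np.ndarray:
    # keep derived seeds in [0, 2^31)
    return np.random.SeedSequence(int(seed)).generate_state(n) % (2 ** 31)


def expected_sfs_mc(model: DemographicModel, n_sims: int, seed: int,
                    folded: bool = True, floor: float | None = None
                    ) -> JointSFS:
    """Probability-normalized Monte-Carlo expected joint SFS.

    Mean over ``n_sims`` simulated genealogies (mutational expectation taken
    analytically from branch lengths), normalized over polymorphic cells.
    Zero cells are floored at ``1/(10 * n_sims * n_cells)`` (configurable)
    and the spectrum renormalized, so observed mass never lands on a
    zero-probability cell.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    sfs = branch_sfs_mc(model, n_sims, seed, folded=folded).normalized()
    m = sfs.polymorphic_mask()
    if floor is None:
        floor = 1.0 / (10.0 * n_sims * m.sum())
    c = sfs.counts
    c[m] = np.maximum(c[m], floor)
    c[m] /= c[m].sum()
    return sfs


def reweight_supported(ref: DemographicModel,
                       models: list[DemographicModel]) -> bool:
    """Whether path reweighting from ``ref`` covers every model: no model may
    merge earlier than the reference, and none may allow migration at times
    when the reference is already merged (support condition of the
    importance weights)."""
    t_ref = ref.divergence_time
    for m in models:
        if m.divergence_time < t_ref - 1e-9:
            return False
        for i, e in enumerate(m.epochs):
            end = (m.epochs[i + 1].start_time if i + 1 < len(m.epochs)
                   else m.divergence_time)
            end = min(end, m.divergence_time)
            if end > t_ref + 1e-9 and e.migration.any():
                return False
    return True


_NEG = -1e7  # log of an impossible event; a single one kills the weight


def _partition_cells(models: list[DemographicModel]) -> np.ndarray:
    """Lower bounds of a common time partition refining every model's
    epoch structure (epoch starts and divergence times)."""
    bounds = {0.0}
    for m in models:
        bounds.update(e.start_time for e in m.epochs)
        bounds.add(m.divergence_time)
    return np.array(sorted(bounds))


def _path_coefficients(model: DemographicModel, cells: np.ndarray
                       ) -> np.ndarray:
    """Per-cell coefficients such that a path's log density under ``model``
    is ``stats.ravel() @ coef.ravel()`` for the statistics of
    :func:`demogscape._core.sim_path_stats` on the same partition."""
    starts, two_n, migs, t_div, two_n_anc = model._arrays()
    coef = np.zeros((cells.size, 10))
    for c, lo in enumerate(cells):
        if lo >= t_div - 1e-9:          # merged: one deme of the ancestral size
            lam = 1.0 / two_n_anc
            coef[c, 0] = coef[c, 1] = coef[c, 2] = -lam
            coef[c, 5] = coef[c, 6] = coef[c, 7] = math.log(lam)
        else:
            e = int(np.searchsorted(starts, lo, side="right") - 1)
            lam0 = 1.0 / two_n[e, 0]
            lam1 = 1.0 / two_n[e, 1]
            m01 = migs[e, 0, 1]
            m10 = migs[e, 1, 0]
            coef[c, 0] = -lam0
            coef[c, 1] = -lam1
            coef[c, 3] = -m01
            coef[c, 4] = -m10
            coef[c, 5] = math.log(lam0)
            coef[c, 6] = math.log(lam1)
            coef[c, 7] = _NEG               # cross-deme merge impossible
            coef[c, 8] = math.log(m01) if m01 > 0 else _NEG
            coef[c, 9] = math.log(m10) if m10 > 0 else _NEG
    return coef


def reweighted_sfs_grid(ref_model: DemographicModel,
                        models: list[DemographicModel], n_sims: int,
                        seed: int, folded: bool = True):
    """Expected SFS for a family of models from one reference ensemble.

    Simulates ``n_sims`` genealogies under ``ref_model``, recording each
    path's sufficient statistics on a common time partition, then reweights
    every path by its exact likelihood ratio under every model in ``models``
    (self-normalized importance sampling). All grid points therefore share
    the same randomness and their likelihood differences are low-variance.
    Returns ``(spectra, ess)``: floored, probability-normalized spectra
    (``None`` where all weights vanish) and the effective sample size per
    model. Caller must ensure :func:`reweight_supported` holds.
    """
    n1, n2 = ref_model.sample_sizes
    starts, two_n, migs, t_div, two_n_anc = ref_model._arrays()
    cells = _partition_cells([ref_model] + list(models))
    n_cells = cells.size
    shape = (n1 + 1, n2 + 1)
    stats_all = np.empty((n_sims, n_cells * 10))
    sfs_all = np.empty((n_sims, shape[0] * shape[1]), dtype=np.float32)
    tmp = np.zeros(shape)
    seeds = locus_seeds(seed, n_sims)
    for i in range(n_sims):
        parent, node_time, stats = sim_path_stats(
            seeds[i, 0], n1, n2, starts, two_n, migs, t_div, two_n_anc,
            cells)
        stats_all[i] = stats.ravel()
        tmp[:] = 0.0
        branch_sfs(parent, node_time, n1, n2, tmp)
        sfs_all[i] = tmp.ravel()

    coef_ref = _path_coefficients(ref_model, cells).ravel()
    coefs = np.stack([_path_coefficients(m, cells).ravel() - coef_ref
                      for m in models])
    logw = stats_all @ coefs.T                       # (paths, models)
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    wsum = w.sum(axis=0)
    w2sum = (w ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ess = np.where(w2sum > 0, wsum ** 2 / w2sum, 0.0)
    means = (w.T @ sfs_all).astype(np.float64)

    spectra = []
    for g in range(len(models)):
        if wsum[g] <= 0 or not np.isfinite(wsum[g]):
            spectra.append(None)
            continue
        c = (means[g] / wsum[g]).reshape(shape)
        c[0, 0] = 0.0
        c[n1, n2] = 0.0
        sfs = JointSFS(np.maximum(c, 0.0), n1, n2, folded=False)
        if folded:
            sfs = sfs.fold()
        sfs = sfs.normalized()
        m = sfs.polymorphic_mask()
        floor = 1.0 / (10.0 * max(ess[g], 1.0) * m.sum())
        cc = sfs.counts
        cc[m] = np.maximum(cc[m], floor)
        cc[m] /= cc[m].sum()
        spectra.append(sfs)
    return spectra, ess


def composite_loglik(observed: JointSFS, expected: JointSFS) -> float:
    """Multinomial composite log10-likelihood over polymorphic entries."""
    if observed.counts.shape != expected.counts.shape:
        raise ValueError("SFS dimensions do not match")
    if observed.folded != expected.folded:
        raise ValueError("folding of observed and expected differ")
    m = observed.polymorphic_mask()
    O = observed.counts[m]
    p = expected.counts[m]
    use = O > 0
    if (p[use] <= 0).any():
        raise ValueError("observed mass on a zero-expected cell; "
                         "use a floored expected spectrum")
    return float((O[use] * np.log10(p[use])).sum())


def aic(result: LikelihoodResult | float, n_free: int | None = None) -> float:
    """AIC = 2k - 2 ln(10) * log10 L (natural-log conversion)."""
    if isinstance(result, LikelihoodResult):
        ll, k = result.log10_lik, result.n_free
    else:
        ll, k = float(result), int(n_free)
    return 2.0 * k - 2.0 * math.log(10.0) * ll


def _log_scale(name: str) -> bool:
    return name.startswith(("n_", "m_"))


def _default_start(spec: ScenarioSpec) -> dict[str, float]:
    start = {}
    for name, (lo, hi) in spec.free_parameters.items():
        start[name] = math.sqrt(lo * hi) if _log_scale(name) else (lo + hi) / 2
    # keep internal event times inside the divergence time
    t_div = start["t_div"]
    for k in list(start):
        if k.startswith("t_") and k != "t_div" and start[k] >= t_div:
            start[k] = 0.5 * t_div
    if "t_flow_off_start" in start:
        start["t_flow_off_start"] = 0.6 * t_div
        start["t_flow_off_end"] = 0.3 * t_div
    return start


def _objective_factory(spec, observed, sample_sizes, n_sims):
    def objective(params: dict[str, float], eval_seed: int) -> float:
        try:
            model = build_scenario(spec, params, sample_sizes=sample_sizes)
        except ValueError:
            return -np.inf
        exp = expected_sfs_mc(model, n_sims, eval_seed,
                              folded=observed.folded)
        return composite_loglik(observed, exp)
    return objective


class _Ensemble:
    """Reference genealogy ensemble reused across conditional updates.

    Wraps :func:`reweighted_sfs_grid` with a fixed reference point; callers
    rebuild it (cheaply) when the effective sample size of the models being
    evaluated collapses.
    """

    def __init__(self, ref_model: DemographicModel, n_sims: int, seed: int):
        self.ref = ref_model
        self.n_sims = n_sims
        self.seed = seed

    def loglik(self, models, observed: JointSFS):
        spectra, ess = reweighted_sfs_grid(self.ref, models, self.n_sims,
                                           self.seed, folded=observed.folded)
        lls = np.full(len(models), -np.inf)
        for i, s in enumerate(spectra):
            if s is not None:
                lls[i] = composite_loglik(observed, s)
        return lls, ess


def _golden_1d(fun, lo, hi, log_scale: bool, n_iter: int = 8):
    """Bounded golden-section maximization; returns (argmax, max)."""
    if log_scale:
        tr, inv = math.log, math.exp
    else:
        tr, inv = (lambda x: x), (lambda x: x)
    a, b = tr(lo), tr(hi)
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = fun(inv(c)), fun(inv(d))
    for _ in range(n_iter):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = fun(inv(c))
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = fun(inv(d))
    return (inv(c), fc) if fc >= fd else (inv(d), fd)


def maximize_likelihood(spec: ScenarioSpec, observed: JointSFS,
                        n_cycles: int = 40, n_sims: int = 500,
                        seed: int = 1, start: dict[str, float] | None = None,
                        golden_iters: int = 8, final_sims_factor: int = 4,
                        use_reweighting: bool = True, grid_span: float = 6.0,
                        grid_points: int = 11, ensemble_factor: int = 8,
                        min_ess: float = 150.0) -> LikelihoodResult:
    """Cyclic conditional maximization of the composite likelihood (ECM).

    Per cycle each free parameter is maximized in one dimension with the
    others fixed, re-using common random numbers within the cycle. Size and
    migration-rate parameters are updated by argmax over a log grid spanning
    ``grid_span``-fold around the current value, evaluated by exact path
    reweighting against a shared per-cycle genealogy ensemble of
    ``n_sims * ensemble_factor`` paths (rebuilt whenever the importance
    weights degenerate); time parameters, whose grid models cannot share a
    dominating reference, use bounded golden section with ``n_sims`` direct
    simulations per evaluation. The final point is re-evaluated at an
    elevated Monte-Carlo size. ``n_cycles=0`` evaluates the start point
    only.
    """
    sample_sizes = (observed.n1, observed.n2)
    objective = _objective_factory(spec, observed, sample_sizes, n_sims)
    params = dict(start) if start is not None else _default_start(spec)
    cycle_seeds = _subseeds(seed, max(n_cycles, 1) + 1)
    any_finite = False

    def build(p):
        try:
            return build_scenario(spec, p, sample_sizes=sample_sizes)
        except ValueError:
            return None

    for cycle in range(n_cycles):
        eval_seed = int(cycle_seeds[cycle])
        ensemble: _Ensemble | None = None
        for name in spec.free_parameters:
            lo, hi = spec.free_parameters[name]
            if use_reweighting and _log_scale(name):
                cur = params[name]
                glo = max(lo, cur / grid_span)
                ghi = min(hi, cur * grid_span)
                grid = np.geomspace(glo, ghi, grid_points)
                models = [build(dict(params, **{name: float(v)}))
                          for v in grid]
                feas = [(v, m) for v, m in zip(grid, models)
                        if m is not None]
                updated = False
                for _attempt in range(2):
                    if not feas:
                        break
                    if ensemble is None:
                        ref = build(params)
                        if ref is None:
                            break
                        ensemble = _Ensemble(
                            ref, n_sims * ensemble_factor, eval_seed)
                    if not reweight_supported(ensemble.ref,
                                              [m for _, m in feas]):
                        break
                    lls, ess = ensemble.loglik([m for _, m in feas],
                                               observed)
                    ok = ess >= min_ess
                    if ok.any():
                        k = int(np.argmax(np.where(ok, lls, -np.inf)))
                        params[name] = float(feas[k][0])
                        any_finite = True
                        updated = True
                        break
                    ensemble = None       # weights degenerate: rebuild
                if updated:
                    continue

            def fun(v, _name=name, _seed=eval_seed):
                trial = dict(params)
                trial[_name] = v
                return objective(trial, _seed)

            best_v, best_f = _golden_1d(fun, lo, hi, _log_scale(name),
                                        golden_iters)
            if np.isfinite(best_f):
                params[name] = best_v
                any_finite = True

    final_seed = int(cycle_seeds[-1])
    final = _objective_factory(spec, observed, sample_sizes,
                               n_sims * final_sims_factor)(params, final_seed)
    if not np.isfinite(final) and not any_finite and n_cycles > 0:
        raise RuntimeError(
            f"likelihood non-finite throughout for scenario {spec.name}; "
            f"start={params}")
    return LikelihoodResult(final, params, spec.n_free,
                            n_sims * final_sims_factor, seed)


def model_select(observed: JointSFS, scenarios: list[ScenarioSpec],
                 runs_per_scenario: int = 3, n_cycles: int = 2,
                 n_sims: int = 200, seed: int = 1, golden_iters: int = 6,
                 final_sims: int = 10_000) -> ModelSelectionTable:
    """AIC ranking of scenarios: best of several independent ECM runs each.

    Runs differ in their RNG streams (and hence Monte-Carlo surfaces); a
    scenario whose runs all fail is excluded from the ranking. Every
    scenario's best point is re-evaluated at ``final_sims`` simulations with
    one shared seed, so the cross-scenario comparison is made on a common
    Monte-Carlo footing.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    table = ModelSelectionTable()
    run_seeds = _subseeds(seed, len(scenarios) * runs_per_scenario + 1)
    final_seed = int(run_seeds[-1])
    sample_sizes = (observed.n1, observed.n2)
    i = 0
    for spec in scenarios:
        best: LikelihoodResult | None = None
        for _ in range(runs_per_scenario):
            s = int(run_seeds[i])
            i += 1
            try:
                res = maximize_likelihood(spec, observed, n_cycles, n_sims,
                                          seed=s, golden_iters=golden_iters)
            except RuntimeError:
                continue
            if best is None or res.log10_lik > best.log10_lik:
                best = res
        if best is None or not np.isfinite(best.log10_lik):
            table.failed.append(spec.scenario_id)
            continue
        model = build_scenario(spec, best.params, sample_sizes=sample_sizes)
        ll = composite_loglik(observed,
                              expected_sfs_mc(model, final_sims, final_seed,
                                              folded=observed.folded))
        table.rows.append({
            "scenario_id": spec.scenario_id, "name": spec.name,
            "log10_lik": ll, "n_free": spec.n_free,
            "aic": aic(ll, spec.n_free), "params": best.params,
        })
    table.finalize()
    return table


def profile_recover(fixture: DemographicModel, spec: ScenarioSpec,
                    truth_params: dict[str, float], target_param: str,
                    grid: np.ndarray, n_loci: int = 2000, n_sims: int = 2000,
                    seed: int = 1, folded: bool = True,
                    observed: JointSFS | None = None,
                    strategy: str = "auto", ensemble_sims: int = 20_000,
                    min_ess: float = 200.0) -> ProfileResult:
    """1-D profile of the composite likelihood along ``grid`` for one
    parameter, all others held at their generative values.

    The observed SFS is simulated from ``fixture`` (``n_loci`` loci with
    Poisson mutations) unless supplied. Under ``strategy="reweight"`` (the
    default when valid) a single ensemble of ``ensemble_sims`` genealogies —
    simulated at the reference point and exactly reweighted to every grid
    value — provides the expected spectra, so all grid points share common
    random numbers and the profile's shape is low-variance; grid points
    whose importance-sampling effective sample size falls below ``min_ess``
    are re-evaluated by direct simulation (``n_sims`` genealogies each), as
    is the whole grid under ``strategy="direct"``. Grid points structurally
    inconsistent with the held parameters (e.g. a divergence time below a
    fixed internal event time) get zero likelihood. A maximum on the first
    or last feasible grid point is flagged as a boundary profile.
    """
    if strategy not in ("auto", "reweight", "direct"):
        raise ValueError("strategy must be auto, reweight or direct")
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size < 1:
        raise ValueError("empty grid")
    s_obs, s_exp = (int(x) for x in _subseeds(seed, 2))
    if observed is None:
        fix = DemographicModel(
            fixture.sample_sizes, fixture.epochs, fixture.divergence_time,
            fixture.n_anc, fixture.mutation_rate, fixture.locus_length,
            n_loci, fixture.size_units)
        observed = simulate_dataset(fix, s_obs, emit="sfs")
        if folded:
            observed = observed.fold()

    models: list[DemographicModel | None] = []
    for v in grid:
        params = dict(truth_params)
        params[target_param] = float(v)
        try:
            models.append(build_scenario(spec, params,
                                         sample_sizes=fixture.sample_sizes))
        except ValueError:
            models.append(None)
    feasible = [i for i, m in enumerate(models) if m is not None]
    if not feasible:
        raise ValueError("no feasible grid point for profile")

    lls = np.full(grid.size, -np.inf)
    direct_idx = list(feasible)
    if strategy in ("auto", "reweight"):
        feas_models = [models[i] for i in feasible]
        # the reference must merge no later than any grid model: profiling
        # the divergence time itself anchors it at the smallest grid value
        if target_param == "t_div":
            ref = min(feas_models, key=lambda m: m.divergence_time)
        else:
            ref = build_scenario(spec, truth_params,
                                 sample_sizes=fixture.sample_sizes)
        ok = reweight_supported(ref, feas_models)
        if not ok and strategy == "reweight":
            raise ValueError("reweighting unsupported for this grid "
                             "(migration active beyond the reference merger)")
        if ok:
            spectra, ess = reweighted_sfs_grid(ref, feas_models,
                                               ensemble_sims, s_exp,
                                               folded=folded)
            direct_idx = []
            for j, i in enumerate(feasible):
                if spectra[j] is None or ess[j] < min_ess:
                    direct_idx.append(i)
                else:
                    lls[i] = composite_loglik(observed, spectra[j])
    for i in direct_idx:
        exp = expected_sfs_mc(models[i], n_sims, s_exp, folded=folded)
        lls[i] = composite_loglik(observed, exp)

    k_best = int(np.argmax(lls))
    edge = {feasible[0], feasible[-1]}
    return ProfileResult(target_param, grid, lls, float(grid[k_best]),
                         at_boundary=len(feasible) > 1 and k_best in edge)


def profile_suite(fixture: DemographicModel, spec: ScenarioSpec,
                  truth_params: dict[str, float],
                  grids: dict[str, np.ndarray], n_loci: int = 2000,
                  seed: int = 1, ensemble_sims: int = 20_000,
                  direct_sims: int = 20_000, fallback_sims: int = 2000,
                  min_ess: float = 200.0, folded: bool = True
                  ) -> dict[str, ProfileResult]:
    """Profile several parameters against one simulated observed SFS.

    All parameters whose grids admit path reweighting from the truth
    reference share a single genealogy ensemble (one simulation, one weight
    matrix for every grid point of every parameter); the rest — notably the
    divergence time, whose grid models disagree about when migration stops
    being possible — are evaluated by direct simulation with ``direct_sims``
    genealogies per grid point. Low-ESS reweighted points fall back to
    direct evaluation with ``fallback_sims``.
    """
    s_obs, s_exp = (int(x) for x in _subseeds(seed, 2))
    fix = DemographicModel(
        fixture.sample_sizes, fixture.epochs, fixture.divergence_time,
        fixture.n_anc, fixture.mutation_rate, fixture.locus_length,
        n_loci, fixture.size_units)
    observed = simulate_dataset(fix, s_obs, emit="sfs")
    if folded:
        observed = observed.fold()
    ref = build_scenario(spec, truth_params,
                         sample_sizes=fixture.sample_sizes)

    per_param: dict[str, dict] = {}
    batch_models: list[DemographicModel] = []
    batch_slots: list[tuple[str, int]] = []
    for param, grid in grids.items():
        grid = np.asarray(grid, dtype=np.float64)
        models = []
        for v in grid:
            p = dict(truth_params)
            p[param] = float(v)
            try:
                models.append(build_scenario(
                    spec, p, sample_sizes=fixture.sample_sizes))
            except ValueError:
                models.append(None)
        feas = [m for m in models if m is not None]
        if not feas:
            raise ValueError(f"no feasible grid point for {param}")
        supported = reweight_supported(ref, feas)
        per_param[param] = {"grid": grid, "models": models,
                            "supported": supported,
                            "lls": np.full(grid.size, -np.inf)}
        if supported:
            for i, m in enumerate(models):
                if m is not None:
                    batch_slots.append((param, i))
                    batch_models.append(m)

    if batch_models:
        spectra, ess = reweighted_sfs_grid(ref, batch_models, ensemble_sims,
                                           s_exp, folded=folded)
        for (param, i), sfs, e in zip(batch_slots, spectra, ess):
            st = per_param[param]
            if sfs is None or e < min_ess:
                st["lls"][i] = composite_loglik(
                    observed,
                    expected_sfs_mc(st["models"][i], fallback_sims, s_exp,
                                    folded=folded))
            else:
                st["lls"][i] = composite_loglik(observed, sfs)

    results: dict[str, ProfileResult] = {}
    for param, st in per_param.items():
        if not st["supported"]:
            for i, m in enumerate(st["models"]):
                if m is not None:
                    st["lls"][i] = composite_loglik(
                        observed,
                        expected_sfs_mc(m, direct_sims, s_exp,
                                        folded=folded))
        lls = st["lls"]
        grid = st["grid"]
        feasible = [i for i, m in enumerate(st["models"]) if m is not None]
        k_best = int(np.argmax(lls))
        results[param] = ProfileResult(
            param, grid, lls, float(grid[k_best]),
            at_boundary=len(feasible) > 1
            and k_best in (feasible[0], feasible[-1]))
    return results
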