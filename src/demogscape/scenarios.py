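"""The 12-scenario two-population model family and the best-fit history.

Scenarios factor into a size regime (post-divergence deme sizes constant, or
changing once per deme) crossed with a gene-flow regime (none, early-only,
recent-only, constant, a rate change, or an interrupted on-off-on history),
giving 2 x 6 = 12 models. Parameters are expressed in natural units — years,
diploid effective sizes, per-generation migration probabilities — and
converted to generations with a fixed generation time when a simulator model
is built.

Deme 0 is the northern population, deme 1 the southern. ``m_ns`` denotes
gene flow from north into south; as a backward-in-time lineage rate this is
the rate at which a southern lineage's ancestor is found in the north.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .coalescent import DemographicModel, Epoch

__all__ = [
    "MUTATION_RATE",
    "GENERATION_TIME",
    "DIVERGENCE_BOUNDS_YEARS",
    "BEST_FIT_PARAMS",
    "HIATUS_FIGURE_YEARS",
    "HIATUS_TEXT_YEARS",
    "ScenarioSpec",
    "scenario_family",
    "get_scenario",
    "build_scenario",
    "best_fit_model",
    "years_to_generations",
]

MUTATION_RATE = 2.38e-9          # per site per generation
GENERATION_TIME = 2.5            # years
DIVERGENCE_BOUNDS_YEARS = (20_000.0, 100_000.0)

# Published figure-caption hiatus bounds; the results text prints a slightly
# different pair. The figure values parameterize the fixture.
HIATUS_FIGURE_YEARS = (45_820.0, 30_660.0)
HIATUS_TEXT_YEARS = (45_860.0, 31_660.0)

#: Best-fit parameterization of the (changed sizes, interrupted flow) model.
BEST_FIT_PARAMS: dict[str, float] = {
    "n_anc": 534_000.0,
    "t_div": 66_033.0,           # years
    "n_north_old": 57_679.0,     # post-divergence, before growth
    "n_south_old": 28_407.0,
    "n_north_recent": 81_000.0,  # after growth
    "n_south_recent": 190_000.0,
    "t_north_change": 32_000.0,  # years
    "t_south_change": 41_000.0,
    "m_ns": 8.19e-3,             # north -> south
    "m_sn": 4.25e-3,             # south -> north
    "t_flow_off_start": HIATUS_FIGURE_YEARS[0],
    "t_flow_off_end": HIATUS_FIGURE_YEARS[1],
}

SIZE_REGIMES = ("constant", "changed")
FLOW_REGIMES = ("none", "early", "recent", "constant", "rate_change",
                "interrupted")

_SIZE_BOUNDS = (100.0, 5e6)
_RATE_BOUNDS = (1e-6, 0.1)
_TIME_BOUNDS = (500.0, 100_000.0)   # internal event times, years


def years_to_generations(t_years: float,
                         generation_time: float = GENERATION_TIME) -> float:
    if t_years < 0:
        raise ValueError("time must be >= 0")
    return t_years / generation_time


@dataclass(frozen=True)
class ScenarioSpec:
    """One member of the model family, with its free parameters and bounds."""

    scenario_id: int
    size_regime: str
    flow_regime: str
    free_parameters: dict[str, tuple[float, float]] = field(default_factory=dict)
    mutation_rate: float = MUTATION_RATE
    generation_time: float = GENERATION_TIME

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    @property
    def name(self) -> str:
        return f"{self.size_regime}-size/{self.flow_regime}-flow"


def _free_params(size_regime: str, flow_regime: str):
    p: dict[str, tuple[float, float]] = {
        "n_anc": _SIZE_BOUNDS,
        "t_div": DIVERGENCE_BOUNDS_YEARS,
        "n_north_old": _SIZE_BOUNDS,
        "n_south_old": _SIZE_BOUNDS,
    }
    if size_regime == "changed":
        p.update(n_north_recent=_SIZE_BOUNDS, n_south_recent=_SIZE_BOUNDS,
                 t_north_change=_TIME_BOUNDS, t_south_change=_TIME_BOUNDS)
    if flow_regime in ("early", "recent", "constant", "interrupted"):
        p.update(m_ns=_RATE_BOUNDS, m_sn=_RATE_BOUNDS)
    if flow_regime in ("early", "recent"):
        p["t_flow_change"] = _TIME_BOUNDS
    if flow_regime == "rate_change":
        p.update(m_ns_old=_RATE_BOUNDS, m_sn_old=_RATE_BOUNDS,
                 m_ns_recent=_RATE_BOUNDS, m_sn_recent=_RATE_BOUNDS,
                 t_flow_change=_TIME_BOUNDS)
    if flow_regime == "interrupted":
        p.update(t_flow_off_start=_TIME_BOUNDS, t_flow_off_end=_TIME_BOUNDS)
    return p


def scenario_family() -> list[ScenarioSpec]:
    """All 12 scenarios, ids 1-12 (size regime outer, flow regime inner)."""
    specs = []
    for i, (size, flow) in enumerate(product(SIZE_REGIMES, FLOW_REGIMES),
                                     start=1):
        specs.append(ScenarioSpec(i, size, flow, _free_params(size, flow)))
    return specs


def get_scenario(size_regime: str, flow_regime: str) -> ScenarioSpec:
    for s in scenario_family():
        if s.size_regime == size_regime and s.flow_regime == flow_regime:
            return s
    raise KeyError((size_regime, flow_regime))


def _mig_matrix(m_ns: float, m_sn: float) -> np.ndarray:
    # backward rates: southern lineage -> north at m_ns, northern -> south
    # at m_sn (deme 0 = north, deme 1 = south)
    return np.array([[0.0, m_sn], [m_ns, 0.0]])


def build_scenario(spec: ScenarioSpec, params: dict[str, float],
                   sample_sizes: tuple[int, int] = (20, 20),
                   n_loci: int = 2000, locus_length: int = 300,
                   size_units: str = "diploid") -> DemographicModel:
    """Assemble a :class:`DemographicModel` from named parameter values.

    Validates that every free parameter is supplied and in bounds, that
    internal event times fall inside the divergence time, and (for the
    interrupted regime) that the flow-off window is ordered.
    """
    missing = set(spec.free_parameters) - set(params)
    if missing:
        raise ValueError(f"missing parameter(s): {sorted(missing)}")
    for name, (lo, hi) in spec.free_parameters.items():
        v = params[name]
        if not lo <= v <= hi:
            raise ValueError(f"parameter {name}={v} outside [{lo}, {hi}]")
    t_div_y = params["t_div"]
    internal_times = [k for k in ("t_north_change", "t_south_change",
                                  "t_flow_change", "t_flow_off_start",
                                  "t_flow_off_end") if k in params]
    for k in internal_times:
        if params[k] >= t_div_y:
            raise ValueError(f"parameter {k} must be < t_div")
    if spec.flow_regime == "interrupted":
        if not params["t_flow_off_start"] > params["t_flow_off_end"]:
            raise ValueError("t_flow_off_start must predate t_flow_off_end "
                             "(be the larger years-ago value)")

    gen = spec.generation_time

    def sizes_at(t_y: float):
        n_n = params["n_north_old"]
        n_s = params["n_south_old"]
        if spec.size_regime == "changed":
            if t_y < params["t_north_change"]:
                n_n = params["n_north_recent"]
            if t_y < params["t_south_change"]:
                n_s = params["n_south_recent"]
        return (n_n, n_s)

    def migration_at(t_y: float) -> np.ndarray:
        flow = spec.flow_regime
        if flow == "none":
            return np.zeros((2, 2))
        if flow == "constant":
            return _mig_matrix(params["m_ns"], params["m_sn"])
        if flow == "early":   # flow only in (t_flow_change, t_div]
            on = t_y >= params["t_flow_change"]
            return (_mig_matrix(params["m_ns"], params["m_sn"]) if on
                    else np.zeros((2, 2)))
        if flow == "recent":  # flow only in (0, t_flow_change]
            on = t_y < params["t_flow_change"]
            return (_mig_matrix(params["m_ns"], params["m_sn"]) if on
                    else np.zeros((2, 2)))
        if flow == "rate_change":
            if t_y < params["t_flow_change"]:
                return _mig_matrix(params["m_ns_recent"],
                                   params["m_sn_recent"])
            return _mig_matrix(params["m_ns_old"], params["m_sn_old"])
        # interrupted: on, off during the hiatus, on again
        off = params["t_flow_off_end"] <= t_y < params["t_flow_off_start"]
        return (np.zeros((2, 2)) if off
                else _mig_matrix(params["m_ns"], params["m_sn"]))

    boundaries = {0.0}
    boundaries.update(params[k] for k in internal_times)
    starts_y = sorted(b for b in boundaries if b < t_div_y)
    epochs = [Epoch(years_to_generations(t, gen), sizes_at(t),
                    migration_at(t)) for t in starts_y]
    return DemographicModel(
        sample_sizes, epochs, years_to_generations(t_div_y, gen),
        params["n_anc"], spec.mutation_rate, locus_length, n_loci,
        size_units)


def best_fit_model(sample_sizes: tuple[int, int] = (20, 20),
                   n_loci: int = 2000, locus_length: int = 300
                   ) -> DemographicModel:
    """The published best-fit history: changed sizes, interrupted gene flow."""
    spec = get_scenario("changed", "interrupted")
    return build_scenario(spec, BEST_FIT_PARAMS, sample_sizes, n_loci,
                          locus_length)


def extract_params(spec: ScenarioSpec, model: DemographicModel
                   ) -> dict[str, float]:
    """Inverse of :func:`build_scenario` for round-trip checks: read the
    scenario's named parameters back off an epoch-structured model."""
    gen = spec.generation_time
    out: dict[str, float] = {"n_anc": model.n_anc,
                             "t_div": model.divergence_time * gen}
    eps = model.epochs
    out["n_north_old"] = eps[-1].sizes[0]
    out["n_south_old"] = eps[-1].sizes[1]
    if spec.size_regime == "changed":
        out["n_north_recent"] = eps[0].sizes[0]
        out["n_south_recent"] = eps[0].sizes[1]
        for e_prev, e in zip(eps, eps[1:]):
            if e.sizes[0] != e_prev.sizes[0]:
                out["t_north_change"] = e.start_time * gen
            if e.sizes[1] != e_prev.sizes[1]:
                out["t_south_change"] = e.start_time * gen
    flow = spec.flow_regime
    on = [e for e in eps if e.migration.any()]
    if flow in ("early", "recent", "constant", "interrupted") and on:
        out["m_ns"] = on[0].migration[1, 0]
        out["m_sn"] = on[0].migration[0, 1]
    if flow == "rate_change":
        out["m_ns_recent"] = eps[0].migration[1, 0]
        out["m_sn_recent"] = eps[0].migration[0, 1]
        out["m_ns_old"] = eps[-1].migration[1, 0]
        out["m_sn_old"] = eps[-1].migration[0, 1]
        for e_prev, e in zip(eps, eps[1:]):
            if not np.array_equal(e.migration, e_prev.migration):
                out["t_flow_change"] = e.start_time * gen
    if flow in ("early", "recent"):
        for e_prev, e in zip(eps, eps[1:]):
            if e.migration.any() != e_prev.migration.any():
                out["t_flow_change"] = e.start_time * gen
    if flow == "interrupted":
        for e_prev, e in zip(eps, eps[1:]):
            if e_prev.migration.any() and not e.migration.any():
                out["t_flow_off_end"] = e.start_time * gen
            if not e_prev.migration.any() and e.migration.any():
                out["t_flow_off_start"] = e.start_time * gen
    return out
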