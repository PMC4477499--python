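"""Column startup integration, steady-state metrics, recycle, and sweeps.

The study-style startup procedure is used: the discretized column is
integrated through startup with a stiff implicit method (BDF) to a long
final time, and the final state is declared steady when the max-norm of
the re-evaluated right-hand side falls below a threshold.  Exit metrics
(titers, ethanol/acetate ratio, gas conversions) are read at the top of
the column.  Gas recycle mixes a fraction of the exit gas back into the
fresh feed at fixed total inlet molar concentration and is resolved by
an outer fixed-point iteration over full startup simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import BDF

from . import kinetics as kin
from .network import MetabolicNetwork
from .transport import ColumnModel, ColumnState, FIELDS

__all__ = [
    "SimulationSettings",
    "SimulationResult",
    "SteadyStateMetrics",
    "RecycleSpec",
    "simulate_startup",
    "steady_state_metrics",
    "apply_gas_recycle",
    "simulate_with_recycle",
    "fresh_feed_conversions",
    "run_parameter_sweep",
]

#: acetate below this titer (g/L) reports the ethanol/acetate ratio as +inf
RATIO_ACETATE_FLOOR = 1e-6


@dataclass(frozen=True)
class SimulationSettings:
    """Integration controls for a startup simulation.

    final_time (h) and n_nodes default to the reference procedure (1000 h, 100
    nodes).  rtol/atol are the stiff-solver tolerances (defaults match
    ode15s, the solver the original study used).  steady_threshold is the
    max-norm of the right-hand side (fields' native units per hour) below
    which the final state is flagged steady.  The model is deterministic;
    ``seed`` is recorded in metadata for provenance only.
    """

    final_time: float = 1000.0
    n_nodes: int = 100
    rtol: float = 1.0e-3
    atol: float = 1.0e-6
    steady_threshold: float = 1.0e-2
    n_snapshots: int = 11
    scheme: str = "third-order-upwind"
    seed: int | None = None
    # stop marching once the RHS max-norm is below steady_threshold (the
    # remaining horizon cannot change the state); the steady flag and
    # residual are computed identically either way
    stop_at_steady: bool = True

    def __post_init__(self) -> None:
        if self.final_time <= 0:
            raise ValueError("final time must be positive")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SimulationResult:
    """Snapshots and final state of one startup simulation."""

    times: np.ndarray
    states: np.ndarray  # (n_snapshots, 9, n)
    final_state: ColumnState
    steady: bool
    steady_residual: float
    z: np.ndarray
    inlet_gas: dict[str, float]
    fresh_feed: dict[str, float]
    settings: SimulationSettings
    lp_infeasible_nodes: int = 0
    n_rhs_evaluations: int = 0

    def state_at(self, i: int) -> ColumnState:
        return ColumnState(self.states[i])


@dataclass(frozen=True)
class SteadyStateMetrics:
    """Exit (z = L) concentrations and derived performance measures."""

    biomass: float
    ethanol: float
    acetate: float
    co_liquid: float
    h2_liquid: float
    co2_liquid: float
    co_gas: float
    h2_gas: float
    co2_gas: float
    ethanol_acetate_ratio: float
    co_conversion: float
    h2_conversion: float
    steady: bool

    def to_dict(self) -> dict:
        d = {
            "biomass_gL": self.biomass,
            "ethanol_gL": self.ethanol,
            "acetate_gL": self.acetate,
            "co_liquid_mM": self.co_liquid,
            "h2_liquid_mM": self.h2_liquid,
            "co2_liquid_mM": self.co2_liquid,
            "co_gas_mM": self.co_gas,
            "h2_gas_mM": self.h2_gas,
            "co2_gas_mM": self.co2_gas,
            "co_conversion": self.co_conversion,
            "h2_conversion": self.h2_conversion,
            "steady": self.steady,
        }
        if math.isinf(self.ethanol_acetate_ratio):
            d["ethanol_acetate_ratio"] = None
            d["ethanol_acetate_ratio_infinite"] = True
        else:
            d["ethanol_acetate_ratio"] = self.ethanol_acetate_ratio
            d["ethanol_acetate_ratio_infinite"] = False
        return d


@dataclass(frozen=True)
class RecycleSpec:
    """Fraction of exit gas mixed back into the fresh feed."""

    alpha: float
    fixed_point_tol: float = 1.0e-4
    max_passes: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("recycle fraction must lie in [0, 1)")


def build_column_model(
    network: MetabolicNetwork,
    uptake: kin.UptakeKinetics,
    geometry: kin.ColumnGeometry,
    gas_params: kin.GasPhysicalParams,
    feed_fractions: tuple[float, float, float],
    settings: SimulationSettings,
    initial_biomass: float = 0.1,
    inlet_gas: dict[str, float] | None = None,
    solver_backend: str = "glpk",
    biology=None,
) -> ColumnModel:
    return ColumnModel(
        network,
        uptake,
        geometry,
        gas_params,
        feed_fractions=feed_fractions,
        inlet_gas=inlet_gas,
        n_nodes=settings.n_nodes,
        scheme=settings.scheme,
        initial_biomass=initial_biomass,
        solver_backend=solver_backend,
        biology=biology,
    )


# Crawl detection for the hybrid integrator: when the (leaky) count of
# BDF steps below the floor reaches the threshold after the initial stiff
# layer, a short implicit-Euler bridge carries the state across the
# sliding window and adaptive BDF resumes.
_CRAWL_STEP_FLOOR = 5.0e-3  # h
_CRAWL_STEP_COUNT = 250
_CRAWL_EARLIEST_T = 10.0  # h
#: model-time width of one bridge and its nominal step (h)
_BRIDGE_SPAN = 15.0
_BRIDGE_STEP = 0.25
_MAX_BRIDGES = 400


def _implicit_euler_bridge(model, t, y, t_end, settings, sampler):
    """Backward-Euler bridge across an LP-kink sliding window.

    High-order error estimators never recover while the trajectory
    slides along a kink surface of the embedded LP solution (the step
    stays pinned near 1e-3 h); backward Euler is insensitive to the kink
    and crosses the window in a few dozen steps.  Accuracy within the
    bridge is first order, which smears the transient locally; steady
    states are exact fixed points of the scheme and are unaffected.
    """
    h = _BRIDGE_STEP
    eye = sp.identity(y.size, format="csc")

    def scaled_norm(g, ref):
        scale = settings.atol + settings.rtol * np.abs(ref)
        return float(np.sqrt(np.mean((g / scale) ** 2)))

    while t < t_end - 1e-9:
        h = min(h, t_end - t)
        y_new = y.copy()
        converged = False
        # piecewise-linear RHS: on stagnation refresh the Jacobian at the
        # current iterate (semismooth strategy) before cutting the step
        for _refresh in range(3):
            lu = spla.splu((eye - h * model.jacobian(t + h, y_new)).tocsc())
            for _ in range(8):
                g = y_new - y - h * model.rhs(t + h, y_new)
                if scaled_norm(g, y_new) < 0.5:
                    converged = True
                    break
                y_new = y_new - lu.solve(g)
            if converged:
                break
        if not converged:
            h *= 0.5
            if h < 1e-8:
                raise RuntimeError(
                    f"implicit-Euler bridge stalled at t = {t:.3f} h"
                )
            continue
        sampler(t, y, t + h, y_new)
        t += h
        y = y_new
        h = min(h * 1.5, _BRIDGE_STEP)
    return t, y


def simulate_startup(
    model: ColumnModel,
    settings: SimulationSettings,
    initial: ColumnState | None = None,
) -> SimulationResult:
    """Integrate column startup and flag steadiness of the final state.

    Adaptive BDF handles the stiff startup transient; if the step size
    collapses persistently on an LP-kink surface (a known failure mode of
    high-order error estimators on piecewise-linear right-hand sides),
    the remainder of the horizon is marched with damped implicit Euler,
    whose fixed points are exactly the model's steady states.
    """
    y0 = (initial or model.initial_state()).flatten()
    t_eval = np.linspace(0.0, settings.final_time, settings.n_snapshots)
    snapshots = np.empty((settings.n_snapshots, y0.size))
    snapshots[0] = y0
    filled = np.zeros(settings.n_snapshots, dtype=bool)
    filled[0] = True

    def fill_linear(t0, ya, t1, yb):
        mask = ~filled & (t_eval > t0) & (t_eval <= t1 + 1e-9)
        for i in np.nonzero(mask)[0]:
            w = 0.0 if t1 == t0 else (t_eval[i] - t0) / (t1 - t0)
            snapshots[i] = (1 - w) * ya + w * yb
            filled[i] = True

    t_cur, y_cur = 0.0, y0
    n_bridges = 0
    nfev = 0
    steady_early = False
    while t_cur < settings.final_time - 1e-9:
        solver = BDF(
            model.rhs, t_cur, y_cur, settings.final_time,
            jac=model.jacobian, rtol=settings.rtol, atol=settings.atol,
        )
        crawl = 0
        crawled = False
        while solver.status == "running":
            message = solver.step()
            if solver.status == "failed":
                dy = model.rhs(solver.t, solver.y)
                worst = int(np.abs(dy).argmax())
                raise RuntimeError(
                    f"integrator failed at t = {solver.t:.3f} h (field "
                    f"{FIELDS[worst // model.grid.n]}, node "
                    f"{worst % model.grid.n}): {message}"
                )
            dense = solver.dense_output()
            mask = (
                ~filled
                & (t_eval >= dense.t_min - 1e-12)
                & (t_eval <= dense.t_max + 1e-12)
            )
            for i in np.nonzero(mask)[0]:
                snapshots[i] = dense(t_eval[i])
                filled[i] = True
            if solver.t > _CRAWL_EARLIEST_T and solver.h_abs < _CRAWL_STEP_FLOOR:
                crawl += 1
            else:
                # leaky counter: brief excursions above the floor should
                # not reset the crawl evidence accumulated so far
                crawl = max(crawl - 3, 0)
            if crawl >= _CRAWL_STEP_COUNT:
                crawled = True
                break
            if (
                settings.stop_at_steady
                and solver.h_abs > 20.0
                and solver.t > _CRAWL_EARLIEST_T
            ):
                resid = float(np.abs(model.rhs(solver.t, solver.y)).max())
                nfev += 1
                if resid < settings.steady_threshold:
                    steady_early = True
                    break
        nfev += solver.nfev
        t_cur, y_cur = solver.t, solver.y.copy()
        if steady_early or not crawled:
            break
        n_bridges += 1
        if n_bridges > _MAX_BRIDGES:
            raise RuntimeError(
                f"integration kept sliding on LP kinks after {_MAX_BRIDGES} "
                f"bridges (t = {t_cur:.2f} h)"
            )
        t_cur, y_cur = _implicit_euler_bridge(
            model, t_cur, y_cur,
            min(t_cur + _BRIDGE_SPAN, settings.final_time),
            settings, fill_linear,
        )
    y_final = y_cur
    if not filled[-1]:
        snapshots[-1] = y_final
        filled[-1] = True
    # any remaining unfilled snapshot times (none expected) take the final state
    for i in np.nonzero(~filled)[0]:
        snapshots[i] = y_final
    n = model.grid.n
    states = snapshots.reshape(settings.n_snapshots, len(FIELDS), n)
    final = ColumnState(y_final.reshape(len(FIELDS), n).copy())
    residual = float(np.abs(model.rhs(settings.final_time, final.flatten())).max())
    return SimulationResult(
        times=t_eval,
        states=states,
        final_state=final,
        steady=residual < settings.steady_threshold,
        steady_residual=residual,
        z=model.grid.z,
        inlet_gas=dict(model.inlet_gas),
        fresh_feed=dict(model.fresh_feed),
        settings=settings,
        lp_infeasible_nodes=model.lp_infeasible_nodes,
        n_rhs_evaluations=nfev,
    )


def steady_state_metrics(result: SimulationResult) -> SteadyStateMetrics:
    """Exit values at z = L plus conversions and the ethanol/acetate ratio.

    Conversions are concentration-based, 1 - G(L)/G_feed (identical to
    molar-flow conversions under the constant-velocity treatment).  The
    ratio is mass-basis (g/L over g/L) and reported as +inf when acetate
    is below 1e-6 g/L.
    """
    st = result.final_state
    exit_ = {name: float(st[name][-1]) for name in FIELDS}
    feed = result.inlet_gas
    co_conv = 1.0 - exit_["C_G"] / feed["co"] if feed["co"] > 0 else 0.0
    h2_conv = 1.0 - exit_["H_G"] / feed["h2"] if feed["h2"] > 0 else 0.0
    if exit_["A_L"] < RATIO_ACETATE_FLOOR:
        ratio = math.inf
    else:
        ratio = exit_["E_L"] / exit_["A_L"]
    return SteadyStateMetrics(
        biomass=exit_["X"],
        ethanol=exit_["E_L"],
        acetate=exit_["A_L"],
        co_liquid=exit_["C_L"],
        h2_liquid=exit_["H_L"],
        co2_liquid=exit_["D_L"],
        co_gas=exit_["C_G"],
        h2_gas=exit_["H_G"],
        co2_gas=exit_["D_G"],
        ethanol_acetate_ratio=ratio,
        co_conversion=co_conv,
        h2_conversion=h2_conv,
        steady=result.steady,
    )


def apply_gas_recycle(
    fresh_feed: dict[str, float],
    exit_gas: dict[str, float],
    alpha: float,
) -> dict[str, float]:
    """Effective inlet gas concentrations with partial exit-gas recycle.

    The total inlet molar concentration is held at the fresh-feed value
    (recycle displaces fresh gas rather than adding throughput), so the
    recycled stream contributes through its composition: per species,
    inlet_i = (1 - alpha) fresh_i + alpha x_exit_i C_total.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("recycle fraction must lie in [0, 1)")
    total = sum(fresh_feed.values())
    exit_total = sum(exit_gas.values())
    if exit_total <= 0:
        raise ValueError("exit gas stream is empty")
    return {
        role: (1.0 - alpha) * fresh_feed[role]
        + alpha * (exit_gas[role] / exit_total) * total
        for role in fresh_feed
    }


def simulate_with_recycle(
    network: MetabolicNetwork,
    uptake: kin.UptakeKinetics,
    geometry: kin.ColumnGeometry,
    gas_params: kin.GasPhysicalParams,
    feed_fractions: tuple[float, float, float],
    settings: SimulationSettings,
    recycle: RecycleSpec,
    initial_biomass: float = 0.1,
    solver_backend: str = "glpk",
) -> tuple[SimulationResult, int]:
    """Outer fixed-point iteration: simulate, re-mix the inlet, repeat.

    Returns the converged result and the number of passes.  Raises after
    ``max_passes`` without the inlet composition settling to within
    ``fixed_point_tol`` relative change.
    """
    base = build_column_model(
        network, uptake, geometry, gas_params, feed_fractions, settings,
        initial_biomass=initial_biomass, solver_backend=solver_backend,
    )
    fresh = dict(base.fresh_feed)
    inlet = dict(fresh)
    for n_pass in range(1, recycle.max_passes + 1):
        model = build_column_model(
            network, uptake, geometry, gas_params, feed_fractions, settings,
            initial_biomass=initial_biomass, inlet_gas=inlet,
            solver_backend=solver_backend,
        )
        result = simulate_startup(model, settings)
        st = result.final_state
        exit_gas = {
            "co": float(st["C_G"][-1]),
            "h2": float(st["H_G"][-1]),
            "co2": float(st["D_G"][-1]),
        }
        new_inlet = apply_gas_recycle(fresh, exit_gas, recycle.alpha)
        scale = max(sum(fresh.values()), 1e-12)
        change = max(abs(new_inlet[r] - inlet[r]) for r in inlet) / scale
        inlet = new_inlet
        if change < recycle.fixed_point_tol:
            return result, n_pass
    raise RuntimeError(
        f"gas-recycle fixed point did not converge in {recycle.max_passes} passes "
        f"(last relative change {change:.3e})"
    )


def fresh_feed_conversions(
    result: SimulationResult, alpha: float
) -> dict[str, float]:
    """Conversions accounted against the fresh feed under recycle.

    The net amount of species i leaving the system is the non-recycled
    share of the exit stream; the fresh input is the non-displaced share
    of the inlet.  With alpha = 0 this reduces to the plain conversions.
    """
    st = result.final_state
    exit_gas = {
        "co": float(st["C_G"][-1]),
        "h2": float(st["H_G"][-1]),
        "co2": float(st["D_G"][-1]),
    }
    fresh = result.fresh_feed
    total = sum(fresh.values())
    exit_total = sum(exit_gas.values())
    out = {}
    for role in ("co", "h2"):
        fed = (1.0 - alpha) * fresh[role]
        if fed <= 0:
            out[role] = 0.0
            continue
        net_out = exit_gas[role] - alpha * (exit_gas[role] / exit_total) * total
        out[role] = 1.0 - net_out / fed
    return out


def _set_dotted(obj, path: str, value):
    """Set a dotted attribute/key path on nested dataclasses/dicts."""
    parts = path.split(".")
    target = obj
    for p in parts[:-1]:
        target = target[p] if isinstance(target, dict) else getattr(target, p)
    last = parts[-1]
    if isinstance(target, dict):
        if last not in target:
            raise KeyError(f"unknown parameter path {path!r}")
        target[last] = value
    else:
        if not hasattr(target, last):
            raise KeyError(f"unknown parameter path {path!r}")
        object.__setattr__(target, last, value) if _is_frozen(target) else setattr(
            target, last, value
        )


def _is_frozen(obj) -> bool:
    params = getattr(type(obj), "__dataclass_params__", None)
    return bool(params and params.frozen)


def run_parameter_sweep(
    network: MetabolicNetwork,
    base_config,
    param_path: str,
    values,
    solver_backend: str = "glpk",
) -> pd.DataFrame:
    """One full startup per value; failed runs are recorded, not raised.

    ``base_config`` is a :class:`syncol.config.RunConfig`; ``param_path``
    is a dotted path into it (e.g. ``"geometry.u_gas"`` or
    ``"feed.x_co"``).  Changing a feed mole fraction rebalances the other
    nonzero fractions to keep the sum at one.  Returns a table of value
    -> steady-state metrics with a ``failed`` column.
    """
    rows = []
    for value in values:
        cfg = base_config.with_override(param_path, value)
        try:
            model = build_column_model(
                network,
                cfg.to_uptake_kinetics(),
                cfg.to_geometry(),
                cfg.to_gas_params(),
                cfg.feed_tuple(),
                cfg.to_settings(),
                initial_biomass=cfg.initial.biomass,
                solver_backend=solver_backend,
            )
            result = simulate_startup(model, cfg.to_settings())
            metrics = steady_state_metrics(result)
            row = {"value": value, "failed": False, **metrics.to_dict()}
        except Exception as exc:  # record and continue
            row = {"value": value, "failed": True, "error": str(exc)}
        rows.append(row)
    return pd.DataFrame(rows)


def interpolate_sweep(table: pd.DataFrame, column: str, at_values) -> np.ndarray:
    """Linear interpolation of a sweep column over the swept values."""
    ok = table[~table["failed"]]
    return np.interp(np.asarray(at_values, dtype=float), ok["value"], ok[column])
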