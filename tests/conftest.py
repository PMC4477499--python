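import numpy as np
import pytest

from syncol import (
    ColumnGeometry,
    GasPhysicalParams,
    LexicographicSolver,
    RunConfig,
    UptakeKinetics,
    toy_wlp_network,
)


@pytest.fixture(scope="session")
def toy_network():
    return toy_wlp_network()


@pytest.fixture(scope="session")
def toy_solver(toy_network):
    return LexicographicSolver(toy_network)


@pytest.fixture()
def kinetics_nominal():
    return UptakeKinetics()


@pytest.fixture()
def geometry_nominal():
    return ColumnGeometry()


@pytest.fixture()
def gas_nominal():
    return GasPhysicalParams()


@pytest.fixture()
def config_nominal():
    return RunConfig()


def brute_force_lexicographic(network, uptake_bounds, order=None):
    """Independent lexicographic FBA oracle on scipy.optimize.linprog.

    Deliberately written without reusing any package solver machinery:
    the feasible set is rebuilt per stage, prior optima are fixed by
    plain bound narrowing, and the growth-infeasible case reproduces the
    starvation extension (maximize maintenance ATP first).
    """
    from scipy.optimize import linprog

    S = network.stoichiometry.toarray()
    lo = network.lower_bounds.copy()
    hi = network.upper_bounds.copy()
    for role in ("co", "h2", "co2"):
        lo[network.role_index(role)] = -float(uptake_bounds.get(role, 0.0))
    if order is None:
        order = [
            ("biomass", -1.0),  # maximize
            ("co", +1.0),       # maximize uptake = minimize signed flux
            ("h2", +1.0),
            ("co2", +1.0),      # minimize synthesis
            ("acetate", +1.0),
            ("ethanol", +1.0),
        ]

    def solve_stage(j, sign, lo, hi):
        c = np.zeros(S.shape[1])
        c[j] = sign
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=np.column_stack([lo, hi]),
                      method="highs", options={"presolve": False})
        return res

    starving = False
    first = True
    stages = list(order)
    while stages:
        role, sign = stages[0]
        j = network.role_index(role)
        res = solve_stage(j, sign, lo, hi)
        if res.status == 2 and first:
            # starvation: relax maintenance, maximize it, then continue
            starving = True
            jm = network.role_index("atpm")
            demand = lo[jm]
            lo[jm], hi[jm] = 0.0, demand
            res_m = solve_stage(jm, -1.0, lo, hi)
            if res_m.status != 0 or res_m.x[jm] < 1e-12:
                return {"status": "infeasible-as-zero", "mu": 0.0,
                        "fluxes": np.zeros(S.shape[1])}
            band = max(1e-9 * abs(res_m.x[jm]), 1e-12)
            lo[jm], hi[jm] = max(res_m.x[jm] - band, 0.0), res_m.x[jm] + band
            res = solve_stage(j, sign, lo, hi)
        assert res.status == 0, f"oracle stage {role} failed: {res.message}"
        first = False
        opt = res.x[j]
        band = max(1e-9 * abs(opt), 1e-12)
        lo[j], hi[j] = opt - band, opt + band
        stages.pop(0)
        x = res.x
    mu = 0.0 if starving else max(x[network.role_index("biomass")], 0.0)
    return {
        "status": "starving" if starving else "optimal",
        "mu": mu,
        "v_co": x[network.role_index("co")],
        "v_h2": x[network.role_index("h2")],
        "v_co2": x[network.role_index("co2")],
        "v_ethanol": x[network.role_index("ethanol")],
        "v_acetate": x[network.role_index("acetate")],
        "fluxes": x,
    }
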