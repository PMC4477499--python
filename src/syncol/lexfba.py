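"""Lexicographic flux balance analysis.

Dynamic FBA couples an ODE integrator to exchange fluxes returned by a
linear program, so those fluxes must be *unique* functions of the uptake
bounds — otherwise the right-hand side is not well defined.  Uniqueness
is obtained by lexicographic optimization: an ordered sequence of LPs
over the same feasible set {S v = 0, l <= v <= u}, where after each
solve the just-optimized flux is pinned to its optimum (within a small
two-sided tolerance band) before the next objective is optimized.

Every objective here is a single exchange flux, so "pinning" is a bound
update on one column.  That makes the sequence cheap to re-solve with a
warm-started simplex; the GLPK backend keeps one problem instance alive
and mutates column bounds in place, which is what makes embedding
hundreds of these solves inside one ODE right-hand-side evaluation
affordable.

Sign convention: exchange fluxes are negative for consumption and
positive for secretion.  Kinetic uptake bounds are positive magnitudes
and are applied as lower bounds ``-bound`` on the exchange columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import MetabolicNetwork

__all__ = [
    "LexicographicObjectives",
    "DEFAULT_OBJECTIVES",
    "FluxSolution",
    "LexicographicSolver",
    "solve_lexicographic_fba",
    "ModelError",
]


class ModelError(RuntimeError):
    """The LP is unbounded or irrecoverably ill-posed (missing bound)."""


@dataclass(frozen=True)
class LexicographicObjectives:
    """Ordered (exchange role, sense) pairs; sense is 'max' or 'min'."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for role, sense in self.entries:
            if sense not in ("max", "min"):
                raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


#: Growth first, then gas uptakes, then byproduct syntheses minimized.
DEFAULT_OBJECTIVES = LexicographicObjectives(
    (
        ("biomass", "max"),
        ("co", "max"),
        ("h2", "max"),
        ("co2", "min"),
        ("acetate", "min"),
        ("ethanol", "min"),
    )
)

#: Roles whose uptake bounds are set from kinetics before each solve.
UPTAKE_ROLES = ("co", "h2", "co2")

#: Roles whose objective sense refers to the uptake magnitude, i.e. the
#: negative of the signed exchange flux ("maximize CO uptake" drives the
#: exchange flux toward its lower bound).
CONSUMPTION_ROLES = ("co", "h2")


@dataclass
class FluxSolution:
    """Growth rate and signed exchange fluxes from the final LP.

    status:

    * ``"optimal"`` — maintenance met, growth LP solved;
    * ``"starving"`` — the uptake bounds cannot cover the full ATP
      maintenance demand; mu = 0 and the exchanges come from the
      starvation extension (maintenance ATP production maximized before
      the usual stages), which keeps the fluxes continuous across the
      feasibility boundary;
    * ``"infeasible-as-zero"`` — no uptake is possible at all; mu = 0
      and every exchange flux is exactly zero.
    """

    mu: float
    v_co: float
    v_h2: float
    v_co2: float
    v_ethanol: float
    v_acetate: float
    status: str
    fluxes: np.ndarray | None = None

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


_ZERO_KEYS = ("mu", "v_co", "v_h2", "v_co2", "v_ethanol", "v_acetate")


def _infeasible_as_zero(n: int) -> FluxSolution:
    return FluxSolution(
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0, "infeasible-as-zero", np.zeros(n)
    )


class _GlpkBackend:
    """Persistent GLPK problem with in-place bound updates and warm starts."""

    def __init__(self, network: MetabolicNetwork):
        import swiglpk as glp

        glp.glp_term_out(glp.GLP_OFF)
        self.glp = glp
        self.n = network.n_reactions
        lp = glp.glp_create_prob()
        glp.glp_add_rows(lp, network.n_metabolites)
        glp.glp_add_cols(lp, self.n)
        for i in range(network.n_metabolites):
            glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, 0.0, 0.0)
        for j in range(self.n):
            self._set_col(lp, j + 1, network.lower_bounds[j], network.upper_bounds[j])
        coo = network.stoichiometry.tocoo()
        nnz = coo.nnz
        ia = glp.intArray(nnz + 1)
        ja = glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        for k, (i, j, v) in enumerate(zip(coo.row, coo.col, coo.data), start=1):
            ia[k], ja[k], ar[k] = int(i) + 1, int(j) + 1, float(v)
        glp.glp_load_matrix(lp, nnz, ia, ja, ar)
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        parm.meth = glp.GLP_DUALP
        self.lp = lp
        self.parm = parm
        glp.glp_std_basis(lp)

    def reset_basis(self) -> None:
        """Return to the canonical starting basis.

        Solving from a fixed basis makes the whole lexicographic sequence
        a pure function of its inputs (bitwise-reproducible fluxes),
        instead of depending on the basis left by the previous call.
        """
        self.glp.glp_std_basis(self.lp)

    def _set_col(self, lp, col: int, lo: float, hi: float) -> None:
        glp = self.glp
        if lo == hi:
            glp.glp_set_col_bnds(lp, col, glp.GLP_FX, lo, hi)
        elif np.isinf(lo) and np.isinf(hi):
            glp.glp_set_col_bnds(lp, col, glp.GLP_FR, 0.0, 0.0)
        elif np.isinf(lo):
            glp.glp_set_col_bnds(lp, col, glp.GLP_UP, 0.0, hi)
        elif np.isinf(hi):
            glp.glp_set_col_bnds(lp, col, glp.GLP_LO, lo, 0.0)
        else:
            glp.glp_set_col_bnds(lp, col, glp.GLP_DB, lo, hi)

    def set_bounds(self, j: int, lo: float, hi: float) -> None:
        self._set_col(self.lp, j + 1, lo, hi)

    def solve_single(self, j: int, sense: str) -> str:
        """Optimize flux j alone; returns 'optimal'/'infeasible'/'unbounded'."""
        glp = self.glp
        glp.glp_set_obj_coef(self.lp, j + 1, -1.0 if sense == "max" else 1.0)
        ret = glp.glp_simplex(self.lp, self.parm)
        status = glp.glp_get_status(self.lp)
        if ret != 0 or status not in (glp.GLP_OPT, glp.GLP_NOFEAS, glp.GLP_UNBND):
            # numerical trouble: rebuild a basis and retry cold
            glp.glp_std_basis(self.lp)
            ret = glp.glp_simplex(self.lp, self.parm)
            status = glp.glp_get_status(self.lp)
        glp.glp_set_obj_coef(self.lp, j + 1, 0.0)
        if status == glp.GLP_OPT:
            return "optimal"
        if status == glp.GLP_NOFEAS:
            return "infeasible"
        if status == glp.GLP_UNBND:
            return "unbounded"
        raise ModelError(f"GLPK simplex failed (ret={ret}, status={status})")

    def value(self, j: int) -> float:
        return self.glp.glp_get_col_prim(self.lp, j + 1)

    def all_values(self) -> np.ndarray:
        return np.array([self.value(j) for j in range(self.n)])


class _ScipyBackend:
    """scipy.optimize.linprog (HiGHS) backend; slower, used for cross-checks."""

    def __init__(self, network: MetabolicNetwork):
        self.S = network.stoichiometry.tocsr()
        self.n = network.n_reactions
        self.lo = network.lower_bounds.copy()
        self.hi = network.upper_bounds.copy()
        self._x: np.ndarray | None = None

    def reset_basis(self) -> None:  # stateless backend
        pass

    def set_bounds(self, j: int, lo: float, hi: float) -> None:
        self.lo[j], self.hi[j] = lo, hi

    def solve_single(self, j: int, sense: str) -> str:
        from scipy.optimize import linprog

        c = np.zeros(self.n)
        c[j] = -1.0 if sense == "max" else 1.0
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([self.lo, self.hi]),
            method="highs",
            # presolve misclassifies LPs whose bounds carry the narrow
            # pinning bands of earlier lexicographic stages
            options={"presolve": False},
        )
        if res.status == 0:
            self._x = res.x
            return "optimal"
        if res.status == 2:
            return "infeasible"
        if res.status == 3:
            return "unbounded"
        raise ModelError(f"linprog failed: {res.message}")

    def value(self, j: int) -> float:
        return float(self._x[j])

    def all_values(self) -> np.ndarray:
        return self._x.copy()


class LexicographicSolver:
    """Reusable lexicographic FBA solver bound to one network.

    Parameters
    ----------
    network:
        Validated metabolic network.
    objectives:
        Ordered roles and senses; defaults to growth max, CO/H2 uptake
        max, CO2/acetate/ethanol synthesis min.
    fix_tolerance:
        Relative half-width of the band used to pin each optimized flux
        before the next solve (absolute 1e-12 floor near zero).  Two-sided
        pinning avoids the numerical brittleness of exact equality fixing
        under LP degeneracy.
    backend:
        'glpk' (persistent, warm-started) or 'scipy' (HiGHS, stateless).
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        objectives: LexicographicObjectives = DEFAULT_OBJECTIVES,
        fix_tolerance: float = 1e-9,
        abs_fix_tolerance: float = 1e-12,
        backend: str = "glpk",
    ):
        self.network = network
        self.objectives = objectives
        self.fix_tolerance = fix_tolerance
        self.abs_fix_tolerance = abs_fix_tolerance
        # Translate semantic senses to signed-flux senses: for consumption
        # roles, maximizing uptake means minimizing the signed exchange flux.
        flip = {"max": "min", "min": "max"}
        self._obj_cols = [
            (
                network.role_index(role),
                flip[sense] if role in CONSUMPTION_ROLES else sense,
            )
            for role, sense in objectives
        ]
        self._uptake_cols = {r: network.role_index(r) for r in UPTAKE_ROLES}
        self._atpm_col = network.role_index("atpm")
        self._report_cols = {
            key: network.role_index(role)
            for key, role in (
                ("mu", "biomass"),
                ("v_co", "co"),
                ("v_h2", "h2"),
                ("v_co2", "co2"),
                ("v_ethanol", "ethanol"),
                ("v_acetate", "acetate"),
            )
        }
        if backend == "glpk":
            self._backend = _GlpkBackend(network)
        elif backend == "scipy":
            self._backend = _ScipyBackend(network)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        self.backend_name = backend
        self._fallback: "LexicographicSolver | None" = None

    def begin_batch(self) -> None:
        """Reset the solver basis once before a batch of warm solves.

        A batch caller (one RHS sweep over the column) resets here and
        then passes ``fresh_basis=False`` to :meth:`solve`, letting the
        simplex warm-start from the neighboring node's basis.  The batch
        as a whole remains a pure function of its inputs because it
        always starts from the same canonical basis.
        """
        self._backend.reset_basis()

    def solve(
        self,
        uptake_bounds: dict[str, float],
        keep_fluxes: bool = True,
        fresh_basis: bool = True,
    ) -> FluxSolution:
        """Solve the lexicographic sequence for the given uptake magnitudes.

        ``uptake_bounds`` maps roles in {'co', 'h2', 'co2'} to nonnegative
        maximum uptake magnitudes (mmol/gDW/h); omitted roles keep the
        network's default lower bound.
        """
        for widen in (1.0, 1.0e3, 1.0e6):
            result = self._solve_once(uptake_bounds, keep_fluxes, widen, fresh_basis)
            if result is not None:
                return result
        # Near the maintenance-feasibility knife edge (optimal growth exactly
        # zero) GLPK can keep reporting NOFEAS after pinning; hand those rare
        # solves to the HiGHS backend, which resolves the degenerate vertex.
        if self.backend_name == "glpk":
            if self._fallback is None:
                self._fallback = LexicographicSolver(
                    self.network,
                    objectives=self.objectives,
                    fix_tolerance=self.fix_tolerance,
                    abs_fix_tolerance=self.abs_fix_tolerance,
                    backend="scipy",
                )
            return self._fallback.solve(uptake_bounds, keep_fluxes=keep_fluxes)
        raise ModelError(
            "LP stayed infeasible after pinning prior objectives even with "
            "a widened tolerance band; the network is numerically ill-posed"
        )

    def _solve_once(
        self,
        uptake_bounds: dict[str, float],
        keep_fluxes: bool,
        widen: float,
        fresh_basis: bool = True,
    ) -> FluxSolution | None:
        """One pass of the lexicographic sequence.

        Returns None when a stage after the first reports infeasible,
        which signals that the pinning band was too tight for the solver's
        feasibility tolerance at this vertex; the caller retries with a
        deterministically widened band.
        """
        be = self._backend
        net = self.network
        if fresh_basis or widen > 1.0:
            be.reset_basis()
        touched: list[int] = []
        try:
            for role, bound in uptake_bounds.items():
                j = self._uptake_cols[role]
                if bound < 0:
                    raise ValueError(f"negative uptake bound for {role!r}")
                be.set_bounds(j, -float(bound), net.upper_bounds[j])
                touched.append(j)
            starving = False
            stages = list(self._obj_cols)
            for stage, (j, sense) in enumerate(stages):
                status = be.solve_single(j, sense)
                if status == "unbounded":
                    raise ModelError(
                        f"objective on reaction {net.reactions[j]!r} is unbounded; "
                        "the network is missing a flux bound"
                    )
                if status == "infeasible":
                    if stage > 0:
                        return None
                    # Maintenance cannot be met.  Starvation extension:
                    # relax the ATPM lower bound, maximize maintenance ATP
                    # production first, then run the usual stages (growth
                    # comes out zero).  Keeps fluxes continuous across the
                    # feasibility boundary.
                    starving = True
                    j_m = self._atpm_col
                    demand = net.lower_bounds[j_m]
                    be.set_bounds(j_m, 0.0, demand)
                    if j_m not in touched:
                        touched.append(j_m)
                    status = be.solve_single(j_m, "max")
                    if status != "optimal":
                        return None
                    opt_m = be.value(j_m)
                    if opt_m < self.abs_fix_tolerance:
                        return _infeasible_as_zero(net.n_reactions)
                    half = widen * max(
                        self.fix_tolerance * abs(opt_m), self.abs_fix_tolerance
                    )
                    be.set_bounds(j_m, max(opt_m - half, 0.0), opt_m + half)
                    status = be.solve_single(j, sense)  # re-run growth stage
                    if status != "optimal":
                        return None
                opt = be.value(j)
                half = widen * max(
                    self.fix_tolerance * abs(opt), self.abs_fix_tolerance
                )
                be.set_bounds(j, opt - half, opt + half)
                if j not in touched:
                    touched.append(j)
            values = {k: be.value(j) for k, j in self._report_cols.items()}
            fluxes = be.all_values() if keep_fluxes else None
        finally:
            for j in touched:
                be.set_bounds(j, net.lower_bounds[j], net.upper_bounds[j])
        # tiny negatives from the tolerance band are clipped on mu only
        mu = 0.0 if starving else max(values["mu"], 0.0)
        return FluxSolution(
            mu=mu,
            v_co=values["v_co"],
            v_h2=values["v_h2"],
            v_co2=values["v_co2"],
            v_ethanol=values["v_ethanol"],
            v_acetate=values["v_acetate"],
            status="starving" if starving else "optimal",
            fluxes=fluxes,
        )


def solve_lexicographic_fba(
    network: MetabolicNetwork,
    uptake_bounds: dict[str, float],
    objectives: LexicographicObjectives = DEFAULT_OBJECTIVES,
    fix_tolerance: float = 1e-9,
    backend: str = "glpk",
) -> FluxSolution:
    """One-shot lexicographic FBA solve (builds a solver and discards it)."""
    solver = LexicographicSolver(
        network, objectives=objectives, fix_tolerance=fix_tolerance, backend=backend
    )
    return solver.solve(uptake_bounds)
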