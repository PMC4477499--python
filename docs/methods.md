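# Methods

`syncol` simulates a gas-fed bubble column in which every point along the
column height hosts a population of *Clostridium ljungdahlii* described
by constraint-based metabolism.  This note records the model, the
numerical choices, and what the bundled toy network does and does not
represent.

## Model structure

**State.** Nine fields on an axial grid over the column height
`z ∈ [0, L]`: biomass `X` (g/L), dissolved CO, H₂, CO₂ (mmol/L), ethanol
and acetate titers (g/L), and gas-phase CO, H₂, CO₂ (mmol/L, per unit
gas volume).  Both phases flow upward; velocities, holdup, and
mass-transfer coefficients are constant in space and time.

**Transport.** Liquid-phase fields obey convection–dispersion balances

    ∂f/∂t = source + (k_m/ε_L)(f* − f) − (u_L/ε_L) ∂f/∂z + D_A ∂²f/∂z²

with a Danckwerts inlet condition `u_L f(0) − ε_L D_A f′(0) = u_L f_feed`
(the liquid feed carries no cells, products, or dissolved gases, so
`f_feed = 0`) and zero slope at the exit.  Gas-phase fields are pure
convection with Dirichlet feed values at the inlet.  Gas–liquid transfer
is `k_m (f* − f)` per reactor volume, with the saturation concentration
`f*` from Henry's law at the ideal-gas partial pressure `p_i = G_i R T`.
This convention (rather than `y_i P(z)`) reproduces the nominal
"calculated" feed/saturation values exactly and is the default; the
local-pressure convention is available as a configuration switch
(`gas.partial_pressure_mode: local-pressure`).

**Biology.** At each node, local dissolved concentrations set maximum
uptake rates through inhibited Monod kinetics

    v_i = v_max,i S_i/(K_m,i + S_i) · 1/(1 + (E + A)/K_I)

optionally with CO substrate inhibition of CO uptake
(`K_m + C + C²/K_I,C` in the denominator) and CO cross-inhibition of H₂
uptake (extra factor `1/(1 + C/K_I,H)`); the inhibition constants are
tabulated in g/L, so dissolved CO is converted with a molar mass of
28.01 g/mol inside those terms only.  The uptake bounds enter a
flux-balance LP over the stoichiometry `S v = 0` as lower bounds
`−v_i` on the exchange fluxes (negative flux = consumption).  Exchange
fluxes are made unique by lexicographic optimization in the order:
maximize growth, maximize CO uptake, maximize H₂ uptake, minimize CO₂
synthesis, minimize acetate synthesis, minimize ethanol synthesis; each
optimized flux is pinned inside a two-sided band (relative half-width
1e-9, absolute floor 1e-12) before the next stage.  CO₂ may be
re-assimilated: its exchange is free in both directions up to the
kinetic uptake bound.

**Growth and sources.**  `μ` is the biomass-reaction flux (1/h); the
liquid balances receive `μX`, `v_i X` for the gases, and `M_E v_E X`,
`M_A v_A X` for the products with `M_E = 0.04607`, `M_A = 0.06005`
g/mmol.

**Starvation extension.**  When the uptake bounds cannot cover the ATP
maintenance demand the growth LP is infeasible.  Reporting zero fluxes
there makes the right-hand side discontinuous and, in practice, makes
the stiff integrator fail by step-size underflow when product inhibition
pushes high-biomass nodes onto that boundary.  Instead, the maintenance
lower bound is relaxed, maintenance ATP production is maximized as a
leading objective, and the usual stages follow with `μ = 0`.  Exchange
fluxes are then continuous across the feasibility boundary, and a cell
that can take up nothing at all still reports exactly zero fluxes
(status `infeasible-as-zero`; partial coverage reports `starving`).
Biologically this is maintenance acetogenesis: a starving culture still
runs `4 CO → acetate + 2 CO₂ + ATP` as fast as its uptake allows.

## Nominal parameters

Defaults reproduce the nominal study conditions: reactor 25 m × 5 m²,
`u_G` 75 m/h, `u_L` 0.25 m/h, `D_A` 0.25 m²/h, 37 °C, 1.013×10⁵ Pa top
pressure, 60/40 CO/H₂ feed, Henry constants 8×10⁻⁴ / 6.6×10⁻⁴ /
2.5×10⁻² mol/L/atm, `k_m` 80 / 200 / 80 1/h, holdup fit
`ε_G = 0.53 u_G/(540 + u_G)`, uptake `v_max` 35 / 70 / 35 mmol/gDW/h,
`K_m` 0.02 mmol/L, `K_I` 10 g/L, maintenance 0.45 mmol ATP/gDW/h,
initial biomass 0.1 g/L with saturated liquid and feed-composition gas.
The gas constant is the textbook 8.314 J/mol/K; with the full CODATA
value the derived feed concentration shifts from 80.64 to 80.63 mmol/L,
i.e., off the tabulated value at its printed precision.

## Numerics

* **Discretization.** Method of lines on a uniform grid (default 100
  nodes).  Convection: third-order upwind-biased stencil
  `(2f_{j+1} + 3f_j − 6f_{j−1} + f_{j−2})/(6Δz)`, exact for cubics, with
  first-order upwind at nodes adjacent to the boundaries and at the
  outflow node (zero slope enters through the mirrored diffusion ghost).
  Dispersion: second-order central differences; the Danckwerts inlet is
  closed with a ghost value from the flux balance.  The inlet gas node is
  pinned to the feed (its time derivative is zero).
* **Integration.** Adaptive BDF with an analytic Jacobian: the transport
  and transfer parts are assembled once as a constant sparse matrix; the
  biology block of each node (∂(μ, v)/∂(local liquid state)) is obtained
  by finite differences of the per-node LP map.  Tolerances default to
  rtol 1e-3 / atol 1e-6 — the defaults of ode15s, the solver family this
  class of model was originally built on.  Tighter tolerances change the
  steady exit metrics by well under 0.1% and only slow the transient.
* **Kink sliding and bridging.**  The LP solution is piecewise linear in
  the uptake bounds.  When the trajectory slides along a kink surface
  (e.g., the moving boundary where ethanol synthesis switches on), the
  BDF error estimator pins the step near 1e-3 h indefinitely.  A leaky
  counter detects this and a short backward-Euler bridge (nominal step
  0.25 h, 15 h span, semismooth Newton with per-iterate Jacobian
  refresh) carries the state across before BDF resumes.  Steady states
  are exact fixed points of backward Euler, so bridging cannot bias the
  steady solution; within a bridge the transient is first-order accurate.
* **Steady state.**  The run is declared steady when the max-norm of the
  re-evaluated right-hand side falls below `steady_threshold` (default
  1e-2 in native units per hour; the observed steady residuals are
  ~1e-3–1e-5).  By default integration stops once this is verified —
  continuing to the nominal 1000 h horizon cannot change the state; the
  check and the flag are computed identically either way.
* **LP backend.**  A persistent GLPK problem with in-place bound updates;
  each solve starts from the canonical basis so results are
  bitwise-reproducible, and within one right-hand-side sweep the simplex
  warm-starts from the neighboring node.  Narrow pinning bands can make
  GLPK misreport infeasibility at the exact zero-growth vertex; such
  solves retry with widened bands and finally fall back to HiGHS
  (scipy `linprog`, presolve off).  Negative state values produced by
  integrator undershoot are clamped to zero before entering kinetics;
  the transport terms use the raw values.
* **Biomass viability floor.**  Densities below 1e-12 g/L — less than a
  single bacterial cell in the whole 125 m³ reactor — contribute no
  biological sources.  Without the floor, roundoff in the implicit
  solver's LU factorizations seeds ~1e-16 g/L phantom biomass into an
  exactly sterile column, which exponential growth then amplifies into
  spurious colonization over a long horizon.

## The toy Wood–Ljungdahl network

The bundled fixture lumps syngas acetogenesis into eight reactions over
five internal pools (acetyl-CoA, ATP, reducing equivalents RED, internal
CO₂ and acetate): CO and H₂ oxidation each yield 2 RED, the reductive
acetyl-CoA pathway fixes `2 CO₂ + 8 RED → acetyl-CoA`, acetate kinase is
the only ATP source (`acetyl-CoA → acetate + ATP`), ethanol derives from
acetate by the AOR route (`acetate + 4 RED → ethanol`), biomass costs
`10 acetyl-CoA + 20 ATP`, and maintenance hydrolyzes 0.45 mmol
ATP/gDW/h.  Net conversions are the canonical fermentation
stoichiometries — `4 CO → acetate + 2 CO₂`, `6 CO → ethanol + 4 CO₂`,
`2 CO₂ + 6 H₂ → ethanol` — so the lexicographic optimum secretes ethanol
exactly when electrons outrun carbon (H₂ uptake above CO uptake) and
acetate plus CO₂ otherwise, with growth collapsing when maintenance ATP
cannot be covered.  One mmol of the biomass species is one gram dry
weight (20 mmol C).

What the fixture does *not* emulate: genome-scale yields (its biomass is
far cheaper than iHN637's, so steady titers and biomass overshoot the
genome-scale predictions severalfold), the gradual ethanol/acetate
coexistence region (the toy switches sharply at H₂ uptake = CO uptake),
2,3-butanediol, and any pH or thermodynamic effects.  Passing the column
tests therefore validates the transport/solver machinery and the
qualitative regime structure, not quantitative titers for
*C. ljungdahlii*.  Quantitative reproduction requires the iHN637
reconstruction (BiGG id `iHN637`) placed at `models/iHN637.xml` or
`.json`, which activates the genome-scale checks; those runs are
hours-scale.

## Known limitations

* Constant holdup, velocities, and `k_L a`: no bubble-size or
  hydrodynamic models; no radial structure; no flux limiters.
* pH is implicitly constant; product inhibition is lumped into a single
  `K_I` acting on all uptakes.
* The recycle model displaces fresh feed at fixed total inlet molar
  concentration (isolating the composition effect); it does not model
  increased gas throughput or compression work.
* Transient snapshots inside a bridge window are first-order accurate;
  all steady-state quantities are unaffected.
* The washout threshold depends on the biomass boundary treatment; with
  the zero-feed Danckwerts inlet and upwind outflow used here, dilution
  `u_L/(ε_L L)` above the maximum growth rate empties the column.
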