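"""Gas uptake kinetics and gas-phase physical relations.

This module holds the algebraic closures of the column model: inhibited
Monod uptake bounds for the dissolved gases (with an optional CO
substrate/cross inhibition variant), the hydrostatic pressure profile,
the gas-holdup correlation, Henry's-law saturation concentrations, and
ideal-gas feed concentrations.

Unit conventions (fixed, no unit algebra is performed):

* dissolved and gas-phase concentrations: mmol/L (numerically equal to
  mol/m^3),
* ethanol/acetate titers: g/L,
* uptake rates and flux bounds: mmol/gDW/h,
* pressure: Pa internally; Henry constants are the atm-based values the
  literature tabulates (mol/L/atm), and the Pa<->atm conversion is
  centralized in :func:`partial_pressure_atm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UptakeKinetics",
    "GasPhysicalParams",
    "ColumnGeometry",
    "uptake_bound",
    "uptake_bound_co_inhibited",
    "hydrostatic_pressure",
    "gas_holdup",
    "partial_pressure_atm",
    "saturation_concentration",
    "feed_gas_concentrations",
]

#: Universal gas constant, J/(mol K).  The textbook rounding (not the
#: full CODATA value) is used deliberately: it reproduces the tabulated
#: feed gas concentrations (80.64 / 53.76 mmol/L) to their printed
#: precision, which the longer constant does not.
R_SI = 8.314
#: Pascals per standard atmosphere.
PA_PER_ATM = 101325.0
#: Molar mass of CO, g/mmol (used only inside the CO-inhibition terms,
#: whose constants are tabulated in g/L).
M_CO = 0.02801

GAS_ROLES = ("co", "h2", "co2")


@dataclass(frozen=True)
class UptakeKinetics:
    """Monod uptake parameters for the dissolved gases.

    Defaults are the nominal values for *C. ljungdahlii*: maximum uptake
    rates of 35 (CO), 70 (H2) and 35 (CO2) mmol/gDW/h, saturation
    constants of 0.02 mmol/L for all three gases, and a combined
    ethanol+acetate product-inhibition constant of 10 g/L.  The CO
    self/cross inhibition constants default to 1e6 g/L, which makes the
    inhibited form numerically indistinguishable from the base form.
    """

    v_max: dict[str, float] = field(
        default_factory=lambda: {"co": 35.0, "h2": 70.0, "co2": 35.0}
    )
    k_m: dict[str, float] = field(
        default_factory=lambda: {"co": 0.02, "h2": 0.02, "co2": 0.02}
    )
    k_i_product: float = 10.0
    k_i_co_on_co: float = 1.0e6
    k_i_co_on_h2: float = 1.0e6
    co_inhibition: bool = False

    def __post_init__(self) -> None:
        for role in GAS_ROLES:
            if self.v_max[role] < 0 or self.k_m[role] <= 0:
                raise ValueError(f"nonpositive Monod constants for {role!r}")
        if self.k_i_product <= 0 or self.k_i_co_on_co <= 0 or self.k_i_co_on_h2 <= 0:
            raise ValueError("inhibition constants must be positive")


@dataclass(frozen=True)
class ColumnGeometry:
    """Reactor geometry and flow settings.

    length (m), cross-sectional area (m^2), superficial gas velocity u_G
    (m/h), liquid velocity u_L (m/h), liquid axial dispersion D_A (m^2/h).
    """

    length: float = 25.0
    area: float = 5.0
    u_gas: float = 75.0
    u_liquid: float = 0.25
    dispersion: float = 0.25

    def __post_init__(self) -> None:
        if self.length <= 0 or self.area <= 0:
            raise ValueError("column length and area must be positive")
        if self.u_gas < 0 or self.u_liquid < 0 or self.dispersion < 0:
            raise ValueError("velocities and dispersion must be nonnegative")


@dataclass(frozen=True)
class GasPhysicalParams:
    """Henry constants, mass-transfer coefficients, and holdup parameters.

    henry: mol/L/atm per gas role; k_m: gas-liquid mass-transfer
    coefficients (1/h) per role; temperature (K); top-of-column pressure
    (Pa); liquid density (kg/m^3); gravitational acceleration (m/s^2);
    holdup correlation parameters eps_g_max (-) and k_g (m/h).
    """

    henry: dict[str, float] = field(
        default_factory=lambda: {"co": 8.0e-4, "h2": 6.6e-4, "co2": 2.5e-2}
    )
    k_m: dict[str, float] = field(
        default_factory=lambda: {"co": 80.0, "h2": 200.0, "co2": 80.0}
    )
    temperature: float = 310.15
    pressure_top: float = 1.013e5
    rho_liquid: float = 1000.0
    gravity: float = 9.81
    eps_g_max: float = 0.53
    k_g: float = 540.0
    # Convention for the partial pressure entering Henry's law.  The
    # "concentration" mode (p_i = G_i R T) reproduces the tabulated feed
    # saturation values; "local-pressure" uses y_i P(z) instead.
    partial_pressure_mode: str = "concentration"

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.pressure_top <= 0:
            raise ValueError("temperature and pressure must be positive")
        if self.partial_pressure_mode not in ("concentration", "local-pressure"):
            raise ValueError(
                "partial_pressure_mode must be 'concentration' or 'local-pressure'"
            )


def _product_inhibition(ethanol, acetate, k_i: float):
    return 1.0 / (1.0 + (np.asarray(ethanol) + np.asarray(acetate)) / k_i)


def _check_nonneg(**named) -> None:
    for name, value in named.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"negative concentration for {name!r}")


def uptake_bound(concentration, ethanol, acetate, kinetics: UptakeKinetics, role: str):
    """Base inhibited-Monod uptake bound, mmol/gDW/h.

    v = v_max * S / (K_m + S) * 1 / (1 + (E + A) / K_I).  Scalar or
    elementwise over arrays.
    """
    if role not in GAS_ROLES:
        raise KeyError(f"unknown gas role {role!r}")
    _check_nonneg(substrate=concentration, ethanol=ethanol, acetate=acetate)
    s = np.asarray(concentration, dtype=float)
    monod = kinetics.v_max[role] * s / (kinetics.k_m[role] + s)
    out = monod * _product_inhibition(ethanol, acetate, kinetics.k_i_product)
    return float(out) if np.isscalar(concentration) else out


def uptake_bound_co_inhibited(
    co, h2, ethanol, acetate, kinetics: UptakeKinetics
):
    """CO-inhibited uptake bounds for CO and H2 as a pair, mmol/gDW/h.

    CO uptake carries a substrate-inhibition term C^2/K_I,C and H2 uptake
    a cross-inhibition factor 1/(1 + C/K_I,H).  The inhibition constants
    are tabulated in g/L while dissolved CO is carried in mmol/L, so the
    dissolved CO concentration is converted to g/L inside these terms
    only (molar mass 28.01 g/mol).
    """
    _check_nonneg(co=co, h2=h2, ethanol=ethanol, acetate=acetate)
    c = np.asarray(co, dtype=float)
    h = np.asarray(h2, dtype=float)
    c_gl = c * M_CO
    prod = _product_inhibition(ethanol, acetate, kinetics.k_i_product)
    co_bound = (
        kinetics.v_max["co"]
        * c
        / (kinetics.k_m["co"] + c + c * c_gl / kinetics.k_i_co_on_co)
        * prod
    )
    # K_m + S -> 0 only when both are zero, which the Monod numerator kills.
    co_bound = np.where(c > 0, co_bound, 0.0)
    h2_bound = (
        kinetics.v_max["h2"]
        * h
        / (kinetics.k_m["h2"] + h)
        * prod
        / (1.0 + c_gl / kinetics.k_i_co_on_h2)
    )
    if np.isscalar(co) and np.isscalar(h2):
        return float(co_bound), float(h2_bound)
    return co_bound, h2_bound


def gas_uptake_bounds(c_l, h_l, d_l, e_l, a_l, kinetics: UptakeKinetics):
    """Uptake bounds (CO, H2, CO2) from local liquid-phase concentrations.

    Dispatches to the CO-inhibited pair when ``kinetics.co_inhibition``
    is set; CO2 always uses the base form.
    """
    if kinetics.co_inhibition:
        b_co, b_h2 = uptake_bound_co_inhibited(c_l, h_l, e_l, a_l, kinetics)
    else:
        b_co = uptake_bound(c_l, e_l, a_l, kinetics, "co")
        b_h2 = uptake_bound(h_l, e_l, a_l, kinetics, "h2")
    b_co2 = uptake_bound(d_l, e_l, a_l, kinetics, "co2")
    return b_co, b_h2, b_co2


def hydrostatic_pressure(z, geometry: ColumnGeometry, params: GasPhysicalParams):
    """Pressure (Pa) at height z (m) from the liquid head above it."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > geometry.length):
        raise ValueError("z outside the column")
    p = params.pressure_top + params.rho_liquid * params.gravity * (geometry.length - z)
    return float(p) if p.ndim == 0 else p


def gas_holdup(u_gas: float, params: GasPhysicalParams) -> float:
    """Gas volume fraction from the fitted holdup correlation.

    eps_G = eps_G,max * u_G / (K_G + u_G); saturates at eps_G,max.
    """
    if u_gas < 0:
        raise ValueError("superficial gas velocity must be nonnegative")
    return params.eps_g_max * u_gas / (params.k_g + u_gas)


def partial_pressure_atm(gas_concentration, temperature: float):
    """Ideal-gas partial pressure (atm) from concentration (mmol/L)."""
    g = np.asarray(gas_concentration, dtype=float)
    return g * R_SI * temperature / PA_PER_ATM


def saturation_concentration(gas_concentration, henry: float, temperature: float):
    """Henry's-law dissolved saturation concentration (mmol/L).

    p_i = G_i R T (ideal gas); C* = H_i p_i, with H_i in mol/L/atm.
    """
    if np.any(np.asarray(gas_concentration) < 0):
        raise ValueError("negative gas-phase concentration")
    p_atm = partial_pressure_atm(gas_concentration, temperature)
    out = henry * p_atm * 1000.0  # mol/L -> mmol/L
    return float(out) if np.isscalar(gas_concentration) else out


def feed_gas_concentrations(
    x_co: float,
    x_h2: float,
    x_co2: float,
    geometry: ColumnGeometry,
    params: GasPhysicalParams,
) -> dict[str, float]:
    """Feed gas-phase concentrations (mmol/L) at bottom-of-column pressure.

    The total molar concentration is P(0)/(R T) with P(0) from the
    hydrostatic profile; species concentrations are mole-fraction shares.
    """
    fractions = {"co": x_co, "h2": x_h2, "co2": x_co2}
    for role, x in fractions.items():
        if x < 0:
            raise ValueError(f"negative mole fraction for {role!r}")
    if abs(sum(fractions.values()) - 1.0) > 1e-12:
        raise ValueError(
            f"feed mole fractions sum to {sum(fractions.values())!r}, expected 1"
        )
    p0 = hydrostatic_pressure(0.0, geometry, params)
    total = p0 / (R_SI * params.temperature)  # mol/m^3 == mmol/L
    return {role: x * total for role, x in fractions.items()}
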