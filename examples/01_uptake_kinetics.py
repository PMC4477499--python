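"""Monod uptake bounds and the gas-phase closures of the column model.

Evaluates the inhibited Monod uptake expression at the saturated
dissolved-gas concentrations of the nominal reactor, the hydrostatic
pressure profile, the gas holdup correlation, and the ideal-gas feed
concentrations.
"""

from syncol import (
    ColumnGeometry,
    GasPhysicalParams,
    UptakeKinetics,
    feed_gas_concentrations,
    gas_holdup,
    hydrostatic_pressure,
    saturation_concentration,
    uptake_bound,
)

kin = UptakeKinetics()
geo = ColumnGeometry()
gas = GasPhysicalParams()

print("Bottom-of-column pressure P(0) = %.4g Pa (top %.4g Pa)" % (
    hydrostatic_pressure(0.0, geo, gas), gas.pressure_top))
print("Gas holdup at u_G = %g m/h: eps_G = %.4f" % (geo.u_gas, gas_holdup(geo.u_gas, gas)))

feed = feed_gas_concentrations(0.6, 0.4, 0.0, geo, gas)
print("Feed gas concentrations (ideal gas at P(0)): CO %.2f, H2 %.2f mmol/L"
      % (feed["co"], feed["h2"]))

c_sat = saturation_concentration(feed["co"], gas.henry["co"], gas.temperature)
h_sat = saturation_concentration(feed["h2"], gas.henry["h2"], gas.temperature)
print("Henry's-law saturated liquid: CO %.3f, H2 %.3f mmol/L" % (c_sat, h_sat))

v_clean = uptake_bound(c_sat, 0.0, 0.0, kin, "co")
v_inhib = uptake_bound(c_sat, 20.0, 20.0, kin, "co")
print("CO uptake bound at saturation: %.2f mmol/gDW/h (clean medium)" % v_clean)
print("  ... with 20 g/L ethanol + 20 g/L acetate: %.2f mmol/gDW/h" % v_inhib)
print("The product-inhibition factor 1/(1+(E+A)/K_I) throttles uptake as")
print("titers approach and exceed K_I = %g g/L." % kin.k_i_product)
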