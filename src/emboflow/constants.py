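"""Built-in physical constants and published model coefficients.

The Sisko coefficients shipped here are the published fits for the two
non-adhesive embolic agents studied at laboratory (20 °C) and physiological
(37 °C) temperature.  Units: ``mu0`` and ``k`` in mPa·s (centipoise); ``n``
dimensionless.  The carrier solvent of both agents is DMSO (>90 % of the
liquid phase), so DMSO thermal properties are used for the catheter
heat-transfer model.
"""

from __future__ import annotations

from .rheology import SiskoParams, TemperatureViscosityLaw

CAL_TO_J = 4.184

#: DMSO-dominated liquid-phase properties.
DMSO_DENSITY_KG_M3 = 1100.0
DMSO_CONDUCTIVITY_W_M_K = 0.2
DMSO_SPECIFIC_HEAT_CAL_G_C = 0.47
DMSO_SPECIFIC_HEAT_J_KG_K = DMSO_SPECIFIC_HEAT_CAL_G_C * CAL_TO_J * 1000.0

#: Fully developed laminar Nusselt number, constant-wall-temperature tube.
NUSSELT_LAMINAR_CONST_WALL_T = 3.66

#: Clinical delivery rate used throughout the default scenarios, m^3/s.
DEFAULT_INFLOW_M3_S = 0.6e-6 / 60.0  # 0.6 mL/min

#: 6 Fr catheter lumen diameter used for the velocity/Reynolds scenarios, m.
CATHETER_LUMEN_6FR_M = 2.0e-3
#: Narrow microcatheter lumen used for the thermal scenarios, m.
CATHETER_LUMEN_MICRO_M = 1.0e-3

LAB_TEMPERATURE_C = 20.0
BODY_TEMPERATURE_C = 37.0

ONYX18_20C = SiskoParams(
    mu0=31.6187, k=1.80968, n=-0.004368, temperature=20.0, polymer_label="Onyx-18"
)
ONYX18_37C = SiskoParams(
    mu0=18.0138, k=3.17306, n=0.271126, temperature=37.0, polymer_label="Onyx-18"
)
SQUID12_20C = SiskoParams(
    mu0=19.4711, k=2.9736, n=-0.03329, temperature=20.0, polymer_label="Squid-12"
)
SQUID12_37C = SiskoParams(
    mu0=12.1248, k=1.10875, n=-0.5586, temperature=37.0, polymer_label="Squid-12"
)

#: All published parameter sets keyed by (polymer, temperature °C).
SISKO_REGISTRY: dict[tuple[str, float], SiskoParams] = {
    ("Onyx-18", 20.0): ONYX18_20C,
    ("Onyx-18", 37.0): ONYX18_37C,
    ("Squid-12", 20.0): SQUID12_20C,
    ("Squid-12", 37.0): SQUID12_37C,
}

ONYX18_LAW = TemperatureViscosityLaw(params_cold=ONYX18_20C, params_warm=ONYX18_37C)
SQUID12_LAW = TemperatureViscosityLaw(params_cold=SQUID12_20C, params_warm=SQUID12_37C)

TEMPERATURE_LAWS: dict[str, TemperatureViscosityLaw] = {
    "Onyx-18": ONYX18_LAW,
    "Squid-12": SQUID12_LAW,
}

# Plausible coefficients for the same agents when the radiopaque tantalum
# powder has settled out (vial not agitated).  Synthetic stand-ins, not
# measured values: chosen so the unmixed curve departs from the mixed one
# mainly below 1 1/s, the qualitative signature seen experimentally.
ONYX18_20C_UNMIXED = SiskoParams(
    mu0=28.0, k=6.0, n=-0.30, temperature=20.0, polymer_label="Onyx-18-unmixed"
)
SQUID12_20C_UNMIXED = SiskoParams(
    mu0=17.5, k=5.5, n=-0.25, temperature=20.0, polymer_label="Squid-12-unmixed"
)

UNMIXED_REGISTRY: dict[tuple[str, float], SiskoParams] = {
    ("Onyx-18", 20.0): ONYX18_20C_UNMIXED,
    ("Squid-12", 20.0): SQUID12_20C_UNMIXED,
}
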