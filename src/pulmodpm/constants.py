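"""Physical constants and unit conventions.

Internal unit conventions (see docs/methods.md):

* pressures        mmHg
* volumes          ml (BTPS for gas spaces)
* flows            ml/s inside the solver, ml/min or L/min at API boundaries
* gas amounts      ml STPD
* concentrations   ml STPD gas per ml (of BTPS gas space, or of blood)
* diffusing capacity D_L  ml/(mmHg*min)
"""

#: mmHg of partial pressure per unit gas concentration (ml STPD / ml BTPS).
#: P = C * RT_BTPS converts an alveolar/airway concentration to partial
#: pressure at body temperature (310 K) and ambient pressure, i.e. the
#: familiar factor 863 = 760 * 310 / 273 of the alveolar gas equation.
RT_BTPS = 863.0

#: Water vapour pressure at 37 C, mmHg.
P_H2O = 47.0

#: Standard sea-level barometric pressure, mmHg.
P_BAROMETRIC = 760.0

#: Dry-air O2 fraction.
FIO2_AIR = 0.2094

SECONDS_PER_MINUTE = 60.0


def inspired_concentration(fraction: float, barometric_mmhg: float = P_BAROMETRIC) -> float:
    """Tracheal (humidified) gas concentration for a dry inspired fraction.

    Inspired gas is warmed and saturated with water vapour, so the partial
    pressure entering the trachea is ``fraction * (Pb - 47)`` and the
    concentration in ml STPD per ml BTPS is that over 863.
    """
    return fraction * (barometric_mmhg - P_H2O) / RT_BTPS
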