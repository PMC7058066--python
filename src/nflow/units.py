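"""Unit handling for activity x parameter products.

The budget's canonical unit is Gg N y-1 (1 Gg = 1e9 g = 1e6 kg = 1e3 t).
Every evaluated term must reduce to it through this small declared conversion
table; unknown units fail loudly because silent unit slips are the dominant
failure mode in element budgets.

Activity units are either masses (t, kt, Mt, kg, Gg) or dimensionless
carriers (capita, head, ha, km2, ...). Parameter units are either

* ``"<mass>/<carrier>"`` -- e.g. ``kg/t`` (emission factor), ``kg/capita``
  (excretion rate), ``kg/ha`` (areal fixation rate); the activity's unit must
  convert to the factor's carrier; or
* ``"1"`` -- a dimensionless multiplier applied to an activity that already
  is a nitrogen mass (e.g. ammonia-N production in kt).
"""

from __future__ import annotations

from .errors import UnitError

#: mass unit -> Gg per unit
MASS_TO_GG: dict[str, float] = {
    "g": 1e-9,
    "kg": 1e-6,
    "t": 1e-3,
    "kt": 1.0,
    "Mt": 1e3,
    "Gg": 1.0,
}

#: carrier unit -> (base carrier, base units per unit)
CARRIER_TO_BASE: dict[str, tuple[str, float]] = {
    "t": ("t", 1.0),
    "kt": ("t", 1e3),
    "Mt": ("t", 1e6),
    "capita": ("capita", 1.0),
    "head": ("head", 1.0),
    "ha": ("ha", 1.0),
    "km2": ("ha", 100.0),
    "m3": ("m3", 1.0),
    "Mm3": ("m3", 1e6),
    "1": ("1", 1.0),
}

DIMENSIONLESS = ("1", "fraction", "")


def term_to_gg(amount: float, activity_unit: str, value: float, parameter_unit: str) -> float:
    """Convert one activity x parameter product to Gg N.

    Raises :class:`UnitError` naming the offending unit when the product does
    not reduce to a nitrogen mass.
    """
    p_unit = parameter_unit.strip()
    a_unit = activity_unit.strip()
    if p_unit in DIMENSIONLESS:
        # parameter is a pure ratio: the activity itself must be an N mass
        if a_unit not in MASS_TO_GG:
            raise UnitError(
                f"dimensionless parameter requires a mass-valued activity, "
                f"got activity unit {a_unit!r}"
            )
        return amount * MASS_TO_GG[a_unit] * value
    if "/" not in p_unit:
        raise UnitError(
            f"cannot interpret parameter unit {p_unit!r}: expected '<mass>/<carrier>' or '1'"
        )
    mass_part, carrier_part = (s.strip() for s in p_unit.split("/", 1))
    if mass_part not in MASS_TO_GG:
        raise UnitError(f"unknown mass unit {mass_part!r} in parameter unit {p_unit!r}")
    if carrier_part not in CARRIER_TO_BASE:
        raise UnitError(f"unknown carrier unit {carrier_part!r} in parameter unit {p_unit!r}")
    if a_unit not in CARRIER_TO_BASE:
        raise UnitError(f"unknown activity unit {a_unit!r}")
    a_base, a_scale = CARRIER_TO_BASE[a_unit]
    p_base, p_scale = CARRIER_TO_BASE[carrier_part]
    if a_base != p_base:
        raise UnitError(
            f"activity unit {a_unit!r} is not commensurable with factor carrier "
            f"{carrier_part!r}"
        )
    # activity in factor-carrier units, times factor, gives mass in mass_part units
    mass = amount * (a_scale / p_scale) * value
    return mass * MASS_TO_GG[mass_part]
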