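"""Concentration units and exact power-of-ten conversions.

Two dimension families are supported: mass per volume of water
(``mg/L``, ``ug/L``, ``ng/L``) and mass per mass of soil (``mg/kg``,
``ug/kg``, ``ng/kg``).  Conversions within a family are exact powers of
ten; conversions across families are refused.
"""

from __future__ import annotations

from .errors import UnitError

# decimal exponent relative to grams per litre / kilogram; conversions use
# exponent arithmetic so factors are exact powers of ten
_PER_VOLUME = {"g/L": 0, "mg/L": -3, "ug/L": -6, "ng/L": -9}
_PER_MASS = {"g/kg": 0, "mg/kg": -3, "ug/kg": -6, "ng/kg": -9}

_ALIASES = {"µg/L": "ug/L", "μg/L": "ug/L", "µg/kg": "ug/kg", "μg/kg": "ug/kg"}


def canonical(unit: str) -> str:
    unit = _ALIASES.get(unit, unit)
    if unit not in _PER_VOLUME and unit not in _PER_MASS:
        raise UnitError(f"unknown concentration unit {unit!r}")
    return unit


def family(unit: str) -> str:
    unit = canonical(unit)
    return "per_volume" if unit in _PER_VOLUME else "per_mass"


def conversion_factor(src: str, dst: str) -> float:
    """Multiplier converting a value in ``src`` to ``dst`` (exact power of ten)."""
    src, dst = canonical(src), canonical(dst)
    if family(src) != family(dst):
        raise UnitError(f"cannot convert {src} (per {family(src)}) to {dst}")
    table = _PER_VOLUME if family(src) == "per_volume" else _PER_MASS
    return 10.0 ** (table[src] - table[dst])


# one metric tonne expressed in nanograms (used by the PEC formulas)
NG_PER_TONNE = 1e15
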