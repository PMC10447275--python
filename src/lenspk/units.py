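"""Unit parsing and normalization.

Every quantity inside the package lives in one internal system:
length cm, volume mL (= cm^3), time s, mass ng.  Derived units follow
(flows mL/s, permeabilities cm/s, diffusivities cm^2/s, concentrations
ng/mL, rates ng/s).  Input files and the printed literature values mix
µl/min, mL/min, hours and percent; everything is converted exactly once,
on the way in.

Tissue concentrations quoted per gram (ng/g) are treated as ng/mL under
an assumed tissue density of 1 g/mL.
"""

from __future__ import annotations

import re
from typing import Union

Number = Union[int, float]


class UnitError(ValueError):
    """Raised for an unknown or dimensionally wrong unit tag."""


# Base-unit scale factors (value in tagged unit -> value in internal unit).
_LENGTH = {"cm": 1.0, "mm": 0.1, "um": 1e-4, "µm": 1e-4, "m": 100.0}
_AREA = {"cm2": 1.0, "cm^2": 1.0, "mm2": 0.01, "mm^2": 0.01}
_VOLUME = {"ml": 1.0, "ul": 1e-3, "µl": 1e-3, "l": 1e3, "cm3": 1.0, "cm^3": 1.0}
_TIME = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0,
         "day": 86400.0, "d": 86400.0}
_MASS = {"ng": 1.0, "ug": 1e3, "µg": 1e3, "mg": 1e6, "g": 1e9}

# ng/g aliases ng/mL: density 1 g/mL for every tissue.
_CONC_DENOM = {"ml": 1.0, "g": 1.0, "ul": 1e-3, "l": 1e3}


def _ratio(num: dict, den: dict) -> dict:
    out = {}
    for nu, nf in num.items():
        for du, df in den.items():
            out[f"{nu}/{du}"] = nf / df
    return out


_FACTORS = {
    "length": _LENGTH,
    "area": _AREA,
    "volume": _VOLUME,
    "time": _TIME,
    "mass": _MASS,
    "flow": _ratio(_VOLUME, _TIME),
    "velocity": _ratio(_LENGTH, _TIME),          # permeability cm/s
    "diffusivity": _ratio({"cm2": 1.0, "cm^2": 1.0, "m2": 1e4, "mm2": 1e-2}, _TIME),
    "concentration": _ratio(_MASS, _CONC_DENOM),
    "rate": _ratio(_MASS, _TIME),
}

# Internal (canonical) tag per kind, used when rendering back out.
INTERNAL_UNIT = {
    "length": "cm", "area": "cm2", "volume": "mL", "time": "s", "mass": "ng",
    "flow": "mL/s", "velocity": "cm/s", "diffusivity": "cm2/s",
    "concentration": "ng/mL", "rate": "ng/s",
    "dimensionless": "-", "fraction": "-", "integer": "-",
}

_QUANTITY_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(.*?)\s*$")


def _canon(tag: str) -> str:
    tag = tag.strip().replace(" ", "")
    tag = tag.replace("μ", "u").replace("µ", "u")
    return tag.lower()


def parse_quantity(value: Union[str, Number], kind: str) -> float:
    """Convert ``value`` to the internal unit system.

    Parameters
    ----------
    value : str or number
        Either a bare number (assumed already internal) or a string of
        the form ``"4.2 uL/min"``.
    kind : str
        Dimension of the quantity (``"flow"``, ``"velocity"``, ...).

    Returns
    -------
    float
        The value expressed in {cm, mL, s, ng}.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _QUANTITY_RE.match(str(value))
    if not m:
        raise UnitError(f"cannot parse quantity {value!r}")
    num = float(m.group(1))
    tag = _canon(m.group(2))

    if kind in ("dimensionless", "integer"):
        if tag in ("", "-", "1"):
            return num
        raise UnitError(f"unexpected unit {m.group(2)!r} on dimensionless quantity")
    if kind == "fraction":
        if tag == "%":
            return num / 100.0
        if tag in ("", "-", "1"):
            return num
        raise UnitError(f"unknown fraction unit {m.group(2)!r}")

    try:
        factors = _FACTORS[kind]
    except KeyError:
        raise UnitError(f"unknown quantity kind {kind!r}") from None
    if tag == "":
        return num  # bare number: already internal
    if tag not in factors:
        raise UnitError(f"unknown unit {m.group(2)!r} for kind {kind!r}")
    return num * factors[tag]


def convert_from_internal(value: float, kind: str, unit: str) -> float:
    """Express an internal-system ``value`` in the given printed unit."""
    tag = _canon(unit)
    if kind == "fraction":
        return value * 100.0 if tag == "%" else value
    if kind in ("dimensionless", "integer"):
        return value
    factors = _FACTORS[kind]
    if tag not in factors:
        raise UnitError(f"unknown unit {unit!r} for kind {kind!r}")
    return value / factors[tag]
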