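"""Model parameters: definition, unit normalization, validation, presets.

The simulator couples a drug-eluting soft contact lens (SCL) to a
lumped-compartment description of the rabbit eye: tears, sclera-choroid,
retina, vitreous humor and aqueous humor, with the corneal epithelium as
a purely diagnostic equilibrium compartment.  Two source descriptions
are supported:

``diffusion``
    The lens is an explicit 1-D diffusion slab (thickness H, diffusivity
    D_SCL, partition coefficient K_SCL) exchanging with tears at its
    anterior face and with the aqueous humor across the cornea at its
    posterior face.

``release``
    The lens is replaced by a measured in-vitro release curve
    f(t) = M_Released (1 - exp(-t/T)); a fraction F of the release rate
    enters the aqueous humor and (1 - F) enters the tears.

All values are stored in the internal unit system {cm, mL, s, ng};
:func:`normalize_units` is the single entry point for unit-tagged input.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field, fields
from typing import Optional, Union

from .units import UnitError, parse_quantity, convert_from_internal

__all__ = [
    "AnatomyParams", "PhysiologyParams", "DrugParams", "LensParams",
    "ReleaseSource", "SolverSettings", "ModelParameters", "Diagnostic",
    "normalize_units", "validate", "rabbit_dexamethasone",
    "derive_p_ret_vit", "params_hash", "to_printed",
    "get_param", "set_param", "scale_param",
]


@dataclass
class AnatomyParams:
    """Anatomical volumes (mL) and exposed areas (cm^2)."""
    V_t: float
    V_Vit: float
    V_ScCh: float
    V_Ret: float
    V_Aq: float
    A_Globe: float
    A_Palp: float
    A_Bulb: float
    # No rabbit values are printed in the source tables for the next two;
    # the defaults are suggested working values, not literature data.
    A_Cornea: float = 2.0
    A_SCL: float = 2.27


@dataclass
class PhysiologyParams:
    """Ocular flows and clearances (mL/s)."""
    Q_UvSc: float
    Q_Vit_Aq: float
    Q_Aq: float
    Q_Drain: float
    Clearance_ScCh: float


@dataclass
class DrugParams:
    """Drug-tissue partition coefficients (-), permeabilities (cm/s) and
    aqueous bioavailability F (fraction of released dose)."""
    K_t: float = 1.0
    K_Aq: float = 1.0
    K_Vit: float = 1.0
    K_ScCh: float = 1.0
    K_Ret: float = 1.0
    K_SCL: Optional[float] = None
    K_Ep_Aq: Optional[float] = None
    K_Ep_t: Optional[float] = None
    P_Conj: float = 0.0
    P_ScCh_Ret: float = 0.0
    P_Ret_Vit: float = 0.0
    P_t_Aq: Optional[float] = None
    F: Optional[float] = None


@dataclass
class LensParams:
    """Geometry and transport of the diffusion-mode lens slab."""
    H: float
    D_SCL: float
    C0_SCL: float
    n_nodes: int = 50


@dataclass
class ReleaseSource:
    """Exponential release-curve description, f(t) = M (1 - exp(-t/T))."""
    M_Released: float
    T: float


@dataclass
class SolverSettings:
    """Integration horizon and tolerances.

    The tears compartment (V_t = 7e-3 mL against a drainage of
    ~8e-6 mL/s) makes the system stiff on a multi-day horizon, hence the
    tight default tolerances and the implicit integrator downstream.
    """
    t_end: float = 604800.0       # 7 days
    output_step: float = 600.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12
    seed: int = 0


@dataclass
class ModelParameters:
    anatomy: AnatomyParams
    physiology: PhysiologyParams
    drug: DrugParams
    mode: str = "release"                       # "diffusion" | "release"
    lens: Optional[LensParams] = None
    release: Optional[ReleaseSource] = None
    solver: SolverSettings = field(default_factory=SolverSettings)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


@dataclass
class Diagnostic:
    level: str      # "fatal" | "warning"
    key: str
    message: str

    @property
    def fatal(self) -> bool:
        return self.level == "fatal"


# --------------------------------------------------------------------------
# Key registry: symbol -> (section, field, dimension kind, printed unit)
# --------------------------------------------------------------------------

KEY_REGISTRY = {
    "V_t": ("anatomy", "V_t", "volume", "mL"),
    "V_Vit": ("anatomy", "V_Vit", "volume", "mL"),
    "V_ScCh": ("anatomy", "V_ScCh", "volume", "mL"),
    "V_Ret": ("anatomy", "V_Ret", "volume", "mL"),
    "V_Aq": ("anatomy", "V_Aq", "volume", "mL"),
    "A_Globe": ("anatomy", "A_Globe", "area", "cm2"),
    "A_Palp": ("anatomy", "A_Palp", "area", "cm2"),
    "A_Bulb": ("anatomy", "A_Bulb", "area", "cm2"),
    "A_Cornea": ("anatomy", "A_Cornea", "area", "cm2"),
    "A_SCL": ("anatomy", "A_SCL", "area", "cm2"),
    "Q_UvSc": ("physiology", "Q_UvSc", "flow", "uL/min"),
    "Q_Vit_Aq": ("physiology", "Q_Vit_Aq", "flow", "uL/min"),
    "Q_Aq": ("physiology", "Q_Aq", "flow", "uL/min"),
    "Q_Drain": ("physiology", "Q_Drain", "flow", "uL/min"),
    "Clearance_ScCh": ("physiology", "Clearance_ScCh", "flow", "mL/min"),
    "K_t": ("drug", "K_t", "dimensionless", "-"),
    "K_Aq": ("drug", "K_Aq", "dimensionless", "-"),
    "K_Vit": ("drug", "K_Vit", "dimensionless", "-"),
    "K_ScCh": ("drug", "K_ScCh", "dimensionless", "-"),
    "K_Ret": ("drug", "K_Ret", "dimensionless", "-"),
    "K_SCL": ("drug", "K_SCL", "dimensionless", "-"),
    "K_Ep_Aq": ("drug", "K_Ep_Aq", "dimensionless", "-"),
    "K_Ep_t": ("drug", "K_Ep_t", "dimensionless", "-"),
    "P_Conj": ("drug", "P_Conj", "velocity", "cm/s"),
    "P_ScCh_Ret": ("drug", "P_ScCh_Ret", "velocity", "cm/s"),
    "P_Ret_Vit": ("drug", "P_Ret_Vit", "velocity", "cm/s"),
    "P_t_Aq": ("drug", "P_t_Aq", "velocity", "cm/s"),
    "F": ("drug", "F", "fraction", "%"),
    "H": ("lens", "H", "length", "cm"),
    "D_SCL": ("lens", "D_SCL", "diffusivity", "cm2/s"),
    "C0_SCL": ("lens", "C0_SCL", "concentration", "ng/mL"),
    "n_nodes": ("lens", "n_nodes", "integer", "-"),
    "M_Released": ("release", "M_Released", "mass", "ng"),
    "T": ("release", "T", "time", "s"),
    "t_end": ("solver", "t_end", "time", "s"),
    "output_step": ("solver", "output_step", "time", "s"),
    "rel_tol": ("solver", "rel_tol", "dimensionless", "-"),
    "abs_tol": ("solver", "abs_tol", "dimensionless", "-"),
    "seed": ("solver", "seed", "integer", "-"),
}

_SECTION_CLS = {
    "anatomy": AnatomyParams,
    "physiology": PhysiologyParams,
    "drug": DrugParams,
    "lens": LensParams,
    "release": ReleaseSource,
    "solver": SolverSettings,
}

_REQUIRED = {
    "common": ["V_t", "V_Vit", "V_ScCh", "V_Ret", "V_Aq",
               "A_Globe", "A_Palp", "A_Bulb",
               "Q_UvSc", "Q_Vit_Aq", "Q_Aq", "Q_Drain", "Clearance_ScCh"],
    "diffusion": ["H", "D_SCL", "C0_SCL", "K_SCL", "P_t_Aq"],
    "release": ["M_Released", "T", "F"],
}


def normalize_units(raw: Union[dict, ModelParameters],
                    mode: Optional[str] = None) -> ModelParameters:
    """Build a :class:`ModelParameters` from a raw parameter map.

    ``raw`` may be flat ({symbol: value}) or nested by section
    ({"anatomy": {...}, ...}); values may be bare numbers (taken as
    already internal) or strings carrying a unit tag ("4.2 uL/min").
    Passing an already-built :class:`ModelParameters` returns a copy
    unchanged, so the operation is idempotent.
    """
    if isinstance(raw, ModelParameters):
        return raw.copy()

    flat: dict = {}
    nested_sections = set(_SECTION_CLS)
    for key, val in raw.items():
        if key == "mode":
            if mode is None:
                mode = val
            continue
        if key in nested_sections and isinstance(val, dict):
            flat.update(val)
        else:
            flat[key] = val
    mode = mode or "release"
    if mode not in ("diffusion", "release"):
        raise ValueError(f"unknown mode {mode!r}")

    required = _REQUIRED["common"] + _REQUIRED[mode]
    missing = [k for k in required if k not in flat]
    if missing:
        raise KeyError(
            f"missing required parameter(s) for mode={mode}: {', '.join(missing)}")

    sections: dict = {name: {} for name in _SECTION_CLS}
    for key, val in flat.items():
        if key not in KEY_REGISTRY:
            raise KeyError(f"unknown parameter key {key!r}")
        section, fname, kind, _ = KEY_REGISTRY[key]
        try:
            norm = parse_quantity(val, kind)
        except UnitError as exc:
            raise UnitError(f"{key}: {exc}") from None
        if kind == "integer":
            norm = int(round(norm))
        sections[section][fname] = norm

    params = ModelParameters(
        anatomy=AnatomyParams(**sections["anatomy"]),
        physiology=PhysiologyParams(**sections["physiology"]),
        drug=DrugParams(**sections["drug"]),
        mode=mode,
        lens=LensParams(**sections["lens"]) if sections["lens"] else None,
        release=ReleaseSource(**sections["release"]) if sections["release"] else None,
        solver=SolverSettings(**sections["solver"]),
    )
    return params


def validate(params: ModelParameters) -> list:
    """Check a unit-normalized parameter set; returns a list of
    :class:`Diagnostic` (empty on a clean physiological set).

    Sign violations and mode/source mismatches are fatal; physiological
    plausibility checks (e.g. uveoscleral outflow exceeding total
    aqueous turnover) only warn.
    """
    diags: list = []

    def fatal(key, msg):
        diags.append(Diagnostic("fatal", key, msg))

    def warn(key, msg):
        diags.append(Diagnostic("warning", key, msg))

    a, ph, d = params.anatomy, params.physiology, params.drug
    for f in fields(a):
        v = getattr(a, f.name)
        if not (v > 0) or not math.isfinite(v):
            fatal(f.name, f"anatomical quantity {f.name} must be strictly "
                          f"positive, got {v}")
    for f in fields(ph):
        v = getattr(ph, f.name)
        if v < 0 or not math.isfinite(v):
            fatal(f.name, f"flow {f.name} must be non-negative, got {v}")
    for f in fields(d):
        v = getattr(d, f.name)
        if v is None:
            continue
        if f.name.startswith("K_") and not v > 0:
            fatal(f.name, f"partition coefficient {f.name} must be > 0, got {v}")
        if f.name.startswith("P_") and v < 0:
            fatal(f.name, f"permeability {f.name} must be >= 0, got {v}")
    if d.F is not None and not (0.0 <= d.F <= 1.0):
        fatal("F", f"bioavailability F must lie in [0, 1], got {d.F}")

    if params.mode == "diffusion":
        if params.lens is None:
            fatal("lens", "mode=diffusion requires lens parameters")
        else:
            L = params.lens
            if L.H <= 0:
                fatal("H", f"lens thickness must be > 0, got {L.H}")
            if L.D_SCL <= 0:
                fatal("D_SCL", f"lens diffusivity must be > 0, got {L.D_SCL}")
            if L.C0_SCL < 0:
                fatal("C0_SCL", f"initial loading must be >= 0, got {L.C0_SCL}")
            if L.n_nodes < 3:
                fatal("n_nodes", f"need at least 3 grid nodes, got {L.n_nodes}")
        if d.K_SCL is None:
            fatal("K_SCL", "mode=diffusion requires K_SCL")
        if d.P_t_Aq is None:
            fatal("P_t_Aq", "mode=diffusion requires P_t_Aq")
    else:
        if params.release is None:
            fatal("release", "mode=release requires a release source (M_Released, T)")
        else:
            if params.release.M_Released <= 0:
                fatal("M_Released", "released mass must be > 0")
            if params.release.T <= 0:
                fatal("T", "release time constant must be > 0")
        if d.F is None:
            fatal("F", "mode=release requires the aqueous bioavailability F")

    s = params.solver
    if s.t_end <= 0:
        fatal("t_end", "t_end must be > 0")
    if s.output_step <= 0:
        fatal("output_step", "output_step must be > 0")
    if s.rel_tol <= 0 or s.abs_tol <= 0:
        fatal("rel_tol", "solver tolerances must be > 0")

    # warn-only physiological plausibility
    if not diags:
        if ph.Q_UvSc > ph.Q_Aq:
            warn("Q_UvSc", "uveoscleral outflow exceeds total aqueous "
                           "turnover Q_Aq; it is normally a fraction of it")
        if a.A_SCL < a.A_Cornea:
            warn("A_SCL", "lens area smaller than corneal area")
        if not (a.V_t < a.V_Aq < a.V_Vit):
            warn("V_t", "expected V_t < V_Aq < V_Vit for a physiological eye")
    return diags


def derive_p_ret_vit(p_scch_ret: float, fraction_higher: float = 0.30) -> float:
    """Inner-limiting-membrane permeability derived from the retinal
    pigment epithelium permeability.

    The ILM is a weaker barrier than the RPE; its permeability is taken
    a fixed fraction (default 30%) higher than ``p_scch_ret``.
    """
    return p_scch_ret * (1.0 + fraction_higher)


# --------------------------------------------------------------------------
# Rabbit / dexamethasone preset
# --------------------------------------------------------------------------

#: Literature parameter set for dexamethasone delivered to the rabbit eye,
#: written with the units in which the values are reported.
RABBIT_DEXAMETHASONE_PRINTED = {
    "mode": "release",
    # anatomy
    "V_t": "7E-03 mL",
    "V_Vit": "1.7 mL",
    "V_ScCh": "0.361 mL",
    "V_Ret": "0.086 mL",
    "V_Aq": "0.325 mL",
    "A_Globe": "8.6 cm2",
    "A_Palp": "14 cm2",
    "A_Bulb": "3 cm2",
    # suggested working values; no rabbit value is reported
    "A_Cornea": "2.0 cm2",
    "A_SCL": "2.27 cm2",
    # physiology
    "Q_UvSc": "0.176 uL/min",
    "Q_Vit_Aq": "0.19 uL/min",
    "Q_Aq": "4.2 uL/min",
    "Q_Drain": "0.5 uL/min",
    "Clearance_ScCh": "1 mL/min",
    # drug
    "K_t": 1, "K_Aq": 1, "K_Vit": 1,
    "K_ScCh": 15, "K_Ret": 10,
    "P_Conj": "2.50E-06 cm/s",
    "P_ScCh_Ret": "10E-06 cm/s",
    "F": "2.08 %",
    # release curve: representative sandwich-lens values (the study lens
    # releases ~200 ug of dexamethasone over about a week); chosen here,
    # not literature data.
    "M_Released": "2.0E05 ng",
    "T": "2 day",
}
# ILM permeability: 30% higher than the RPE value.
RABBIT_DEXAMETHASONE_PRINTED["P_Ret_Vit"] = "%.6G cm/s" % derive_p_ret_vit(10e-6)


def rabbit_dexamethasone() -> ModelParameters:
    """Release-mode rabbit/dexamethasone validation parameter set,
    unit-normalized.  Deterministic: identical across calls."""
    return normalize_units(RABBIT_DEXAMETHASONE_PRINTED)


def rabbit_diffusion_demo() -> ModelParameters:
    """Diffusion-mode demonstration set: rabbit anatomy/physiology with a
    plausible weekly dexamethasone lens.

    The lens values (H = 100 um, D_SCL = 1e-9 cm^2/s, K_SCL = 20,
    P_t_Aq = 1e-5 cm/s, ~200 ug load) are working choices for
    demonstration and testing; they are not literature data.  P_t_Aq sits
    inside the 2-25e-6 cm/s span reported ex vivo for dexamethasone
    across the cornea.
    """
    raw = {k: v for k, v in RABBIT_DEXAMETHASONE_PRINTED.items()
           if k not in ("mode", "M_Released", "T", "F")}
    raw.update({
        "mode": "diffusion",
        "H": "0.01 cm",
        "D_SCL": "1e-9 cm2/s",
        "C0_SCL": "8.8e6 ng/mL",   # ~200 ug over H * A_SCL
        "n_nodes": 50,
        "K_SCL": 20,
        "P_t_Aq": "1e-5 cm/s",
    })
    return normalize_units(raw)


# --------------------------------------------------------------------------
# Serialization helpers
# --------------------------------------------------------------------------

def to_flat_dict(params: ModelParameters) -> dict:
    """Flatten to {symbol: internal value}, skipping absent fields."""
    out: dict = {"mode": params.mode}
    for key, (section, fname, _, _) in KEY_REGISTRY.items():
        obj = getattr(params, section)
        if obj is None:
            continue
        val = getattr(obj, fname)
        if val is not None:
            out[key] = val
    return out


def to_printed(params: ModelParameters) -> dict:
    """Render back to the printed units ({symbol: (value, unit)})."""
    out = {}
    for key, val in to_flat_dict(params).items():
        if key == "mode":
            continue
        _, _, kind, unit = KEY_REGISTRY[key]
        out[key] = (convert_from_internal(val, kind, unit), unit)
    return out


def params_hash(params: ModelParameters) -> str:
    """Stable short hash identifying a parameter set."""
    payload = json.dumps(to_flat_dict(params), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def get_param(params: ModelParameters, name: str) -> float:
    section, fname, _, _ = KEY_REGISTRY[name]
    obj = getattr(params, section)
    if obj is None:
        raise AttributeError(f"section {section!r} absent in mode={params.mode}")
    return getattr(obj, fname)


def set_param(params: ModelParameters, name: str, value) -> ModelParameters:
    """Return a deep copy with one named parameter replaced."""
    out = params.copy()
    section, fname, _, _ = KEY_REGISTRY[name]
    obj = getattr(out, section)
    if obj is None:
        raise AttributeError(f"section {section!r} absent in mode={params.mode}")
    setattr(obj, fname, value)
    return out


def scale_param(params: ModelParameters, name: str, factor: float) -> ModelParameters:
    return set_param(params, name, get_param(params, name) * factor)
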