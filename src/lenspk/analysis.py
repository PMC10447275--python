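"""Exposure metrics, mass-balance audit, local sensitivity analysis and
randomized uncertainty propagation.

The local sensitivity analysis perturbs one parameter at a time by a
fixed fraction (default +-10%), re-simulates, and reports the normalized
coefficient

    delta_metric(%) / |delta_parameter(%)|

for the AUC and Cmax of every compartment; +10% and -10% rows are kept
separate.  The anatomical parameters are held constant throughout, as
are the solver settings.

The uncertainty cloud draws every non-anatomical parameter
independently and uniformly within a +-range band around its nominal
value (N runs, seeded) and retains, per compartment, the pointwise
envelope (min/max) together with the 2.5/50/97.5 percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import COMPARTMENTS, EyeModel, Trajectory
from .parameters import ModelParameters, get_param, scale_param

__all__ = [
    "compute_metrics", "mass_balance_residual",
    "local_sensitivity", "uncertainty_cloud",
    "SensitivityTable", "UncertaintyEnsemble",
    "default_sensitivity_parameters", "default_randomized_parameters",
]

_PHYSIOLOGY = ["Q_UvSc", "Q_Vit_Aq", "Q_Aq", "Q_Drain", "Clearance_ScCh"]
_DRUG_COMMON = ["K_t", "K_Aq", "K_Vit", "K_ScCh", "K_Ret",
                "P_Conj", "P_ScCh_Ret", "P_Ret_Vit"]


def default_sensitivity_parameters(params: ModelParameters) -> List[str]:
    """Barrier properties, physiological transport pathways and partition
    coefficients (plus F in release mode); anatomical parameters and the
    measured release curve are excluded."""
    names = _PHYSIOLOGY + list(_DRUG_COMMON)
    if params.mode == "release":
        names += ["F"]
    else:
        names += ["P_t_Aq", "K_SCL", "D_SCL"]
    return [n for n in names if _present(params, n)]


def default_randomized_parameters(params: ModelParameters) -> List[str]:
    """All input values except the anatomical parameters: the sensitivity
    set plus the source description (M_Released and T, or the loading)."""
    names = default_sensitivity_parameters(params)
    if params.mode == "release":
        names += ["M_Released", "T"]
    else:
        names += ["C0_SCL"]
    return [n for n in names if _present(params, n)]


def _present(params: ModelParameters, name: str) -> bool:
    try:
        return get_param(params, name) is not None
    except AttributeError:
        return False


# --------------------------------------------------------------------------
# Exposure metrics and mass audit
# --------------------------------------------------------------------------

def compute_metrics(traj: Trajectory) -> pd.DataFrame:
    """Per-compartment AUC (trapezoid over the output grid), Cmax and
    its time; one row per concentration series."""
    rows = {}
    for name, series in traj.concentrations.items():
        series = np.asarray(series)
        i = int(np.argmax(series))
        rows[name] = {
            "auc": float(np.trapezoid(series, traj.times)),
            "cmax": float(series[i]),
            "t_cmax": float(traj.times[i]),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _stored_mass(traj: Trajectory, params: ModelParameters,
                 idx: int) -> float:
    stored = sum(traj.concentrations[n][idx]
                 * traj.compartment_volume(n, params) for n in COMPARTMENTS)
    if traj.lens_mass is not None:
        stored += traj.lens_mass[idx]
    return stored


def mass_balance_residual(traj: Trajectory, params: ModelParameters,
                          idx: int = -1) -> float:
    """|stored + removed - delivered| / delivered at an output time
    (default: final).  Closes to solver tolerance when every sink is
    accounted for."""
    stored = _stored_mass(traj, params, idx)
    removed = sum(traj.sinks[s][idx] for s in traj.sinks)
    delivered = traj.delivered[idx]
    if delivered == 0:
        return abs(stored + removed)
    return abs(stored + removed - delivered) / delivered


# --------------------------------------------------------------------------
# Local (one-at-a-time) sensitivity
# --------------------------------------------------------------------------

@dataclass
class SensitivityTable:
    """Normalized one-at-a-time sensitivity coefficients."""
    frame: pd.DataFrame       # parameter, direction, compartment, coefficients
    perturbation: float
    failed: List[str] = field(default_factory=list)

    def top_parameters(self, compartment: str, metric: str = "d_auc_pct_per_pct",
                       k: int = 3, direction: Optional[str] = None) -> List[str]:
        """Parameters ranked by |coefficient| for one compartment; when
        ``direction`` is None the +/- rows are reduced by the larger
        magnitude per parameter."""
        sub = self.frame[self.frame.compartment == compartment]
        if direction is not None:
            sub = sub[sub.direction == direction]
        mags = sub.groupby("parameter")[metric].apply(lambda s: s.abs().max())
        return list(mags.sort_values(ascending=False).index[:k])


def local_sensitivity(params: ModelParameters, perturbation: float = 0.10,
                      parameters: Optional[Sequence[str]] = None,
                      ) -> SensitivityTable:
    """One-at-a-time local sensitivity of AUC and Cmax.

    Each listed parameter is scaled by (1 +- perturbation) in turn, the
    model re-simulated, and the percentage change of each compartment's
    AUC and Cmax divided by the (absolute) percentage change of the
    parameter.  A perturbed run that fails is flagged and skipped; the
    other rows are unaffected.
    """
    if perturbation <= 0:
        raise ValueError("perturbation must be a positive fraction")
    if parameters is None:
        parameters = default_sensitivity_parameters(params)

    base = EyeModel(params).simulate()
    base_met = base.metrics()
    comps = [c for c in base_met.index if base_met.loc[c, "auc"] > 0]

    rows = []
    failed = []
    for name in parameters:
        for sign, label in ((1.0, "+"), (-1.0, "-")):
            factor = 1.0 + sign * perturbation
            try:
                pert = scale_param(params, name, factor)
                met = EyeModel(pert).simulate().metrics()
            except Exception as exc:   # failed run: flag, keep going
                failed.append(f"{name}{label}{perturbation:.0%}: {exc}")
                continue
            denom = perturbation * 100.0
            for comp in comps:
                d_auc = (met.loc[comp, "auc"] / base_met.loc[comp, "auc"]
                         - 1.0) * 100.0
                d_cmax = (met.loc[comp, "cmax"] / base_met.loc[comp, "cmax"]
                          - 1.0) * 100.0
                rows.append({
                    "parameter": name,
                    "direction": f"{label}{perturbation:.0%}",
                    "compartment": comp,
                    "d_auc_pct_per_pct": d_auc / denom,
                    "d_cmax_pct_per_pct": d_cmax / denom,
                })
    return SensitivityTable(pd.DataFrame(rows), perturbation, failed)


# --------------------------------------------------------------------------
# Randomized uncertainty propagation
# --------------------------------------------------------------------------

@dataclass
class UncertaintyEnsemble:
    """Envelope and percentiles of a randomized-parameter ensemble."""
    n_runs: int
    seed: int
    rel_range: float
    parameters: List[str]
    times: np.ndarray
    nominal: Dict[str, np.ndarray]
    envelopes: Dict[str, pd.DataFrame]   # per compartment: min/p2_5/p50/p97_5/max
    failures: int = 0
    runs: Optional[Dict[str, np.ndarray]] = None   # (n_runs, n_times), optional


def uncertainty_cloud(params: ModelParameters, n_runs: int = 400,
                      rel_range: float = 0.10, seed: int = 0,
                      parameters: Optional[Sequence[str]] = None,
                      keep_runs: bool = False) -> UncertaintyEnsemble:
    """Monte-Carlo uncertainty propagation.

    Every listed parameter (default: all non-anatomical inputs) is drawn
    independently and uniformly in [1-rel_range, 1+rel_range] times its
    nominal value for each of ``n_runs`` simulations.  Fully reproducible
    from ``seed``; failed runs are counted and excluded.
    """
    if parameters is None:
        parameters = default_randomized_parameters(params)
    parameters = list(parameters)

    nominal_res = EyeModel(params).simulate()
    times = nominal_res.trajectory.times
    nominal = {c: nominal_res.trajectory.concentrations[c] for c in COMPARTMENTS}

    rng = np.random.default_rng(seed)
    factors = rng.uniform(1.0 - rel_range, 1.0 + rel_range,
                          size=(n_runs, len(parameters)))

    stacks = {c: np.empty((n_runs, times.size)) for c in COMPARTMENTS}
    failures = 0
    kept = 0
    for run in range(n_runs):
        p = params.copy()
        for j, name in enumerate(parameters):
            p = scale_param(p, name, factors[run, j])
        try:
            traj = EyeModel(p).simulate().trajectory
        except Exception:
            failures += 1
            continue
        for c in COMPARTMENTS:
            stacks[c][kept] = traj.concentrations[c]
        kept += 1

    envelopes = {}
    for c in COMPARTMENTS:
        data = stacks[c][:kept]
        q = np.percentile(data, [2.5, 50.0, 97.5], axis=0)
        envelopes[c] = pd.DataFrame({
            "time_s": times,
            "nominal": nominal[c],
            "min": data.min(axis=0),
            "p2_5": q[0], "p50": q[1], "p97_5": q[2],
            "max": data.max(axis=0),
        })
    return UncertaintyEnsemble(
        n_runs=n_runs, seed=seed, rel_range=rel_range,
        parameters=parameters, times=times, nominal=nominal,
        envelopes=envelopes, failures=failures,
        runs={c: stacks[c][:kept].copy() for c in COMPARTMENTS}
        if keep_runs else None)
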