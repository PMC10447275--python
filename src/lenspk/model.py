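"""Coupled lens-eye pharmacokinetic model and its integrator.

Five well-mixed compartments exchange drug: tears, sclera-choroid,
retina, vitreous humor and aqueous humor.  Transport between them is
either a flow term Q*C or a membrane term A*P*(C_i/K_i - C_j/K_j); the
corneal epithelium is a diagnostic equilibrium compartment computed
after the fact.  Drug enters from the contact lens, either through the
explicit diffusion slab (mode "diffusion") or through a measured
release curve split between tears and aqueous humor by the
bioavailability F (mode "release").

Five sink accumulators track every route by which drug irreversibly
leaves the system -- tear drainage, palpebral conjunctiva, uveoscleral
seepage into the orbit, choroidal blood-flow clearance, and aqueous
renovation -- so that the mass budget can be audited at every output
time.  Because the total aqueous turnover Q_Aq already includes the
uveoscleral fraction Q_UvSc that re-enters the sclera-choroid, the
aqueous-renovation sink logs only (Q_Aq - Q_UvSc)*C_Aq; nothing is
counted twice.

The whole system is linear in concentration.  The integrator exploits
this by assembling the exact constant Jacobian once and handing it to a
stiff implicit method (BDF): the tears compartment relaxes in minutes
while the horizon is a week.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import lens as lens_mod
from .parameters import ModelParameters, params_hash, validate
from .release import ReleaseFit, cumulative_release, release_rate

__all__ = [
    "COMPARTMENTS", "SINKS", "EyeState", "Trajectory",
    "EyeModel", "SimulationResult", "simulate",
    "rhs_diffusion_mode", "rhs_release_mode", "epithelium_concentration",
]

COMPARTMENTS = ("C_t", "C_ScCh", "C_Ret", "C_Vit", "C_Aq")
SINKS = ("drainage", "palpebral", "uveoscleral", "choroidal", "aqueous")


@dataclass
class EyeState:
    """Instantaneous state of the compartments (spec-level view)."""
    C_t: float = 0.0
    C_ScCh: float = 0.0
    C_Ret: float = 0.0
    C_Vit: float = 0.0
    C_Aq: float = 0.0
    lens: Optional[lens_mod.LensProfile] = None
    sink_accumulators: Dict[str, float] = field(
        default_factory=lambda: {k: 0.0 for k in SINKS})


@dataclass
class Trajectory:
    """Time-stamped concentrations plus cumulative sink masses."""
    times: np.ndarray
    concentrations: Dict[str, np.ndarray]     # C_t..C_Aq, optionally C_Ep
    sinks: Dict[str, np.ndarray]              # cumulative ng per sink
    delivered: np.ndarray                     # cumulative source mass (ng)
    mode: str
    params_hash: str
    lens_mass: Optional[np.ndarray] = None    # diffusion mode only
    lens_profiles: Optional[np.ndarray] = None  # (n_times, n_nodes)
    lens_grid: Optional[lens_mod.LensGrid] = None

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if t.size == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and increase strictly")
        for name, series in {**self.concentrations, **self.sinks}.items():
            if len(series) != t.size:
                raise ValueError(f"series {name} length mismatch")

    def compartment_volume(self, name: str, params: ModelParameters) -> float:
        return {"C_t": params.anatomy.V_t, "C_ScCh": params.anatomy.V_ScCh,
                "C_Ret": params.anatomy.V_Ret, "C_Vit": params.anatomy.V_Vit,
                "C_Aq": params.anatomy.V_Aq}[name]


# --------------------------------------------------------------------------
# Right-hand sides
# --------------------------------------------------------------------------

def _compartment_rates(c: np.ndarray, tears_in: float, aq_in: float,
                       p: ModelParameters, V_t_eff: Optional[float] = None):
    """Concentration derivatives (per volume) and sink mass rates for the
    five compartments, given the mass rates entering tears and aqueous.

    Implements the transport arrows: lens->tears (a), drainage (b),
    palpebral loss (c), bulbar tears<->sclera-choroid exchange (d),
    uveoscleral inflow (e) and seepage (f), choroidal clearance (g),
    sclera-choroid<->retina (h), retina<->vitreous (i), vitreous->aqueous
    (j), lens->aqueous (k) and aqueous renovation (l).
    """
    a, ph, d = p.anatomy, p.physiology, p.drug
    C_t, C_ScCh, C_Ret, C_Vit, C_Aq = c

    bulbar = d.P_Conj * a.A_Bulb * (C_t / d.K_t - C_ScCh / d.K_ScCh)     # (d)
    scch_ret = a.A_Globe * d.P_ScCh_Ret * (C_ScCh / d.K_ScCh - C_Ret / d.K_Ret)  # (h)
    ret_vit = a.A_Globe * d.P_Ret_Vit * (C_Ret / d.K_Ret - C_Vit / d.K_Vit)      # (i)

    dC = np.empty(5)
    dC[0] = (tears_in - ph.Q_Drain * C_t - d.P_Conj * a.A_Palp * C_t
             - bulbar) / (V_t_eff if V_t_eff is not None else a.V_t)
    dC[1] = (ph.Q_UvSc * C_Aq - ph.Q_UvSc * C_ScCh / d.K_ScCh + bulbar
             - ph.Clearance_ScCh * C_ScCh - scch_ret) / a.V_ScCh
    dC[2] = (scch_ret - ret_vit) / a.V_Ret
    dC[3] = (ret_vit - ph.Q_Vit_Aq * C_Vit) / a.V_Vit
    dC[4] = (ph.Q_Vit_Aq * C_Vit + aq_in - ph.Q_Aq * C_Aq) / a.V_Aq

    sink_rates = np.array([
        ph.Q_Drain * C_t,                     # tear drainage
        d.P_Conj * a.A_Palp * C_t,            # palpebral conjunctiva
        ph.Q_UvSc * C_ScCh / d.K_ScCh,        # uveoscleral seepage
        ph.Clearance_ScCh * C_ScCh,           # choroidal clearance
        (ph.Q_Aq - ph.Q_UvSc) * C_Aq,         # net aqueous renovation
    ])
    return dC, sink_rates


def rhs_release_mode(state: EyeState, t: float,
                     params: ModelParameters) -> EyeState:
    """Release-mode derivative: tears receive (1-F) R(t), aqueous F R(t)."""
    if params.mode != "release" or params.release is None:
        raise ValueError("rhs_release_mode requires release-mode parameters")
    fit = ReleaseFit(params.release.M_Released, params.release.T)
    R = float(release_rate(t, fit))
    F = params.drug.F
    c = np.array([state.C_t, state.C_ScCh, state.C_Ret, state.C_Vit, state.C_Aq])
    dC, sink_rates = _compartment_rates(c, (1.0 - F) * R, F * R, params)
    return EyeState(*dC, lens=None,
                    sink_accumulators=dict(zip(SINKS, sink_rates)))


def rhs_diffusion_mode(state: EyeState, params: ModelParameters) -> EyeState:
    """Diffusion-mode derivative; ``state.lens`` must carry the profile.
    The returned state's ``lens`` holds the profile time-derivative at
    nodes 1..n-1 (node 0 is slaved to tears equilibrium)."""
    if params.mode != "diffusion" or params.lens is None:
        raise ValueError("rhs_diffusion_mode requires diffusion-mode parameters")
    if state.lens is None:
        raise ValueError("diffusion-mode state must carry a lens profile")
    profile = state.lens
    tears_in = lens_mod.face_flux_discrete(profile, params, C_t=state.C_t)
    aq_in = lens_mod.back_flux(profile, state.C_Aq, params)
    V_t_eff = (params.anatomy.V_t + params.anatomy.A_SCL
               * params.drug.K_SCL * profile.grid.dy / 2.0)
    c = np.array([state.C_t, state.C_ScCh, state.C_Ret, state.C_Vit, state.C_Aq])
    dC, sink_rates = _compartment_rates(c, tears_in, aq_in, params,
                                        V_t_eff=V_t_eff)
    dlens = lens_mod.lens_rhs(profile, state.C_t, state.C_Aq, params)
    dprofile = lens_mod.LensProfile(profile.grid,
                                    np.concatenate(([np.nan], dlens)))
    return EyeState(*dC, lens=dprofile,
                    sink_accumulators=dict(zip(SINKS, sink_rates)))


def epithelium_concentration(C_Aq, C_t, params: ModelParameters):
    """Corneal epithelium concentration, in equilibrium with aqueous on
    one side and tears on the other: (K_Ep/Aq C_Aq + K_Ep/t C_t) / 2."""
    d = params.drug
    if d.K_Ep_Aq is None or d.K_Ep_t is None:
        raise ValueError("K_Ep_Aq and K_Ep_t must be supplied for C_Ep")
    return (d.K_Ep_Aq * np.asarray(C_Aq) + d.K_Ep_t * np.asarray(C_t)) / 2.0


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

class EyeModel:
    """Ocular pharmacokinetic model bound to a parameter set.

    Examples
    --------
    >>> from lenspk.parameters import rabbit_dexamethasone
    >>> res = EyeModel(rabbit_dexamethasone()).simulate()
    >>> res.trajectory.concentrations["C_Aq"].max() > 0
    True
    """

    def __init__(self, params: ModelParameters):
        fatal = [d for d in validate(params) if d.fatal]
        if fatal:
            msgs = "; ".join(f"{d.key}: {d.message}" for d in fatal)
            raise ValueError(f"invalid parameters: {msgs}")
        self.params = params
        if params.mode == "release":
            self._fit = ReleaseFit(params.release.M_Released, params.release.T)
        else:
            self._fit = None
        if params.mode == "diffusion":
            self.grid = lens_mod.make_grid(params)
            self._n_lens = self.grid.n_nodes - 1   # nodes 1..n-1 integrated
            # the anterior half-cell rides with the tears (it is slaved to
            # tears equilibrium), so the tears balance carries its capacity
            self._V_t_eff = (params.anatomy.V_t
                             + params.anatomy.A_SCL * params.drug.K_SCL
                             * self.grid.dy / 2.0)
        else:
            self.grid = None
            self._n_lens = 0
            self._V_t_eff = None
        self.n_states = self._n_lens + 10

    # ---- packing ---------------------------------------------------------

    def _lens_profile(self, y: np.ndarray) -> lens_mod.LensProfile:
        C_t = y[self._n_lens]
        nodes = np.concatenate(([self.params.drug.K_SCL * C_t],
                                y[:self._n_lens]))
        return lens_mod.LensProfile(self.grid, nodes)

    def _rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        c = y[self._n_lens:self._n_lens + 5]
        if p.mode == "release":
            f = self._fit
            R = f.M_Released / f.T * np.exp(-t / f.T)
            tears_in, aq_in = (1.0 - p.drug.F) * R, p.drug.F * R
            dlens = np.empty(0)
        else:
            profile = self._lens_profile(y)
            tears_in = lens_mod.face_flux_discrete(profile, p)
            aq_in = lens_mod.back_flux(profile, c[4], p)
            dlens = lens_mod.lens_rhs(profile, c[0], c[4], p)
        dC, sink_rates = _compartment_rates(c, tears_in, aq_in, p,
                                            V_t_eff=self._V_t_eff)
        return np.concatenate((dlens, dC, sink_rates))

    # ---- linear structure ------------------------------------------------

    def system_matrix(self):
        """Exact (A, b) of the linear system y' = A y + R(t) b.

        The model is linear in concentration, so A is obtained exactly by
        evaluating the right-hand side on the canonical basis; b is the
        source direction (zero in diffusion mode, where the source is the
        lens initial condition instead).
        """
        n = self.n_states
        base = self._rhs(0.0, np.zeros(n))
        A = np.empty((n, n))
        for i in range(n):
            e = np.zeros(n)
            e[i] = 1.0
            A[:, i] = self._rhs(0.0, e) - base
        if self.params.mode == "release":
            b = base / float(release_rate(0.0, self._fit))
        else:
            b = np.zeros(n)
        return A, b

    # ---- integration -----------------------------------------------------

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        if self.params.mode == "diffusion":
            y0[:self._n_lens] = self.params.lens.C0_SCL
        return y0

    def simulate(self, t_end: Optional[float] = None,
                 output_step: Optional[float] = None) -> "SimulationResult":
        p = self.params
        t_end = float(t_end if t_end is not None else p.solver.t_end)
        step = float(output_step if output_step is not None else p.solver.output_step)
        t_eval = np.arange(0.0, t_end, step)
        if t_eval[-1] < t_end:
            t_eval = np.append(t_eval, t_end)

        A, _ = self.system_matrix()
        sol = solve_ivp(self._rhs, (0.0, t_end), self.initial_state(),
                        method="BDF", jac=A, t_eval=t_eval,
                        rtol=p.solver.rel_tol, atol=p.solver.abs_tol)
        if not sol.success:
            raise RuntimeError(
                f"stiff integration failed near t = {sol.t[-1] if sol.t.size else 0:.6g} s: "
                f"{sol.message}")

        m = self._n_lens
        conc = {name: sol.y[m + i] for i, name in enumerate(COMPARTMENTS)}
        sinks = {name: sol.y[m + 5 + i] for i, name in enumerate(SINKS)}

        neg = min(series.min() for series in conc.values())
        if neg < -10.0 * p.solver.abs_tol * max(1.0, max(
                series.max() for series in conc.values())):
            warnings.warn(
                f"negative concentration {neg:.3g} beyond tolerance; "
                "solver tolerances may be misconfigured", stacklevel=2)

        if p.drug.K_Ep_Aq is not None and p.drug.K_Ep_t is not None:
            conc["C_Ep"] = epithelium_concentration(conc["C_Aq"], conc["C_t"], p)

        if p.mode == "release":
            delivered = cumulative_release(sol.t, self._fit)
            lens_masses = profiles = None
        else:
            profiles = np.empty((sol.t.size, self.grid.n_nodes))
            profiles[:, 0] = p.drug.K_SCL * conc["C_t"]
            profiles[:, 1:] = sol.y[:m].T
            lens_masses = np.trapezoid(profiles, dx=self.grid.dy, axis=1) \
                * p.anatomy.A_SCL
            # budget against the discrete initial mass (anterior node slaved
            # to tears equilibrium at t=0), which is what the grid resolves
            delivered = np.full(sol.t.size, lens_masses[0])

        traj = Trajectory(times=sol.t, concentrations=conc, sinks=sinks,
                          delivered=delivered, mode=p.mode,
                          params_hash=params_hash(p),
                          lens_mass=lens_masses, lens_profiles=profiles,
                          lens_grid=self.grid)
        return SimulationResult(self, traj)


class SimulationResult:
    """Results wrapper: trajectory plus exposure metrics and audits."""

    def __init__(self, model: EyeModel, trajectory: Trajectory):
        self.model = model
        self.params = model.params
        self.trajectory = trajectory

    def metrics(self):
        from .analysis import compute_metrics
        return compute_metrics(self.trajectory)

    def mass_balance_residual(self) -> float:
        from .analysis import mass_balance_residual
        return mass_balance_residual(self.trajectory, self.params)

    def to_frame(self):
        from .io import trajectory_to_frame
        return trajectory_to_frame(self.trajectory)

    def summary(self) -> str:
        tr = self.trajectory
        met = self.metrics()
        lines = [
            "Ocular pharmacokinetics simulation",
            "=" * 64,
            f"mode            {tr.mode}",
            f"parameters      {tr.params_hash}",
            f"horizon         {tr.times[-1]:.6g} s "
            f"({tr.times[-1] / 86400.0:.3g} days), "
            f"{tr.times.size} output points",
            f"mass residual   {self.mass_balance_residual():.3e} "
            "(fraction of delivered dose)",
            "",
            f"{'compartment':<12}{'AUC (ng*s/mL)':>16}{'Cmax (ng/mL)':>16}"
            f"{'t(Cmax) (h)':>14}",
            "-" * 58,
        ]
        for name, row in met.iterrows():
            lines.append(f"{name:<12}{row['auc']:>16.6g}{row['cmax']:>16.6g}"
                         f"{row['t_cmax'] / 3600.0:>14.4g}")
        return "\n".join(lines)


def simulate(params: ModelParameters) -> Trajectory:
    """Integrate the selected mode's system from rest; returns the
    :class:`Trajectory` (see :class:`EyeModel` for the full results
    object)."""
    return EyeModel(params).simulate().trajectory
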