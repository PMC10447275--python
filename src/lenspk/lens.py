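"""1-D drug diffusion across the contact lens (method of lines).

The lens is a homogeneous slab of thickness H discretized on a uniform
grid with y = 0 at the anterior (tears-facing) face and y = H at the
posterior (cornea-facing) face.  Interior nodes follow

    dC/dt = D_SCL d2C/dy2

by second-order central differences.  The anterior face is in
instantaneous partition equilibrium with the tears, C(0) = K_SCL * C_t
(the node is algebraically slaved, not integrated).  The posterior face
carries a flux-matching condition: the total diffusive rate leaving the
back of the lens equals the transcorneal rate into the aqueous humor,

    (-D_SCL dC/dy|_H) * A_SCL = A_Cornea * P_t_Aq * (C(H)/K_SCL - C_Aq),

imposed through a second-order ghost node.  Both boundary exchanges are
total mass rates (ng/s), which is the only dimensionally consistent
reading that conserves drug between lens, tears and aqueous humor.

Sign convention: `front_flux` and `back_flux` are positive when drug
leaves the lens, so d(lens mass)/dt = -front_flux - back_flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "LensGrid", "LensProfile", "make_grid", "init_uniform_loading",
    "lens_rhs", "front_flux", "back_flux", "lens_drug_mass",
    "integrate_slab_dirichlet",
]


@dataclass(frozen=True)
class LensGrid:
    """Uniform node positions spanning [0, H]."""
    n_nodes: int
    H: float

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ValueError("lens grid needs at least 3 nodes")
        if self.H <= 0:
            raise ValueError("lens thickness must be positive")

    @property
    def dy(self) -> float:
        return self.H / (self.n_nodes - 1)

    @property
    def y(self) -> np.ndarray:
        return np.linspace(0.0, self.H, self.n_nodes)


@dataclass
class LensProfile:
    grid: LensGrid
    C_SCL: np.ndarray    # ng/mL of lens, one value per node

    def __post_init__(self):
        self.C_SCL = np.asarray(self.C_SCL, dtype=float)
        if self.C_SCL.shape != (self.grid.n_nodes,):
            raise ValueError("profile length does not match grid")


def make_grid(params: ModelParameters) -> LensGrid:
    _require_diffusion(params)
    return LensGrid(params.lens.n_nodes, params.lens.H)


def init_uniform_loading(grid: LensGrid, C0: float) -> LensProfile:
    """Uniformly loaded lens, the t = 0 condition."""
    if C0 < 0:
        raise ValueError("loading concentration must be non-negative")
    return LensProfile(grid, np.full(grid.n_nodes, float(C0)))


def _require_diffusion(params: ModelParameters):
    if params.mode != "diffusion" or params.lens is None:
        raise ValueError("lens PDE is only defined for mode='diffusion'")


def lens_rhs(profile: LensProfile, C_t: float, C_Aq: float,
             params: ModelParameters) -> np.ndarray:
    """Time derivative of the lens profile at nodes 1..n-1.

    Node 0 is slaved to K_SCL * C_t and carries no derivative of its
    own; the returned array has length ``n_nodes - 1`` (interior nodes
    plus the flux-condition back node).
    """
    _require_diffusion(params)
    D = params.lens.D_SCL
    K = params.drug.K_SCL
    dy = profile.grid.dy
    C = profile.C_SCL.copy()
    C[0] = K * C_t  # Dirichlet slaving

    dC = np.empty(profile.grid.n_nodes - 1)
    # interior central differences
    dC[:-1] = D * (C[:-2] - 2.0 * C[1:-1] + C[2:]) / dy**2
    # back node: ghost value from the flux-matching gradient
    J_back = back_flux(profile, C_Aq, params)
    g = -J_back / (D * params.anatomy.A_SCL)      # dC/dy at y = H
    dC[-1] = D * (2.0 * C[-2] - 2.0 * C[-1] + 2.0 * dy * g) / dy**2
    return dC


def front_flux(profile: LensProfile, params: ModelParameters,
               C_t: float = None) -> float:
    """Total rate (ng/s) delivered from the anterior lens face into the
    tears; positive when the lens is richer than tears equilibrium.

    One-sided second-order gradient at y = 0.  If ``C_t`` is given the
    face value is refreshed to K_SCL * C_t before differencing.
    """
    _require_diffusion(params)
    C = profile.C_SCL
    if C_t is not None:
        C = C.copy()
        C[0] = params.drug.K_SCL * C_t
    dy = profile.grid.dy
    grad0 = (-3.0 * C[0] + 4.0 * C[1] - C[2]) / (2.0 * dy)
    return params.lens.D_SCL * params.anatomy.A_SCL * grad0


def face_flux_discrete(profile: LensProfile, params: ModelParameters,
                       C_t: float = None) -> float:
    """Discrete conservation-law flux (ng/s) through the anterior face:
    D_SCL * A_SCL * (C1 - C0) / dy.

    This is the rate the semi-discrete scheme actually transports out of
    the first grid cell, hence the quantity the tears balance must
    receive for the lens + compartments budget to close exactly (the
    anterior half-cell, slaved to tears equilibrium, is carried as an
    extra tears capacitance by the integrator).  It agrees with
    :func:`front_flux` to O(dy^2) on smooth profiles.
    """
    _require_diffusion(params)
    C = profile.C_SCL
    C0 = C[0] if C_t is None else params.drug.K_SCL * C_t
    return (params.lens.D_SCL * params.anatomy.A_SCL
            * (C[1] - C0) / profile.grid.dy)


def back_flux(profile: LensProfile, C_Aq: float,
              params: ModelParameters) -> float:
    """Total transcorneal rate (ng/s) from the posterior lens face into
    the aqueous humor: A_Cornea * P_t_Aq * (C(H)/K_SCL - C_Aq).
    Negative values (reverse flux) are permitted."""
    _require_diffusion(params)
    C_H = profile.C_SCL[-1]
    return (params.anatomy.A_Cornea * params.drug.P_t_Aq
            * (C_H / params.drug.K_SCL - C_Aq))


def lens_drug_mass(profile: LensProfile, params: ModelParameters) -> float:
    """Drug mass (ng) held by the lens: trapezoidal quadrature of the
    profile over [0, H] times the lens area."""
    _require_diffusion(params)
    return float(np.trapezoid(profile.C_SCL, dx=profile.grid.dy)
                 * params.anatomy.A_SCL)


def integrate_slab_dirichlet(n_nodes: int, H: float, D: float, C0: float,
                             t: float, rtol: float = 1e-10,
                             atol: float = 1e-12) -> np.ndarray:
    """Reference configuration: slab with both faces clamped to zero and
    a uniform initial load, integrated with the same spatial operator as
    the lens.  Used to verify the discretization against the classical
    Fourier-series solution.

    Returns the full profile (both boundary nodes zero) at time ``t``.
    """
    from scipy.integrate import solve_ivp

    dy = H / (n_nodes - 1)
    n_int = n_nodes - 2

    def rhs(_t, c):
        full = np.concatenate(([0.0], c, [0.0]))
        return D * (full[:-2] - 2.0 * full[1:-1] + full[2:]) / dy**2

    # constant Jacobian of the linear operator
    main = np.full(n_int, -2.0 * D / dy**2)
    off = np.full(n_int - 1, D / dy**2)
    jac = np.diag(main) + np.diag(off, 1) + np.diag(off, -1)

    sol = solve_ivp(rhs, (0.0, t), np.full(n_int, float(C0)), method="BDF",
                    jac=jac, rtol=rtol, atol=atol, t_eval=[t])
    if not sol.success:
        raise RuntimeError(f"slab integration failed: {sol.message}")
    return np.concatenate(([0.0], sol.y[:, -1], [0.0]))
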