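"""In-vitro release fitting, release rate, and aqueous bioavailability.

The cumulative in-vitro release from the lens is described by a single
exponential,

    f(t) = M_Released * (1 - exp(-t/T)),

fitted to (time, cumulative mass) data by unweighted nonlinear least
squares on the cumulative curve (fitting the differentiated rate would
amplify measurement noise).  The release rate follows in closed form,

    R(t) = df/dt = (M_Released / T) * exp(-t/T),

and integrates back to M_Released over [0, inf).

The aqueous bioavailability is the fraction of the released dose that
reaches the aqueous humor,

    F = Q_Aq * AUC(C_Aq) / M_Released,

with AUC obtained by fitting the aqueous concentration series to a
mono-exponential decay C0 * exp(-t/tau) and integrating it to zero
concentration (i.e. to infinity), AUC = C0 * tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ReleaseDataset", "AqueousPKDataset", "ReleaseFit",
    "fit_exponential_release", "release_rate", "cumulative_release",
    "compute_bioavailability", "ExponentialReleaseModel", "ReleaseFitResult",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot be performed or fails."""


@dataclass
class ReleaseDataset:
    """Cumulative in-vitro release measurements."""
    times: np.ndarray                    # s
    cumulative_released: np.ndarray      # ng
    uncertainty: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_released = np.asarray(self.cumulative_released, float)
        if self.times.ndim != 1 or self.times.shape != self.cumulative_released.shape:
            raise ValueError("times and cumulative_released must be 1-D and aligned")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        tol = np.max(self.uncertainty) if self.uncertainty is not None else 0.0
        if np.any(np.diff(self.cumulative_released) < -tol):
            raise ValueError("cumulative release must be non-decreasing "
                             "(beyond stated uncertainty)")


@dataclass
class AqueousPKDataset:
    """Aqueous-humor concentration time series (in-vivo-like)."""
    times: np.ndarray            # s
    C_Aq: np.ndarray             # ng/mL
    uncertainty: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.C_Aq = np.asarray(self.C_Aq, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.C_Aq.shape:
            raise ValueError("times and C_Aq must be 1-D and aligned")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative, strictly increasing")


@dataclass
class ReleaseFit:
    """Exponential release-curve parameters with fit diagnostics."""
    M_Released: float        # ng
    T: float                 # s
    residual_norm: float = 0.0
    n_points: int = 0

    def __post_init__(self):
        if self.M_Released <= 0 or self.T <= 0:
            raise ValueError("M_Released and T must be positive")


def cumulative_release(t, fit: ReleaseFit):
    """f(t) = M (1 - exp(-t/T)), the cumulative mass released by time t."""
    return fit.M_Released * (1.0 - np.exp(-np.asarray(t, float) / fit.T))


def release_rate(t, fit: ReleaseFit):
    """R(t) = (M/T) exp(-t/T), the instantaneous release rate (ng/s)."""
    return fit.M_Released / fit.T * np.exp(-np.asarray(t, float) / fit.T)


def _initial_guess(t: np.ndarray, f: np.ndarray):
    """Deterministic, scale-free starting point: M0 = max(f); T0 = time
    at which the curve crosses 63.2% of M0, by linear interpolation."""
    M0 = float(np.max(f))
    target = (1.0 - np.exp(-1.0)) * M0
    idx = np.searchsorted(f, target)
    if idx == 0:
        T0 = max(t[0], 1.0)
    elif idx >= len(t):
        T0 = t[-1]
    else:
        t0, t1 = t[idx - 1], t[idx]
        f0, f1 = f[idx - 1], f[idx]
        T0 = t0 + (target - f0) / (f1 - f0) * (t1 - t0) if f1 > f0 else t1
    return M0, max(T0, 1e-12)


def fit_exponential_release(data: ReleaseDataset) -> ReleaseFit:
    """Least-squares fit of the exponential release model to cumulative
    data.  Deterministic given the data (fixed initialization rule)."""
    t, f = data.times, data.cumulative_released
    if len(t) < 3:
        raise FitError("need at least 3 points to fit the release curve")
    if not np.any((t > 0) & (f > 0)):
        raise FitError("no release signal: all cumulative values are zero")

    p0 = _initial_guess(t, f)
    try:
        popt, _ = curve_fit(
            lambda tt, M, T: M * (1.0 - np.exp(-tt / T)),
            t, f, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"release fit did not converge (start {p0}): {exc}") from exc
    M, T = float(popt[0]), float(popt[1])
    resid = f - M * (1.0 - np.exp(-t / T))
    return ReleaseFit(M, T, residual_norm=float(np.linalg.norm(resid)),
                      n_points=len(t))


def fit_exponential_decay(t: np.ndarray, c: np.ndarray):
    """Fit c = C0 exp(-t/tau); returns (C0, tau).  Start values come
    from a log-linear regression on the positive points."""
    pos = c > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(c[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) or 1.0
        C00 = float(np.exp(intercept))
    else:
        tau0, C00 = (t[-1] - t[0]) or 1.0, float(np.max(c))
    try:
        popt, _ = curve_fit(lambda tt, C0, tau: C0 * np.exp(-tt / tau),
                            t, c, p0=(C00, max(tau0, 1e-9)), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"exponential decay fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1])


def compute_bioavailability(aq: AqueousPKDataset, Q_Aq: float,
                            M_Released: float) -> float:
    """Aqueous bioavailability F (fraction of the released dose).

    Fits the aqueous series to C0 * exp(-t/tau), takes the closed-form
    AUC = C0 * tau (the integral extrapolated to zero concentration),
    and returns Q_Aq * AUC / M_Released.
    """
    if len(aq.times) < 3:
        raise FitError("need at least 3 aqueous concentration points")
    if Q_Aq <= 0 or M_Released <= 0:
        raise ValueError("Q_Aq and M_Released must be positive")
    if np.all(aq.C_Aq == 0):
        return 0.0
    C0, tau = fit_exponential_decay(aq.times, aq.C_Aq)
    if tau <= 0:
        raise FitError(f"fitted decay time constant is non-positive ({tau})")
    auc = C0 * tau
    F = Q_Aq * auc / M_Released
    if F > 1.0:
        warnings.warn(f"computed bioavailability F = {F:.3g} exceeds 1; "
                      "inputs are mutually inconsistent", stacklevel=2)
    return F


# --------------------------------------------------------------------------
# Model/Results wrappers
# --------------------------------------------------------------------------

class ExponentialReleaseModel:
    """Exponential release model bound to a dataset; ``fit()`` returns a
    :class:`ReleaseFitResult`."""

    def __init__(self, data: ReleaseDataset):
        self.data = data

    @classmethod
    def from_dataframe(cls, frame, time_col="time_s", value_col="cumulative_ng"):
        return cls(ReleaseDataset(frame[time_col].to_numpy(),
                                  frame[value_col].to_numpy()))

    def fit(self) -> "ReleaseFitResult":
        return ReleaseFitResult(self, fit_exponential_release(self.data))


class ReleaseFitResult:
    def __init__(self, model: ExponentialReleaseModel, fit: ReleaseFit):
        self.model = model
        self.release_fit = fit

    @property
    def M_Released(self) -> float:
        return self.release_fit.M_Released

    @property
    def T(self) -> float:
        return self.release_fit.T

    def rate(self, t):
        return release_rate(t, self.release_fit)

    def predict(self, t):
        return cumulative_release(t, self.release_fit)

    def summary(self) -> str:
        f = self.release_fit
        lines = [
            "Exponential release fit  f(t) = M (1 - exp(-t/T))",
            "-" * 50,
            f"M_Released      {f.M_Released: .6g} ng",
            f"T               {f.T: .6g} s  ({f.T / 3600.0:.3g} h)",
            f"residual norm   {f.residual_norm: .4g} ng",
            f"n points        {f.n_points}",
        ]
        return "\n".join(lines)
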