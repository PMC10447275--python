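"""Synthetic in-vitro release and in-vivo-like aqueous datasets with
known ground truth.

Raw release/PK tables from the animal studies behind this model are not
publicly tabulated, so testable stand-ins are generated from the same
closed forms the fitters assume: cumulative release
f(t) = M (1 - exp(-t/T)) and aqueous decay C(t) = C0 exp(-t/tau).
Measurement error is modelled as multiplicative Gaussian noise
(value * (1 + eps), eps ~ N(0, CV^2)): concentration assays scale their
error with magnitude.  Negative noisy values are clipped to zero (and
counted), since concentrations are physical.  All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .model import EyeModel, Trajectory
from .parameters import ModelParameters
from .release import AqueousPKDataset, ReleaseDataset

__all__ = ["SyntheticSpec", "generate_release_data", "generate_aqueous_data",
           "generate_trajectory_fixture"]

logger = logging.getLogger(__name__)

#: Default measurement noise level, echoing the large variability typical
#: of reported in-vivo ocular concentrations.
DEFAULT_CV = 0.10


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``truth`` is (M_Released, T) for release data or (C0, tau) for
    aqueous decay data, in internal units (ng, s, ng/mL).

    ``spacing`` sets the sampling protocol.  The default, "geometric",
    is the dense-early design of kinetic studies: a t = 0 sample, the
    first nonzero sample at 1/64 of the span, and the rest geometrically
    spaced up to the span (roughly sample-time doubling).  Under
    multiplicative noise this is what makes the time constant well
    identified; uniformly spaced sampling ("linear") leaves most points
    on the plateau, where the curve carries no kinetic information.
    """
    truth: Tuple[float, float]
    n_points: int = 10
    t_span: Tuple[float, float] = (0.0, 604800.0)
    noise: str = "none"                  # "none" | "multiplicative-gaussian"
    noise_cv: float = DEFAULT_CV
    seed: int = 0
    spacing: str = "geometric"           # "geometric" | "linear"

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("need at least 3 points")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.t_span[1] <= self.t_span[0]:
            raise ValueError("time span must be positive")
        if self.noise not in ("none", "multiplicative-gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.spacing not in ("geometric", "linear"):
            raise ValueError(f"unknown spacing {self.spacing!r}")


def _times(spec: SyntheticSpec) -> np.ndarray:
    t0, t1 = spec.t_span
    if spec.spacing == "linear" or t0 > 0:
        return np.linspace(t0, t1, spec.n_points)
    return np.concatenate(([0.0],
                           np.geomspace(t1 / 64.0, t1, spec.n_points - 1)))


def _apply_noise(values: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    if spec.noise == "none" or spec.noise_cv == 0:
        return values.copy()
    rng = np.random.default_rng(spec.seed)
    noisy = values * (1.0 + rng.normal(0.0, spec.noise_cv, size=values.shape))
    n_neg = int(np.sum(noisy < 0))
    if n_neg:
        logger.info("clipped %d negative noisy values to 0", n_neg)
        noisy = np.clip(noisy, 0.0, None)
    return noisy


def generate_release_data(spec: SyntheticSpec):
    """Cumulative release samples from f(t) = M (1 - exp(-t/T)).

    Returns
    -------
    (ReleaseDataset, dict)
        The dataset and a truth record {"M_Released", "T", "seed"}.
    """
    M, T = spec.truth
    t = _times(spec)
    clean = M * (1.0 - np.exp(-t / T))
    noisy = _apply_noise(clean, spec)
    if spec.noise != "none":
        # noise can break monotonicity; pass the implied uncertainty so the
        # dataset's monotonicity check tolerates it
        unc = np.full_like(noisy, 6.0 * spec.noise_cv * max(M, 1.0))
    else:
        unc = None
    data = ReleaseDataset(t, noisy, uncertainty=unc)
    return data, {"M_Released": M, "T": T, "seed": spec.seed}


def generate_aqueous_data(spec: SyntheticSpec):
    """Aqueous concentration samples from C(t) = C0 exp(-t/tau)."""
    C0, tau = spec.truth
    t = _times(spec)
    clean = C0 * np.exp(-t / tau)
    data = AqueousPKDataset(t, _apply_noise(clean, spec))
    return data, {"C0": C0, "tau": tau, "seed": spec.seed}


def generate_trajectory_fixture(params: ModelParameters,
                                t_end: float = 3600.0,
                                output_step: float = 300.0) -> Trajectory:
    """Short-horizon, coarse-output simulation for round-trip and metric
    tests; deterministic for fixed parameters."""
    return EyeModel(params).simulate(t_end=t_end,
                                    output_step=output_step).trajectory
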