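"""Stretched-exponential-plus-aging relaxation model for surface-stress traces.

After a step dilatation of a complex fluid-fluid interface, the surface
stress relaxes as

    gamma(t) = a * exp(-(t / tau1)**beta) + b * exp(-t / tau2) + c

The first term is a Kohlrausch-Williams-Watts (KWW) stretched exponential:
``beta < 1`` signals dynamic heterogeneity, i.e. a broad distribution of
local relaxation times. The second, regular exponential describes the slow
aging of the interface (post-adsorption structural rearrangement) that is
present even without deformation; including it decouples the step response
from the aging background. ``c`` is the long-time stress offset.

Units: stress in mN/m, time in seconds, throughout the experimental chain.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import gamma as _gamma_fn

__all__ = [
    "KWWAgingParameters",
    "SurfacePressureRecord",
    "evaluate_kww_aging",
    "kww_mean_relaxation_time",
    "surface_pressure",
]

PARAM_FIELDS = ("a", "tau1", "beta", "b", "tau2", "c")


@dataclass(frozen=True)
class KWWAgingParameters:
    """The six parameters of the KWW-plus-aging relaxation model.

    Attributes
    ----------
    a : float
        Amplitude of the stretched-exponential term (mN/m). Sign encodes
        the deformation direction (positive for expansion, negative for
        compression under the usual convention).
    tau1 : float
        KWW relaxation time (s); must be positive.
    beta : float
        Stretch exponent, 0 < beta <= 1. beta = 1 recovers a regular
        exponential; beta < 1 indicates dynamic heterogeneity.
    b : float
        Amplitude of the aging exponential (mN/m).
    tau2 : float
        Aging time scale (s); must be positive and is typically much
        longer than tau1.
    c : float
        Long-time stress offset (mN/m).
    """

    a: float
    tau1: float
    beta: float
    b: float
    tau2: float
    c: float

    def __post_init__(self) -> None:
        vals = asdict(self)
        for name, v in vals.items():
            if not math.isfinite(float(v)):
                raise ValueError(f"non-finite parameter {name}={v!r}")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError(
                f"relaxation times must be positive (tau1={self.tau1}, tau2={self.tau2})"
            )
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"stretch exponent must be in (0, 1], got beta={self.beta}")

    # -- serialization: flat key/value record with exactly the six fields --
    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in PARAM_FIELDS}

    @classmethod
    def from_dict(cls, record: dict) -> "KWWAgingParameters":
        extra = set(record) - set(PARAM_FIELDS)
        if extra:
            raise ValueError(f"unknown parameter fields: {sorted(extra)}")
        return cls(**{k: float(record[k]) for k in PARAM_FIELDS})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "KWWAgingParameters":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class SurfacePressureRecord:
    """Surface pressure bookkeeping: pi = gamma0 - gamma_t.

    gamma0 is the surface tension of the bare fluid-fluid interface and
    gamma_t the measured surface stress of the covered one; pi is the
    reduction caused by the adsorbed film (all mN/m).
    """

    gamma0: float
    gamma_t: float

    @property
    def pi(self) -> float:
        return self.gamma0 - self.gamma_t


def evaluate_kww_aging(params: KWWAgingParameters, t):
    """Evaluate the KWW-plus-aging model at time(s) ``t`` (seconds).

    Parameters
    ----------
    params : KWWAgingParameters
        Validated model parameters.
    t : float or array_like
        Time(s) since the start of relaxation; must be >= 0.

    Returns
    -------
    float or ndarray
        Surface stress a*exp(-(t/tau1)^beta) + b*exp(-t/tau2) + c, in mN/m.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = (
        params.a * np.exp(-((t_arr / params.tau1) ** params.beta))
        + params.b * np.exp(-t_arr / params.tau2)
        + params.c
    )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def kww_mean_relaxation_time(tau1: float, beta: float) -> float:
    """Mean relaxation time of the KWW term, <tau> = (tau1/beta) * Gamma(1/beta).

    This is the integral of exp(-(t/tau1)^beta) over t in [0, inf); for
    beta < 1 it exceeds tau1, reflecting the long tail of the underlying
    relaxation-time distribution.
    """
    if tau1 <= 0:
        raise ValueError(f"tau1 must be positive, got {tau1}")
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    return (tau1 / beta) * float(_gamma_fn(1.0 / beta))


def surface_pressure(gamma0: float, gamma_t: float) -> float:
    """Surface pressure pi = gamma0 - gamma(t), in mN/m."""
    if not (math.isfinite(gamma0) and math.isfinite(gamma_t)):
        raise ValueError("surface tensions must be finite")
    return gamma0 - gamma_t
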