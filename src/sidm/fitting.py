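"""Fitting the KWW-plus-aging model to step-relaxation traces.

The measurement protocol fits the model to the first 1000 s of the
relaxation, starting from the extremum of the surface stress after the
area step (the maximum in expansion, the minimum in compression), with
time re-zeroed at that extremum.

KWW fits are notoriously multi-modal (beta and tau1 trade off against the
aging background), so the optimizer is a bounded nonlinear least squares
with multi-start initialization over a (tau1, beta) grid; the aging time
is kept identifiable by optimizing the ratio r = tau2/tau1 with a lower
bound of 5, so the aging exponential can never collapse onto the KWW term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .relaxation import KWWAgingParameters, PARAM_FIELDS
from .tensiometry import RelaxationTrace

__all__ = [
    "FitResult",
    "AsymmetryReport",
    "locate_step_extremum",
    "fit_relaxation",
    "asymmetry_report",
]

logger = logging.getLogger(__name__)

BETA_MIN = 0.05
TAU_RATIO_MIN = 5.0  # identifiability: tau2 >= 5 * tau1


@dataclass
class FitResult:
    """Outcome of fitting the relaxation model to one trace.

    window is the [t_start, t_end] interval actually used (absolute trace
    time); extremum_index the sample the fit starts from; residual_rms in
    mN/m. param_uncertainties are Jacobian-based standard errors in the
    order (a, tau1, beta, b, tau2, c); entries are NaN where the covariance
    is singular (e.g. a parameter pinned at a bound).
    """

    params: KWWAgingParameters
    param_uncertainties: dict
    residual_rms: float
    window: tuple
    extremum_index: int
    converged: bool
    n_restarts_used: int
    truncated: bool = False
    phase_label: str = "expansion"

    @property
    def beta_stderr(self) -> float:
        return self.param_uncertainties["beta"]


@dataclass
class AsymmetryReport:
    """Expansion/compression asymmetry of the relaxation dynamics.

    delta_beta = beta_compression - beta_expansion: positive values mean
    the compressed film relaxes closer to a single-exponential (more
    homogeneous) than the expanded one. The heterogeneity flags mark, per
    phase, whether beta < 1 by more than its standard error.
    """

    delta_beta: float
    tau1_ratio: float
    beta_expansion: float
    beta_compression: float
    heterogeneous_expansion: bool
    heterogeneous_compression: bool


def locate_step_extremum(trace: RelaxationTrace, search_window: float | None = None) -> int:
    """Index of the post-step stress extremum.

    For an expansion the surface stress rises during the step and decays
    afterwards, so the relevant extremum is the maximum of gamma within
    [step_time, step_time + search_window]; for a compression it is the
    minimum. ``search_window`` defaults to 3x the step duration.
    """
    if search_window is None:
        search_window = 3.0 * trace.step_duration
    lo = trace.step_time
    hi = trace.step_time + search_window
    mask = (trace.t >= lo) & (trace.t <= hi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(
            f"no samples in the step search window [{lo}, {hi}] s"
        )
    seg = trace.gamma[idx]
    if trace.step_fraction > 0:
        return int(idx[np.argmax(seg)])
    return int(idx[np.argmin(seg)])


def _model_theta(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Model in optimizer coordinates theta = (a, tau1, beta, b, r, c)."""
    a, tau1, beta, b, r, c = theta
    tau2 = r * tau1
    return a * np.exp(-((t / tau1) ** beta)) + b * np.exp(-t / tau2) + c


def _linear_amplitudes(t, y, tau1, beta, r):
    """Best (a, b, c) for fixed nonlinear parameters (linear least squares)."""
    cols = np.column_stack([
        np.exp(-((t / tau1) ** beta)),
        np.exp(-t / (r * tau1)),
        np.ones_like(t),
    ])
    coef, *_ = np.linalg.lstsq(cols, y, rcond=None)
    return coef


def _natural_jacobian(params: KWWAgingParameters, t: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the model w.r.t. the six natural parameters."""
    a, tau1, beta, b, tau2, c = (params.a, params.tau1, params.beta,
                                 params.b, params.tau2, params.c)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = t / tau1
        xb = x ** beta
        e1 = np.exp(-xb)
        e2 = np.exp(-t / tau2)
        d_a = e1
        d_tau1 = a * e1 * xb * beta / tau1
        logx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), 0.0)
        d_beta = -a * e1 * xb * logx
        d_b = e2
        d_tau2 = b * e2 * t / tau2 ** 2
        d_c = np.ones_like(t)
    return np.column_stack([d_a, d_tau1, d_beta, d_b, d_tau2, d_c])


def _param_stderr(params: KWWAgingParameters, t: np.ndarray,
                  resid: np.ndarray) -> dict:
    """Jacobian-based standard errors at the optimum (NaN where singular)."""
    n, p = len(t), 6
    out = {k: float("nan") for k in PARAM_FIELDS}
    if n <= p:
        return out
    J = _natural_jacobian(params, t)
    sigma2 = float(resid @ resid) / (n - p)
    JTJ = J.T @ J
    try:
        cov = np.linalg.inv(JTJ) * sigma2
    except np.linalg.LinAlgError:
        return out
    diag = np.diag(cov)
    for k, v in zip(PARAM_FIELDS, diag):
        out[k] = float(np.sqrt(v)) if v >= 0 else float("nan")
    return out


def fit_relaxation(trace: RelaxationTrace, window_s: float = 1000.0,
                   restarts: int = 16, seed: int = 0) -> FitResult:
    """Fit the six-parameter relaxation model to a trace.

    Samples from the post-step extremum through extremum + ``window_s``
    are used, with time re-zeroed at the extremum. Initialization is a
    multi-start over log-spaced tau1 in [1, window/2] crossed with
    beta in {0.4, 0.6, 0.8, 1.0} (``restarts`` caps how many are tried,
    in a seed-shuffled order beyond the first 16); amplitudes are seeded
    by linear least squares at each start. Bounds: 0.05 <= beta <= 1,
    tau1 > 0, tau2 >= 5 * tau1. Best restart by residual sum of squares,
    ties broken toward the largest beta (the less-stretched explanation).
    """
    i0 = locate_step_extremum(trace)
    t0 = trace.t[i0]
    t_end_req = t0 + window_s
    truncated = bool(t_end_req > trace.t[-1] + 1e-12)
    if truncated:
        warnings.warn(
            f"fit window [{t0:.1f}, {t_end_req:.1f}] s extends past trace end "
            f"({trace.t[-1]:.1f} s); truncating", stacklevel=2)
    mask = (trace.t >= t0) & (trace.t <= t_end_req)
    t = trace.t[mask] - t0
    y = trace.gamma[mask]
    if len(t) < 30:
        raise ValueError(f"need >= 30 samples in the fit window, got {len(t)}")

    window_len = float(t[-1])
    n_tau = 4
    tau1_grid = np.geomspace(1.0, max(window_len / 2.0, 2.0), n_tau)
    beta_grid = np.array([0.4, 0.6, 0.8, 1.0])
    starts = [(tau, b) for tau in tau1_grid for b in beta_grid]
    if restarts < len(starts):
        # keep the coarse grid order deterministic, truncate from a
        # seed-shuffled tail so small restart counts still span the grid
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(starts))
        starts = [starts[i] for i in order[:restarts]]
    elif restarts > len(starts):
        rng = np.random.default_rng(seed)
        extra = restarts - len(starts)
        for _ in range(extra):
            starts.append((float(np.exp(rng.uniform(np.log(1.0), np.log(max(window_len / 2.0, 2.0))))),
                           float(rng.uniform(0.3, 1.0))))

    r_init_base = 10.0 * window_s  # tau2 initialized at 10x the window
    lb = np.array([-np.inf, 1e-3, BETA_MIN, -np.inf, TAU_RATIO_MIN, -np.inf])
    ub = np.array([np.inf, 1e6, 1.0, np.inf, 1e7, np.inf])

    best = None
    n_used = 0
    for tau1_0, beta_0 in starts:
        r0 = np.clip(r_init_base / tau1_0, TAU_RATIO_MIN, 1e7)
        a0, b0, c0 = _linear_amplitudes(t, y, tau1_0, beta_0, r0)
        theta0 = np.clip(np.array([a0, tau1_0, beta_0, b0, r0, c0]), lb, ub)
        try:
            sol = least_squares(
                lambda th: _model_theta(th, t) - y, theta0,
                bounds=(lb, ub), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            logger.debug("restart (tau1=%g, beta=%g) failed: %s", tau1_0, beta_0, exc)
            continue
        n_used += 1
        ssr = 2.0 * sol.cost
        if best is None or ssr < best[0] * (1 - 1e-10) or (
                abs(ssr - best[0]) <= 1e-10 * max(ssr, best[0], 1e-300)
                and sol.x[2] > best[1].x[2]):
            best = (ssr, sol)

    if best is None:
        raise RuntimeError("all fit restarts failed to evaluate")

    ssr, sol = best
    theta = sol.x
    params = KWWAgingParameters(
        a=float(theta[0]), tau1=float(theta[1]), beta=float(theta[2]),
        b=float(theta[3]), tau2=float(theta[4] * theta[1]), c=float(theta[5]),
    )
    resid = _model_theta(theta, t) - y
    rms = float(np.sqrt(np.mean(resid ** 2)))
    stderr = _param_stderr(params, t, resid)
    converged = bool(sol.success)
    if not converged:
        logger.warning("relaxation fit did not converge (status %s)", sol.status)
    logger.info("fit: beta=%.4f tau1=%.3f s rms=%.3e mN/m (%d restarts)",
                params.beta, params.tau1, rms, n_used)
    return FitResult(
        params=params,
        param_uncertainties=stderr,
        residual_rms=rms,
        window=(float(t0), float(min(t_end_req, trace.t[-1]))),
        extremum_index=i0,
        converged=converged,
        n_restarts_used=n_used,
        truncated=truncated,
        phase_label=trace.phase_label,
    )


def _is_heterogeneous(fit: FitResult) -> bool:
    """beta below 1 by more than its standard error."""
    se = fit.param_uncertainties["beta"]
    if not np.isfinite(se):
        se = 0.0
    return bool(fit.params.beta < 1.0 - se)


def asymmetry_report(fit_expansion: FitResult,
                     fit_compression: FitResult) -> AsymmetryReport:
    """Quantify the expansion/compression asymmetry from two fits.

    Refuses unconverged inputs, naming the offending side.
    """
    bad = [label for label, f in (("expansion", fit_expansion),
                                  ("compression", fit_compression))
           if not f.converged]
    if bad:
        raise ValueError(f"unconverged fit on: {', '.join(bad)}")
    be = fit_expansion.params.beta
    bc = fit_compression.params.beta
    return AsymmetryReport(
        delta_beta=bc - be,
        tau1_ratio=fit_compression.params.tau1 / fit_expansion.params.tau1,
        beta_expansion=be,
        beta_compression=bc,
        heterogeneous_expansion=_is_heterogeneous(fit_expansion),
        heterogeneous_compression=_is_heterogeneous(fit_compression),
    )
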