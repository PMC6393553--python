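"""Synthetic drop-tensiometry traces for step dilatation experiments.

Emulates the measurement protocol of a pendant-drop tensiometer probing a
complex fluid-fluid interface: a long adsorption/aging phase during which
stabilizer accumulates at the interface and the surface stress drifts
slowly, an area step (typically +/-10 or 20 %, applied over ~2 s) that
drives the stress to an extremum, and a relaxation phase following the
KWW-plus-aging model with additive Gaussian measurement noise.

These traces carry known ground-truth parameters, so the full
generate -> fit -> compare loop can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .relaxation import KWWAgingParameters, evaluate_kww_aging

__all__ = [
    "RelaxationTrace",
    "DeformationProtocol",
    "TraceGenerationSpec",
    "generate_trace",
    "generate_paired_experiment",
]


@dataclass
class RelaxationTrace:
    """A sampled surface-stress-vs-time signal with step-protocol metadata.

    t is the absolute time grid (s, strictly increasing); gamma the surface
    stress samples (mN/m). step_time marks the instant the area step begins,
    step_fraction the signed relative area change (+0.10 = 10 % expansion),
    step_duration how long the actuator takes to apply it.
    """

    t: np.ndarray
    gamma: np.ndarray
    step_time: float
    step_fraction: float
    step_duration: float
    phase_label: str = "expansion"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.t.ndim != 1 or self.gamma.ndim != 1:
            raise ValueError("t and gamma must be 1-d arrays")
        if len(self.t) != len(self.gamma):
            raise ValueError(
                f"length mismatch: len(t)={len(self.t)} vs len(gamma)={len(self.gamma)}"
            )
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        if not 0.0 < abs(self.step_fraction) < 1.0:
            raise ValueError("|step_fraction| must be in (0, 1)")
        if self.phase_label not in ("adsorption", "expansion", "compression"):
            raise ValueError(f"unknown phase_label {self.phase_label!r}")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class DeformationProtocol:
    """Timing of a step dilatation experiment.

    equilibration_s: adsorption/aging phase before the step (experimental
    practice ranges from ~1000 s up to several hours). step_duration_s
    defaults to the 2 s actuator ramp typical of drop tensiometers.
    """

    equilibration_s: float = 2000.0
    step_fraction: float = 0.10
    step_duration_s: float = 2.0
    hold_s: float = 1200.0
    sample_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if not 1000.0 <= self.equilibration_s <= 21600.0:
            raise ValueError(
                "equilibration_s outside experimental practice [1000, 21600] s"
            )
        if self.step_duration_s <= 0 or self.hold_s <= 0 or self.sample_interval_s <= 0:
            raise ValueError("durations must be positive")
        if not 0.0 < abs(self.step_fraction) < 1.0:
            raise ValueError("|step_fraction| must be in (0, 1)")


@dataclass(frozen=True)
class TraceGenerationSpec:
    """Ground truth for a synthetic trace.

    relax_params is the post-step truth; adsorption_amplitude/tau describe
    the pre-step aging decay b'*exp(-t/tau') + c (tau' >> tau1 by default,
    mimicking the long adsorption tails of protein/particle stabilizers).
    """

    relax_params: KWWAgingParameters
    adsorption_amplitude: float = 8.0
    adsorption_tau: float = 2000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.adsorption_tau <= 0:
            raise ValueError("adsorption_tau must be positive")


# Fixture defaults for the four constants the experiments do not pin down.
DEFAULT_FIXTURE = dict(a=5.0, b=1.0, tau2=2000.0, c=50.0)


def fixture_params(beta: float, tau1: float, **overrides) -> KWWAgingParameters:
    """KWWAgingParameters with the package's standard fixture constants."""
    kw = dict(DEFAULT_FIXTURE)
    kw.update(overrides)
    return KWWAgingParameters(beta=beta, tau1=tau1, **kw)


def _noise_free_gamma(spec: TraceGenerationSpec, protocol: DeformationProtocol,
                      t: np.ndarray) -> np.ndarray:
    """Model value at absolute times t (no noise)."""
    p = spec.relax_params
    t_step = protocol.equilibration_s
    t_end = t_step + protocol.step_duration_s
    gamma = np.empty_like(t)

    # adsorption/aging phase: slow decay toward the pre-step plateau
    pre = t < t_step
    gamma[pre] = p.c + spec.adsorption_amplitude * np.exp(-t[pre] / spec.adsorption_tau)

    # value the adsorption curve has reached when the step starts
    g_pre_end = p.c + spec.adsorption_amplitude * np.exp(-t_step / spec.adsorption_tau)
    # post-step extremum: model value at relaxation time zero
    g_extremum = p.a + p.b + p.c

    # linear actuator ramp over the step
    ramp = (t >= t_step) & (t < t_end)
    frac = (t[ramp] - t_step) / protocol.step_duration_s
    gamma[ramp] = g_pre_end + frac * (g_extremum - g_pre_end)

    # relaxation, time re-zeroed at step end
    post = t >= t_end
    gamma[post] = evaluate_kww_aging(p, t[post] - t_end)
    return gamma


def generate_trace(spec: TraceGenerationSpec,
                   protocol: DeformationProtocol) -> RelaxationTrace:
    """Generate one synthetic step-relaxation trace.

    The trace covers the adsorption phase, the linear area-step ramp and
    the post-step relaxation; Gaussian noise of sd ``spec.noise_sd`` is
    added with a generator seeded by ``spec.seed`` (identical inputs and
    seed give a bit-identical trace).
    """
    total = protocol.equilibration_s + protocol.step_duration_s + protocol.hold_s
    t = np.arange(0.0, total + 0.5 * protocol.sample_interval_s,
                  protocol.sample_interval_s)
    gamma = _noise_free_gamma(spec, protocol, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        gamma = gamma + rng.normal(0.0, spec.noise_sd, size=len(t))
    phase = "expansion" if protocol.step_fraction > 0 else "compression"
    return RelaxationTrace(
        t=t,
        gamma=gamma,
        step_time=protocol.equilibration_s,
        step_fraction=protocol.step_fraction,
        step_duration=protocol.step_duration_s,
        phase_label=phase,
    )


def generate_paired_experiment(
    spec_exp: TraceGenerationSpec,
    spec_comp: TraceGenerationSpec,
    protocol: DeformationProtocol,
) -> tuple[RelaxationTrace, RelaxationTrace]:
    """Generate an expansion/compression pair sharing the adsorption baseline.

    ``protocol.step_fraction`` (must be positive) is used for the expansion
    leg and its negation for the compression leg; both traces use the same
    adsorption parameters, as in the experimental protocol where the same
    droplet is expanded and later compressed.
    """
    if protocol.step_fraction <= 0:
        raise ValueError("paired experiment needs a positive (expansion) step_fraction")
    if spec_exp.adsorption_amplitude != spec_comp.adsorption_amplitude or \
            spec_exp.adsorption_tau != spec_comp.adsorption_tau:
        raise ValueError("paired traces must share the adsorption baseline")
    a_exp, a_comp = spec_exp.relax_params.a, spec_comp.relax_params.a
    if a_exp != 0 and a_comp != 0 and np.sign(a_exp) == np.sign(a_comp):
        raise ValueError(
            "expansion and compression stress amplitudes must have opposite signs"
        )
    proto_comp = replace(protocol, step_fraction=-protocol.step_fraction)
    trace_exp = generate_trace(spec_exp, protocol)
    trace_comp = generate_trace(spec_comp, proto_comp)
    return trace_exp, trace_comp
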