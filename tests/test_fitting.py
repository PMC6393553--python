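"""KWW-plus-aging fitting: extremum location, recovery, asymmetry."""

from dataclasses import replace

import numpy as np
import pytest

from sidm import (DeformationProtocol, TraceGenerationSpec, asymmetry_report,
                  fit_relaxation, fixture_params, generate_paired_experiment,
                  generate_trace, locate_step_extremum)


def make_trace(beta=0.55, tau1=19.5, noise_sd=0.0, seed=0, step_fraction=0.10,
               a=None, hold_s=1200.0, **overrides):
    if a is not None:
        overrides["a"] = a
    elif step_fraction < 0:
        overrides["a"] = -5.0
    spec = TraceGenerationSpec(relax_params=fixture_params(beta, tau1, **overrides),
                               noise_sd=noise_sd, seed=seed)
    proto = DeformationProtocol(equilibration_s=2000.0, step_fraction=step_fraction,
                                hold_s=hold_s)
    return generate_trace(spec, proto)


class TestLocateStepExtremum:
    def test_expansion_peak_at_step_end(self):
        tr = make_trace()
        i = locate_step_extremum(tr)
        assert tr.t[i] == pytest.approx(2002.0)

    def test_compression_minimum_mirrors_expansion(self):
        exp = make_trace(step_fraction=0.10)
        comp = make_trace(step_fraction=-0.10)
        assert locate_step_extremum(comp) == locate_step_extremum(exp)

    def test_injected_noisy_peak_found(self):
        tr = make_trace(noise_sd=0.05, seed=3)
        i = locate_step_extremum(tr)
        # argmax oracle over the same search window
        lo, hi = tr.step_time, tr.step_time + 3 * tr.step_duration
        m = (tr.t >= lo) & (tr.t <= hi)
        assert i == np.flatnonzero(m)[np.argmax(tr.gamma[m])]

    def test_empty_window_error(self):
        tr = make_trace()
        short = replace(tr)
        short.t = tr.t[tr.t < 1500.0]
        short.gamma = tr.gamma[:len(short.t)]
        with pytest.raises(ValueError, match="window"):
            locate_step_extremum(short)


@pytest.mark.parametrize("beta", [0.4, 0.55, 0.7, 0.85, 1.0])
@pytest.mark.parametrize("tau1", [10.0, 30.0])
def test_noise_free_recovery_grid(beta, tau1):
    """Noise-free parameter recovery across the (beta, tau1) truth grid."""
    fit = fit_relaxation(make_trace(beta=beta, tau1=tau1), seed=0)
    assert fit.converged
    assert fit.params.beta == pytest.approx(beta, rel=1e-3)
    assert fit.params.tau1 == pytest.approx(tau1, rel=1e-3)
    assert fit.residual_rms < 1e-6


def test_noise_free_recovery_mid_tau():
    fit = fit_relaxation(make_trace(beta=0.55, tau1=20.0), seed=0)
    assert fit.params.tau1 == pytest.approx(20.0, rel=1e-3)


def test_single_exponential_limit_hits_beta_bound():
    fit = fit_relaxation(make_trace(beta=1.0, tau1=20.0, b=0.0), seed=0)
    assert fit.params.beta == pytest.approx(1.0, abs=1e-6)


def test_offset_and_time_shift_invariance():
    base = make_trace(beta=0.55, tau1=19.5)
    fit0 = fit_relaxation(base, seed=0)
    shifted = replace(base)
    shifted.gamma = base.gamma + 13.0
    fit_c = fit_relaxation(shifted, seed=0)
    assert fit_c.params.beta == pytest.approx(fit0.params.beta, rel=1e-6)
    assert fit_c.params.c == pytest.approx(fit0.params.c + 13.0, rel=1e-6)
    tshift = replace(base, step_time=base.step_time + 500.0)
    tshift.t = base.t + 500.0
    fit_t = fit_relaxation(tshift, seed=0)
    assert fit_t.params.beta == pytest.approx(fit0.params.beta, rel=1e-6)
    assert fit_t.params.tau1 == pytest.approx(fit0.params.tau1, rel=1e-6)


def test_noisy_residual_rms_matches_noise():
    fit = fit_relaxation(make_trace(noise_sd=0.05, seed=5), seed=0)
    assert fit.residual_rms == pytest.approx(0.05, rel=0.2)


def test_truncation_warning_recorded():
    tr = make_trace(hold_s=400.0)
    with pytest.warns(UserWarning, match="truncat"):
        fit = fit_relaxation(tr, window_s=1000.0, seed=0)
    assert fit.truncated


def test_too_few_samples_rejected():
    tr = make_trace()
    short = replace(tr)
    keep = tr.t <= 2012.0
    short.t, short.gamma = tr.t[keep], tr.gamma[keep]
    with pytest.raises(ValueError, match="30 samples"):
        fit_relaxation(short, window_s=10.0)


def test_tau2_identifiability_constraint_held():
    # truth tau2/tau1 ~ 100, well inside the bound; the fitted ratio must
    # never violate tau2 >= 5 tau1
    fit = fit_relaxation(make_trace(beta=0.5, tau1=25.0), seed=0)
    assert fit.params.tau2 >= 5.0 * fit.params.tau1 - 1e-9


class TestAsymmetryReport:
    def _pair(self, beta_exp=0.55, beta_comp=1.0):
        spec_e = TraceGenerationSpec(relax_params=fixture_params(beta_exp, 19.5))
        spec_c = TraceGenerationSpec(relax_params=fixture_params(beta_comp, 62.9, a=-5.0))
        proto = DeformationProtocol(equilibration_s=2000.0, step_fraction=0.10,
                                    hold_s=1200.0)
        exp, comp = generate_paired_experiment(spec_e, spec_c, proto)
        return fit_relaxation(exp, seed=0), fit_relaxation(comp, seed=0)

    def test_delta_beta(self):
        # PPI(native): beta 0.42 in expansion vs 0.73 in compression
        fe, fc = self._pair(beta_exp=0.42, beta_comp=0.73)
        rep = asymmetry_report(fe, fc)
        assert rep.delta_beta == pytest.approx(0.31, abs=2e-3)

    def test_identical_fits_no_asymmetry(self):
        fe, _ = self._pair()
        rep = asymmetry_report(fe, fe)
        assert rep.delta_beta == 0.0
        assert rep.tau1_ratio == pytest.approx(1.0)

    def test_nanoparticle_pattern_heterogeneity_flags(self):
        # nanosphere-like: stretched in expansion, plain exponential in
        # compression -- heterogeneity disappears on compression
        fe, fc = self._pair(beta_exp=0.55, beta_comp=1.0)
        rep = asymmetry_report(fe, fc)
        assert rep.heterogeneous_expansion
        assert not rep.heterogeneous_compression

    def test_unconverged_input_refused(self):
        fe, fc = self._pair()
        fc.converged = False
        with pytest.raises(ValueError, match="compression"):
            asymmetry_report(fe, fc)
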