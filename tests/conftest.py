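"""Shared fixtures: deterministic phenotypes and trace specs."""

import numpy as np
import pytest
from hypothesis import settings

from pilarray.synth import ChannelPhenotype, TraceSpec

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def fixed_phenotype(latency=3.6, tau1=1.7, tau2=12.2, amp=150.0, **kw) -> ChannelPhenotype:
    """Phenotype with zero population spread: every draw hits the mean."""
    defaults = dict(
        name="fixed", latency_mean_ms=latency, latency_sd_ms=0.0,
        tau1_mean_ms=tau1, tau1_sd_ms=0.0, tau2_mean_ms=tau2, tau2_sd_ms=0.0,
        peak_amp_mean_pA=amp, peak_amp_sd_pA=0.0, responder_prob=1.0,
        threshold_mean_nm=10.0, threshold_sd_nm=0.0)
    defaults.update(kw)
    return ChannelPhenotype(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def clean_trace_spec():
    return TraceSpec(baseline_noise_sd_pA=0.0, seed=7)


@pytest.fixture
def unfiltered_trace_spec():
    return TraceSpec(baseline_noise_sd_pA=0.0, filter_cutoff_hz=None, seed=7)
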