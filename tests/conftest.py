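import numpy as np
import pytest

from drwhite import (
    DecompositionConfig,
    TraceSimParams,
    locate_recognition_site,
    make_reference,
    simulate_trace_pair,
)


@pytest.fixture(scope="session")
def ref():
    """Default synthetic construct used across trace tests."""
    return make_reference(seed=1)


@pytest.fixture(scope="session")
def break_position(ref):
    return locate_recognition_site(ref)


@pytest.fixture
def noise_free():
    return TraceSimParams(seed=0, signal_sd=0.0, background_sd=0.0)


@pytest.fixture(scope="session")
def small_ref():
    """Short construct for small-K oracle problems."""
    return make_reference(seed=7, amplicon_len=400)


def small_instance(small_ref, seed, window_len=50, max_indel=5):
    """A small decomposition problem with random truth for oracle checks.

    Returns (control, sample, cfg, truth) with the decomposition window
    capped at ``window_len`` positions and shifts within +/-``max_indel``.
    """
    rng = np.random.default_rng(seed)
    brk = locate_recognition_site(small_ref)
    shifts = np.arange(-max_indel, max_indel + 1)
    support = rng.choice(shifts, size=rng.integers(1, 5), replace=False)
    w = rng.dirichlet(np.ones(len(support)))
    truth = {int(k): float(v) for k, v in zip(support, w)}
    cfg = DecompositionConfig(
        max_indel=max_indel,
        decomp_window=(brk + max_indel + 6, brk + max_indel + 5 + window_len),
    )
    control, sample, _ = simulate_trace_pair(
        small_ref, truth, TraceSimParams(seed=int(rng.integers(2**31)))
    )
    return control, sample, cfg, truth
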