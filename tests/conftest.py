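import numpy as np
import pytest

from nanolock.synth import (
    AcquisitionConfig,
    MixSpec,
    PoreModel,
    closed_nanolock_species,
    open_nanolock_species,
    ruler_species,
)


@pytest.fixture(scope="session")
def fast_acq():
    """Reduced-rate acquisition used throughout the suite: 1 MHz sampling,
    200 kHz analysis filter (the filter, not the sampler, limits
    resolution)."""
    return AcquisitionConfig(
        sampling_rate=1e6,
        analog_bandwidth=5e5,
        digital_filter_cutoff=2e5,
        voltage_mv=150.0,
        duration_s=5.0,
        rng_seed=0,
    )


@pytest.fixture(scope="session")
def pore():
    return PoreModel()


@pytest.fixture(scope="session")
def quiet_pore():
    return PoreModel(noise_rms_pa=0.0)


def dense_mix(species, rate_hz=50.0, conc_nm=30.0):
    """Single-species mix with the capture rate pinned to ``rate_hz``."""
    from dataclasses import replace

    return MixSpec(components=((replace(species, capture_rate_per_nm=rate_hz / conc_nm), conc_nm),))


@pytest.fixture(scope="session")
def detected_circular(fast_acq, pore):
    """~250 detected circular events shared by detection/classification tests."""
    from nanolock.detect import CusumEventDetector, match_events_to_truth
    from nanolock.synth import simulate_trace

    trace = simulate_trace(fast_acq, pore, dense_mix(closed_nanolock_species()), rng=1)
    events = CusumEventDetector().transform(trace)
    return match_events_to_truth(events, trace.events), trace


@pytest.fixture(scope="session")
def detected_ruler(fast_acq, pore):
    from nanolock.detect import CusumEventDetector, match_events_to_truth
    from nanolock.synth import simulate_trace

    trace = simulate_trace(fast_acq, pore, dense_mix(ruler_species()), rng=2)
    events = CusumEventDetector().transform(trace)
    return match_events_to_truth(events, trace.events), trace
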