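import numpy as np
import pytest

import liftgate as lg


@pytest.fixture(scope="session")
def topology():
    return lg.default_topology()


@pytest.fixture(scope="session")
def staining_script():
    return lg.parse_script(lg.reference_staining_script(), source_path="staining.loc")


@pytest.fixture(scope="session")
def wash_script_parsed():
    return lg.parse_script(lg.wash_script(), source_path="wash.loc")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def spaced_transits(rng: np.random.Generator, n: int, duration_s: float,
                    jitter_s: float) -> tuple[float, ...]:
    """Jittered even grid: transit times that respect a minimum spacing."""
    grid = (np.arange(n) + 0.5) * (duration_s / n)
    return tuple(grid + rng.uniform(-jitter_s, jitter_s, n))


@pytest.fixture(scope="session")
def benchmark_video():
    """100-particle synthetic acquisition at high SNR, with ground truth."""
    rng = np.random.default_rng(1234)
    n, dur = 100, 4.0
    grid = (np.arange(n) + 0.5) * (dur / n)
    transits = tuple(grid + rng.uniform(-0.01, 0.01, n))
    spec = lg.SyntheticVideoSpec(duration_s=dur, n_particles=n,
                                 transit_times_s=transits, amplitude=200.0,
                                 rng_seed=99)
    optics = lg.OpticsConfig()
    frames, truth = lg.generate_video(spec, optics)
    return frames, truth, optics
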