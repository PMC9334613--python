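import pytest

from nirsync import build_montage, build_schedule, simulate_dyad
from nirsync.preprocess import preprocess_recording

FS = 7.81


@pytest.fixture(scope="session")
def mini_montage():
    return build_montage("mini-8")


@pytest.fixture(scope="session")
def single_montage():
    return build_montage("single-1")


@pytest.fixture(scope="session")
def short_schedule():
    """Desk-scale session: 6 trials per block, 30 s rests."""
    return build_schedule(1, trials_per_block=6, rest_s=30.0)


@pytest.fixture(scope="session")
def tiny_schedule():
    """Smallest session that still covers the analysis band in every segment."""
    return build_schedule(1, trials_per_block=4, rest_s=30.0)


@pytest.fixture(scope="session")
def sim_pair(mini_montage, short_schedule):
    return simulate_dyad(mini_montage, short_schedule, seed=42)


@pytest.fixture(scope="session")
def hb_pair(sim_pair):
    ra, rb = sim_pair
    return preprocess_recording(ra), preprocess_recording(rb)


def simulate_hb_set(montage, schedule, coupling, n_dyads, seed0):
    """Simulate and preprocess a set of dyads; helper shared across tests."""
    out = {}
    for i in range(n_dyads):
        ra, rb = simulate_dyad(montage, schedule, coupling, seed=seed0 + i)
        out[f"d{i + 1:02d}"] = (preprocess_recording(ra), preprocess_recording(rb))
    return out
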