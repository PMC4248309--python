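import numpy as np
import pandas as pd
import pytest

import loopscape as ls
from loopscape.config import SimConfig, CallerConfig
from loopscape.simulate import make_loop_truth
from loopscape.pets import AnchorSet


SMALL_SIM = dict(
    genome=(("chr1", 2_000_000),),
    n_peaks=60,
    peak_width_bp=2000,
    n_true_loops=20,
    loop_pet_rate=10.0,
    n_background_pets=5000,
    max_distance_bp=1_000_000,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, **SMALL_SIM)


@pytest.fixture(scope="session")
def small_peaks(small_config):
    return ls.simulate_peaks(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_peaks):
    return make_loop_truth(small_peaks, small_config)


@pytest.fixture(scope="session")
def small_pets(small_config, small_peaks, small_truth):
    return ls.simulate_pets(small_peaks, small_truth, small_config)


@pytest.fixture(scope="session")
def small_anchored(small_config, small_peaks, small_pets):
    clean, _, report = ls.filter_pets(small_pets)
    anchored, _ = ls.assign_to_anchors(clean, small_peaks, report)
    return anchored


@pytest.fixture(scope="session")
def small_call(small_anchored, small_peaks):
    return ls.call_interactions(small_anchored, small_peaks, CallerConfig(seed=7))


@pytest.fixture(scope="session")
def small_tracks(small_config, small_peaks, small_truth):
    return ls.simulate_companion_tracks(small_config, small_peaks, small_truth)


def toy_anchors(positions, width=1000, chrom="chr1", extension_bp=1500):
    """AnchorSet from a list of start positions (fixed width)."""
    df = pd.DataFrame({
        "chrom": chrom,
        "start": list(positions),
        "end": [p + width for p in positions],
    })
    df["id"] = [f"P{i:06d}" for i in range(len(df))]
    return AnchorSet(df, extension_bp=extension_bp)


def toy_pet(chrom1, m1, chrom2, m2, strand1="+", strand2="-", name="pet", rl=50):
    return {
        "chrom1": chrom1, "start1": m1 - rl // 2, "end1": m1 + rl // 2, "strand1": strand1,
        "chrom2": chrom2, "start2": m2 - rl // 2, "end2": m2 + rl // 2, "strand2": strand2,
        "name": name,
    }


def pets_frame(rows):
    return pd.DataFrame(rows)
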