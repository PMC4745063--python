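import numpy as np
import pandas as pd
import pytest

from colocmap import GenomeLayout, FeatureTrack, make_windows


@pytest.fixture
def toy_layout():
    return GenomeLayout((("chrT", 1_000_000), ("chrU", 750_000)))


@pytest.fixture
def toy_grid(toy_layout):
    # chrT: 2 windows of 500 kb; chrU: 1 window (250 kb trailing discarded)
    return make_windows(toy_layout, 500_000)


def make_track(name, rows, mode="density"):
    """rows: list of (chrom, start, end[, score])."""
    cols = ["chrom", "start", "end"]
    if rows and len(rows[0]) == 4:
        cols.append("score")
    df = pd.DataFrame(rows, columns=cols)
    return FeatureTrack(name, mode, df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
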