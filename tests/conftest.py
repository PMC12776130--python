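import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_pairs(rows):
    """Pair table from (pos1, pos2, strand1, strand2) tuples on one chromosome."""
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(rows))],
            "chrom1": "chr1",
            "pos1": [r[0] for r in rows],
            "chrom2": "chr1",
            "pos2": [r[1] for r in rows],
            "strand1": [r[2] for r in rows],
            "strand2": [r[3] for r in rows],
        }
    )


def make_regions(rows):
    """Region table from (chrom, start, end) or (chrom, start, end, name)."""
    return pd.DataFrame(
        [(r[0], r[1], r[2], r[3] if len(r) > 3 else ".") for r in rows],
        columns=["chrom", "start", "end", "name"],
    )


def make_track(values, chrom="chr1", bin_size=100_000):
    starts = np.arange(len(values)) * bin_size
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + bin_size, "value": values}
    )
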