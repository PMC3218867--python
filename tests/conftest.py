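import numpy as np
import pandas as pd
import pytest

from scnascan.io import CopyProfileSet, MarkerSet
from scnascan.ziggurat import EVENT_COLUMNS


def marker_set(n: int, chrom: str = "1", spacing: int = 1000) -> MarkerSet:
    return MarkerSet(pd.DataFrame({
        "marker": [f"m{i}" for i in range(n)],
        "chrom": chrom,
        "pos": (np.arange(n) + 1) * spacing,
    }))


def profile_set(matrix: np.ndarray, chrom: str = "1") -> CopyProfileSet:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    samples = [f"S{i}" for i in range(matrix.shape[0])]
    return CopyProfileSet(samples, marker_set(matrix.shape[1], chrom), {chrom: matrix})


def event_frame(rows) -> pd.DataFrame:
    """rows: (sample, chrom, start, end, amp[, arm_fraction, klass, direction])."""
    full = []
    for r in rows:
        sample, chrom, start, end, amp = r[:5]
        arm_fraction = r[5] if len(r) > 5 else 0.1
        klass = r[6] if len(r) > 6 else "focal"
        direction = r[7] if len(r) > 7 else ("amp" if amp > 0 else "del")
        full.append((sample, chrom, start, end, amp, arm_fraction, klass, direction))
    return pd.DataFrame(full, columns=EVENT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
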