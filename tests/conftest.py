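import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from covhap import CoverageHistogram, SmoothedCurve


@pytest.fixture
def gaussian_histogram():
    """Unimodal histogram: ~1e5 bases around 100X (deterministic shape)."""
    cov = np.arange(40, 161)
    dens = np.exp(-0.5 * ((cov - 100) / 12.0) ** 2)
    counts = {int(c): int(round(1e5 * d / dens.sum())) for c, d in zip(cov, dens)}
    counts = {c: n for c, n in counts.items() if n > 0}
    return CoverageHistogram(counts=counts, source="gaussian fixture")


@pytest.fixture
def bimodal_histogram():
    """Two modes at 50X and 100X with comparable mass plus a gap."""
    cov = np.arange(20, 161)
    dens = np.exp(-0.5 * ((cov - 50) / 6.0) ** 2) + np.exp(-0.5 * ((cov - 100) / 8.0) ** 2)
    counts = {int(c): int(round(1e5 * d / dens.sum())) for c, d in zip(cov, dens)}
    counts = {c: n for c, n in counts.items() if n > 0}
    return CoverageHistogram(counts=counts, source="bimodal fixture")


def make_curve(values):
    values = np.asarray(values, dtype=float)
    return SmoothedCurve(coverage_bins=np.arange(len(values)), values=values)
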