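import numpy as np
import pytest

from unwrapseq import FragmentSet, LandscapeSpec, simulate_tss_landscape


@pytest.fixture
def small_fragments() -> FragmentSet:
    """Ten fragments with lengths {40 x4, 90 x2, 110, 130 x2, 150}, one window."""
    lengths = [40, 40, 40, 40, 90, 90, 110, 130, 130, 150]
    starts = [1000 - L // 2 for L in lengths]
    ends = [s + L for s, L in zip(starts, lengths)]
    return FragmentSet(
        np.array(["chr1"] * 10, dtype=object),
        np.array(starts),
        np.array(ends),
        label="toy",
    )


@pytest.fixture(scope="session")
def tss_landscape():
    """A mid-size promoter landscape shared across read-only tests."""
    return simulate_tss_landscape(
        LandscapeSpec(n_refpoints=500, n_downstream=1, seed=101)
    )
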