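import numpy as np
import pandas as pd
import pytest

from scml import CountTable, DesignTable, QpcrTable


@pytest.fixture
def spiked_table() -> CountTable:
    """Four background taxa plus the three canonical spikes, six samples."""
    rng = np.random.default_rng(42)
    samples = [f"S{i}" for i in range(1, 7)]
    bg = pd.DataFrame(
        rng.integers(50, 5000, size=(4, 6)),
        index=["BG1", "BG2", "BG3", "BG4"],
        columns=samples,
    )
    spikes = pd.DataFrame(
        rng.integers(100, 2000, size=(3, 6)),
        index=["OTU_S.ruber", "OTU_R.radiobacter", "OTU_A.acidiphilus"],
        columns=samples,
    )
    spike_map = {
        "S.ruber": "OTU_S.ruber",
        "R.radiobacter": "OTU_R.radiobacter",
        "A.acidiphilus": "OTU_A.acidiphilus",
    }
    return CountTable(pd.concat([bg, spikes]), spike_map)


@pytest.fixture
def dilution_design(spiked_table) -> DesignTable:
    """2-fold dilution series, constant reference, one spike at half ref."""
    samples = spiked_table.sample_ids
    return DesignTable(
        dilution_factor=pd.Series([1, 2, 4, 8, 16, 32], index=samples, dtype=float),
        spike_copies=pd.DataFrame(
            {
                "S.ruber": [3e8] * 6,
                "R.radiobacter": [1.5e8] * 6,
                "A.acidiphilus": [3e8, 1.5e8, 3e8, 6e8, 3e8, 1.5e8],
            },
            index=samples,
        ),
    )


@pytest.fixture
def qpcr_table(spiked_table) -> QpcrTable:
    rng = np.random.default_rng(7)
    totals = pd.Series(
        rng.uniform(1e8, 5e9, size=len(spiked_table.sample_ids)),
        index=spiked_table.sample_ids,
    )
    return QpcrTable(totals)


def random_count_table(rng: np.random.Generator, n_taxa=5, n_samples=4) -> CountTable:
    counts = pd.DataFrame(
        rng.integers(1, 10_000, size=(n_taxa, n_samples)),
        index=[f"T{i}" for i in range(n_taxa)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return CountTable(counts, {"S.ruber": "T0"})
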