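import numpy as np
import pandas as pd
import pytest

from uromics import IntensityMatrix, SampleTable, SimConfig, simulate_dataset


def make_annotation(groups=("DOM", "MUS"), sexes=("M", "F"), n_per_cell=3,
                    n_blanks=2) -> SampleTable:
    rows = []
    for g in groups:
        for s in sexes:
            for i in range(n_per_cell):
                sid = f"{g}_{s}{i}"
                rows.append((sid, g, s, "specimen", f"ind_{sid}"))
    for b in range(n_blanks):
        rows.append((f"B{b}", "blank", "NA", "blank", f"blank{b}"))
    return SampleTable(pd.DataFrame(rows, columns=SampleTable.COLUMNS))


def make_matrix(values, ann: SampleTable, kind="volatile",
                feature_ids=None) -> IntensityMatrix:
    values = np.asarray(values, float)
    fids = feature_ids or [f"F{i}" for i in range(values.shape[0])]
    return IntensityMatrix(values, fids, ann.sample_ids, kind)


@pytest.fixture(scope="session")
def small_annotation():
    return make_annotation()


@pytest.fixture(scope="session")
def sim_default():
    """One default-scale synthetic dataset shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_small():
    """Scaled-down dataset for cheap smoke tests."""
    cfg = SimConfig(n_per_cell=4, n_blanks=3, n_volatiles=200, n_proteins=80,
                    sexbias_volatiles_male=12, sexbias_volatiles_female=4,
                    sexbias_proteins_male=3, sexbias_proteins_female=10,
                    n_pairs=3, seed=2)
    return simulate_dataset(cfg)
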