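import numpy as np
import pandas as pd
import pytest

from txport import SampleMeta, SpectralCountMatrix


def build_design(n_reps=3, conditions=("WT", "mut"), bait="BAIT",
                 n_no_tag=1):
    design = []
    for cond in conditions:
        for r in range(1, n_reps + 1):
            design.append(SampleMeta(f"{cond}_{r}", cond, False, bait, r))
    for k in range(1, n_no_tag + 1):
        design.append(SampleMeta(f"no_tag_{k}", "no_tag", True, None, k))
    return design


def build_matrix(rows: dict, design):
    """rows: protein id -> per-sample counts (in design order)."""
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[s.sample_id for s in design],
                                dtype=float)
    return SpectralCountMatrix(values=df, samples=design)


@pytest.fixture
def design_3v3():
    return build_design(n_reps=3)


@pytest.fixture
def design_2v2():
    return build_design(n_reps=2, conditions=("WT", "fcp1-1"), bait="RPB1")


@pytest.fixture
def toy_matrix(design_3v3):
    # bait + three preys with distinct behaviors; one background-heavy
    rows = {
        "BAIT": [100, 100, 100, 100, 100, 100, 0],
        "P1": [10, 12, 11, 40, 44, 42, 1],
        "P2": [8, 9, 7, 7, 9, 8, 0],
        "STICKY": [30, 31, 29, 30, 28, 32, 30],
    }
    return build_matrix(rows, design_3v3)
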