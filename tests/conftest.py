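import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from deepamp.pileup import COUNT_COLS, PileupTable
from deepamp import simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_column(
    amplicon_id="amp0000",
    direction="F",
    chrom="chrSim",
    pos=1050,
    read_pos=51,
    ref="A",
    counts=(990, 3, 2, 5),
):
    return {
        "amplicon_id": amplicon_id,
        "direction": direction,
        "chrom": chrom,
        "pos": pos,
        "read_pos": read_pos,
        "ref": ref,
        **{c: int(v) for c, v in zip(COUNT_COLS, counts)},
        "depth": int(sum(counts)),
    }


def make_table(columns, sample_id="test", trim_len=122):
    df = pd.DataFrame(columns)
    return PileupTable(df, sample_id=sample_id, meta={"trim_len": trim_len}).validate()


@pytest.fixture(scope="session")
def small_designs():
    return simulate.make_design(n_amplicons=3)


@pytest.fixture(scope="session")
def small_reference(small_designs):
    return simulate.make_reference(small_designs, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
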