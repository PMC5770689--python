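import numpy as np
import pandas as pd
import pytest

from translatomics import QuantTable
from translatomics.simulate import SimConfig, gen_proteome, gen_transcripts


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_proteins=200)


@pytest.fixture(scope="session")
def small_proteome(small_config):
    return gen_proteome(small_config)


@pytest.fixture(scope="session")
def small_transcripts(small_config, small_proteome):
    _, truth = small_proteome
    return gen_transcripts(small_config, truth)


@pytest.fixture()
def quant_row():
    """Single-protein quant table factory."""

    def make(values, orientation=None, protein_id="P1"):
        cols = [f"rep{i + 1}" for i in range(len(values))]
        data = pd.DataFrame([values], index=[protein_id], columns=cols, dtype=float)
        orient = orientation or {c: "standard" for c in cols}
        return QuantTable(data, orient)

    return make


def random_rna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGU"), size=length, p=p))
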