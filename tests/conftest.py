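import numpy as np
import pandas as pd
import pytest

from ensemblefe.esmacs import ENERGY_COMPONENTS
from ensemblefe.synthetic import (
    CompoundSeriesSpec,
    EsmacsSeriesSpec,
    TISeriesSpec,
    gen_compound_series,
    gen_esmacs_dataset,
    gen_ti_dataset,
)

ZERO_NOISE = {c: 0.0 for c in ENERGY_COMPONENTS}


@pytest.fixture(scope="session")
def default_compounds() -> pd.DataFrame:
    """The full emulated series: 140 neutral + 10 charged compounds."""
    return gen_compound_series(CompoundSeriesSpec(seed=11))


@pytest.fixture(scope="session")
def noiseless_ti_table() -> tuple[pd.DataFrame, dict[str, float]]:
    """Three noiseless edges with planted ΔΔG, plus the truth map."""
    truths = {"L30~L2": -2.88, "L2~L7": 1.5, "L30~L7": -1.38}
    spec = TISeriesSpec(
        edges=(("L30", "L2", -2.88), ("L2", "L7", 1.5), ("L30", "L7", -1.38)),
        n_samples_per_window=8,
        within_replica_sd=0.0,
        between_replica_sd=0.0,
        seed=21,
    )
    return gen_ti_dataset(spec), truths


@pytest.fixture()
def noiseless_esmacs_table() -> tuple[pd.DataFrame, dict[str, float]]:
    # planted values whose component split (0.45/0.25/0.25/0.05) is exact in binary
    truth = {"A": -40.0, "B": -20.0}
    spec = EsmacsSeriesSpec(
        true_affinity_map=truth,
        n_replicas=3,
        n_frames=6,
        component_noise_sds=ZERO_NOISE,
        between_replica_sd=0.0,
        seed=4,
    )
    return gen_esmacs_dataset(spec), truth
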