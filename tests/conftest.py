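import numpy as np
import pandas as pd
import pytest

from rootheat.simulate import SimConfig


@pytest.fixture
def four_sample_design():
    """Minimal one-contrast design: 2 treatments x 2 replicates, one plate."""
    return pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3", "s4"],
            "tissue": "RH",
            "treatment": ["control_25C", "control_25C", "heat_40C", "heat_40C"],
            "time_h": 3,
            "replicate": ["r1", "r2", "r1", "r2"],
            "plate": ["p1", "p1", "p1", "p1"],
            "libsize": [1000, 1000, 1000, 1000],
        }
    )


@pytest.fixture
def small_rnaseq_config():
    return SimConfig(
        n_genes=300,
        tissues=("RH",),
        timepoints=(3,),
        de_fraction=0.10,
        effect_log_fc=float(np.log(2.0)),
        sigma_rep=0.1,
        sigma_plate=0.1,
        seed=11,
    )
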