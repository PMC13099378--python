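import warnings

import numpy as np
import pandas as pd
import pytest

from abxgut import synthetic as sy

warnings.filterwarnings("ignore", message=".*MLE may be on the boundary.*")
warnings.filterwarnings("ignore", message=".*converge.*")


@pytest.fixture(scope="session")
def small_sim() -> sy.SimData:
    """One shared small synthetic study with the default planted effects."""
    cfg = sy.SimConfig(
        n_per_cohort=(400, 300, 250),
        species_count=60,
        sequencing_depth=8000,
        seed=7,
    )
    return sy.simulate(cfg)


def toy_records(rows) -> pd.DataFrame:
    """Prescription records from (pid, atc, date, ddd, strength) tuples."""
    return pd.DataFrame(
        rows,
        columns=["participant_id", "atc_code", "dispense_date", "ddd_total", "strength_mg"],
    )


def toy_participants(ids, sampling="2016-06-01", **flags) -> pd.DataFrame:
    samp = pd.Timestamp(sampling)
    df = pd.DataFrame(
        {
            "cohort": "cohort1",
            "sampling_date": samp,
            "visit1_date": samp - pd.Timedelta(days=9),
            "visit2_date": samp,
            "ibd": 0,
            "pulmonary": 0,
            "family_id": "",
        },
        index=pd.Index(ids, name="participant_id"),
    )
    for k, v in flags.items():
        df[k] = v
    return df
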