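import numpy as np
import pandas as pd
import pytest

from cistroshift import datasets
from cistroshift.simulate import (SimConfig, cistrome_from_status_counts,
                                  simulate_cistromes)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=42, n_windows=1000)


@pytest.fixture(scope="session")
def small_matrix(small_config):
    return simulate_cistromes(small_config)


@pytest.fixture(scope="session")
def published_matrix():
    """Matrix realizing the worked-example joint status counts exactly."""
    return cistrome_from_status_counts(datasets.GR_RELA_STATUS_COUNTS,
                                       SimConfig(seed=7))


def tiny_matrix(rows, width=400):
    """Build a minimal CistromeMatrix from (window_id, factor-block dict)
    rows; unspecified stats default to insignificant."""
    from cistroshift.io import CistromeMatrix

    recs = []
    for i, (wid, blocks) in enumerate(rows):
        rec = {"window_id": wid, "chrom": "chr1", "start": 1000 * (i + 1),
               "end": 1000 * (i + 1) + width}
        for (fac, cond), vals in blocks.items():
            rec[f"{fac}_{cond}_intensity"] = vals.get("intensity", 2.0)
            rec[f"{fac}_{cond}_log2fc"] = vals.get("log2fc", 0.0)
            rec[f"{fac}_{cond}_fdr"] = vals.get("fdr", 1.0)
            rec[f"{fac}_{cond}_summit"] = vals.get("summit", np.nan)
        recs.append(rec)
    return CistromeMatrix(pd.DataFrame(recs), width=width)
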