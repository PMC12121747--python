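import numpy as np
import pandas as pd
import pytest

from rdrtb.simulate import SimConfig, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Reduced-size study conditions for fast module tests."""
    return SimConfig(n_per_arm=80, seed=3)


@pytest.fixture
def sim_pair(small_config):
    return simulate_trial(small_config, np.random.default_rng(3))


def make_frame(rows, n_visits=4):
    """Build a trial frame from (id, arm, scores, withdrawal_visit, rd) tuples.

    ``scores`` may contain None for missing cells.
    """
    records = []
    for sid, arm, scores, wvis, rd in rows:
        rec = {"id": sid, "arm": arm}
        for j in range(n_visits + 1):
            rec[f"y{j}"] = np.nan if scores[j] is None else float(scores[j])
        rec["withdrawal_visit"] = np.nan if wvis is None else float(wvis)
        rec["rd_flag"] = bool(rd)
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture
def toy_frame():
    """8 subjects, 2 non-RD withdrawers per arm, 3 RD donors per arm."""
    return make_frame(
        [
            (1, "treatment", [25, 22, 20, 18, 15], None, False),
            (2, "treatment", [27, 25, 22, 20, 18], None, False),
            (3, "treatment", [24, 22, 21, 20, 20], 4, True),
            (4, "treatment", [26, 24, 22, 21, 21], 3, True),
            (5, "treatment", [23, 21, 20, 19, 19], 2, True),
            (6, "treatment", [28, 26, None, None, None], 2, False),
            (7, "treatment", [22, 20, 18, None, None], 3, False),
            (8, "treatment", [30, 27, 25, 23, None], 4, False),
            (11, "placebo", [25, 24, 24, 23, 23], None, False),
            (12, "placebo", [26, 26, 25, 25, 24], None, False),
            (13, "placebo", [27, 26, 24, 22, 21], 3, True),
            (14, "placebo", [24, 23, 21, 20, 19], 2, True),
            (15, "placebo", [25, 25, 23, 22, 20], 4, True),
            (16, "placebo", [28, 27, None, None, None], 2, False),
            (17, "placebo", [23, 22, 22, None, None], 3, False),
            (18, "placebo", [26, 25, 24, 23, None], 4, False),
        ]
    )
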