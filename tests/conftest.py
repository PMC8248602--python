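import numpy as np
import pandas as pd
import pytest

from occmot.config import PetSimConfig, RegionSpec


@pytest.fixture(scope="session")
def noiseless_pet_study():
    """Noiseless baseline + 50%/80% blockade study over the default regions."""
    from occmot.simulate import gen_pet_study

    cfg = PetSimConfig(noise_sd=0.0, seed=11, occupancy_truth={"MO": 0.5, "HO": 0.8})
    return cfg, gen_pet_study(cfg)


def make_refusal_cells(rows):
    """Minimal aggregate-refusal-shaped table from (cond, type, level, rate[, n, rt]) tuples."""
    out = []
    for row in rows:
        cond, trial_type, level, rate = row[:4]
        n = row[4] if len(row) > 4 else 1000
        rt = row[5] if len(row) > 5 else np.nan
        out.append(
            {
                "monkey": "M1",
                "session": f"{cond}-s0",
                "condition": cond,
                "task": "reward_size" if trial_type == "n/a" else "work_delay",
                "trial_type": trial_type,
                "level": level,
                "n_presented": n,
                "n_refused": int(round(rate * n)),
                "refusal_rate": rate,
                "mean_rt_ms": rt,
            }
        )
    return pd.DataFrame(out)
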