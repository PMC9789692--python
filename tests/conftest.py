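"""Shared fixtures: composition constants and a reconstructed per-bird trial.

The reconstructed trial has 7 treatments x 7 birds whose raw-variable
treatment means equal the published treatment means exactly (balanced
zero-sum offsets; egg weight held constant within treatment so the mean of
per-bird egg masses equals the product of the means)."""

import numpy as np
import pandas as pd
import pytest

from quailarg import Composition, reference

# balanced zero-sum offsets across the 7 birds of a treatment
_OFFSETS = np.array([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0])


@pytest.fixture(scope="session")
def composition():
    return Composition()


@pytest.fixture(scope="session")
def implied_composition():
    """Composition with the egg arginine coefficient implied by the
    published deposition column (7.0 mg/g)."""
    return Composition(egg_arg_coeff=reference.IMPLIED_EGG_ARG_COEFF)


@pytest.fixture(scope="session")
def reconstructed_trial():
    """49-bird trial whose raw treatment means equal the published ones."""
    tm = reference.treatment_means()
    rows = []
    for _, t in tm.iterrows():
        ep_mean = t["egg_production"] / 100.0
        bw_init_mean = t["body_weight"] - t["bw_change"] / 2.0
        for j, off in enumerate(_OFFSETS, start=1):
            rows.append({
                "observation": len(rows) + 1,
                "cage": f"{t['treatment']}R{j}",
                "treatment": t["treatment"],
                "replicate": j,
                "arg_level": t["arg_level"],
                "feed_intake": t["feed_intake"] + 0.1 * off,
                "egg_production": np.clip(ep_mean + 0.004 * off, 0.0, 1.0),
                "egg_weight": t["egg_weight"],
                "bw_initial": bw_init_mean + 1.5 * off,
                "bw_final": bw_init_mean + t["bw_change"] + 1.5 * off,
            })
    return pd.DataFrame(rows)


@pytest.fixture()
def trial_csv(tmp_path, reconstructed_trial):
    path = tmp_path / "trial.csv"
    reconstructed_trial.to_csv(path, index=False)
    return path
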