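import numpy as np
import pandas as pd
import pytest

from tripgait.body import BodyModel
from tripgait.events import detect_gait_events
from tripgait.synthetic import (GaitTrialSpec, cohort_spec,
                                generate_feature_table, generate_marker_trial,
                                table1_spec)


@pytest.fixture(scope="session")
def t1_spec():
    return table1_spec()


@pytest.fixture(scope="session")
def cohort_table():
    """Default 298-row, 40-feature synthetic cohort."""
    return generate_feature_table(cohort_spec(), seed=7)


@pytest.fixture(scope="session")
def boosted_table():
    """Separation-boosted cohort for pipeline-recovery checks."""
    return generate_feature_table(cohort_spec().with_boost(3.0), seed=7)


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free synthetic walking trial with its detected events."""
    spec = GaitTrialSpec(gait_speed=1.2, cadence=120.0, trunk_lean=3.0,
                         max_toe_height=0.16, leg_length=0.9, noise_sd=0.0)
    traj = generate_marker_trial(spec, seed=3)
    events = detect_gait_events(traj)
    return spec, traj, events


@pytest.fixture(scope="session")
def body_model():
    return BodyModel(sex="M", leg_length=0.9)


def make_blob_table(n_per_class=100, n_noise=0, spread=1.0, seed=0):
    """Three well-separated Gaussian blobs as a labelled feature table."""
    rng = np.random.default_rng(seed)
    centers = {"no_fall": (0.0, 0.0), "L_fall": (8.0, 0.0), "E_fall": (0.0, 8.0)}
    rows = []
    for cls, (cx, cy) in centers.items():
        block = rng.normal([cx, cy], spread, size=(n_per_class, 2))
        df = pd.DataFrame(block, columns=["f1", "f2"])
        for j in range(n_noise):
            df[f"noise{j}"] = rng.normal(0, 1, n_per_class)
        df["outcome"] = cls
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
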