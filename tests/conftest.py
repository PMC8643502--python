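import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from diaschisis import CohortConfig, generate_cohort, zscore_standardize

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort (22 unilateral + 7 bilateral)."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def default_zscores(default_cohort):
    return zscore_standardize(default_cohort.volumes)


def make_volume_table(records):
    """records: (subject, dataset, role, lobe, area, t, volume)."""
    return pd.DataFrame(
        records,
        columns=["subject_id", "dataset_id", "role", "lobe", "area_label",
                 "time_months", "volume_ml"],
    )


@pytest.fixture
def tiny_area_table():
    """Three datasets, one area: baselines 8/10/12 ml, one follow-up."""
    rows = []
    for i, (v0, v1) in enumerate([(8.0, 6.0), (10.0, 10.0), (12.0, 12.0)]):
        sub = f"s{i}"
        rows.append((sub, f"{sub}_L", "target", "frontal", "G_front_sup", 0.0, v0))
        rows.append((sub, f"{sub}_L", "target", "frontal", "G_front_sup", 2.0, v1))
    return make_volume_table(rows)


def random_masks(n, shape=(5, 5, 5), seed=0, p=0.4):
    from diaschisis import LesionMask

    rng = np.random.default_rng(seed)
    affine = np.eye(4)
    return [
        LesionMask((rng.random(shape) < p).astype(np.uint8), affine,
                   dataset_id=f"d{i}", side="left")
        for i in range(n)
    ]
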