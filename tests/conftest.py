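import numpy as np
import pandas as pd
import pytest

from nociquant import simulate
from nociquant.tables import FeatureTable


@pytest.fixture(scope="session")
def small_timecourse():
    """8-subject microdialysate cohort with 10 planted 2x features among 200."""
    return simulate.gen_metabolomics_timecourse(
        8, 200, 10, effect_size=2.0, noise_cv=0.2, seed=11
    )


@pytest.fixture(scope="session")
def lipid_cohort():
    """10-pair lipidomics cohort, 5 planted 5x fold changes among 100 features."""
    fc = {f"L{i:04d}": 5.0 for i in range(5)}
    table = simulate.gen_lipidomics_cohort(
        10, 100, planted_fc=fc, noise_cv=0.2, seed=21
    )
    return table, fc


@pytest.fixture(scope="session")
def mixed_calcium_cohort():
    """Default class-mix calcium cohort with well-separated amplitudes."""
    return simulate.gen_calcium_traces(
        300, baseline_sd=0.01, amplitude_mean=0.1, amplitude_sd=0.0, seed=4
    )


def toy_feature_table(intensities, conditions, weights=None, qc_rows=()):
    """Hand-built FeatureTable from a 2-D array for arithmetic checks."""
    intensities = np.asarray(intensities, dtype=float)
    n, m = intensities.shape
    sids = [f"s{i}" for i in range(n)]
    fids = [f"f{j}" for j in range(m)]
    samples = pd.DataFrame(
        {
            "subject": [f"sub{i}" for i in range(n)],
            "condition": [None if i in qc_rows else conditions[i] for i in range(n)],
            "fraction": np.nan,
            "is_qc": [i in qc_rows for i in range(n)],
            "weight_mg": weights if weights is not None else np.nan,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    features = pd.DataFrame(
        {"mz": np.linspace(400, 500, m), "rt_s": 100.0, "ion_mode": "+"},
        index=pd.Index(fids, name="feature_id"),
    )
    return FeatureTable(
        intensities=pd.DataFrame(intensities, index=samples.index, columns=features.index),
        features=features,
        samples=samples,
    )
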