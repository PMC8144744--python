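import numpy as np
import pandas as pd
import pytest

import phase4d as p4


@pytest.fixture(scope="session")
def small_table():
    """10-patient synthetic phase-feature table with known truth."""
    design = p4.SimulationDesign(n_patients=10, n_features=20, seed=42)
    table, truth = p4.gen_phase_features(design)
    return table, truth, design


@pytest.fixture(scope="session")
def phantom():
    """Small 4D phantom: images, reference GTV, translations, phases."""
    design = p4.PhantomDesign(shape=(32, 32, 32), radius_mm=6.0,
                              amplitude_mm=5.0, seed=7)
    images, gtv_ref, translations, phases = p4.gen_phantom_4d(design)
    return design, images, gtv_ref, translations, phases


@pytest.fixture(scope="session")
def survival_cohort():
    """n=120 cohort with three planted prognostic features."""
    plants = ["tumour|f0001", "peritumour|f0002", "tumour|f0005"]
    design = p4.SimulationDesign(
        n_patients=120, n_features=25, seed=11,
        planted_features=plants, planted_log_hr=[1.0, -1.0, 0.9],
        event_fraction=0.35)
    table, truth = p4.gen_phase_features(design)
    fm = p4.build_feature_set(table, "mean")
    survival, clinical = p4.gen_outcomes(fm.values, design, volume=truth.volume)
    clinical = p4.merge_categories(clinical)
    return table, truth, fm, survival, clinical, design


def long_frame(values, patients, phases, rois, features):
    """Helper to build a long-format frame from a dense array X[n, ph, roi, f]."""
    rows = []
    for i, pat in enumerate(patients):
        for j, ph in enumerate(phases):
            for k, roi in enumerate(rois):
                for l, feat in enumerate(features):
                    rows.append((pat, ph, roi, feat, values[i, j, k, l]))
    return pd.DataFrame(rows, columns=["patient", "phase", "roi", "feature",
                                       "value"])
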