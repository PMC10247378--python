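import numpy as np
import pandas as pd
import pytest

from metprime.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic cohort shared by integration tests."""
    cfg = SimulationConfig(seed=11, n_primary=20, n_metastatic=20,
                           cancer_types=("breast",))
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_samples():
    def build(n_met=4, n_pri=4, cancer_type="breast"):
        rows = []
        for i in range(n_met):
            rows.append({"sample_id": f"M{i}", "patient_id": f"PM{i}",
                         "cohort": "metastatic", "cancer_type": cancer_type,
                         "cancer_subtype": "", "age_at_biopsy": 60.0,
                         "sex": "female", "biopsy_site_class": "distant",
                         "tumor_purity": 0.8, "genome_ploidy": 2.0,
                         "wgd": False, "msi": False, "hrd": False})
        for i in range(n_pri):
            rows.append({"sample_id": f"P{i}", "patient_id": f"PP{i}",
                         "cohort": "primary", "cancer_type": cancer_type,
                         "cancer_subtype": "", "age_at_biopsy": 60.0,
                         "sex": "female", "biopsy_site_class": "unknown",
                         "tumor_purity": 0.8, "genome_ploidy": 2.0,
                         "wgd": False, "msi": False, "hrd": False})
        return pd.DataFrame(rows)
    return build
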