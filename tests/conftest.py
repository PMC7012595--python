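import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario synthetic cohort with raw layers (shared)."""
    from bioage_panel.simulate import simulate_cohort
    return simulate_cohort(seed=11, include_raw=True)


@pytest.fixture(scope="session")
def masked_cohort(default_sim):
    from bioage_panel.simulate import make_missingness
    return make_missingness(default_sim.cohort, seed=11)


@pytest.fixture()
def toy_cohort_csv(tmp_path):
    """4-row, 2-individual long-format file for I/O tests."""
    df = pd.DataFrame({
        "pair_id": ["P1", "P1", "P1", "P1"],
        "individual_id": ["A", "A", "B", "B"],
        "sex": [0, 0, 1, 1],
        "birth_year": [1920, 1920, 1921, 1921],
        "wave": [1, 2, 1, 3],
        "ca": [66.5, 69.5, 65.5, 71.5],
        "ba_fi": [0.1, 0.15, 0.2, np.nan],
    })
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False)
    return path, df
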