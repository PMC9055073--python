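import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crckit.simulate import CohortSimConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_mutation_table(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical mutation table from sparse row dicts."""
    defaults = {
        "sample_id": "S1",
        "gene": "APC",
        "chrom": "5",
        "pos": 100,
        "ref": "C",
        "alt": "T",
        "func_class": "Missense_Mutation",
        "vaf": 0.3,
        "depth": 100,
        "alt_reads": 30,
        "trinuc_context": "ACG",
        "pop_af_1000g": 0.0,
        "pop_af_exac": 0.0,
        "oncogenicity": "unknown",
        "n_neoantigens": 0,
        "is_silent": False,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture(scope="session")
def small_cohort():
    """120-sample simulated cohort shared across integration tests."""
    cfg = CohortSimConfig(n_samples=120, seed=11)
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
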