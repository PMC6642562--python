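import numpy as np
import pandas as pd
import pytest

from fcomix import ReferenceLibrary, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def toy_library() -> ReferenceLibrary:
    """Small well-separated fetal/adult panel used across unit tests."""
    return ReferenceLibrary(
        probe_ids=("cg00000001", "cg00000002", "cg00000003",
                   "cg00000004", "cg00000005"),
        fetal=np.array([0.9, 0.1, 0.8, 0.2, 0.7]),
        adult=np.array([0.2, 0.8, 0.1, 0.9, 0.3]),
        gene=("EZH2", "", "", "", ""),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at generator defaults, shared where read-only."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture()
def tiny_sheet() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    n = 16
    return pd.DataFrame(
        {
            "group": ["tumor"] * 8 + ["nontumor"] * 8,
            "age": rng.normal(60, 10, n).round(1),
            "gender": list(np.where(rng.random(n) < 0.5, "male", "female")),
            "race": list(rng.choice(["white", "black"], n)),
            "vital_status": list(rng.choice(["alive", "dead"], n)),
            "study": "TOY",
        },
        index=pd.Index([f"S{i:02d}" for i in range(n)], name="sample_id"),
    )
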