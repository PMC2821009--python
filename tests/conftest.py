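import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_diplotypes(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    """Cohort frame with exact diplotype counts (no phenotypes)."""
    rows = []
    i = 0
    for (a, b), n in counts.items():
        for _ in range(n):
            i += 1
            rows.append((f"i{i}", "P1", a, b))
    return pd.DataFrame(rows, columns=["id", "population", "hap_a", "hap_b"])


@pytest.fixture
def small_effect_cohort():
    """n=1500 cohort with a 0.5-SD HDL effect on the h1->h2 branch."""
    from hapscan.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_individuals=(1500,),
        populations=("P1",),
        n_haplotypes=12,
        seq_length=120,
        effect_branch=("h1", "h2"),
        effect_sizes={"hdl": 0.5},
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
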