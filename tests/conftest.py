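import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def pareto_oracle(scores: np.ndarray) -> np.ndarray:
    """O(n^2) all-pairs weak-domination front (maximization); row indices.

    Independent of the package's front implementation: literal translation
    of the definition — a row is on the front iff no other row is >= in all
    dimensions and > in at least one.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    keep = []
    for i in range(n):
        dominated = False
        for k in range(n):
            if k == i:
                continue
            if (scores[k] >= scores[i]).all() and (scores[k] > scores[i]).any():
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return np.array(keep, dtype=int)


@pytest.fixture(scope="session")
def small_dataset():
    """Modest simulated dataset with signal, shared across unit tests."""
    from paretognome.simulate import SimulationConfig, simulate_dataset

    config = SimulationConfig(
        n_individuals=600, n_markers=400, n_causal=10, effect_size=0.8,
        case_fraction=0.5, maf_low=0.1, maf_high=0.5, seed=11,
    )
    gm, variants, phen, truth = simulate_dataset(config)
    return gm, variants, phen, truth


@pytest.fixture(scope="session")
def recovery_dataset():
    """The parameter-recovery study condition: 2,000 individuals, 5,000
    markers, 20 planted causal markers with per-allele log-odds 0.5,
    MAF in [0.1, 0.5], no LD, balanced classes."""
    from paretognome.simulate import SimulationConfig, simulate_dataset

    config = SimulationConfig(
        n_individuals=2000, n_markers=5000, n_causal=20, effect_size=0.5,
        case_fraction=0.5, maf_low=0.1, maf_high=0.5, ld_block_size=1,
        ld_rho=0.0, missing_rate=0.0, seed=20240,
    )
    gm, variants, phen, truth = simulate_dataset(config)
    return gm, variants, phen, truth
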