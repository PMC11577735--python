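import numpy as np
import pytest

import constru as cs


def cytscore_of(cohort) -> np.ndarray:
    return cs.score_signature(cohort.expr, cs.builtin_signature("CYTscore")).scores.to_numpy()


def scan_genes(cohort) -> list[str]:
    """Scan universe: everything except the two score genes themselves."""
    return [g for g in cohort.expr.feature_ids if g not in ("GZMA", "PRF1")]


@pytest.fixture(scope="session")
def small_cohort():
    """A null cohort small enough for fast unit tests."""
    spec = cs.SimulationSpec(n_samples=150, n_genes=60, seed=42)
    return cs.cap_cohort(cs.simulate_cohort(spec), 8.0)


@pytest.fixture(scope="session")
def planted_spec():
    """One conditioning gene whose upper tertile carries a protective score effect."""
    return cs.SimulationSpec(n_samples=300, n_genes=50, seed=7,
                             planted=[cs.PlantedGene(5, "T3", -1.0)])


@pytest.fixture(scope="session")
def planted_cohort(planted_spec):
    return cs.cap_cohort(cs.simulate_cohort(planted_spec), 8.0)


@pytest.fixture(scope="session")
def planted_scan(planted_cohort):
    table = cs.constru_scan(planted_cohort, cytscore_of(planted_cohort),
                            genes=scan_genes(planted_cohort))
    return cs.correlation_filter(table)
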