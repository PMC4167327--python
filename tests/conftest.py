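import numpy as np
import pandas as pd
import pytest

import h2mix as hm


@pytest.fixture(scope="session")
def ref_fixed() -> hm.H2FixedEffects:
    return hm.reference_fixed_effects()


@pytest.fixture(scope="session")
def ref_V() -> hm.RandomEffectsCov:
    return hm.reference_random_effects_cov()


@pytest.fixture(scope="session")
def theta_black(ref_fixed) -> hm.ThetaVector:
    return hm.compose_theta(ref_fixed, hm.SubjectEffects(0.0, 0.0), race=0)


@pytest.fixture(scope="session")
def theta_white(ref_fixed) -> hm.ThetaVector:
    return hm.compose_theta(ref_fixed, hm.SubjectEffects(0.0, 0.0), race=1)


@pytest.fixture(scope="session")
def default_panel() -> pd.DataFrame:
    """One seeded panel at the default scenario (13 states x 2 races x 36 years)."""
    return hm.simulate_panel(hm.SimulationScenario(seed=1))


@pytest.fixture(scope="session")
def noise_free_panel(ref_fixed) -> pd.DataFrame:
    """Panel lying exactly on the two population curves (no noise, no random effects)."""
    rows = []
    t = np.arange(1, 37, dtype=float)
    for s in range(13):
        for race in (0, 1):
            theta = hm.compose_theta(ref_fixed, hm.SubjectEffects(0.0, 0.0), race)
            mu = hm.h2_mean(theta, t)
            for ti, m in zip(t, mu):
                rows.append((f"S{s + 1:02d}", race, int(ti) + 1974, ti, m))
    return pd.DataFrame(rows, columns=["subject", "race", "year", "t", "rate"])


def random_admissible_theta(rng: np.random.Generator) -> hm.ThetaVector:
    """Draw a theta whose curve is admissible on [1, 36] (rejection sampling)."""
    while True:
        theta = hm.ThetaVector(
            theta1=float(rng.uniform(0.5, 10.0)),
            theta2=float(rng.uniform(-1.0, -0.05)),
            theta3=float(rng.uniform(0.001, 0.2)),
            theta4=float(rng.uniform(0.5, 2.0)),
            theta5=float(rng.uniform(-0.2, 0.2)),
            theta6=float(rng.uniform(-0.0005, 0.0005)),
        )
        try:
            hm.h2_mean(theta, np.linspace(1.0, 36.0, 50))
        except hm.AdmissibilityError:
            continue
        return theta
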