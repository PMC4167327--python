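"""Seeded synthetic panels with the structure the mixed model assumes.

The generator emulates a 13-state, two-race, 36-year (1975-2010) panel of
age-adjusted mortality rates: smooth monotone-declining H2 trajectories per
(state, race) series, a persistent Black-White gap that narrows over time,
bivariate-normal state-level deviations in the level and decay-rate
parameters, and additive homoscedastic Gaussian observation noise truncated
at zero.

The reference parameters were calibrated once so that the two population
curves pass through the combined 13-state endpoint rates (Black 13.95 ->
4.20, White 4.88 -> 2.24 per 100,000 over 1975-2010) with an interior pace
maximum for both arms and a monotonically narrowing rate ratio; the
residual variance matches the 1.0442 residual scale of the reference
analysis.  See docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .model import (
    AdmissibilityError,
    H2FixedEffects,
    RandomEffectsCov,
    SubjectEffects,
    compose_theta,
    h2_mean,
)

__all__ = [
    "SimulationScenario",
    "simulate_panel",
    "load_fixture",
    "reference_fixed_effects",
    "reference_random_effects_cov",
    "FIXTURE_NAMES",
    "TIME_ORIGIN",
]

#: model time is year - TIME_ORIGIN, so 1975 maps to t = 1
TIME_ORIGIN = 1974

REFERENCE_ALPHA = (2.5, -1.6352, -0.9353, 0.00534, -0.00302, 1.4)
REFERENCE_SIGMA2 = 1.0442
REFERENCE_V = (0.0225, -2.4e-05, 6.4e-07)


def reference_fixed_effects() -> H2FixedEffects:
    """Calibrated fixed effects reproducing the combined endpoint rates."""
    return H2FixedEffects(alpha=np.array(REFERENCE_ALPHA), sigma2_eps=REFERENCE_SIGMA2)


def reference_random_effects_cov() -> RandomEffectsCov:
    """Between-state covariance of the (level, rate) random effects."""
    return RandomEffectsCov(*REFERENCE_V)


@dataclass(frozen=True)
class SimulationScenario:
    """Design of one synthetic panel.

    Defaults reproduce the 13 x 2 x 36 = 936-row study layout.  ``b_clip_sd``
    truncates random-effect draws at that many standard deviations so that
    extreme states cannot leave the curve's admissible parameter region
    (negligible at the reference scale).  ``noise_sd_by_race`` is a hook for
    heteroscedastic noise; by default both arms share sqrt(sigma2_eps).
    """

    n_subjects: int = 13
    start_year: int = 1975
    end_year: int = 2010
    fixed: H2FixedEffects = field(default_factory=reference_fixed_effects)
    V: RandomEffectsCov = field(default_factory=reference_random_effects_cov)
    seed: int = 0
    b_clip_sd: float = 4.0
    noise_sd_by_race: tuple[float, float] | None = None

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def state_labels(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


def simulate_panel(scenario: SimulationScenario = SimulationScenario()) -> pd.DataFrame:
    """Draw one panel: long format (subject, race, year, t, rate).

    Each (state, race) series gets its own b ~ N2(0, V) (clipped at
    ``b_clip_sd`` standard deviations per axis); rates are the series curve
    plus N(0, sigma2_eps) noise, truncated at zero.  Fully determined by
    ``scenario.seed``.
    """
    fixed, V = scenario.fixed, scenario.V
    if not V.is_positive_definite:
        raise AdmissibilityError("scenario V must be positive definite")
    years = scenario.years
    if len(years) < 1:
        raise ValueError("scenario has no years")
    t = (years - TIME_ORIGIN).astype(float)
    if np.any(t < 1):
        raise ValueError("years must not precede the 1975 time origin")

    # fail fast if the population curves are inadmissible before drawing
    for race in (0, 1):
        h2_mean(compose_theta(fixed, SubjectEffects(0.0, 0.0), race), t)

    chol = np.linalg.cholesky(V.matrix)
    sds = np.sqrt(np.diag(V.matrix))
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for state in scenario.state_labels:
        for race in (0, 1):
            z = rng.standard_normal(2)
            z = np.clip(z, -scenario.b_clip_sd, scenario.b_clip_sd)
            b = chol @ z
            effects = SubjectEffects(b1=float(b[0]), b2=float(b[1]))
            theta = compose_theta(fixed, effects, race)
            mu = h2_mean(theta, t)
            if scenario.noise_sd_by_race is not None:
                sd = scenario.noise_sd_by_race[race]
            else:
                sd = np.sqrt(fixed.sigma2_eps)
            rate = np.maximum(mu + sd * rng.standard_normal(len(t)), 0.0)
            for yr, ti, r in zip(years, t, rate):
                rows.append((state, race, int(yr), float(ti), float(r)))
    return pd.DataFrame(rows, columns=["subject", "race", "year", "t", "rate"])


# ---------------------------------------------------------------------------
# printed fixtures


FIXTURE_NAMES = (
    "table1",
    "table2",
    "table3",
    "table4",
    "table5",
    "endpoints_by_state",
)


class PrintedFixture:
    """Read-only transcription of printed reference values plus citations."""

    def __init__(self, name: str, data: pd.DataFrame):
        self.name = name
        self._data = data

    @property
    def data(self) -> pd.DataFrame:
        return self._data.copy()

    def __getitem__(self, key):
        if self.name == "endpoints_by_state":
            sub = self._data[self._data["state"] == key]
            if len(sub) == 0:
                raise KeyError(key)
            return {
                int(r.year): (float(r.black), float(r.white))
                for r in sub.itertuples()
            }
        keycol = self._data.columns[0]
        sub = self._data[self._data[keycol] == key]
        if len(sub) == 0:
            raise KeyError(key)
        return SimpleNamespace(**sub.iloc[0].to_dict())

    def __len__(self) -> int:
        return len(self._data)


def load_fixture(name: str) -> PrintedFixture:
    """Load one of the shipped printed-value fixtures by name.

    Every row carries a ``citation`` string naming its printed source;
    transcription inconsistencies present in the source are kept as printed
    and annotated in the ``flag`` column rather than silently corrected.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    ref = importlib.resources.files("h2mix").joinpath("fixtures", f"{name}.csv")
    with ref.open("r") as fh:
        data = pd.read_csv(fh, comment="#")
    return PrintedFixture(name, data)
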