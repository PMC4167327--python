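"""Hyperbolastic type II (H2) mean curve and its pace-of-decline analytics.

The population curve for one subject is

    m(t; theta) = (theta1 + theta5) /
                  (1 + theta2 * arcsinh(exp(-(theta3 + theta6) * t**theta4)))

a hyperbolastic type II curve in which ``theta1`` is the level (asymptote,
rate-per-100,000 units), ``theta2`` the dimensionless arcsinh coefficient
(negative for a curve that declines towards its asymptote), ``theta3`` the
decay rate (inverse model-time units), and ``theta4`` the time exponent.
``theta5`` and ``theta6`` are the two random-effect slots: they perturb the
level and the decay rate respectively and are exactly zero for the
population (fixed-effects) curve.

Per-subject parameters are assembled as ``theta_i = A_i @ alpha + B_i @ b_i``
where ``A_i`` couples a binary race covariate (1 = White, 0 = Black) to the
level and rate components and ``B_i`` places the two random effects into the
slots that vanish in the fixed-effects reduction.

Model time is years since 1974, so t = 1 corresponds to calendar year 1975.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "AdmissibilityError",
    "IdenticalCurvesError",
    "ThetaVector",
    "H2FixedEffects",
    "SubjectEffects",
    "RandomEffectsCov",
    "DesignMaps",
    "PaceMax",
    "compose_theta",
    "h2_mean",
    "pace_of_decline",
    "max_pace",
    "equal_pace_time",
    "DEFAULT_TIME_RANGE",
    "DENOM_MIN",
]

#: default admissible model-time interval (1975..2010 in years-since-1974)
DEFAULT_TIME_RANGE: tuple[float, float] = (1.0, 36.0)

#: smallest admissible value of the curve denominator
DENOM_MIN: float = 1e-8

ALPHA_NAMES = ("level", "level_race", "shape", "rate", "rate_race", "power")


class AdmissibilityError(ValueError):
    """Raised when curve parameters leave the admissible region."""


class IdenticalCurvesError(ValueError):
    """Raised when a crossing search is given two identical curves.

    The pace difference is then identically zero, which has no isolated
    crossing times; this is distinct from "no sign change found".
    """


class ThetaVector(NamedTuple):
    """Curve parameters for a single subject.

    ``theta5``/``theta6`` carry the subject's random-effect perturbations of
    the level and decay rate; both are zero on the population curve.
    """

    theta1: float
    theta2: float
    theta3: float
    theta4: float
    theta5: float = 0.0
    theta6: float = 0.0

    @property
    def level(self) -> float:
        return self.theta1 + self.theta5

    @property
    def rate(self) -> float:
        return self.theta3 + self.theta6

    def validate(self) -> "ThetaVector":
        if not np.all(np.isfinite(self)):
            raise AdmissibilityError(f"non-finite theta components: {self}")
        return self


class SubjectEffects(NamedTuple):
    """Mean-zero random deviations of one subject's level and decay rate."""

    b1: float
    b2: float


@dataclass(frozen=True)
class H2FixedEffects:
    """Fixed-effect vector alpha and the residual variance.

    alpha is ordered ``(level, level_race, shape, rate, rate_race, power)``:
    the Black-arm level and decay rate, the race shifts of those two
    components, the shared arcsinh coefficient and the shared time exponent.
    """

    alpha: np.ndarray
    sigma2_eps: float

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.shape != (len(ALPHA_NAMES),):
            raise ValueError(
                f"alpha must have length {len(ALPHA_NAMES)}, got shape {alpha.shape}"
            )
        if not np.all(np.isfinite(alpha)):
            raise ValueError("alpha must be finite")
        if not (np.isfinite(self.sigma2_eps) and self.sigma2_eps > 0):
            raise ValueError(f"sigma2_eps must be > 0, got {self.sigma2_eps}")
        object.__setattr__(self, "alpha", alpha)

    def named(self) -> dict[str, float]:
        return dict(zip(ALPHA_NAMES, self.alpha))


@dataclass(frozen=True)
class RandomEffectsCov:
    """Symmetric 2x2 covariance matrix V of the bivariate random effects."""

    v11: float
    v12: float
    v22: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.v11, self.v12, self.v22])):
            raise ValueError("covariance entries must be finite")
        if self.v11 < 0 or self.v22 < 0 or self.det < 0:
            raise ValueError(
                f"V must be positive semi-definite: v11={self.v11}, "
                f"v12={self.v12}, v22={self.v22}"
            )

    @property
    def det(self) -> float:
        return self.v11 * self.v22 - self.v12 ** 2

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.v11, self.v12], [self.v12, self.v22]])

    @property
    def is_positive_definite(self) -> bool:
        return self.v11 > 0 and self.v22 > 0 and self.det > 0

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RandomEffectsCov":
        m = np.asarray(m, dtype=float)
        if m.shape != (2, 2) or not np.isclose(m[0, 1], m[1, 0]):
            raise ValueError("V must be a symmetric 2x2 matrix")
        return cls(v11=float(m[0, 0]), v12=float(m[0, 1]), v22=float(m[1, 1]))


@dataclass(frozen=True)
class DesignMaps:
    """Design matrices mapping (alpha, race) and b_i into theta_i.

    ``A(race)`` is the 6x6 fixed-effects design: it couples the race
    indicator to the level and rate components and leaves theta5/theta6 at
    zero.  ``B()`` is the 6x2 random-effects design placing (b1, b2) into
    exactly those two slots.
    """

    n_alpha: int = field(default=len(ALPHA_NAMES))

    def A(self, race: int) -> np.ndarray:
        race = _check_race(race)
        a = np.zeros((6, self.n_alpha))
        a[0, 0] = 1.0
        a[0, 1] = race
        a[1, 2] = 1.0
        a[2, 3] = 1.0
        a[2, 4] = race
        a[3, 5] = 1.0
        return a

    def B(self) -> np.ndarray:
        b = np.zeros((6, 2))
        b[4, 0] = 1.0
        b[5, 1] = 1.0
        return b


DESIGN = DesignMaps()


def _check_race(race) -> int:
    if race not in (0, 1):
        raise AdmissibilityError(f"race indicator must be 0 or 1, got {race!r}")
    return int(race)


def compose_theta(
    fixed: H2FixedEffects,
    effects: SubjectEffects,
    race: int,
    design: DesignMaps = DESIGN,
) -> ThetaVector:
    """Assemble one subject's theta_i = A_i @ alpha + B_i @ b_i."""
    race = _check_race(race)
    b = np.asarray(effects, dtype=float)
    if b.shape != (2,):
        raise ValueError(f"expected two random effects, got shape {b.shape}")
    if not np.all(np.isfinite(b)):
        raise AdmissibilityError(f"non-finite random effects: {effects}")
    theta = design.A(race) @ fixed.alpha + design.B() @ b
    return ThetaVector(*theta).validate()


# ---------------------------------------------------------------------------
# array core shared with the fitting machinery


def _curve_denominator(shape, rate, power, t):
    """1 + a*arcsinh(exp(-delta * t**gamma)), overflow-safe for negative delta."""
    x = rate * np.power(t, power)
    # arcsinh(exp(-x)) = log(exp(-x) + sqrt(exp(-2x) + 1)); for very negative x
    # this approaches -x + log(2).  Evaluate via logaddexp-style stabilisation.
    with np.errstate(over="ignore"):
        u = np.exp(-x)
    s = np.where(x < -30.0, -x + np.log(2.0), np.arcsinh(np.minimum(u, 1e300)))
    return s, u, shape * s + 1.0


def _mean_arrays(level, shape, rate, power, t, *, clip: bool = False):
    """Curve mean on arrays (broadcasting); optionally clip the denominator.

    ``clip=True`` is used inside the marginal-likelihood machinery where
    quadrature points may wander outside the admissible region: the
    denominator is floored at DENOM_MIN so the integrand stays finite (the
    resulting huge residuals annihilate those points' weight).
    """
    s, u, denom = _curve_denominator(shape, rate, power, t)
    if clip:
        denom = np.maximum(denom, DENOM_MIN)
    return level / denom, s, u, denom


def _pace_arrays(level, shape, rate, power, t, *, clip: bool = False):
    """Negative analytic time-derivative of the curve mean, on arrays."""
    s, u, denom = _curve_denominator(shape, rate, power, t)
    if clip:
        denom = np.maximum(denom, DENOM_MIN)
    # u / sqrt(1 + u^2) tends to 1 as u -> inf; guard against overflowed u
    with np.errstate(invalid="ignore"):
        w = np.where(u > 1e150, 1.0, u / np.sqrt(1.0 + u * u))
    dsdt = -rate * power * np.power(t, power - 1.0) * w
    return level * shape * dsdt / (denom * denom)


def _theta_parts(theta: ThetaVector):
    theta = ThetaVector(*theta).validate()
    return theta.level, theta.theta2, theta.rate, theta.theta4


def _check_admissible(theta: ThetaVector, t: np.ndarray) -> None:
    level, shape, rate, power = _theta_parts(theta)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise AdmissibilityError("model time must be positive (t = year - 1974)")
    if level <= 0:
        raise AdmissibilityError(f"level parameter must be positive, got {level}")
    _, _, denom = _curve_denominator(shape, rate, power, t)
    if np.any(denom < DENOM_MIN):
        raise AdmissibilityError(
            f"curve denominator fell below {DENOM_MIN:g} "
            f"(min {np.min(denom):.3g}) for theta={tuple(theta)}"
        )


# ---------------------------------------------------------------------------
# public scalar/array operations


def h2_mean(theta: ThetaVector, t):
    """Mean mortality rate (per 100,000) of the H2 curve at model time t.

    t may be a scalar or array in model-time units (years since 1974).
    Raises AdmissibilityError when the parameters make the denominator
    non-positive (or nearly so) at any requested time.
    """
    _check_admissible(theta, t)
    level, shape, rate, power = _theta_parts(theta)
    m, *_ = _mean_arrays(level, shape, rate, power, np.asarray(t, dtype=float))
    return m if np.ndim(t) else float(m)


def pace_of_decline(theta: ThetaVector, t):
    """Pace of decline -dm/dt at model time t (positive while falling)."""
    _check_admissible(theta, t)
    level, shape, rate, power = _theta_parts(theta)
    p = _pace_arrays(level, shape, rate, power, np.asarray(t, dtype=float))
    return p if np.ndim(t) else float(p)


class PaceMax(NamedTuple):
    """Location and value of the maximum pace of decline on an interval."""

    t: float
    pace: float
    degenerate: bool = False


def max_pace(
    theta: ThetaVector,
    t_range: tuple[float, float] = DEFAULT_TIME_RANGE,
    *,
    n_grid: int = 64,
) -> PaceMax:
    """Maximise the pace of decline over a closed interval.

    A coarse grid locates the basin, a bounded scalar optimisation refines
    any interior maximum, and both endpoints are checked.  A flat curve
    (pace identically ~0) is reported as degenerate at the left endpoint.
    """
    lo, hi = float(t_range[0]), float(t_range[1])
    if not lo < hi:
        raise ValueError(f"degenerate interval {t_range}")
    grid = np.linspace(lo, hi, n_grid)
    pace = pace_of_decline(theta, grid)
    if np.max(np.abs(pace)) < 1e-12:
        return PaceMax(t=lo, pace=0.0, degenerate=True)

    k = int(np.argmax(pace))
    t_best, p_best = float(grid[k]), float(pace[k])
    # refine in the bracket around the best grid point
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]
    if a < b:
        res = minimize_scalar(
            lambda t: -pace_of_decline(theta, t),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if np.isfinite(res.fun) and -res.fun > p_best:
            t_best, p_best = float(res.x), float(-res.fun)
    for t_end in (lo, hi):
        p_end = pace_of_decline(theta, t_end)
        if p_end > p_best:
            t_best, p_best = t_end, p_end
    return PaceMax(t=t_best, pace=p_best, degenerate=False)


def equal_pace_time(
    theta_a: ThetaVector,
    theta_b: ThetaVector,
    t_range: tuple[float, float] = DEFAULT_TIME_RANGE,
    *,
    n_scan: int = 512,
) -> list[float]:
    """Times where the two curves' paces of decline cross.

    Sign changes of pace_a - pace_b are bracketed on an ``n_scan``-point
    grid and polished by root bracketing to well below 1e-6 in t.  Returns
    an empty list when the difference never changes sign; raises
    IdenticalCurvesError for identical parameter vectors (the difference is
    then identically zero, which is not an isolated crossing).
    """
    theta_a = ThetaVector(*theta_a)
    theta_b = ThetaVector(*theta_b)
    if tuple(theta_a) == tuple(theta_b):
        raise IdenticalCurvesError(
            "identical curves: pace difference is identically zero"
        )
    lo, hi = float(t_range[0]), float(t_range[1])
    if not lo < hi:
        raise ValueError(f"degenerate interval {t_range}")

    def diff(t):
        return pace_of_decline(theta_a, t) - pace_of_decline(theta_b, t)

    grid = np.linspace(lo, hi, n_scan)
    d = diff(grid)
    roots: list[float] = []
    for i in range(n_scan - 1):
        d0, d1 = d[i], d[i + 1]
        if d0 == 0.0:
            if i == 0 or d[i - 1] * d1 < 0:
                roots.append(float(grid[i]))
            continue
        if d0 * d1 < 0:
            roots.append(float(brentq(diff, grid[i], grid[i + 1], xtol=1e-12)))
    if d[-1] == 0.0 and n_scan > 1 and d[-2] != 0.0:
        roots.append(float(grid[-1]))
    return sorted(roots)
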