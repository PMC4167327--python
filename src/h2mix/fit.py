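"""Marginal maximum-likelihood estimation of the H2 mixed-effects model.

Each (state, race) series i carries a bivariate random effect
b_i = (b1, b2) ~ N2(0, V) perturbing the level and decay rate of its H2
curve; observations are the curve plus homoscedastic Gaussian noise.  The
random effects are integrated out of the Gaussian residual likelihood by
adaptive Gauss-Hermite quadrature centred and scaled at each series'
conditional mode (Laplace approximation when a single node is used).

Panels are long-format pandas DataFrames with columns ``subject`` (state
label), ``race`` (0 = Black, 1 = White), ``t`` (model time, years since
1974) and ``rate`` (deaths per 100,000).  The random-effect unit is the
(subject, race) series, so a 13-state two-race panel has 26 series and the
default degrees of freedom for Wald t-intervals is 26 - 2 = 24.
"""

from __future__ import annotations

import math
from functools import lru_cache
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    ALPHA_NAMES,
    DENOM_MIN,
    AdmissibilityError,
    H2FixedEffects,
    RandomEffectsCov,
    SubjectEffects,
    compose_theta,
    h2_mean,
    _curve_denominator,
    _mean_arrays,
)

__all__ = [
    "PanelObservation",
    "FitConfig",
    "FitResult",
    "conditional_loglik",
    "marginal_loglik",
    "fit_mle",
    "wald_ci",
    "predict_subject",
    "validate_panel",
    "default_init",
]

PANEL_COLUMNS = ("subject", "race", "t", "rate")

LOG2PI = math.log(2.0 * math.pi)


class PanelObservation(NamedTuple):
    """One (series, time) measurement: the y_ij of the model."""

    subject_id: str
    race: int
    t: float
    rate: float


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format panel and return it with canonical dtypes."""
    if not isinstance(panel, pd.DataFrame):
        panel = pd.DataFrame(panel, columns=PANEL_COLUMNS)
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing columns {missing}")
    if len(panel) == 0:
        raise ValueError("panel is empty")
    out = panel.copy()
    out["race"] = out["race"].astype(int)
    if not out["race"].isin((0, 1)).all():
        raise ValueError("race must be coded 0 (Black) or 1 (White)")
    out["t"] = out["t"].astype(float)
    out["rate"] = out["rate"].astype(float)
    if (out["rate"] < 0).any():
        raise ValueError("rates must be nonnegative")
    if out.duplicated(subset=["subject", "race", "t"]).any():
        dup = out[out.duplicated(subset=["subject", "race", "t"], keep=False)]
        raise ValueError(
            f"duplicate (subject, race, t) keys in panel:\n{dup.head()}"
        )
    return out


# ---------------------------------------------------------------------------
# conditional (given b) likelihood


def conditional_loglik(
    fixed: H2FixedEffects,
    effects: SubjectEffects,
    race: int,
    observations: pd.DataFrame,
) -> float:
    """Gaussian log-density of one series' observations about its H2 curve."""
    if fixed.sigma2_eps <= 0:
        raise ValueError("sigma2_eps must be positive")
    if len(observations) == 0:
        raise ValueError("observations must be non-empty")
    theta = compose_theta(fixed, effects, race)
    t = observations["t"].to_numpy(dtype=float)
    y = observations["rate"].to_numpy(dtype=float)
    mu = h2_mean(theta, t)
    s2 = fixed.sigma2_eps
    resid = y - mu
    return float(-0.5 * len(y) * (LOG2PI + math.log(s2)) - np.sum(resid**2) / (2 * s2))


# ---------------------------------------------------------------------------
# packed panel representation (vectorised across series)


class _Packed(NamedTuple):
    keys: list[tuple[str, int]]
    race: np.ndarray  # (S,)
    t: np.ndarray  # (S, Tmax), padded
    y: np.ndarray  # (S, Tmax), padded
    mask: np.ndarray  # (S, Tmax) float 0/1
    nobs: np.ndarray  # (S,)


def _pack(panel: pd.DataFrame) -> _Packed:
    # canonical (subject, race, t) ordering makes every floating-point sum
    # independent of the caller's row order
    panel = validate_panel(panel).sort_values(
        ["subject", "race", "t"], kind="mergesort"
    )
    groups = panel.groupby(["subject", "race"], sort=True)
    keys, ts, ys = [], [], []
    for (subj, race), g in groups:
        keys.append((subj, int(race)))
        ts.append(g["t"].to_numpy(dtype=float))
        ys.append(g["rate"].to_numpy(dtype=float))
    tmax = max(len(t) for t in ts)
    S = len(keys)
    t = np.ones((S, tmax))  # pad with a valid positive time
    y = np.zeros((S, tmax))
    mask = np.zeros((S, tmax))
    for i, (ti, yi) in enumerate(zip(ts, ys)):
        t[i, : len(ti)] = ti
        y[i, : len(yi)] = yi
        mask[i, : len(ti)] = 1.0
    race = np.array([k[1] for k in keys], dtype=float)
    return _Packed(keys, race, t, y, mask, mask.sum(axis=1))


def _series_params(alpha: np.ndarray, race: np.ndarray):
    """Per-series population (level, rate) plus shared (shape, power)."""
    level = alpha[0] + alpha[1] * race
    rate = alpha[3] + alpha[4] * race
    return level, float(alpha[2]), rate, float(alpha[5])


def _curve_jet(level0, shape, rate0, power, b, t, mask):
    """mu and its first/second b-derivatives for all series at once."""
    L = (level0 + b[:, 0])[:, None]
    d = (rate0 + b[:, 1])[:, None]
    s, u, denom = _curve_denominator(shape, d, power, t)
    denom = np.maximum(denom, DENOM_MIN)
    with np.errstate(invalid="ignore"):
        w = np.where(u > 1e150, 1.0, u / np.sqrt(1.0 + u * u))
        dw = np.where(u > 1e150, 0.0, u / np.power(1.0 + u * u, 1.5))
    tg = np.power(t, power)
    mu = L / denom
    J1 = (1.0 / denom) * mask
    J2 = (L * shape * tg * w / denom**2) * mask
    d12 = (shape * tg * w / denom**2) * mask
    d22 = (
        L * shape * tg * (-tg * dw / denom**2 + 2.0 * shape * tg * w * w / denom**3)
    ) * mask
    return mu, J1, J2, d12, d22


def _gauss_newton_modes(
    alpha: np.ndarray,
    sigma2: float,
    Vinv: np.ndarray,
    packed: _Packed,
    b0: np.ndarray | None = None,
    max_iter: int = 40,
    gtol: float = 1e-12,
):
    """Vectorised damped Newton search for all series' conditional modes.

    Maximises g(b) = conditional loglik + random-effects log-prior per
    series with the exact 2x2 Hessian (Gauss-Newton fallback where the
    exact matrix loses positive definiteness).  Returns modes (S,2), the
    negative Hessians H (S,2,2) at the modes, and g at the modes.
    """
    level0, shape, rate0, power = _series_params(alpha, packed.race)
    t, y, mask = packed.t, packed.y, packed.mask
    S = len(packed.keys)
    b = np.zeros((S, 2)) if b0 is None else b0.copy()

    # log phi2(b; 0, V) = -log(2*pi) - 0.5*log|V| - 0.5 b' Vinv b
    log_prior_const = -LOG2PI + 0.5 * math.log(np.linalg.det(Vinv))
    ll_const = -0.5 * packed.nobs * (LOG2PI + math.log(sigma2))

    def g_of(bb):
        L = (level0 + bb[:, 0])[:, None]
        d = (rate0 + bb[:, 1])[:, None]
        mu, _, _, _ = _mean_arrays(L, shape, d, power, t, clip=True)
        resid = (y - mu) * mask
        ll = -0.5 * np.sum(resid**2, axis=1) / sigma2 + ll_const
        lp = -0.5 * np.einsum("si,ij,sj->s", bb, Vinv, bb) + log_prior_const
        return ll + lp

    def hess_of(bb, resid, J1, J2, d12, d22):
        Hgn = np.empty((S, 2, 2))
        Hgn[:, 0, 0] = np.sum(J1 * J1, axis=1) / sigma2 + Vinv[0, 0]
        Hgn[:, 0, 1] = Hgn[:, 1, 0] = np.sum(J1 * J2, axis=1) / sigma2 + Vinv[0, 1]
        Hgn[:, 1, 1] = np.sum(J2 * J2, axis=1) / sigma2 + Vinv[1, 1]
        H = Hgn.copy()
        H[:, 0, 1] -= np.sum(resid * d12, axis=1) / sigma2
        H[:, 1, 0] = H[:, 0, 1]
        H[:, 1, 1] -= np.sum(resid * d22, axis=1) / sigma2
        bad = (H[:, 0, 0] <= 0) | (H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2 <= 0)
        if np.any(bad):
            H[bad] = Hgn[bad]
        return H

    g = g_of(b)
    H = None
    for _ in range(max_iter):
        mu, J1, J2, d12, d22 = _curve_jet(level0, shape, rate0, power, b, t, mask)
        resid = (y - mu) * mask
        grad = np.stack(
            [np.sum(resid * J1, axis=1), np.sum(resid * J2, axis=1)], axis=1
        ) / sigma2 - b @ Vinv
        H = hess_of(b, resid, J1, J2, d12, d22)
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        # dimensionless Newton decrement: grad' H^{-1} grad per series
        decrement = np.einsum("si,si->s", grad, step)
        active = decrement > gtol
        if not np.any(active):
            break
        step[~active] = 0.0
        scale = np.ones(S)
        g_new = g
        for _ in range(25):
            b_new = b + step * scale[:, None]
            g_new = g_of(b_new)
            worse = active & (g_new < g - 1e-12)
            if not np.any(worse):
                break
            scale[worse] *= 0.5
        improved = active & (g_new >= g)
        b[improved] = b_new[improved]
        g = np.where(improved, g_new, g)
        if not np.any(improved):
            break
    if H is None:  # pragma: no cover - max_iter >= 1 always
        mu, J1, J2, d12, d22 = _curve_jet(level0, shape, rate0, power, b, t, mask)
        H = hess_of(b, (y - mu) * mask, J1, J2, d12, d22)
    return b, H, g_of(b)


@lru_cache(maxsize=8)
def _herm2d(nodes: int):
    """Cached 2-D tensor Gauss-Hermite abscissae, log-weights and |z|^2."""
    z, wq = np.polynomial.hermite.hermgauss(nodes)
    Z = np.array([(zk, zl) for zk in z for zl in z])
    logW = np.array([math.log(wk) + math.log(wl) for wk in wq for wl in wq])
    zsq = np.sum(Z**2, axis=1)
    for arr in (Z, logW, zsq):
        arr.setflags(write=False)
    return Z, logW, zsq


def _agh_loglik(
    alpha: np.ndarray,
    sigma2: float,
    V: RandomEffectsCov,
    packed: _Packed,
    nodes: int,
    b0: np.ndarray | None = None,
):
    """Adaptive Gauss-Hermite marginal log-likelihood; returns (total, per-series, modes)."""
    Vinv = np.linalg.inv(V.matrix)
    modes, H, g_mode = _gauss_newton_modes(alpha, sigma2, Vinv, packed, b0=b0)
    if not np.all(np.isfinite(g_mode)):
        bad = packed.keys[int(np.argmax(~np.isfinite(g_mode)))]
        raise RuntimeError(f"non-finite integrand at the mode for series {bad}")

    # Cholesky of each H; A = inv(Lh)^T satisfies A A^T = H^{-1}
    Lh = np.linalg.cholesky(H)
    logdetA = -np.log(Lh[:, 0, 0] * Lh[:, 1, 1])

    if nodes == 1:
        # Laplace: log integral = g(mode) + log(2*pi) + log|det A|
        per = g_mode + LOG2PI + logdetA
        return float(np.sum(per)), per, modes

    Z, logW, zsq = _herm2d(nodes)

    A = np.linalg.inv(np.transpose(Lh, (0, 2, 1)))  # (S,2,2), A = Lh^{-T}
    pts = modes[:, None, :] + math.sqrt(2.0) * np.einsum("sij,qj->sqi", A, Z)

    level0, shape, rate0, power = _series_params(alpha, packed.race)
    L = level0[:, None, None] + pts[:, :, 0:1]
    d = rate0[:, None, None] + pts[:, :, 1:2]
    mu, _, _, _ = _mean_arrays(L, shape, d, power, packed.t[:, None, :], clip=True)
    resid = (packed.y[:, None, :] - mu) * packed.mask[:, None, :]
    ll = -0.5 * np.sum(resid**2, axis=2) / sigma2 \
         - 0.5 * packed.nobs[:, None] * (LOG2PI + math.log(sigma2))
    lp = -0.5 * np.einsum("sqi,ij,sqj->sq", pts, Vinv, pts) \
         - LOG2PI - 0.5 * math.log(V.det)
    expo = ll + lp + zsq[None, :] + logW[None, :]
    m = np.max(expo, axis=1)
    per = math.log(2.0) + logdetA + m + np.log(np.sum(np.exp(expo - m[:, None]), axis=1))
    return float(np.sum(per)), per, modes


def marginal_loglik(
    fixed: H2FixedEffects,
    V: RandomEffectsCov,
    panel: pd.DataFrame,
    *,
    nodes: int = 7,
) -> float:
    """Log-likelihood with the bivariate random effects integrated out.

    The integral over each series' b_i is evaluated by Gauss-Hermite
    quadrature recentred at the series' conditional mode and rescaled by the
    curvature there (``nodes`` points per axis; 1 node gives the Laplace
    approximation).  The result is invariant to series ordering.
    """
    if not V.is_positive_definite:
        raise ValueError(f"V must be positive definite, got {V}")
    if nodes < 1:
        raise ValueError("nodes must be >= 1")
    packed = _pack(panel)
    total, _, _ = _agh_loglik(fixed.alpha, fixed.sigma2_eps, V, packed, nodes)
    return total


# ---------------------------------------------------------------------------
# maximum likelihood


@dataclass(frozen=True)
class FitConfig:
    """Knobs for the marginal-ML fit.

    nodes: Gauss-Hermite nodes per random-effect axis (1 = Laplace).
    include_random_effects: fit the full mixed model, or the fixed-effects
        H2 curve alone (V omitted; useful for noise-free identity checks).
    df: degrees of freedom for t-intervals; default n_series - 2.
    restarts: jittered restarts attempted after a failed optimisation.
    """

    nodes: int = 9
    include_random_effects: bool = True
    df: int | None = None
    level: float = 0.95
    maxiter: int = 500
    ftol: float = 1e-9
    gtol: float = 1e-5
    restarts: int = 3
    seed: int = 0
    hessian_rel_step: float = 1e-4
    compute_ses: bool = True


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics of one marginal-ML fit."""

    names: list[str]
    estimates: np.ndarray
    ses: np.ndarray
    df: int
    t_values: np.ndarray
    p_values: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    loglik: float
    converged: bool
    message: str
    vcov: np.ndarray | None
    n_series: int
    grad_norm: float
    fixed: H2FixedEffects
    V: RandomEffectsCov | None
    config: FitConfig

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.ses[self.names.index(name)])

    def to_table(self) -> pd.DataFrame:
        """NLMIXED-style parameter table (one row per parameter)."""
        return pd.DataFrame(
            {
                "Parameter": self.names,
                "Estimate": self.estimates,
                "SE": self.ses,
                "DF": self.df,
                "t-value": self.t_values,
                "P-value": self.p_values,
                "Alpha": 1.0 - self.level,
                "Lower": self.ci_lower,
                "Upper": self.ci_upper,
            }
        )


def wald_ci(estimate: float, se: float, df: int, level: float) -> tuple[float, float]:
    """Two-sided t-based Wald interval: estimate +/- t_{(1+level)/2, df} * se."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if se == 0:
        return (estimate, estimate)
    half = stats.t.ppf(0.5 * (1.0 + level), df) * se
    return (estimate - half, estimate + half)


def default_init(panel: pd.DataFrame) -> tuple[H2FixedEffects, RandomEffectsCov]:
    """Rough data-driven starting values for fit_mle.

    Level starts are placed a little below the latest observed arm means
    (the asymptote lies below the final rates of a declining curve); rates
    and shape start at values typical for a 36-year decline.
    """
    panel = validate_panel(panel).sort_values(
        ["subject", "race", "t"], kind="mergesort", ignore_index=True
    )
    first_t = panel["t"].min()
    last_t = panel["t"].max()
    end0 = panel.query("race == 0 and t == @last_t")["rate"].mean()
    end1 = panel.query("race == 1 and t == @last_t")["rate"].mean()
    if not np.isfinite(end0):
        end0 = panel.query("race == 0")["rate"].mean()
    if not np.isfinite(end1):
        end1 = panel.query("race == 1")["rate"].mean()
    level0 = max(0.6 * end0, 0.1)
    level1 = max(0.4 * end1, 0.05)
    alpha = np.array([level0, level1 - level0, -0.9, 0.008, -0.004, 1.2])
    resid_scale = panel.groupby(["race", "t"])["rate"].transform("mean")
    sigma2 = float(np.var(panel["rate"] - resid_scale)) or 1.0
    fixed = H2FixedEffects(alpha=alpha, sigma2_eps=max(sigma2, 1e-4))
    V = RandomEffectsCov(v11=0.02, v12=0.0, v22=1e-6)
    return fixed, V


def _transform(fixed: H2FixedEffects, V: RandomEffectsCov | None) -> np.ndarray:
    p = list(fixed.alpha)
    if V is not None:
        rho = V.v12 / math.sqrt(V.v11 * V.v22)
        rho = min(max(rho, -0.999), 0.999)
        p += [math.log(V.v11), math.log(V.v22), math.atanh(rho)]
    p += [math.log(fixed.sigma2_eps)]
    return np.array(p)


def _untransform(p: np.ndarray, with_re: bool):
    alpha = np.asarray(p[:6], dtype=float)
    if with_re:
        v11 = math.exp(min(p[6], 50.0))
        v22 = math.exp(min(p[7], 50.0))
        rho = math.tanh(p[8])
        V = RandomEffectsCov(v11=v11, v12=rho * math.sqrt(v11 * v22), v22=v22)
        sigma2 = math.exp(min(p[9], 50.0))
    else:
        V = None
        sigma2 = math.exp(min(p[6], 50.0))
    return alpha, V, sigma2


def _population_violation(alpha: np.ndarray, t: np.ndarray) -> float:
    """How far the two population curves stray from the admissible region."""
    viol = 0.0
    for race in (0.0, 1.0):
        level = alpha[0] + alpha[1] * race
        rate = alpha[3] + alpha[4] * race
        if alpha[5] <= 0:
            viol += 1.0 - alpha[5]
            continue
        _, _, denom = _curve_denominator(alpha[2], rate, alpha[5], t)
        dmin = float(np.min(denom))
        if dmin < DENOM_MIN:
            viol += DENOM_MIN - dmin
        if level <= 0:
            viol += 1.0 - level
    return viol


def _fixed_effects_rss(alpha: np.ndarray, packed: _Packed) -> float:
    level0, shape, rate0, power = _series_params(alpha, packed.race)
    mu, _, _, _ = _mean_arrays(
        level0[:, None], shape, rate0[:, None], power, packed.t, clip=True
    )
    resid = (packed.y - mu) * packed.mask
    return float(np.sum(resid**2))


def _param_scales(with_re: bool) -> np.ndarray:
    """Characteristic scales of the transformed parameters.

    The optimiser works in units of these scales so that the quasi-Newton
    steps are well conditioned across components whose natural magnitudes
    differ by orders of magnitude (e.g. curve level vs decay rate).
    """
    s = [0.3, 0.3, 0.05, 0.002, 0.002, 0.1]
    if with_re:
        s += [0.5, 0.5, 0.5]
    s += [0.1]
    return np.array(s)


def _param_bounds(with_re: bool) -> list[tuple[float | None, float | None]]:
    """Generous box constraints on the transformed parameter vector."""
    bounds: list[tuple[float | None, float | None]] = [
        (None, None),  # level
        (None, None),  # level_race
        (None, None),  # shape
        (None, None),  # rate
        (None, None),  # rate_race
        (0.05, 10.0),  # power
    ]
    if with_re:
        bounds += [(-25.0, 5.0), (-25.0, 5.0), (-6.0, 6.0)]  # log v11, log v22, atanh rho
    bounds += [(-20.0, 5.0)]  # log sigma2
    return bounds


def fit_mle(
    panel: pd.DataFrame,
    init: tuple[H2FixedEffects, RandomEffectsCov] | H2FixedEffects | None = None,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Maximise the marginal likelihood over fixed effects and variances.

    Quasi-Newton (L-BFGS-B) optimisation on transformed parameters (log
    variances, atanh correlation); on non-convergence the fit restarts from
    jittered initial values.  Standard errors come from the inverse of a
    central-difference observed-information matrix on the original scale.
    """
    packed = _pack(panel)
    tmin = np.array(
        [len(np.unique(packed.t[i][packed.mask[i] > 0])) for i in range(len(packed.keys))]
    )
    if np.any(tmin < 3):
        bad = packed.keys[int(np.argmax(tmin < 3))]
        raise ValueError(
            f"series {bad} has fewer than 3 distinct time points; "
            "the curve parameters are not identifiable"
        )

    with_re = config.include_random_effects
    if init is None:
        fixed0, V0 = default_init(panel)
        if with_re:
            # two-stage start: a cheap fixed-effects fit positions alpha and
            # sigma2 before the expensive marginal optimisation begins
            stage1 = fit_mle(
                panel,
                init=fixed0,
                config=replace(
                    config, include_random_effects=False, compute_ses=False, restarts=1
                ),
            )
            if stage1.converged:
                fixed0 = stage1.fixed
    elif isinstance(init, H2FixedEffects):
        fixed0, V0 = init, RandomEffectsCov(v11=0.02, v12=0.0, v22=1e-6)
    else:
        fixed0, V0 = init
    if with_re and not V0.is_positive_definite:
        raise ValueError("initial V must be positive definite")

    t_all = np.unique(packed.t[packed.mask > 0])
    if _population_violation(fixed0.alpha, t_all) > 0:
        raise AdmissibilityError("initial values are outside the admissible region")

    warm = {"modes": None}

    def negloglik(p: np.ndarray) -> float:
        alpha, V, sigma2 = _untransform(p, with_re)
        viol = _population_violation(alpha, t_all)
        if viol > 0:
            return 1e6 * (1.0 + viol)
        try:
            if with_re:
                total, _, modes = _agh_loglik(
                    alpha, sigma2, V, packed, config.nodes, b0=warm["modes"]
                )
                warm["modes"] = modes
            else:
                # sigma2 has a closed-form optimum (RSS/n) given alpha, so the
                # fixed-effects objective is the profile log-likelihood; this
                # keeps the zero-noise limit well conditioned
                n = packed.nobs.sum()
                rss = _fixed_effects_rss(alpha, packed)
                total = float(-0.5 * n * (LOG2PI + math.log(max(rss, 1e-300) / n) + 1.0))
        except (np.linalg.LinAlgError, RuntimeError, AdmissibilityError):
            return 1e10
        if not np.isfinite(total):
            return 1e10
        return -total

    p0 = _transform(fixed0, V0 if with_re else None)
    rng = np.random.default_rng(config.seed)
    message = ""
    if not with_re:
        # pure nonlinear least squares: sigma2 is profiled out exactly, so
        # only alpha is free; trust-region reflective handles the zero-noise
        # limit gracefully
        n_total = packed.nobs.sum()

        def residuals(alpha):
            viol = _population_violation(alpha, t_all)
            if viol > 0:
                return np.full(int(n_total), 1e6 * (1.0 + viol))
            level0, shape, rate0, power = _series_params(alpha, packed.race)
            mu, _, _, _ = _mean_arrays(
                level0[:, None], shape, rate0[:, None], power, packed.t, clip=True
            )
            return ((packed.y - mu) * packed.mask)[packed.mask > 0]

        lower = np.array([-np.inf] * 5 + [0.05])
        upper = np.array([np.inf] * 5 + [10.0])
        best_nls = None
        for attempt in range(config.restarts + 1):
            a_start = (
                fixed0.alpha
                if attempt == 0
                else fixed0.alpha * (1.0 + 0.05 * rng.standard_normal(6))
            )
            a_start = np.clip(a_start, lower + 1e-9, upper - 1e-9)
            nls = optimize.least_squares(
                residuals, a_start, bounds=(lower, upper),
                xtol=1e-14, ftol=1e-14, gtol=1e-12, max_nfev=20000,
            )
            if best_nls is None or nls.cost < best_nls.cost:
                best_nls = nls
            if nls.success:
                break
            message = f"restart {attempt + 1}: {nls.message}"
        nls = best_nls
        converged = bool(nls.success)
        if converged:
            message = str(nls.message)
        alpha_hat = nls.x
        rss = max(2.0 * nls.cost, 1e-300)
        sigma2_hat = rss / n_total
        loglik = float(-0.5 * n_total * (LOG2PI + math.log(sigma2_hat) + 1.0))
        res_x = np.concatenate([alpha_hat, [math.log(sigma2_hat)]])
        grad_norm = float(np.max(np.abs(nls.grad)))
    else:
        scales = _param_scales(with_re)
        bounds = [
            (lo / s if lo is not None else None, hi / s if hi is not None else None)
            for (lo, hi), s in zip(_param_bounds(with_re), scales)
        ]

        def negloglik_scaled(ps: np.ndarray) -> float:
            return negloglik(ps * scales)

        best = None
        for attempt in range(config.restarts + 1):
            p_start = p0 / scales
            if attempt > 0:
                p_start = p_start + 0.5 * rng.standard_normal(p_start.shape)
            warm["modes"] = None
            res = optimize.minimize(
                negloglik_scaled,
                p_start,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": config.maxiter,
                    "ftol": config.ftol,
                    "gtol": config.gtol,
                },
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success and res.fun < 1e5:
                break
            message = f"restart {attempt + 1}: {res.message}"
        res = best
        converged = bool(res.success and res.fun < 1e5)
        loglik0 = -negloglik(p0)
        loglik = -float(res.fun)
        if converged and loglik < loglik0 - 1e-6:
            converged = False
            message = "final log-likelihood below initial value"
        if converged:
            message = str(res.message)
        res_x = res.x * scales
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan

    alpha_hat, V_hat, sigma2_hat = _untransform(res_x, with_re)
    fixed_hat = H2FixedEffects(alpha=alpha_hat, sigma2_eps=sigma2_hat)

    names = list(ALPHA_NAMES)
    q = list(alpha_hat)
    if with_re:
        names += ["v11", "v12", "v22"]
        q += [V_hat.v11, V_hat.v12, V_hat.v22]
    names += ["sigma2"]
    q += [sigma2_hat]
    q = np.array(q)

    def negloglik_full(p: np.ndarray) -> float:
        """Non-profiled objective used for the observed information."""
        if with_re:
            return negloglik(p)
        alpha, _, sigma2 = _untransform(p, with_re)
        viol = _population_violation(alpha, t_all)
        if viol > 0:
            return 1e6 * (1.0 + viol)
        n = packed.nobs.sum()
        rss = _fixed_effects_rss(alpha, packed)
        return float(0.5 * rss / sigma2 + 0.5 * n * (LOG2PI + math.log(sigma2)))

    ses = np.full(len(q), np.nan)
    vcov = None
    if converged and config.compute_ses:
        try:
            Hp = _numeric_hessian(
                negloglik_full,
                res_x,
                rel_step=config.hessian_rel_step,
                scales=_param_scales(with_re),
            )
            eig = np.linalg.eigvalsh(Hp)
            if np.all(eig > 0):
                vcov_p = np.linalg.inv(Hp)
                J = _transform_jacobian(res_x, with_re)
                vcov = J @ vcov_p @ J.T
                ses = np.sqrt(np.maximum(np.diag(vcov), 0.0))
            else:
                message += "; observed information not positive definite, SEs undefined"
        except np.linalg.LinAlgError:
            message += "; Hessian factorisation failed, SEs undefined"

    df = config.df if config.df is not None else max(len(packed.keys) - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_values = q / ses
    p_values = 2.0 * stats.t.sf(np.abs(t_values), df)
    ci = np.array(
        [
            wald_ci(e, s, df, config.level) if np.isfinite(s) else (np.nan, np.nan)
            for e, s in zip(q, ses)
        ]
    )

    return FitResult(
        names=names,
        estimates=q,
        ses=ses,
        df=df,
        t_values=t_values,
        p_values=p_values,
        ci_lower=ci[:, 0],
        ci_upper=ci[:, 1],
        level=config.level,
        loglik=loglik,
        converged=converged,
        message=message,
        vcov=vcov,
        n_series=len(packed.keys),
        grad_norm=grad_norm,
        fixed=fixed_hat,
        V=V_hat,
        config=config,
    )


def _transform_jacobian(p: np.ndarray, with_re: bool) -> np.ndarray:
    """Jacobian of original-scale parameters w.r.t. the transformed vector.

    Original order: alpha (6), [v11, v12, v22,] sigma2; transformed order:
    alpha (6), [log v11, log v22, atanh rho,] log sigma2.
    """
    if not with_re:
        J = np.eye(7)
        J[6, 6] = math.exp(p[6])  # d sigma2 / d log sigma2
        return J
    v11 = math.exp(p[6])
    v22 = math.exp(p[7])
    rho = math.tanh(p[8])
    v12 = rho * math.sqrt(v11 * v22)
    J = np.zeros((10, 10))
    J[:6, :6] = np.eye(6)
    J[6, 6] = v11
    J[7, 6] = 0.5 * v12
    J[7, 7] = 0.5 * v12
    J[7, 8] = (1.0 - rho**2) * math.sqrt(v11 * v22)
    J[8, 7] = v22
    J[9, 9] = math.exp(p[9])
    return J


def _numeric_hessian(
    f, x: np.ndarray, rel_step: float = 1e-4, scales: np.ndarray | None = None
) -> np.ndarray:
    """Central-difference Hessian with per-parameter steps.

    Steps are relative to each parameter's characteristic scale (when
    given) rather than its magnitude, so parameters sitting near zero still
    get steps large enough to rise above evaluation noise.
    """
    n = len(x)
    if scales is not None:
        h = 100.0 * rel_step * scales
    else:
        h = rel_step * np.maximum(np.abs(x), 1e-2)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def predict_subject(
    fit: FitResult,
    panel: pd.DataFrame,
    subject_id: str,
    race: int | None = None,
    t_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes fitted curve for one (subject, race) series.

    The series' random effect is set to the mode of its conditional
    distribution given the data at the fitted parameters, and the H2 curve
    is evaluated along the series' observed time range (or ``t_grid``).
    """
    if not fit.converged:
        raise RuntimeError("cannot predict from an unconverged fit")
    panel = validate_panel(panel)
    sub = panel[panel["subject"] == subject_id]
    if len(sub) == 0:
        raise KeyError(f"unknown subject {subject_id!r}")
    if race is None:
        races = sub["race"].unique()
        if len(races) > 1:
            raise ValueError(
                f"subject {subject_id!r} has both races; pass race=0 or race=1"
            )
        race = int(races[0])
    sub = sub[sub["race"] == race]
    if len(sub) == 0:
        raise KeyError(f"no race={race} series for subject {subject_id!r}")

    if fit.V is not None and fit.config.include_random_effects:
        packed = _pack(sub)
        Vinv = np.linalg.inv(fit.V.matrix)
        modes, _, _ = _gauss_newton_modes(
            fit.fixed.alpha, fit.fixed.sigma2_eps, Vinv, packed
        )
        effects = SubjectEffects(b1=float(modes[0, 0]), b2=float(modes[0, 1]))
    else:
        effects = SubjectEffects(b1=0.0, b2=0.0)
    theta = compose_theta(fit.fixed, effects, race)
    if t_grid is None:
        t_grid = np.sort(sub["t"].unique())
    t_grid = np.asarray(t_grid, dtype=float)
    pred = h2_mean(theta, t_grid)
    out = pd.DataFrame({"t": t_grid, "rate_pred": pred})
    out.attrs["effects"] = effects
    out.attrs["subject"] = subject_id
    out.attrs["race"] = race
    return out
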