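"""Unwrapped-fraction statistics and the two-state force model.

The fraction of nucleosomes that unwrap their inner turn within the
observation window, alpha = N_unwrapped / N_total, is a binomial
proportion; exact Clopper-Pearson intervals quantify its uncertainty.
Because reconstituted arrays carry a minor tetrasome population (~26%)
that unwraps far faster than canonical nucleosomes, measured fractions
are corrected to refer to canonical nucleosomes only before model
fitting.

The force dependence of the (tetrasome-corrected) unwrapping probability
is described by a two-state Arrhenius-type model,

    P(F) = 1 / (1 + exp(-(dx / kBT) * (F - F_half)))

where F_half is the force at which half the nucleosomes unwrap within
the window and dx is the effective distance to the transition state.
The rate-limiting free-energy barrier is dG = F_half * dx.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from nucleoforce.mechanics import KBT_ROOM

DEFAULT_TETRASOME_FRACTION = 0.26


@dataclass(frozen=True)
class FractionEstimate:
    """Binomial unwrapped-fraction estimate with an exact 95% (or other) CI."""

    n_unwrapped: int
    n_total: int
    alpha: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    force: float | None = None
    condition: str | None = None


@dataclass(frozen=True)
class ArrheniusFit:
    """Fitted two-state unwrapping-probability model.

    ``f_half`` (pN) is the half force, ``delta_x`` (nm) the effective
    distance to the transition state; standard errors come from the
    binomial-likelihood covariance via the delta method.
    """

    f_half: float
    delta_x: float
    kBT: float = KBT_ROOM
    f_half_se: float = float("nan")
    delta_x_se: float = float("nan")
    covariance: np.ndarray | None = field(default=None, compare=False)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n.

    Computed by beta-distribution quantile inversion; the lower bound is 0
    when k = 0 and the upper bound is 1 when k = n.
    """
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("require 0 <= k <= n with n > 0")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    a = (1.0 - level) / 2.0
    low = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return low, high


def unwrapped_fraction(
    n_unwrapped: int,
    n_total: int,
    level: float = 0.95,
    force: float | None = None,
    condition: str | None = None,
) -> FractionEstimate:
    """Unwrapped fraction alpha = N_unwrapped / N_total with exact CI."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_unwrapped <= n_total):
        raise ValueError("require 0 <= n_unwrapped <= n_total")
    alpha = n_unwrapped / n_total
    lo, hi = clopper_pearson(n_unwrapped, n_total, level)
    return FractionEstimate(n_unwrapped, n_total, alpha, lo, hi, level, force, condition)


def tetrasome_correct(
    alpha: float, tetrasome_fraction: float = DEFAULT_TETRASOME_FRACTION
) -> float:
    """Correct a measured unwrapped fraction for the tetrasome population.

    alpha_corrected = (alpha - f) / (1 - f), clipped to [0, 1].  The
    correction assumes the tetrasome subpopulation (fraction ``f`` of
    assembled particles) always unwraps within the window, so the
    corrected value refers to canonical nucleosomes only.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if not (0.0 <= tetrasome_fraction < 1.0):
        raise ValueError("tetrasome_fraction must lie in [0, 1)")
    return float(np.clip((alpha - tetrasome_fraction) / (1.0 - tetrasome_fraction), 0.0, 1.0))


def arrhenius_probability(force, fit: ArrheniusFit):
    """P(F): probability of inner-turn unwrapping within the window.

    Logistic in force with slope delta_x / kBT; equals 0.5 at F = F_half
    and is strictly increasing in force.
    """
    force = np.asarray(force, dtype=float)
    z = (fit.delta_x / fit.kBT) * (force - fit.f_half)
    p = 1.0 / (1.0 + np.exp(-z))
    return p if p.ndim else float(p)


def fit_arrhenius(
    observations,
    kBT: float = KBT_ROOM,
) -> ArrheniusFit:
    """Fit the two-state model to per-force unwrap counts by binomial MLE.

    Parameters
    ----------
    observations : sequence of (force_pN, n_unwrapped, n_total)
        Tetrasome-corrected counts per clamp force; at least three
        distinct forces are required.

    Notes
    -----
    The model is a logistic regression of unwrap outcome on force:
    P = logistic(b0 + b1*F), with delta_x = b1*kBT and
    F_half = -b0/b1.  The likelihood is maximized with statsmodels'
    binomial GLM; standard errors for (F_half, delta_x) follow from the
    (b0, b1) covariance by the delta method.
    """
    import statsmodels.api as sm

    obs = [(float(f), int(k), int(n)) for f, k, n in observations]
    forces = np.array([o[0] for o in obs])
    ks = np.array([o[1] for o in obs])
    ns = np.array([o[2] for o in obs])
    if len(np.unique(forces)) < 3:
        raise ValueError("need counts at >=3 distinct forces")
    if np.any(ks < 0) or np.any(ks > ns) or np.any(ns <= 0):
        raise ValueError("invalid counts: require 0 <= n_unwrapped <= n_total, n_total > 0")
    if np.all(ks == 0) or np.all(ks == ns):
        raise ValueError(
            "complete separation: all counts are 0 or all are n; "
            "the logistic slope is unidentifiable"
        )

    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    X = sm.add_constant(forces)
    model = sm.GLM(np.column_stack([ks, ns - ks]), X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # quasi-separation (0 or n counts at the extreme forces) is routine
        # for steep sigmoids; the delta-method SEs already reflect it
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit()
    b0, b1 = res.params
    if b1 <= 0:
        raise ValueError("fitted slope is non-positive; unwrapping must increase with force")
    cov_b = np.asarray(res.cov_params())

    delta_x = b1 * kBT
    f_half = -b0 / b1
    # delta method: theta = (F_half, dx) = (-b0/b1, kBT*b1)
    J = np.array([[-1.0 / b1, b0 / b1**2], [0.0, kBT]])
    cov_theta = J @ cov_b @ J.T
    return ArrheniusFit(
        f_half=float(f_half),
        delta_x=float(delta_x),
        kBT=kBT,
        f_half_se=float(np.sqrt(cov_theta[0, 0])),
        delta_x_se=float(np.sqrt(cov_theta[1, 1])),
        covariance=cov_theta,
    )


def delta_g(fit: ArrheniusFit) -> float:
    """Rate-limiting free-energy barrier F_half * delta_x, in kBT units."""
    return fit.f_half * fit.delta_x / fit.kBT


def difference_curve(
    fit_without: ArrheniusFit,
    fit_with: ArrheniusFit,
    f_max: float = 30.0,
) -> dict:
    """Characterize D(F) = P_with(F) - P_without(F) on [0, f_max] pN.

    Returns the force of maximal effect (peak), the peak height, and the
    full-width-at-half-maximum crossing forces — the force range over
    which the remodeler most efficiently promotes unwrapping.
    """

    def d(force):
        return arrhenius_probability(force, fit_with) - arrhenius_probability(
            force, fit_without
        )

    res = optimize.minimize_scalar(
        lambda f: -d(f), bounds=(0.0, f_max), method="bounded",
        options={"xatol": 1e-8},
    )
    peak_force = float(res.x)
    peak_height = float(d(peak_force))
    if peak_height <= 1e-12:
        raise ValueError("difference curve has no positive peak")
    half = peak_height / 2.0
    lo = float(optimize.brentq(lambda f: d(f) - half, 0.0, peak_force, xtol=1e-10)) \
        if d(0.0) < half else 0.0
    hi = float(optimize.brentq(lambda f: d(f) - half, peak_force, f_max, xtol=1e-10)) \
        if d(f_max) < half else f_max
    return {
        "peak_force": peak_force,
        "peak_height": peak_height,
        "fwhm_low": lo,
        "fwhm_high": hi,
    }


def newcombe_difference_ci(
    k1: int, n1: int, k2: int, n2: int, level: float = 0.95
) -> tuple[float, float]:
    """Newcombe score-based CI for a difference of two proportions p1 - p2.

    Provided as a utility for comparing unwrapped fractions between
    conditions; combines Wilson score limits for each proportion.
    """
    z = stats.norm.ppf(1 - (1 - level) / 2)

    def wilson(k, n):
        p = k / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        return center - half, center + half

    l1, u1 = wilson(k1, n1)
    l2, u2 = wilson(k2, n2)
    diff = k1 / n1 - k2 / n2
    return float(diff - np.sqrt((k1 / n1 - l1) ** 2 + (u2 - k2 / n2) ** 2)), float(
        diff + np.sqrt((u1 - k1 / n1) ** 2 + (k2 / n2 - l2) ** 2)
    )
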