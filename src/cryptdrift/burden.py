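"""Mutational burden in normal colon from clone-fixation and fission rates.

A clone that fixes in a crypt (rate ``delta_cfix`` per crypt per year,
constant from birth) founds a patch that expands by crypt fission, a Yule
pure-birth process at per-crypt rate ``rho`` per year. The per-crypt
probability of observing a patch of size ``n`` at age ``t`` is

    F_n(t) = delta_cfix * (1 - exp(-rho t))^n / (rho n),

so patch frequency is conserved (sum_n F_n = delta_cfix * t; Yule patches
never die) and the expected mutant-crypt fraction — the mutational burden —
is

    B(t) = sum_{n>=1} n F_n(t) = delta_cfix * (exp(rho t) - 1) / rho.

The closed form is the default compute path; the literal truncated sum
(500,000 terms by default) is kept as a faithful mode and as the cross-check
oracle. Scaling B(t) by the number of crypts in a colon (42 million by
default) gives whole-organ clone counts; dividing B(70) by a gene's
truncating-mutation frequency in tumours gives the fraction of tumours
explained by the gene being a passenger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "COLON_CRYPTS",
    "DEFAULT_TRUNCATION",
    "BurdenParams",
    "BurdenCurve",
    "patch_prob",
    "burden",
    "colon_count",
    "burden_ci",
    "passenger_fraction",
    "burden_curve",
    "crossing_age",
]

#: Crypts in an adult human colon.
COLON_CRYPTS = 42_000_000

#: Terms retained when evaluating B(t) as an explicit finite sum.
DEFAULT_TRUNCATION = 500_000


@dataclass(frozen=True)
class BurdenParams:
    """Inputs of the burden model.

    delta_cfix : fixation slope, per crypt per year.
    rho : crypt fission rate, per year.
    t : age, years.
    truncation_order : terms kept in the explicit sum mode.
    colon_crypts : crypts per colon, for whole-organ counts.
    """

    delta_cfix: float
    rho: float
    t: float
    truncation_order: int = DEFAULT_TRUNCATION
    colon_crypts: int = COLON_CRYPTS

    def __post_init__(self) -> None:
        if self.delta_cfix < 0 or self.rho < 0 or self.t < 0:
            raise ValueError("delta_cfix, rho and t must be non-negative")
        if self.truncation_order < 1:
            raise ValueError("truncation_order must be >= 1")
        if self.colon_crypts < 1:
            raise ValueError("colon_crypts must be >= 1")


@dataclass(frozen=True)
class BurdenCurve:
    """Burden over an age grid with a plug-in credible band."""

    ages: np.ndarray
    burden_per_crypt: np.ndarray
    ci_lower: np.ndarray | None
    ci_upper: np.ndarray | None
    colon_counts: np.ndarray


def patch_prob(n, params: BurdenParams):
    """Per-crypt probability F_n(t) of a patch of exactly ``n`` crypts.

    Evaluated in log space so very large ``n`` underflows gracefully to 0.
    For ``rho == 0`` the Yule process is frozen and only size-1 patches
    occur, with the analytic limit F_1 = delta_cfix * t.
    """
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("patch size n must be >= 1")
    if params.rho == 0.0:
        return np.where(n_arr == 1, params.delta_cfix * params.t, 0.0)[()]
    q = -np.expm1(-params.rho * params.t)  # 1 - e^{-rho t}
    if q == 0.0:  # t == 0
        return np.zeros_like(n_arr, dtype=float)[()]
    with np.errstate(divide="ignore"):
        log_f = (
            math.log(params.delta_cfix)
            + n_arr * math.log(q)
            - np.log(params.rho * n_arr)
            if params.delta_cfix > 0
            else np.full(n_arr.shape, -np.inf)
        )
    return np.exp(log_f)[()]


def burden(params: BurdenParams, mode: str = "closed") -> float:
    """Expected mutant crypts per crypt, B(t).

    mode="closed" evaluates delta_cfix*(e^{rho t}-1)/rho (exact; rho->0
    limit is delta_cfix*t). mode="sum" evaluates the explicit truncated sum
    sum_{n=1}^{N} n F_n(t), which agrees with the closed form to ~1e-9
    relative error whenever the geometric tail beyond N is negligible.
    Exponents beyond float range are computed in log space and may return inf.
    """
    if mode == "closed":
        x = params.rho * params.t
        if params.rho == 0.0 or x < 1e-12:
            # series limit: (e^x - 1)/rho -> t as rho -> 0
            return params.delta_cfix * params.t
        if x > 700.0:  # expm1 would overflow; log-space closed form
            log_b = math.log(params.delta_cfix) + x - math.log(params.rho) if params.delta_cfix > 0 else -math.inf
            return math.exp(log_b) if log_b < 709 else math.inf
        return params.delta_cfix * math.expm1(x) / params.rho
    if mode == "sum":
        if params.rho == 0.0:
            return params.delta_cfix * params.t
        n = np.arange(1, params.truncation_order + 1)
        return float(np.sum(n * patch_prob(n, params)))
    raise ValueError(f"unknown mode {mode!r}")


def colon_count(params: BurdenParams, mode: str = "closed") -> float:
    """Expected number of mutant crypts in a whole colon at age t."""
    return burden(params, mode=mode) * params.colon_crypts


def burden_ci(
    point: BurdenParams,
    slope_ci: tuple[float, float],
    rho_ci: tuple[float, float],
) -> tuple[float, float]:
    """Plug-in 95% band for B(t) from parameter credible intervals.

    B is monotone increasing in both delta_cfix and rho, so the extremes of
    the (slope, rho) rectangle are attained at (lo, lo) and (hi, hi).
    """
    s_lo, s_hi = slope_ci
    r_lo, r_hi = rho_ci
    if not (s_lo <= point.delta_cfix <= s_hi):
        raise ValueError("slope interval does not bracket the point estimate")
    if not (r_lo <= point.rho <= r_hi):
        raise ValueError("rho interval does not bracket the point estimate")
    lower = burden(replace(point, delta_cfix=s_lo, rho=r_lo))
    upper = burden(replace(point, delta_cfix=s_hi, rho=r_hi))
    return lower, upper


def passenger_fraction(
    burden_at_70: float,
    tumour_truncating_freq: float,
    burden_ci95: tuple[float, float] | None = None,
):
    """Percentage of tumours explained by the gene being a passenger.

    The normal-tissue burden at age 70 is divided by the fraction of tumours
    carrying a truncating mutation in the gene (an external input, e.g.
    extracted from COSMIC) and expressed as a percentage. Values above 100%
    are permitted: normal-tissue selection alone then over-explains the
    gene's tumour prevalence.

    Returns the percentage, or ``(percent, (lo, hi))`` when a burden CI is
    supplied.
    """
    if not 0.0 < tumour_truncating_freq <= 1.0:
        raise ValueError(
            "tumour_truncating_freq must be in (0, 1]: it is the fraction of "
            "tumours with a truncating mutation in the gene"
        )
    pct = 100.0 * burden_at_70 / tumour_truncating_freq
    if burden_ci95 is None:
        return pct
    lo, hi = burden_ci95
    return pct, (100.0 * lo / tumour_truncating_freq, 100.0 * hi / tumour_truncating_freq)


def burden_curve(
    delta_cfix: float,
    rho: float,
    ages,
    slope_ci: tuple[float, float] | None = None,
    rho_ci: tuple[float, float] | None = None,
    colon_crypts: int = COLON_CRYPTS,
) -> BurdenCurve:
    """B(t) over an increasing age grid, with optional plug-in band."""
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1 or np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be a strictly increasing 1-D grid")
    pts = np.array(
        [burden(BurdenParams(delta_cfix, rho, t, colon_crypts=colon_crypts)) for t in ages]
    )
    lo = hi = None
    if slope_ci is not None and rho_ci is not None:
        band = [
            burden_ci(BurdenParams(delta_cfix, rho, t, colon_crypts=colon_crypts), slope_ci, rho_ci)
            for t in ages
        ]
        lo = np.array([b[0] for b in band])
        hi = np.array([b[1] for b in band])
    return BurdenCurve(ages, pts, lo, hi, pts * colon_crypts)


def crossing_age(
    delta_cfix: float,
    rho: float,
    target_freq: float,
    t_max: float = 200.0,
) -> float:
    """Age at which B(t) reaches ``target_freq`` (e.g. a gene's tumour
    frequency), or ``inf`` if it is not reached by ``t_max``.

    B is strictly increasing in t, so the root is unique when it exists.
    """
    if target_freq <= 0:
        raise ValueError("target_freq must be positive")
    if delta_cfix == 0:
        return math.inf

    def f(t: float) -> float:
        return burden(BurdenParams(delta_cfix, rho, t)) - target_freq

    if f(t_max) < 0:
        return math.inf
    return float(brentq(f, 0.0, t_max, xtol=1e-9))
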