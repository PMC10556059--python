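"""Power-law (log10-log10) regression of composition ratios, with bootstrap
inference and spurious-ratio null models.

The tissue As:P ratio is regressed on phosphorus content in log10-log10
space; uptake theory predicts slope −1 (a pure hyperbola), and the question
of interest is whether the fitted exponent is steeper ("supra-hyperbolic").
Two hypothesis tests are reported for the slope b: H0: b = 0 (no dependence)
and H0: b = −1 (the theoretical hyperbola), both conventional t-tests on the
OLS slope, alongside a nonparametric pair-bootstrap percentile CI.

A caveat this module makes testable: for ANY two independent positive random
variables a and b, the regression of log(a/b) on log(b) has expected slope
exactly −1, since Cov(log a − log b, log b)/Var(log b) = −1 when a ⟂ b.  A
fitted slope of −1 is therefore not by itself evidence of the uptake
mechanism; a slope significantly steeper than −1 is informative, as is the
contrast with ratios (As:C) whose denominator is not the limiting nutrient.
:func:`spurious_ratio_null` generates that null distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import NotFittableError

__all__ = [
    "PowerLawFit",
    "fit_power_law",
    "spurious_ratio_null",
    "correlation_summary",
]


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(y) = intercept + slope * log10(x).

    ``ci_low``/``ci_high`` bound the slope by nonparametric pair bootstrap
    (percentile method).  ``p_vs_zero`` and ``p_vs_minus_one`` are two-sided
    t-tests of the slope against 0 and against the theoretical hyperbola
    value −1.  Reproducible bit-for-bit given ``seed``.
    """

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r_squared: float
    n: int
    p_vs_zero: float
    p_vs_minus_one: float
    se_slope: float
    n_boot: int
    seed: int | None
    excluded_nonpositive: int
    method: str = "OLS log10-log10; pair bootstrap percentile CI; t-tests vs 0 and -1"

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "r_squared": self.r_squared,
            "n": self.n,
            "p_vs_zero": self.p_vs_zero,
            "p_vs_minus_one": self.p_vs_minus_one,
            "se_slope": self.se_slope,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "excluded_nonpositive": self.excluded_nonpositive,
            "method": self.method,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _ols_slope_intercept(lx: np.ndarray, ly: np.ndarray):
    mx, my = lx.mean(), ly.mean()
    sxx = np.mean((lx - mx) ** 2)
    sxy = np.mean((lx - mx) * (ly - my))
    slope = sxy / sxx
    return slope, my - slope * mx


def _bootstrap_slopes(
    lx: np.ndarray, ly: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized pair-bootstrap slope replicates (chunked to bound memory)."""
    n = lx.size
    slopes = np.empty(n_boot)
    chunk = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        bx, by = lx[idx], ly[idx]
        mx = bx.mean(axis=1, keepdims=True)
        my = by.mean(axis=1, keepdims=True)
        sxx = ((bx - mx) ** 2).mean(axis=1)
        sxy = ((bx - mx) * (by - my)).mean(axis=1)
        slopes[done : done + m] = sxy / sxx
        done += m
    return slopes


def fit_power_law(
    x,
    y,
    n_boot: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> PowerLawFit:
    """Fit y = 10^a * x^b by OLS on (log10 x, log10 y) pairs.

    Non-positive or non-finite pairs are excluded (count reported); fewer
    than 3 valid pairs raises :class:`~gulfweed.errors.NotFittableError`.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    valid = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    excluded = int(x.size - valid.sum())
    x, y = x[valid], y[valid]
    n = x.size
    if n < 3:
        raise NotFittableError(f"only {n} positive finite pairs; need >= 3")

    lx, ly = np.log10(x), np.log10(y)
    slope, intercept = _ols_slope_intercept(lx, ly)
    resid = ly - (intercept + slope * lx)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = n - 2
    sxx = float(np.sum((lx - lx.mean()) ** 2))
    if dof > 0 and sxx > 0:
        se = np.sqrt(ss_res / dof / sxx)
    else:
        se = np.nan
    if se > 0:
        p_vs_zero = 2 * stats.t.sf(abs(slope / se), dof)
        p_vs_minus_one = 2 * stats.t.sf(abs((slope + 1.0) / se), dof)
    else:  # perfect fit: slope known exactly
        p_vs_zero = 0.0 if slope != 0 else 1.0
        p_vs_minus_one = 0.0 if slope != -1.0 else 1.0

    rng = np.random.default_rng(seed)
    boot = _bootstrap_slopes(lx, ly, n_boot, rng)
    alpha = 1.0 - ci_level
    ci_low, ci_high = np.quantile(boot, [alpha / 2, 1 - alpha / 2])

    return PowerLawFit(
        slope=float(slope),
        intercept=float(intercept),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        r_squared=float(r_squared),
        n=n,
        p_vs_zero=float(p_vs_zero),
        p_vs_minus_one=float(p_vs_minus_one),
        se_slope=float(se),
        n_boot=n_boot,
        seed=seed,
        excluded_nonpositive=excluded,
    )


def spurious_ratio_null(
    n: int,
    seed: int | None = None,
    reps: int = 200,
    sigma_a: float = 1.0,
    sigma_b: float = 1.0,
    rho: float = 0.0,
) -> np.ndarray:
    """Null distribution of the log(a/b)-on-log(b) slope for random a, b.

    Draws ``reps`` datasets of ``n`` lognormal pairs with log-scale SDs
    ``sigma_a``/``sigma_b`` and correlation ``rho`` between log a and log b,
    and fits the ratio-vs-denominator regression to each.  For independent
    a and b (``rho=0``) the slopes center exactly on −1; under correlation
    the population slope is ``rho*sigma_a/sigma_b − 1``.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    za = rng.standard_normal((reps, n))
    zb = rng.standard_normal((reps, n))
    log_b = sigma_b * zb
    log_a = sigma_a * (rho * zb + np.sqrt(max(0.0, 1 - rho**2)) * za)
    log_ratio = log_a - log_b
    mb = log_b.mean(axis=1, keepdims=True)
    mr = log_ratio.mean(axis=1, keepdims=True)
    sxx = ((log_b - mb) ** 2).mean(axis=1)
    sxy = ((log_b - mb) * (log_ratio - mr)).mean(axis=1)
    return sxy / sxx


_RATIO_DENOMS = {"as_to_p": "pct_P", "as_to_n": "pct_N", "as_to_c": "pct_C"}


@dataclass
class CorrelationSummary:
    """Pairwise correlations among As and elemental contents, plus the
    companion ratio-vs-denominator power-law fits that make the hyperbolic /
    non-hyperbolic contrast an output rather than prose."""

    correlations: "pd.DataFrame"  # noqa: F821 - documented type
    ratio_fits: dict = field(default_factory=dict)


def correlation_summary(
    samples,
    variables: Sequence[str] = ("as_ug_g", "pct_P", "pct_N", "pct_C"),
    n_boot: int = 1000,
    seed: int | None = None,
) -> CorrelationSummary:
    """Pairwise Pearson correlations (Fisher-z CIs) among tissue variables,
    plus power-law fits of As:X (weight basis) against %X for X in P, N, C.

    ``samples`` is a tissue table (DataFrame with the documented schema).
    Cells with fewer than 3 complete pairs are flagged with NaN statistics
    and ``ok=False``.
    """
    import pandas as pd

    rows = []
    for i, va in enumerate(variables):
        for vb in variables[i + 1 :]:
            pair = samples[[va, vb]].dropna()
            if len(pair) < 3:
                rows.append(
                    dict(var_a=va, var_b=vb, n=len(pair), r=np.nan,
                         ci_low=np.nan, ci_high=np.nan, p=np.nan, ok=False)
                )
                continue
            r, p = stats.pearsonr(pair[va], pair[vb])
            n = len(pair)
            if abs(r) < 1.0 and n > 3:
                z = np.arctanh(r)
                zse = 1.0 / np.sqrt(n - 3)
                lo, hi = np.tanh(z - 1.959964 * zse), np.tanh(z + 1.959964 * zse)
            else:
                lo = hi = r
            rows.append(
                dict(var_a=va, var_b=vb, n=n, r=float(r),
                     ci_low=float(lo), ci_high=float(hi), p=float(p), ok=True)
            )
    corr = pd.DataFrame(rows)

    fits: dict[str, PowerLawFit | None] = {}
    for name, denom in _RATIO_DENOMS.items():
        pair = samples[["as_ug_g", denom]].dropna()
        pair = pair[(pair["as_ug_g"] > 0) & (pair[denom] > 0)]
        if len(pair) < 3:
            fits[name] = None
            continue
        ratio = (pair["as_ug_g"] / 1e4) / pair[denom]  # weight basis, % / %
        fits[name] = fit_power_law(pair[denom], ratio, n_boot=n_boot, seed=seed)
    return CorrelationSummary(correlations=corr, ratio_fits=fits)
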