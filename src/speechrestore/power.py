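"""A-priori power analysis for the multiple-regression R^2 test.

The omnibus test of a fixed-predictor linear model is F(k, N-k-1); under the
alternative the statistic is noncentral F with noncentrality lambda = f^2*N
(the total-sample-size convention of standard power software; an error-df
convention is available behind a flag). Cohen's f^2 = R^2/(1-R^2), so
f^2 = 0.3 is a medium-to-large effect (R^2 ~ 0.23). The required sample size
is the smallest integer N whose achieved power meets the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PowerSpec", "achieved_power", "required_sample_size", "monte_carlo_power"]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the regression power computation."""

    f2: float
    alpha: float = 0.05
    power: float = 0.9
    n_predictors: int = 4
    lambda_convention: str = "total_n"

    def __post_init__(self) -> None:
        if not self.f2 > 0:
            raise ValueError("f2 must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.n_predictors < 1:
            raise ValueError("need at least one predictor")
        if self.lambda_convention not in ("total_n", "error_df"):
            raise ValueError("lambda_convention must be 'total_n' or 'error_df'")


def achieved_power(spec: PowerSpec, n: int) -> float:
    """Power of the model F test at total sample size ``n``."""
    k = spec.n_predictors
    df2 = n - k - 1
    if df2 < 1:
        return 0.0
    lam = spec.f2 * (n if spec.lambda_convention == "total_n" else df2)
    f_crit = sps.f.isf(spec.alpha, k, df2)
    return float(sps.ncf.sf(f_crit, k, df2, lam))


def required_sample_size(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest N whose noncentral-F power reaches the target.

    Searches upward from N = n_predictors + 2 (the first size with a
    positive error df). Power is nondecreasing in N, so the first hit is
    the minimum.
    """
    n = spec.n_predictors + 2
    while n <= n_max:
        if achieved_power(spec, n) >= spec.power:
            return n
        n += 1
    raise ValueError(f"target power not attainable within N <= {n_max}")


def monte_carlo_power(spec: PowerSpec, n: int, n_reps: int = 10_000, seed: int = 0) -> float:
    """Simulation cross-check of the analytic power at sample size ``n``.

    Each replicate draws a fresh standard-normal design, an equal-weight
    coefficient vector scaled so the population f^2 matches the spec, and
    unit Gaussian noise; the model F test is applied at the spec's alpha.
    Returns the rejection rate.
    """
    k = spec.n_predictors
    df2 = n - k - 1
    if df2 < 1:
        raise ValueError("n too small for the design")
    rng = np.random.default_rng(seed)
    beta = np.full(k, np.sqrt(spec.f2 / k))
    f_crit = sps.f.isf(spec.alpha, k, df2)
    rejections = 0
    batch = 500
    done = 0
    while done < n_reps:
        b = min(batch, n_reps - done)
        X = rng.standard_normal((b, n, k))
        y = X @ beta + rng.standard_normal((b, n))
        y = y - y.mean(axis=1, keepdims=True)
        Xc = X - X.mean(axis=1, keepdims=True)
        # batched least squares via normal equations (k is tiny)
        XtX = np.einsum("bni,bnj->bij", Xc, Xc)
        Xty = np.einsum("bni,bn->bi", Xc, y)
        coef = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        ss_tot = np.sum(y**2, axis=1)
        ss_res = ss_tot - np.einsum("bi,bi->b", coef, Xty)
        r2 = 1.0 - ss_res / ss_tot
        F = (r2 / k) / ((1.0 - r2) / df2)
        rejections += int(np.sum(F > f_crit))
        done += b
    return rejections / n_reps
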