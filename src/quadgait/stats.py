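"""Statistical procedures for phase, index, and spatiotemporal data.

Implements the two-proportion (binomial proportion) z-test in both
variance conventions, the Watson two-sample U-squared test on circular
data with a seeded permutation (or asymptotic) p-value, circular
descriptive statistics, speed-curve regression (exponential decay and
linear) with 95% prediction intervals, and the paired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "ProportionTestResult",
    "two_proportion_z",
    "CircularTestResult",
    "watson_u2",
    "watson_u2_statistic",
    "circular_descriptives",
    "RegressionFit",
    "fit_speed_curve",
    "paired_t",
]


# ---------------------------------------------------------------------------
# two-proportion z-test


@dataclass(frozen=True)
class ProportionTestResult:
    k1: int
    n1: int
    k2: int
    n2: int
    variant: str
    z: float
    p: float


def two_proportion_z(
    k1: int, n1: int, k2: int, n2: int, variant: str = "unpooled"
) -> ProportionTestResult:
    """Two-proportion z-test, z = (p2 - p1) / SE, two-tailed normal p.

    ``variant="pooled"`` uses the pooled standard error
    sqrt(p(1-p)(1/n1 + 1/n2)) with p = (k1+k2)/(n1+n2);
    ``"unpooled"`` uses sqrt(p1(1-p1)/n1 + p2(1-p2)/n2).  The sign of z
    follows p2 - p1.  Raises when the standard error is zero (both
    proportions at the same boundary).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if variant not in ("pooled", "unpooled"):
        raise ValueError(f"unknown variant {variant!r}")
    p1, p2 = k1 / n1, k2 / n2
    if variant == "pooled":
        p = (k1 + k2) / (n1 + n2)
        se = math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    else:
        se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if se == 0.0:
        raise ValueError("zero standard error: both proportions degenerate")
    z = (p2 - p1) / se
    p_two = 2.0 * sps.norm.sf(abs(z))
    return ProportionTestResult(k1=k1, n1=n1, k2=k2, n2=n2, variant=variant, z=z, p=p_two)


# ---------------------------------------------------------------------------
# Watson two-sample U^2


@dataclass(frozen=True)
class CircularTestResult:
    u2: float
    p: float
    n1: int
    n2: int
    method: str
    n_permutations: int = 0
    seed: Optional[int] = None


def watson_u2_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Watson's two-sample U^2 from pooled empirical CDFs on the circle.

    Values are circular fractions in [0, 1).  With d_k the difference of
    the two sample ECDFs at the k-th pooled point (ties weighted by
    multiplicity t_k), U^2 = (n1 n2 / N^2) * [sum t_k d_k^2 -
    (sum t_k d_k)^2 / N].  U^2 is invariant to a common rotation of both
    samples.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    uniq, counts = np.unique(pooled, return_counts=True)
    ca = np.searchsorted(a, uniq, side="right") / n1
    cb = np.searchsorted(b, uniq, side="right") / n2
    d = ca - cb
    sw = float(np.sum(counts * d))
    sw2 = float(np.sum(counts * d * d))
    return (n1 * n2) / n**2 * (sw2 - sw * sw / n)


def watson_u2(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_permutations: int = 9999,
    seed: Optional[int] = None,
    method: str = "permutation",
) -> CircularTestResult:
    """Watson two-sample U^2 test of a common circular distribution.

    ``method="permutation"`` (default) permutes group labels
    ``n_permutations`` times with the given seed and reports
    p = (1 + #{U* >= U}) / (n_permutations + 1).  ``method="asymptotic"``
    uses the large-sample tail series 2 * sum (-1)^(m-1)
    exp(-2 m^2 pi^2 U^2).  Two identical degenerate samples give U^2 = 0,
    p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if method == "permutation" and (a.size < 4 or b.size < 4):
        raise ValueError("permutation mode needs n1, n2 >= 4")
    u2 = watson_u2_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return CircularTestResult(
            u2=0.0, p=1.0, n1=a.size, n2=b.size, method=method, seed=seed
        )
    if method == "asymptotic":
        p = _watson_asymptotic_p(u2)
        return CircularTestResult(u2=u2, p=p, n1=a.size, n2=b.size, method=method)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    count = 0
    n1 = a.size
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if watson_u2_statistic(perm[:n1], perm[n1:]) >= u2 - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return CircularTestResult(
        u2=u2,
        p=p,
        n1=a.size,
        n2=b.size,
        method="permutation",
        n_permutations=n_permutations,
        seed=seed,
    )


def _watson_asymptotic_p(u2: float, terms: int = 50) -> float:
    s = 0.0
    for m in range(1, terms + 1):
        s += (-1) ** (m - 1) * math.exp(-2.0 * m * m * math.pi**2 * u2)
    return min(max(2.0 * s, 0.0), 1.0)


# ---------------------------------------------------------------------------
# circular descriptives


def circular_descriptives(values: Sequence[float]) -> Tuple[float, float, float]:
    """(circular mean, resultant length R, circular SD) of unit-cycle data.

    Values are fractions of a cycle; they are mapped to angles by 2*pi,
    vector-averaged, and the mean mapped back to a fraction in [0, 1).
    Circular SD = sqrt(-2 ln R) (radians).  When R = 0 the mean is
    undefined and NaN is returned for it (and the SD is infinite).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    ang = 2.0 * np.pi * v
    c, s = float(np.cos(ang).mean()), float(np.sin(ang).mean())
    r = math.hypot(c, s)
    if r < 1e-12:
        return float("nan"), 0.0, float("inf")
    mean = (math.atan2(s, c) / (2.0 * math.pi)) % 1.0
    circ_sd = math.sqrt(-2.0 * math.log(r))
    return mean, r, circ_sd


# ---------------------------------------------------------------------------
# speed-curve regression


@dataclass
class RegressionFit:
    """A fitted speed curve with its 95% prediction-interval function.

    ``model`` is "exponential_decay" (y = y0 + a exp(-b x)) or "linear"
    (y = intercept + slope * x).  ``coefficients`` follows that order.
    """

    model: str
    coefficients: Tuple[float, ...]
    r_squared: float
    residual_sd: float
    n: int
    _predict: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    _pi_halfwidth: Callable[[np.ndarray, float], np.ndarray] = field(repr=False)

    def predict(self, x) -> np.ndarray:
        return self._predict(np.asarray(x, dtype=float))

    def prediction_interval(self, x, level: float = 0.95):
        """(lower, upper) prediction bounds for a fresh observation at x."""
        x = np.asarray(x, dtype=float)
        half = self._pi_halfwidth(x, level)
        yhat = self._predict(x)
        return yhat - half, yhat + half


def _exp_model(x, y0, a, b):
    return y0 + a * np.exp(-b * x)


def fit_speed_curve(
    x: Sequence[float], y: Sequence[float], model: str = "exponential_decay"
) -> RegressionFit:
    """Least-squares fit of a spatiotemporal measure against speed.

    Exponential decay ``y = y0 + a exp(-b x)`` or ``linear``.  The 95%
    prediction interval uses the residual variance plus the local fit
    variance (delta method for the exponential model) with a t quantile
    at n - p degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if model == "exponential_decay":
        n_coef = 3
    elif model == "linear":
        n_coef = 2
    else:
        raise ValueError(f"unknown model {model!r}")
    n = x.size
    if n < n_coef + 2:
        raise ValueError("too few points for a meaningful fit")
    if model == "exponential_decay" and np.ptp(x) <= 0:
        raise ValueError("exponential model needs positive spread in x")

    dof = n - n_coef
    if model == "linear":
        X = np.column_stack([np.ones(n), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ssr = float(resid @ resid)
        s2 = ssr / dof
        xtx_inv = np.linalg.inv(X.T @ X)

        def predict(xn):
            return coef[0] + coef[1] * xn

        def halfwidth(xn, level):
            tq = sps.t.ppf(0.5 + level / 2.0, dof)
            Xn = np.column_stack([np.ones(np.size(xn)), np.ravel(xn)])
            lev = np.einsum("ij,jk,ik->i", Xn, xtx_inv, Xn)
            return tq * np.sqrt(s2 * (1.0 + lev)).reshape(np.shape(xn))

        coefficients = (float(coef[0]), float(coef[1]))
    else:
        span = max(np.ptp(y), 1e-9)
        p0 = (float(np.min(y)), float(span), 1.0 / max(float(np.mean(x)), 1e-9))
        try:
            popt, pcov = optimize.curve_fit(
                _exp_model, x, y, p0=p0, maxfev=20000
            )
        except RuntimeError as exc:  # non-convergence
            raise RuntimeError(
                f"exponential fit failed to converge (n={n}, p0={p0}): {exc}"
            ) from exc
        resid = y - _exp_model(x, *popt)
        ssr = float(resid @ resid)
        s2 = ssr / dof

        def predict(xn):
            return _exp_model(xn, *popt)

        def halfwidth(xn, level):
            tq = sps.t.ppf(0.5 + level / 2.0, dof)
            xn = np.asarray(xn, dtype=float)
            e = np.exp(-popt[2] * xn)
            # gradient of the model wrt (y0, a, b) at each x
            g = np.column_stack([np.ones(xn.size), np.ravel(e), -popt[1] * np.ravel(xn) * np.ravel(e)])
            fit_var = np.einsum("ij,jk,ik->i", g, pcov, g)
            return tq * np.sqrt(s2 + fit_var).reshape(xn.shape)

        coefficients = tuple(float(v) for v in popt)

    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return RegressionFit(
        model=model,
        coefficients=coefficients,
        r_squared=r2,
        residual_sd=math.sqrt(s2),
        n=n,
        _predict=predict,
        _pi_halfwidth=halfwidth,
    )


# ---------------------------------------------------------------------------
# paired t


def paired_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, int, float]:
    """Paired t-test on differences a - b: (t, df, two-tailed p).

    Raises when the differences have zero variance (t undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired t needs equal-length samples of size >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d, 0.0):
            return 0.0, int(a.size - 1), 1.0
        raise ValueError("zero variance of nonzero differences")
    t = d.mean() / (sd / math.sqrt(d.size))
    df = int(d.size - 1)
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)
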