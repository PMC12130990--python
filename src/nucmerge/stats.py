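"""Agreement statistics for cell-type proportion validation.

Lin's concordance correlation coefficient (CCC) measures agreement between
two readings of the same quantity as

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2)

with biased (1/n) moment estimators. It factors as ``r * C_b`` — Pearson
correlation times a bias-correction term in (0, 1] penalizing departure of
the best-fit line from the identity — hence ``|CCC| <= |r|`` always. The
confidence interval uses the Fisher z-transform of the estimate with Lin's
asymptotic variance, back-transformed.

A plain two-sample t-test (Welch by default, pooled on request) is provided
for comparing mean proportions between groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ContractError, ValidationError


@dataclass
class CccResult:
    """Concordance estimate with its confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError("CCC interval does not bracket the estimate")


def lin_ccc(x, y, ci_level: float = 0.95) -> CccResult:
    """Lin's concordance correlation coefficient with a z-transform CI.

    Requires two equal-length vectors with ``n >= 3`` finite values and at
    least some variation; two identical constant vectors have undefined
    concordance and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError(
            f"lin_ccc needs two equal-length vectors, got {x.shape} and {y.shape}"
        )
    n = len(x)
    if n < 3:
        raise ContractError(f"lin_ccc needs n >= 3, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ContractError("lin_ccc needs finite values")

    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValidationError(
            "concordance undefined: zero variance in both vectors with equal means"
        )
    p = 2.0 * sxy / denom

    # Lin's asymptotic variance of atanh(p); degenerate cases (|p| = 1,
    # r = 0) collapse the interval to the point estimate.
    r2 = sxy * sxy / (sx2 * sy2) if sx2 > 0 and sy2 > 0 else 0.0
    if r2 == 0.0 or 1.0 - p * p <= 0.0:
        return CccResult(estimate=p, ci_low=p, ci_high=p, n=n)
    u2 = (my - mx) ** 2 / math.sqrt(sx2 * sy2)
    r = math.copysign(math.sqrt(r2), sxy)
    one_m_p2 = 1.0 - p * p
    var_z = (
        (1.0 - r2) * p * p / (one_m_p2 * r2)
        + 2.0 * p**3 * (1.0 - p) * u2 / (r * one_m_p2**2)
        - p**4 * u2 * u2 / (2.0 * r2 * one_m_p2**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = math.atanh(p)
    zq = float(sps.norm.ppf(0.5 + ci_level / 2.0))
    half = zq * math.sqrt(var_z)
    return CccResult(
        estimate=p,
        ci_low=math.tanh(z - half),
        ci_high=math.tanh(z + half),
        n=n,
    )


def pearson_r(x, y) -> float:
    """Pearson correlation (plain; used alongside CCC in diagnostics)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.corrcoef(x, y)[0, 1])


def two_sample_t(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test of means; Welch by default, pooled on request.

    Degenerate variance is handled explicitly: when both samples are
    constant, equal means give ``(0.0, 1.0)`` by convention and different
    means give an infinite statistic with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ContractError("two_sample_t needs n >= 2 in each sample")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)
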