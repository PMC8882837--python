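"""Meta-analytic pooling of per-cohort causal estimates.

Fixed-effect pooling is the inverse-variance-weighted average of per-study
log-ORs; the DerSimonian-Laird random-effects model adds a moment estimate of
the between-study variance tau² to every study's weight.  Both attach
Cochran's Q and I².  The Bonferroni rule divides the family alpha by the
number of exposures tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class PooledResult:
    """A pooled log-OR with CI, p, heterogeneity and per-study inputs."""

    pooled_beta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    pvalue: float
    model: str  # "fixed" | "random"
    tau2: float
    q_stat: float
    q_df: int
    q_pvalue: float
    i2: float
    inputs: pd.DataFrame  # columns: label, beta, se, weight (weights sum to 1)

    def to_row(self) -> dict:
        return {
            "beta": self.pooled_beta, "se": self.se, "or": self.or_value,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue, "model": self.model, "tau2": self.tau2,
            "q": self.q_stat, "q_df": self.q_df, "q_p": self.q_pvalue,
            "i2": self.i2,
        }


def _as_arrays(estimates):
    if isinstance(estimates, pd.DataFrame):
        labels = (
            estimates["label"].tolist()
            if "label" in estimates.columns
            else [f"study_{i}" for i in range(len(estimates))]
        )
        beta = estimates["beta"].to_numpy(dtype=float)
        se = estimates["se"].to_numpy(dtype=float)
    else:
        rows = list(estimates)
        labels = [f"study_{i}" for i in range(len(rows))]
        beta = np.array([r[0] for r in rows], dtype=float)
        se = np.array([r[1] for r in rows], dtype=float)
    if beta.size == 0:
        raise ValidationError("pooling requires at least one estimate")
    if np.any(se <= 0):
        raise ValidationError("all standard errors must be > 0")
    return labels, beta, se


def _finish(labels, beta, se, weights, model, tau2, q, q_df) -> PooledResult:
    wn = weights / weights.sum()
    pooled = float(np.sum(wn * beta))
    pooled_se = float(math.sqrt(1.0 / weights.sum()))
    z = stats.norm.ppf(0.975)
    p = min(1.0, 2.0 * stats.norm.sf(abs(pooled) / pooled_se))
    q_p = float(stats.chi2.sf(q, q_df)) if q_df >= 1 else 1.0
    i2 = max(0.0, (q - q_df) / q) if q > 0 and q_df >= 1 else 0.0
    return PooledResult(
        pooled_beta=pooled, se=pooled_se,
        or_value=math.exp(pooled),
        ci_low=math.exp(pooled - z * pooled_se),
        ci_high=math.exp(pooled + z * pooled_se),
        pvalue=p, model=model, tau2=tau2,
        q_stat=float(q), q_df=int(q_df), q_pvalue=q_p, i2=float(i2),
        inputs=pd.DataFrame(
            {"label": labels, "beta": beta, "se": se, "weight": wn}
        ),
    )


def pool_fixed(estimates) -> PooledResult:
    """Fixed-effect (inverse-variance) pooling of (beta, se) estimates.

    ``estimates`` is a sequence of (beta, se) pairs or a DataFrame with
    columns beta, se (and optionally label).
    """
    labels, beta, se = _as_arrays(estimates)
    v = 1.0 / se**2
    pooled = float(np.sum(v * beta) / v.sum())
    q = float(np.sum(v * (beta - pooled) ** 2))
    return _finish(labels, beta, se, v, "fixed", 0.0, q, beta.size - 1)


def pool_random_dl(estimates) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    tau² = max(0, (Q − (m−1)) / (Σv − Σv²/Σv)) with fixed-effect weights v;
    study weights become 1/(se² + tau²).  With homogeneous inputs
    (Q <= m − 1) tau² truncates to 0 and the result equals :func:`pool_fixed`.
    """
    labels, beta, se = _as_arrays(estimates)
    m = beta.size
    if m < 2:
        raise ValidationError("random-effects pooling needs at least 2 estimates")
    v = 1.0 / se**2
    fixed = float(np.sum(v * beta) / v.sum())
    q = float(np.sum(v * (beta - fixed) ** 2))
    denom = v.sum() - (v**2).sum() / v.sum()
    tau2 = max(0.0, (q - (m - 1)) / denom) if denom > 0 else 0.0
    w = 1.0 / (se**2 + tau2)
    return _finish(labels, beta, se, w, "random", tau2, q, m - 1)


def bonferroni_threshold(m: int, family_alpha: float = 0.05) -> float:
    """Per-test significance threshold controlling the family-wise error rate
    over ``m`` exposures: family_alpha / m."""
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    if not 0.0 < family_alpha < 1.0:
        raise ValidationError(f"family_alpha must lie in (0, 1), got {family_alpha}")
    return family_alpha / m
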