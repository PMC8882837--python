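"""Two-sample MR causal estimators and sensitivity analyses.

All estimators consume a DataFrame of harmonized pairs (columns
``beta_exposure``, ``se_exposure``, ``beta_outcome``, ``se_outcome``; rows
with a harmonization ``action`` column are filtered to retained actions
automatically) and return an :class:`MrResult` on the log-effect scale, with
the odds-ratio translation attached.

Methods
-------
wald_ratio
    Single-SNP estimate bYG/bXG with first-order delta-method SE.
ivw_fixed
    Fixed-effect inverse-variance-weighted average of per-SNP Wald ratios;
    algebraically the weighted least-squares slope of bYG on bXG through the
    origin with weights 1/SE(bYG)².  The main method.
mr_egger
    Weighted regression of bYG on bXG *with* an intercept after orienting
    bXG >= 0; the intercept estimates directional pleiotropy, the slope is
    the bias-adjusted causal effect.  SEs carry a multiplicative
    random-effects scale floored at 1.
weighted_median / weighted_mode
    Robust estimators consistent when >=50% of weight, or the largest
    homogeneous cluster, comes from valid instruments; SEs by seeded
    parametric bootstrap.

Heterogeneity (Cochran's Q, I²) and leave-one-out re-estimation support the
sensitivity workflow; ``diagnostics_data`` produces plot-ready scatter and
funnel tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientInstrumentsError, ValidationError

Z_METHODS = ("wald_ratio", "ivw_fixed", "mr_egger", "weighted_median", "weighted_mode")


@dataclass
class MrResult:
    """One method's causal estimate with CI, p and sensitivity statistics.

    ``beta`` is the causal log-effect per SD of a continuous exposure (per
    log-odds for a binary exposure); ``or_value`` = exp(beta).
    """

    method: str
    beta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    label: str = ""
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    i2: float | None = None

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
            "q": self.q_stat,
            "q_df": self.q_df,
            "q_p": self.q_pvalue,
            "i2": self.i2,
        }


def to_or(beta: float, se: float, alpha: float = 0.05):
    """Translate a log-scale estimate to (OR, CI low, CI high, two-sided p)."""
    if not se > 0:
        raise ValidationError(f"se must be > 0, got {se}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    pvalue = min(1.0, 2.0 * stats.norm.sf(abs(beta) / se))
    return (
        math.exp(beta),
        math.exp(beta - z * se),
        math.exp(beta + z * se),
        pvalue,
    )


def _result(method: str, beta: float, se: float, n_snps: int, **extra) -> MrResult:
    or_value, lo, hi, p = to_or(beta, se)
    return MrResult(
        method=method, beta=beta, se=se, or_value=or_value,
        ci_low=lo, ci_high=hi, pvalue=p, n_snps=n_snps, **extra,
    )


def _extract(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pull (bx, sx, by, sy) arrays out of a pairs frame / record sequence."""
    if isinstance(pairs, pd.DataFrame):
        df = pairs
        if "action" in df.columns:
            from .harmonization import RETAINED_ACTIONS

            df = df[df["action"].isin(RETAINED_ACTIONS)]
        bx = df["beta_exposure"].to_numpy(dtype=float)
        sx = df["se_exposure"].to_numpy(dtype=float)
        by = df["beta_outcome"].to_numpy(dtype=float)
        sy = df["se_outcome"].to_numpy(dtype=float)
    else:
        rows = list(pairs)
        bx = np.array([r["beta_exposure"] for r in rows], dtype=float)
        sx = np.array([r["se_exposure"] for r in rows], dtype=float)
        by = np.array([r["beta_outcome"] for r in rows], dtype=float)
        sy = np.array([r["se_outcome"] for r in rows], dtype=float)
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise ValidationError("all standard errors must be > 0")
    return bx, sx, by, sy


def _rsids(pairs, k: int) -> list[str]:
    if isinstance(pairs, pd.DataFrame) and "rsid" in pairs.columns:
        if "action" in pairs.columns:
            from .harmonization import RETAINED_ACTIONS

            return pairs.loc[
                pairs["action"].isin(RETAINED_ACTIONS), "rsid"
            ].tolist()
        return pairs["rsid"].tolist()
    return [f"snp_{i}" for i in range(k)]


def wald_ratio(pair) -> MrResult:
    """Single-SNP causal estimate bYG/bXG (first-order delta-method SE)."""
    if isinstance(pair, pd.DataFrame):
        bx, sx, by, sy = _extract(pair)
        if bx.size != 1:
            raise ValidationError("wald_ratio takes exactly one pair")
        bx, by, sy = bx[0], by[0], sy[0]
    else:
        bx = float(pair["beta_exposure"])
        by = float(pair["beta_outcome"])
        sy = float(pair["se_outcome"])
    if bx == 0.0:
        raise ValidationError("wald_ratio undefined for beta_exposure = 0")
    return _result("wald_ratio", by / bx, abs(sy / bx), 1)


def cochran_q(pairs, beta_ref: float):
    """Cochran's Q heterogeneity of per-SNP ratios about ``beta_ref``.

    Returns (Q, df, p, I²) with IVW weights w_j = bXG²/SE(bYG)², df = k − 1
    and I² = max(0, (Q − df)/Q).
    """
    bx, _, by, sy = _extract(pairs)
    k = bx.size
    if k < 2:
        raise InsufficientInstrumentsError("cochran_q needs at least 2 pairs")
    w = bx**2 / sy**2
    r = by / bx
    q = float(np.sum(w * (r - beta_ref) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, p, i2


def ivw_fixed(pairs) -> MrResult:
    """Fixed-effect inverse-variance-weighted causal estimate (main method)."""
    bx, _, by, sy = _extract(pairs)
    k = bx.size
    if k == 0:
        raise InsufficientInstrumentsError("ivw_fixed needs at least 1 pair")
    if np.any(bx == 0.0):
        raise ValidationError("ivw_fixed requires all beta_exposure != 0")
    if k == 1:  # degenerate case: identical to the Wald ratio
        beta = float(by[0] / bx[0])
        se = float(abs(sy[0] / bx[0]))
        return _result("ivw_fixed", beta, se, 1)
    w = bx**2 / sy**2
    beta = float(np.sum(w * (by / bx)) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    het = {}
    if k >= 2:
        q, df, qp, i2 = cochran_q(pairs, beta)
        het = {"q_stat": q, "q_df": df, "q_pvalue": qp, "i2": i2}
    return _result("ivw_fixed", beta, se, k, **het)


def mr_egger(pairs) -> MrResult:
    """MR-Egger regression: weighted fit of bYG on bXG with an intercept.

    Pairs are oriented so bXG >= 0 (negating both coefficients of a SNP
    changes nothing causally).  The intercept, with SE and p, is the test for
    directional pleiotropy; the slope is the causal estimate.  Both SEs are
    scaled by max(1, sqrt(Q_resid/(k−2))) (multiplicative random effects).
    """
    bx, _, by, sy = _extract(pairs)
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError("mr_egger needs at least 3 pairs")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.allclose(bx, bx[0]):
        raise ValidationError("mr_egger requires variation in beta_exposure")
    w = 1.0 / sy**2
    # closed-form weighted least squares with intercept
    sw = w.sum()
    mx = np.sum(w * bx) / sw
    my = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    sxy = np.sum(w * (bx - mx) * (by - my))
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = by - intercept - slope * bx
    q_resid = float(np.sum(w * resid**2))
    phi = max(1.0, q_resid / (k - 2))
    se_slope = math.sqrt(phi / sxx)
    se_intercept = math.sqrt(phi * (1.0 / sw + mx**2 / sxx))
    int_p = min(1.0, 2.0 * stats.norm.sf(abs(intercept) / se_intercept))
    i2 = max(0.0, (q_resid - (k - 2)) / q_resid) if q_resid > 0 else 0.0
    return _result(
        "mr_egger", float(slope), se_slope, k,
        egger_intercept=float(intercept),
        egger_intercept_se=se_intercept,
        egger_intercept_p=int_p,
        q_stat=q_resid, q_df=k - 2,
        q_pvalue=float(stats.chi2.sf(q_resid, k - 2)),
        i2=i2,
    )


def _ratio_weights(bx, sx, by, sy):
    """Normalized inverse-variance weights of the per-SNP ratio estimates
    (first-order delta-method variance of bYG/bXG)."""
    var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    w = 1.0 / var
    return w / w.sum()


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation over cumulative
    weight midpoints."""
    order = np.argsort(r)
    r, w = r[order], w[order] / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def _bootstrap_se(bx, sx, by, sy, point_fn, n_boot: int, seed) -> float:
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        est[b] = point_fn(bxb, byb)
    return float(np.std(est, ddof=1))


def weighted_median(pairs, n_boot: int = 1000, seed: int | None = None) -> MrResult:
    """Weighted-median estimator (valid when >=50% of weight is from valid
    instruments); SE by seeded parametric bootstrap."""
    bx, sx, by, sy = _extract(pairs)
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError("weighted_median needs at least 3 pairs")

    def point(bxv, byv):
        return _weighted_median(byv / bxv, _ratio_weights(bxv, sx, byv, sy))

    beta = point(bx, by)
    se = _bootstrap_se(bx, sx, by, sy, point, n_boot, seed)
    return _result("weighted_median", beta, se, k)


def _mode_bandwidth(r: np.ndarray, factor: float) -> float:
    """Rule-of-thumb normal-kernel bandwidth of the ratio estimates."""
    sd = float(np.std(r, ddof=1))
    iqr = float(np.subtract(*np.percentile(r, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        return 0.0
    return factor * 0.9 * spread * r.size ** (-0.2)


def _weighted_mode(r: np.ndarray, w: np.ndarray, bandwidth_factor: float) -> float:
    h = _mode_bandwidth(r, bandwidth_factor)
    if h <= 0:  # degenerate: all ratios (essentially) identical
        return float(np.median(r))
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)

    def neg_density(x):
        return -np.sum(w * np.exp(-0.5 * ((x - r) / h) ** 2))

    x0 = grid[np.argmin([neg_density(x) for x in grid])]
    step = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        neg_density, bounds=(x0 - step, x0 + step), method="bounded",
        options={"xatol": step * 1e-7},
    )
    return float(res.x) if res.success else float(x0)


def weighted_mode(
    pairs, bandwidth_factor: float = 1.0, n_boot: int = 1000,
    seed: int | None = None,
) -> MrResult:
    """Weighted-mode estimator: the maximum of the inverse-variance-weighted
    normal-kernel density of the per-SNP ratios; SE by seeded parametric
    bootstrap."""
    bx, sx, by, sy = _extract(pairs)
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError("weighted_mode needs at least 3 pairs")

    def point(bxv, byv):
        return _weighted_mode(
            byv / bxv, _ratio_weights(bxv, sx, byv, sy), bandwidth_factor
        )

    beta = point(bx, by)
    se = _bootstrap_se(bx, sx, by, sy, point, n_boot, seed)
    return _result("weighted_mode", beta, se, k)


def leave_one_out(pairs) -> list[MrResult]:
    """Re-estimate IVW omitting each SNP in turn (labels = omitted rsid)."""
    bx, sx, by, sy = _extract(pairs)
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError("leave_one_out needs at least 3 pairs")
    rsids = _rsids(pairs, k)
    frame = pd.DataFrame(
        {"beta_exposure": bx, "se_exposure": sx,
         "beta_outcome": by, "se_outcome": sy}
    )
    out = []
    for i in range(k):
        res = ivw_fixed(frame.drop(index=i))
        res.label = rsids[i]
        out.append(res)
    return out


def diagnostics_data(pairs, results: Iterable[MrResult] | Mapping[str, MrResult]):
    """Plot-ready (scatter, funnel) tables.

    The scatter table carries per-SNP (bXG, bYG, SEs); per-method fitted
    lines (slope, intercept) ride in ``scatter.attrs["lines"]``.  The funnel
    table carries per-SNP (ratio, precision = 1/SE(ratio)); the IVW and Egger
    verticals ride in ``funnel.attrs["verticals"]``.
    """
    bx, sx, by, sy = _extract(pairs)
    if bx.size == 0:
        raise ValidationError("diagnostics_data requires non-empty pairs")
    if isinstance(results, Mapping):
        results = list(results.values())
    else:
        results = list(results)
    rsids = _rsids(pairs, bx.size)
    scatter = pd.DataFrame(
        {"rsid": rsids, "beta_exposure": bx, "se_exposure": sx,
         "beta_outcome": by, "se_outcome": sy}
    )
    lines = pd.DataFrame(
        [
            {
                "method": r.method,
                "slope": r.beta,
                "intercept": r.egger_intercept or 0.0,
            }
            for r in results
        ]
    )
    scatter.attrs["lines"] = lines
    ratio = by / bx
    se_ratio = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    funnel = pd.DataFrame(
        {"rsid": rsids, "ratio": ratio, "precision": 1.0 / se_ratio}
    )
    funnel.attrs["verticals"] = {
        r.method: r.beta for r in results if r.method in ("ivw_fixed", "mr_egger")
    }
    return scatter, funnel
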