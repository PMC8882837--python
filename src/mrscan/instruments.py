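"""Genetic-instrument selection and strength metrics.

Instruments for an exposure are SNPs passing a genome-wide significance
threshold (5e-8, relaxed to 5e-6 when fewer than ten SNPs qualify) and mutual
linkage-disequilibrium pruning at r² < 0.1.  Instrument strength is summarised
by the proportion of exposure variance explained,

    R² = 2 β² MAF (1 − MAF) / [2 β² MAF (1 − MAF) + SE(β)² · 2N · MAF (1 − MAF)],

summed over the pruned (approximately independent) SNPs, and by the
F-statistic

    F = R² (N − 1 − k) / [(1 − R²) k],

with N the GWAS sample size and k the number of SNPs in the instrument.
F > 10 is the conventional weak-instrument rule of thumb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sumstats import (
    LdMatrix,
    REQUIRED_COLUMNS,
    SnpAssociation,
    SummaryStatsTable,
    read_summary_stats,
    write_summary_stats,
)

__all__ = [
    "InstrumentSet",
    "variance_explained",
    "f_statistic",
    "filter_complete",
    "select_instruments",
    "read_summary_stats",
    "write_summary_stats",
]


def variance_explained(snp=None, *, beta=None, se=None, eaf=None, n=None) -> float:
    """Proportion of trait variance explained by one SNP.

    Accepts either a :class:`~mrscan.sumstats.SnpAssociation` or explicit
    ``beta``, ``se``, ``eaf``, ``n`` keywords (array-valued inputs allowed).
    MAF is derived as min(eaf, 1 − eaf).
    """
    if isinstance(snp, SnpAssociation):
        beta, se, eaf, n = snp.beta, snp.se, snp.eaf, snp.n
    elif snp is not None:
        raise TypeError("positional argument must be a SnpAssociation")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    if np.any(maf <= 0.0):
        raise ValidationError("MAF must be > 0 to compute variance explained")
    if np.any(se <= 0.0):
        raise ValidationError("se must be > 0")
    if np.any(n <= 0):
        raise ValidationError("n must be > 0")
    num = 2.0 * beta**2 * maf * (1.0 - maf)
    den = num + se**2 * (2.0 * n) * maf * (1.0 - maf)
    out = num / den
    return float(out) if out.ndim == 0 else out


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Instrument-strength F-statistic from total R², sample size and SNP count."""
    if not 0.0 <= r2_total < 1.0:
        raise ValidationError(f"r2_total must lie in [0, 1), got {r2_total}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise ValidationError(f"n must exceed k + 1 (n={n}, k={k})")
    return r2_total * (n - 1 - k) / ((1.0 - r2_total) * k)


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with strength metrics."""

    exposure_id: str
    snps: pd.DataFrame
    threshold_used: float
    trait_type: str = "continuous"
    dropped_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["rsid", "reason"])
    )

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        if self.k > 0:
            r2 = variance_explained(
                beta=self.snps["beta"].to_numpy(),
                se=self.snps["se"].to_numpy(),
                eaf=self.snps["eaf"].to_numpy(),
                n=self.snps["n"].to_numpy(),
            )
            self.r2_per_snp = np.atleast_1d(r2)
            # pruned SNPs are treated as independent: total R² is the sum
            self.r2_total = float(self.r2_per_snp.sum())
            n_max = int(self.snps["n"].max())
            self.f_stat = (
                f_statistic(self.r2_total, n_max, self.k)
                if n_max > self.k + 1
                else float("nan")
            )
        else:
            self.r2_per_snp = np.empty(0)
            self.r2_total = 0.0
            self.f_stat = float("nan")

    @property
    def k(self) -> int:
        return len(self.snps)


def filter_complete(table: SummaryStatsTable) -> SummaryStatsTable:
    """Drop records with any missing required field; log removals.

    The removal log (rsid, reason) is available as ``result.parse_log`` in the
    same shape as the reader's log (line number is the 0-based row index).
    """
    df = table.df
    required = [c for c in REQUIRED_COLUMNS]
    bad = df[required].isna().any(axis=1)
    log = []
    for i in df.index[bad]:
        missing = [c for c in required if pd.isna(df.at[i, c])]
        log.append((int(i), str(df.at[i, "rsid"]), "missing " + ", ".join(missing)))
    out = SummaryStatsTable(
        trait_id=table.trait_id,
        df=df.loc[~bad].copy(),
        trait_type=table.trait_type,
    )
    out.parse_log = list(table.parse_log) + log
    if len(out) == 0:
        warnings.warn(
            f"all {len(df)} records of {table.trait_id!r} were incomplete",
            stacklevel=2,
        )
    return out


def select_instruments(
    table: SummaryStatsTable,
    ld: LdMatrix | None = None,
    p_primary: float = 5e-8,
    p_fallback: float = 5e-6,
    r2_max: float = 0.1,
    fallback_below: int = 10,
) -> InstrumentSet:
    """Apply the significance threshold and greedy LD pruning.

    SNPs with p < ``p_primary`` are candidates; if fewer than
    ``fallback_below`` qualify, the threshold is relaxed to ``p_fallback`` and
    candidacy re-evaluated.  Candidates are ranked by ascending p-value (ties:
    descending |beta|, then rsid) and retained greedily iff their r² with every
    already-retained SNP is below ``r2_max``.  Without an LD matrix all SNPs
    are treated as independent (with a warning).  An empty candidate set after
    fallback yields an empty set with a warning, never an exception.
    """
    df = table.df
    log_rows: list[tuple[str, str]] = []

    threshold = p_primary
    candidates = df[df["pvalue"] < threshold]
    if len(candidates) < fallback_below:
        threshold = p_fallback
        candidates = df[df["pvalue"] < threshold]
    for rs in df.loc[~df.index.isin(candidates.index), "rsid"]:
        log_rows.append((rs, f"p >= {threshold:g}"))

    if len(candidates) == 0:
        warnings.warn(
            f"no instruments for {table.trait_id!r} even at p < {threshold:g}",
            stacklevel=2,
        )
        return InstrumentSet(
            exposure_id=table.trait_id,
            snps=df.iloc[0:0].copy(),
            threshold_used=threshold,
            trait_type=table.trait_type,
            dropped_log=pd.DataFrame(log_rows, columns=["rsid", "reason"]),
        )

    if ld is None:
        warnings.warn(
            f"no LD matrix for {table.trait_id!r}: treating all candidate SNPs "
            "as independent (no pruning)",
            stacklevel=2,
        )
    else:
        missing = [rs for rs in candidates["rsid"] if rs not in ld]
        if missing:
            raise ValidationError(
                f"rsids absent from LD matrix: {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else "")
            )

    order = candidates.assign(_absbeta=candidates["beta"].abs()).sort_values(
        by=["pvalue", "_absbeta", "rsid"], ascending=[True, False, True]
    )
    retained: list[int] = []
    retained_rs: list[str] = []
    for idx, row in order.iterrows():
        if ld is not None:
            conflict = next(
                (rs for rs in retained_rs if ld.get(row["rsid"], rs) >= r2_max),
                None,
            )
            if conflict is not None:
                log_rows.append(
                    (row["rsid"], f"r2 >= {r2_max:g} with retained {conflict}")
                )
                continue
        retained.append(idx)
        retained_rs.append(row["rsid"])

    # emit in ranking order so the result is invariant to input row order
    snps = order.loc[retained].drop(columns="_absbeta").copy()
    return InstrumentSet(
        exposure_id=table.trait_id,
        snps=snps,
        threshold_used=threshold,
        trait_type=table.trait_type,
        dropped_log=pd.DataFrame(log_rows, columns=["rsid", "reason"]),
    )
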