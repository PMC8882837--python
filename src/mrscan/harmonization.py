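"""Align exposure instruments with outcome summary statistics.

Two-sample MR requires the SNP-exposure effect (bXG) and the SNP-outcome
effect (bYG) to be expressed per copy of the *same* effect allele.  Real
summary files disagree in three ways: the outcome file may report the other
allele as the effect allele (swap: flip the sign of bYG and complement the
frequency), it may report alleles on the opposite strand (complement both
alleles, nothing else changes), and palindromic SNPs (A/T or C/G) are
strand-ambiguous, resolvable only by comparing which side of 0.5 the allele
frequency falls on — and not at all when the frequency is close to 0.5.

Each instrument SNP receives exactly one audit ``action``; retained pairs
have action in {kept, flipped, kept_palindromic}.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet
from .sumstats import SummaryStatsTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: actions that keep a pair in the analysis
RETAINED_ACTIONS = ("kept", "flipped", "kept_palindromic")
DROPPED_ACTIONS = (
    "dropped_palindromic",
    "dropped_allele_mismatch",
    "dropped_missing",
    "dropped_outcome_significant",
)

PAIR_COLUMNS = [
    "rsid",
    "beta_exposure",
    "se_exposure",
    "eaf_exposure",
    "beta_outcome",
    "se_outcome",
    "eaf_outcome",
    "pvalue_outcome",
    "action",
    "detail",
]


def _complement_allele(a: str) -> str | None:
    return COMPLEMENT.get(a)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def harmonize(
    instruments: InstrumentSet,
    outcome: SummaryStatsTable,
    palindromic_eaf_window: float = 0.08,
) -> pd.DataFrame:
    """Match instruments to the outcome table by rsid and align effect alleles.

    Returns one row per instrument SNP with columns :data:`PAIR_COLUMNS`.
    Palindromic SNPs whose exposure or outcome eaf lies within
    ``palindromic_eaf_window`` of 0.5 are dropped as unorientable.  All
    problems are per-SNP audit actions, never exceptions.
    """
    out_by_rsid = {r["rsid"]: r for _, r in outcome.df.iterrows()}
    rows = []
    for _, x in instruments.snps.iterrows():
        base = {
            "rsid": x["rsid"],
            "beta_exposure": float(x["beta"]),
            "se_exposure": float(x["se"]),
            "eaf_exposure": float(x["eaf"]),
            "beta_outcome": np.nan,
            "se_outcome": np.nan,
            "eaf_outcome": np.nan,
            "pvalue_outcome": np.nan,
            "action": "dropped_missing",
            "detail": "",
        }
        y = out_by_rsid.get(x["rsid"])
        if y is None:
            base["detail"] = "rsid absent from outcome table"
            rows.append(base)
            continue

        ea_x, oa_x = x["effect_allele"], x["other_allele"]
        ea_y, oa_y = y["effect_allele"], y["other_allele"]
        beta_y, se_y, eaf_y = float(y["beta"]), float(y["se"]), float(y["eaf"])
        p_y = float(y["pvalue"])
        base.update(se_outcome=se_y, pvalue_outcome=p_y)

        if _is_palindromic(ea_x, oa_x) or _is_palindromic(ea_y, oa_y):
            same = {ea_x, oa_x} == {ea_y, oa_y}
            if not (_is_palindromic(ea_x, oa_x) and same):
                base.update(action="dropped_allele_mismatch",
                            detail=f"{ea_x}/{oa_x} vs {ea_y}/{oa_y}")
                rows.append(base)
                continue
            eaf_x = float(x["eaf"])
            # window is the half-width around 0.5: (0.42, 0.58) at the default
            lo, hi = 0.5 - palindromic_eaf_window, 0.5 + palindromic_eaf_window
            if np.isnan(eaf_y) or np.isnan(eaf_x) or lo < eaf_x < hi or lo < eaf_y < hi:
                base.update(
                    action="dropped_palindromic",
                    detail="allele frequency too close to 0.5 to orient strand",
                )
                rows.append(base)
                continue
            # orient by which side of 0.5 the effect-allele frequency falls on
            if (eaf_x < 0.5) == (eaf_y < 0.5):
                base.update(
                    beta_outcome=beta_y, eaf_outcome=eaf_y,
                    action="kept_palindromic", detail="frequencies concordant",
                )
            else:
                base.update(
                    beta_outcome=-beta_y, eaf_outcome=1.0 - eaf_y,
                    action="kept_palindromic",
                    detail="frequencies discordant: outcome effect flipped",
                )
            rows.append(base)
            continue

        cea_y, coa_y = _complement_allele(ea_y), _complement_allele(oa_y)
        if (ea_x, oa_x) == (ea_y, oa_y):
            base.update(beta_outcome=beta_y, eaf_outcome=eaf_y, action="kept")
        elif (ea_x, oa_x) == (oa_y, ea_y):
            base.update(
                beta_outcome=-beta_y, eaf_outcome=1.0 - eaf_y, action="flipped",
                detail="effect/other alleles exchanged in outcome",
            )
        elif (ea_x, oa_x) == (cea_y, coa_y):
            base.update(
                beta_outcome=beta_y, eaf_outcome=eaf_y, action="kept",
                detail="outcome alleles were strand-complemented",
            )
        elif (ea_x, oa_x) == (coa_y, cea_y):
            base.update(
                beta_outcome=-beta_y, eaf_outcome=1.0 - eaf_y, action="flipped",
                detail="outcome alleles strand-complemented and exchanged",
            )
        else:
            base.update(action="dropped_allele_mismatch",
                        detail=f"{ea_x}/{oa_x} vs {ea_y}/{oa_y}")
        rows.append(base)

    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def drop_outcome_significant(
    pairs: pd.DataFrame, threshold: float = 5e-8, use_reported: bool = True
) -> pd.DataFrame:
    """Drop retained pairs whose SNP-outcome association is itself genome-wide
    significant (p < ``threshold``), marking them dropped_outcome_significant.

    Reported outcome p-values are used when available (``use_reported``);
    otherwise p is recomputed from bYG/SE by the two-sided normal
    approximation.
    """
    pairs = pairs.copy()
    retained = pairs["action"].isin(RETAINED_ACTIONS)
    p = pairs["pvalue_outcome"].to_numpy(dtype=float)
    recomputed = 2.0 * stats.norm.sf(
        np.abs(pairs["beta_outcome"].to_numpy(dtype=float))
        / pairs["se_outcome"].to_numpy(dtype=float)
    )
    if use_reported:
        p = np.where(np.isnan(p), recomputed, p)
    else:
        p = recomputed
    hit = retained.to_numpy() & (p < threshold)
    pairs.loc[hit, "action"] = "dropped_outcome_significant"
    pairs.loc[hit, "detail"] = f"outcome p < {threshold:g}"
    return pairs


def retained(pairs: pd.DataFrame) -> pd.DataFrame:
    """Subset of pairs that survive harmonization and filtering."""
    return pairs[pairs["action"].isin(RETAINED_ACTIONS)].reset_index(drop=True)


def write_audit(pairs: pd.DataFrame, path) -> None:
    """Write the per-SNP harmonization audit (rsid, action, reason)."""
    pairs[["rsid", "action", "detail"]].rename(columns={"detail": "reason"}).to_csv(
        path, sep="\t", index=False
    )
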