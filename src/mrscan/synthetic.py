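"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the data a two-sample MR analysis consumes: an
exposure GWAS and a non-overlapping outcome GWAS, each reporting per-SNP
effect sizes with the large-sample standard error for a standardized trait,

    SE(beta_x) = 1 / sqrt(2 * N * MAF * (1 - MAF)),

with a case-fraction factor v = cf*(1-cf) in the denominator for a binary
outcome on the log-odds scale.  Instrument SNPs carry a true effect b_j on
the standardized exposure, drawn half-normal with the effect allele oriented
to the exposure-increasing allele (the usual GWAS reporting convention, and
the orientation on which "directional" pleiotropy is defined); null SNPs let
the p-value thresholding reject something.  The true SNP-outcome effect is

    gamma_j = theta * b_j + alpha_j,

where theta is the causal effect and alpha_j the pleiotropic (direct) effect
under one of four models: none, balanced (mean-zero), directional (non-zero
mean, InSIDE satisfied), or correlated (alpha depends on b_j, violating
InSIDE).  Allele-coding corruption (effect/other swaps, strand flips,
palindromic A/T and C/G pairs) exercises harmonization; every corruption is
recorded in the truth sidecar so tests can check the audit trail exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ValidationError
from .sumstats import LdMatrix, SummaryStatsTable

PLEIOTROPY_MODELS = ("none", "balanced", "directional", "correlated")

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationScenario:
    """Generative truth for a synthetic two-sample MR design."""

    n_instrument_snps: int = 100
    n_null_snps: int | None = None  # default: 10x instruments
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_effect_sd: float = 0.05
    theta: float = 0.0
    pleiotropy_model: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0
    inside_correlation: float = 0.0
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    outcome_type: str = "continuous"
    case_fraction: float | None = None
    ld_block_size: int = 1
    within_block_r2: float = 0.0
    swap_rate: float = 0.0
    strand_flip_rate: float = 0.0
    palindromic_fraction: float = 0.2
    seed: int = 0
    snp_prefix: str = "rs"

    def __post_init__(self) -> None:
        def bad(name, why):
            raise ValidationError(f"scenario field {name!r}: {why}")

        if self.n_instrument_snps < 1:
            bad("n_instrument_snps", "must be a positive integer")
        if self.n_null_snps is not None and self.n_null_snps < 0:
            bad("n_null_snps", "must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            bad("maf_range", "must satisfy 0 < low <= high <= 0.5")
        if not self.exposure_effect_sd > 0:
            bad("exposure_effect_sd", "must be positive")
        if self.pleiotropy_model not in PLEIOTROPY_MODELS:
            bad("pleiotropy_model", f"must be one of {PLEIOTROPY_MODELS}")
        if self.pleiotropy_model == "none" and (
            self.pleiotropy_mean != 0.0 or self.pleiotropy_sd != 0.0
        ):
            bad("pleiotropy_mean", "must be 0 (with pleiotropy_sd=0) when model is 'none'")
        if self.pleiotropy_sd < 0:
            bad("pleiotropy_sd", "must be non-negative")
        if not 0.0 < self.pleiotropy_fraction <= 1.0:
            bad("pleiotropy_fraction", "must lie in (0, 1]")
        if not -1.0 <= self.inside_correlation <= 1.0:
            bad("inside_correlation", "must lie in [-1, 1]")
        if self.n_exposure < 2 or self.n_outcome < 2:
            bad("n_exposure", "sample sizes must be positive integers >= 2")
        if self.outcome_type not in ("continuous", "binary"):
            bad("outcome_type", "must be 'continuous' or 'binary'")
        if self.outcome_type == "binary":
            if self.case_fraction is None or not 0.0 < self.case_fraction < 1.0:
                bad("case_fraction", "required in (0, 1) for a binary outcome")
        elif self.case_fraction is not None:
            bad("case_fraction", "only meaningful for a binary outcome")
        if self.ld_block_size < 1:
            bad("ld_block_size", "must be a positive integer")
        if not 0.0 <= self.within_block_r2 < 1.0:
            bad("within_block_r2", "must lie in [0, 1)")
        for name in ("swap_rate", "strand_flip_rate", "palindromic_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                bad(name, "must lie in [0, 1]")

    @property
    def n_null(self) -> int:
        return (
            10 * self.n_instrument_snps if self.n_null_snps is None else self.n_null_snps
        )

    @property
    def n_snps(self) -> int:
        return self.n_instrument_snps + self.n_null

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown scenario field(s): {', '.join(sorted(unknown))}")
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)


@dataclass
class SimulationTruth:
    """Per-SNP generative truth plus corruption/palindrome flags."""

    df: pd.DataFrame
    theta: float
    scenario: SimulationScenario = field(repr=False, default=None)


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def _draw_truth(scenario: SimulationScenario, rng: np.random.Generator) -> SimulationTruth:
    m = scenario.n_snps
    n_inst = scenario.n_instrument_snps
    is_instrument = np.zeros(m, dtype=bool)
    is_instrument[:n_inst] = True

    maf = rng.uniform(*scenario.maf_range, size=m)
    eaf = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)

    # effect allele oriented to the exposure-increasing allele: half-normal b
    b = np.zeros(m)
    b[:n_inst] = np.abs(rng.normal(0.0, scenario.exposure_effect_sd, size=n_inst))

    alpha = np.zeros(m)
    if scenario.pleiotropy_model != "none" and scenario.pleiotropy_sd >= 0:
        pick = np.zeros(m, dtype=bool)
        pick[:n_inst] = rng.random(n_inst) < scenario.pleiotropy_fraction
        npick = int(pick.sum())
        eps = rng.normal(size=npick)
        if scenario.pleiotropy_model == "balanced":
            alpha[pick] = scenario.pleiotropy_sd * eps
        elif scenario.pleiotropy_model == "directional":
            alpha[pick] = scenario.pleiotropy_mean + scenario.pleiotropy_sd * eps
        else:  # correlated: alpha depends on instrument strength (InSIDE violated)
            bp = b[pick]
            sdb = bp.std()
            zb = (bp - bp.mean()) / sdb if sdb > 0 else np.zeros(npick)
            rho = scenario.inside_correlation
            alpha[pick] = scenario.pleiotropy_mean + scenario.pleiotropy_sd * (
                rho * zb + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
            )
    gamma = scenario.theta * b + alpha

    palindromic = rng.random(m) < scenario.palindromic_fraction
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    non_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    for i in range(m):
        ea[i], oa[i] = (
            _PALINDROMIC_PAIRS[pal_idx[i]] if palindromic[i]
            else _NONPALINDROMIC_PAIRS[non_idx[i]]
        )

    width = len(str(m))
    rsid = np.array(
        [f"{scenario.snp_prefix}{i + 1:0{width}d}" for i in range(m)], dtype=object
    )
    df = pd.DataFrame(
        {
            "rsid": rsid,
            "effect_allele": ea,
            "other_allele": oa,
            "maf": maf,
            "eaf": eaf,
            "b": b,
            "alpha": alpha,
            "gamma": gamma,
            "is_instrument": is_instrument,
            "is_palindromic": palindromic,
            "swapped": np.zeros(m, dtype=bool),
            "strand_flipped": np.zeros(m, dtype=bool),
        }
    )
    return SimulationTruth(df=df, theta=scenario.theta, scenario=scenario)


def _observe(
    truth: SimulationTruth,
    true_beta: np.ndarray,
    n: int,
    variance_factor: float,
    trait_id: str,
    trait_type: str,
    rng: np.random.Generator,
) -> SummaryStatsTable:
    t = truth.df
    maf = t["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * n * variance_factor * maf * (1.0 - maf))
    beta = rng.normal(true_beta, se)
    eaf = t["eaf"].to_numpy()
    eaf_obs = np.clip(
        eaf + rng.normal(0.0, np.sqrt(eaf * (1.0 - eaf) / (2.0 * n))),
        1e-4, 1.0 - 1e-4,
    )
    df = pd.DataFrame(
        {
            "rsid": t["rsid"],
            "effect_allele": t["effect_allele"],
            "other_allele": t["other_allele"],
            "eaf": eaf_obs,
            "beta": beta,
            "se": se,
            "pvalue": _pvalue(beta, se),
            "n": n,
        }
    )
    return SummaryStatsTable(trait_id=trait_id, df=df, trait_type=trait_type)


def simulate_exposure(
    truth: SimulationTruth, rng: np.random.Generator, trait_id: str = "exposure"
) -> SummaryStatsTable:
    scen = truth.scenario
    return _observe(
        truth, truth.df["b"].to_numpy(), scen.n_exposure, 1.0,
        trait_id, "continuous", rng,
    )


def simulate_outcome(
    truth: SimulationTruth,
    rng: np.random.Generator | int,
    trait_id: str = "outcome",
    n_outcome: int | None = None,
    outcome_type: str | None = None,
    case_fraction: float | None = None,
) -> SummaryStatsTable:
    """Draw an outcome cohort from an existing truth (supports extra cohorts
    sharing the same generative truth, as in a multi-cohort outcome design)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    scen = truth.scenario
    n = n_outcome if n_outcome is not None else scen.n_outcome
    otype = outcome_type if outcome_type is not None else scen.outcome_type
    cf = case_fraction if case_fraction is not None else scen.case_fraction
    v = 1.0 if otype == "continuous" else cf * (1.0 - cf)
    return _observe(
        truth, truth.df["gamma"].to_numpy(), n, v, trait_id, otype, rng
    )


def corrupt_allele_coding(
    table: SummaryStatsTable,
    scenario: SimulationScenario,
    rng: np.random.Generator | int | None = None,
) -> tuple[SummaryStatsTable, pd.DataFrame]:
    """Corrupt a table's allele coding per the scenario's rates.

    A *swap* exchanges effect/other alleles, flips the sign of beta and
    complements eaf — an information-preserving recoding harmonization must
    undo.  A *strand flip* complements both alleles and changes nothing else.
    Returns the corrupted table and a per-SNP log (rsid, swapped,
    strand_flipped).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    df = table.df.copy()
    m = len(df)
    swap = rng.random(m) < scenario.swap_rate
    flip = rng.random(m) < scenario.strand_flip_rate

    ea = df["effect_allele"].to_numpy(dtype=object).copy()
    oa = df["other_allele"].to_numpy(dtype=object).copy()
    beta = df["beta"].to_numpy(dtype=float).copy()
    eaf = df["eaf"].to_numpy(dtype=float).copy()

    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    beta[swap] = -beta[swap]
    eaf[swap] = 1.0 - eaf[swap]
    for i in np.flatnonzero(flip):
        ea[i] = _COMPLEMENT[ea[i]]
        oa[i] = _COMPLEMENT[oa[i]]

    df["effect_allele"], df["other_allele"] = ea, oa
    df["beta"], df["eaf"] = beta, eaf
    out = SummaryStatsTable(
        trait_id=table.trait_id, df=df, trait_type=table.trait_type
    )
    log = pd.DataFrame(
        {"rsid": df["rsid"], "swapped": swap, "strand_flipped": flip}
    )
    return out, log


def build_ld_matrix(truth: SimulationTruth) -> LdMatrix:
    """Block-diagonal annotation r² matrix: consecutive SNPs share a block of
    ``ld_block_size`` with pairwise r² = ``within_block_r2``; zero between
    blocks."""
    scen = truth.scenario
    m = len(truth.df)
    r2 = np.zeros((m, m))
    size = scen.ld_block_size
    for start in range(0, m, size):
        stop = min(start + size, m)
        r2[start:stop, start:stop] = scen.within_block_r2
    np.fill_diagonal(r2, 1.0)
    return LdMatrix(truth.df["rsid"].tolist(), r2)


def simulate_two_sample(
    scenario: SimulationScenario,
) -> tuple[SummaryStatsTable, SummaryStatsTable, SimulationTruth]:
    """Generate one exposure GWAS, one outcome GWAS and the truth sidecar.

    Exposure and outcome sampling errors are independent (two non-overlapping
    samples).  Allele-coding corruption, when requested, is applied to the
    outcome table and logged in the truth.  A fixed seed gives byte-identical
    outputs.
    """
    rng = np.random.default_rng(scenario.seed)
    truth = _draw_truth(scenario, rng)
    exposure = simulate_exposure(truth, rng)
    outcome = simulate_outcome(truth, rng)
    if scenario.swap_rate > 0 or scenario.strand_flip_rate > 0:
        outcome, log = corrupt_allele_coding(outcome, scenario, rng)
        truth.df["swapped"] = log["swapped"].to_numpy()
        truth.df["strand_flipped"] = log["strand_flipped"].to_numpy()
    return exposure, outcome, truth


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    df = truth.df.copy()
    df["theta"] = truth.theta
    df.to_csv(path, sep="\t", index=False)
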