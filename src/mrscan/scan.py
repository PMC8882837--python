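"""Phenome-wide MR scan: many exposures against one or more outcome cohorts.

For each exposure the scan selects instruments, harmonizes them against every
outcome cohort, runs the configured estimators, then pools the per-cohort
primary estimates (IVW, which reduces to the Wald ratio at k = 1) into a
combined column by fixed-effect inverse variance (DerSimonian-Laird random
effects by option).  Multiple testing across exposures is handled by the
Bonferroni rule: an exposure is flagged *significant* below
family_alpha / n_exposures and *suggestive* below family_alpha.

Per-exposure randomness (bootstrap SEs) is seeded from (config seed,
exposure id), so adding or removing an exposure never perturbs the others'
results.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, ValidationError
from .estimators import (
    MrResult,
    diagnostics_data,
    ivw_fixed,
    leave_one_out,
    mr_egger,
    weighted_median,
    weighted_mode,
)
from .harmonization import drop_outcome_significant, harmonize, retained
from .instruments import InstrumentSet, select_instruments
from .pooling import bonferroni_threshold, pool_fixed, pool_random_dl
from .sumstats import read_ld_matrix, read_summary_stats

METHOD_NAMES = ("ivw", "egger", "wmedian", "wmode")


@dataclass
class ExposureSpec:
    id: str
    path: str
    trait_type: str = "continuous"
    ld_path: str | None = None


@dataclass
class OutcomeSpec:
    id: str
    path: str
    trait_type: str = "binary"


@dataclass
class ScanConfig:
    """Configuration of one phenome-wide scan."""

    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    p_primary: float = 5e-8
    p_fallback: float = 5e-6
    r2_max: float = 0.1
    fallback_below: int = 10
    palindromic_eaf_window: float = 0.08
    drop_outcome_significant: bool = True
    outcome_p_threshold: float = 5e-8
    methods: tuple = ("ivw", "egger", "wmedian", "wmode")
    n_boot: int = 1000
    family_alpha: float = 0.05
    pool_model: str = "fixed"  # "fixed" | "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ValidationError("config needs at least one exposure and one outcome")
        if not 0.0 < self.family_alpha < 1.0:
            raise ValidationError("family_alpha must lie in (0, 1)")
        if self.pool_model not in ("fixed", "random"):
            raise ValidationError("pool_model must be 'fixed' or 'random'")
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ConfigurationError(
                f"unknown method(s): {', '.join(sorted(unknown))}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            exposures = [ExposureSpec(**e) for e in raw.pop("exposures")]
            outcomes = [OutcomeSpec(**o) for o in raw.pop("outcomes")]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"bad exposures/outcomes block: {exc}") from exc
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(exposures=exposures, outcomes=outcomes, **raw)

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("exposures", "outcomes")
        }
        d["methods"] = list(self.methods)
        d["exposures"] = [vars(e) for e in self.exposures]
        d["outcomes"] = [vars(o) for o in self.outcomes]
        return d


@dataclass
class ExposureArtifacts:
    """Audit and diagnostics bundles for one exposure."""

    instruments: InstrumentSet
    pairs: dict = field(default_factory=dict)  # outcome id -> harmonized frame
    scatter: dict = field(default_factory=dict)
    funnel: dict = field(default_factory=dict)
    loo: dict = field(default_factory=dict)  # outcome id -> leave-one-out frame


@dataclass
class ScanResult:
    results: pd.DataFrame
    artifacts: dict  # exposure id -> ExposureArtifacts
    config: ScanConfig


def _exposure_seed(config_seed: int, exposure_id: str) -> int:
    ss = np.random.SeedSequence([config_seed, zlib.crc32(exposure_id.encode())])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def _run_methods(pairs, methods, n_boot, seed) -> dict[str, MrResult]:
    kept = retained(pairs)
    k = len(kept)
    out: dict[str, MrResult] = {}
    if k == 0:
        return out
    out["ivw"] = ivw_fixed(kept)
    if k >= 3:
        if "egger" in methods:
            try:
                out["egger"] = mr_egger(kept)
            except ValidationError:
                pass  # no variation in bXG
        if "wmedian" in methods:
            out["wmedian"] = weighted_median(kept, n_boot=n_boot, seed=seed)
        if "wmode" in methods:
            out["wmode"] = weighted_mode(kept, n_boot=n_boot, seed=seed + 1)
    return out


def run_scan(config: ScanConfig) -> ScanResult:
    """Execute the scan; returns the master results table plus artifacts."""
    bonf = bonferroni_threshold(len(config.exposures), config.family_alpha)
    outcome_tables = {}
    for o in config.outcomes:
        outcome_tables[o.id] = read_summary_stats(
            o.path, trait_id=o.id, trait_type=o.trait_type
        )

    rows: list[dict] = []
    artifacts: dict[str, ExposureArtifacts] = {}
    for exp in config.exposures:
        table = read_summary_stats(
            exp.path, trait_id=exp.id, trait_type=exp.trait_type
        )
        ld = read_ld_matrix(exp.ld_path) if exp.ld_path else None
        inst = select_instruments(
            table, ld,
            p_primary=config.p_primary, p_fallback=config.p_fallback,
            r2_max=config.r2_max, fallback_below=config.fallback_below,
        )
        art = ExposureArtifacts(instruments=inst)
        artifacts[exp.id] = art
        base = {
            "exposure": exp.id,
            "k_selected": inst.k,
            "threshold_used": inst.threshold_used,
            "r2_total": inst.r2_total,
            "f_stat": inst.f_stat,
        }
        if inst.k == 0:
            rows.append(
                {**base, "outcome": "combined", "method": "none",
                 "status": "no_instruments"}
            )
            continue

        seed = _exposure_seed(config.seed, exp.id)
        primary: list[tuple[str, float, float]] = []
        for i, out_spec in enumerate(config.outcomes):
            pairs = harmonize(
                inst, outcome_tables[out_spec.id],
                palindromic_eaf_window=config.palindromic_eaf_window,
            )
            if config.drop_outcome_significant:
                pairs = drop_outcome_significant(
                    pairs, threshold=config.outcome_p_threshold
                )
            art.pairs[out_spec.id] = pairs
            results = _run_methods(
                pairs, config.methods, config.n_boot, seed + 100 * i
            )
            kept = retained(pairs)
            if not results:
                rows.append(
                    {**base, "outcome": out_spec.id, "method": "none",
                     "status": "no_pairs"}
                )
                continue
            ivw = results["ivw"]
            label = "wald_ratio" if ivw.n_snps == 1 else "ivw_fixed"
            primary.append((out_spec.id, ivw.beta, ivw.se))
            for name, res in results.items():
                method = label if name == "ivw" else res.method
                rows.append(
                    {**base, "outcome": out_spec.id, "status": "ok",
                     **res.to_row(), "method": method}
                )
            scatter, funnel = diagnostics_data(kept, results.values())
            art.scatter[out_spec.id] = scatter
            art.funnel[out_spec.id] = funnel
            if len(kept) >= 3:
                art.loo[out_spec.id] = pd.DataFrame(
                    [{"omitted": r.label, **r.to_row()} for r in leave_one_out(kept)]
                )

        if primary:
            est = pd.DataFrame(primary, columns=["label", "beta", "se"])
            pooled = (
                pool_random_dl(est)
                if config.pool_model == "random" and len(est) >= 2
                else pool_fixed(est)
            )
            rows.append(
                {**base, "outcome": "combined", "status": "ok",
                 "method": f"pool_{pooled.model}",
                 "n_studies": len(primary),
                 **{k: v for k, v in pooled.to_row().items() if k != "model"},
                 "tau2": pooled.tau2,
                 "significant": pooled.pvalue < bonf,
                 "suggestive": pooled.pvalue < config.family_alpha}
            )

    results = pd.DataFrame(rows)
    results.attrs["bonferroni_threshold"] = bonf
    return ScanResult(results=results, artifacts=artifacts, config=config)


def report(scan: ScanResult, out_dir: str | Path) -> list[Path]:
    """Write the master table, per-exposure diagnostics and a run manifest."""
    if scan.results.empty:
        raise ValidationError("cannot report an empty results table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    master = out_dir / "results.tsv"
    scan.results.to_csv(master, sep="\t", index=False)
    written.append(master)

    for exp_id, art in scan.artifacts.items():
        d = out_dir / exp_id
        d.mkdir(exist_ok=True)
        inst = art.instruments
        inst.snps.to_csv(d / "instruments.tsv", sep="\t", index=False)
        inst.dropped_log.to_csv(d / "instrument_drops.tsv", sep="\t", index=False)
        written.append(d / "instruments.tsv")
        for out_id, pairs in art.pairs.items():
            pairs.to_csv(d / f"harmonized_{out_id}.tsv", sep="\t", index=False)
        for out_id, scatter in art.scatter.items():
            scatter.to_csv(d / f"scatter_{out_id}.tsv", sep="\t", index=False)
            scatter.attrs["lines"].to_csv(
                d / f"scatter_lines_{out_id}.tsv", sep="\t", index=False
            )
        for out_id, funnel in art.funnel.items():
            funnel.to_csv(d / f"funnel_{out_id}.tsv", sep="\t", index=False)
        for out_id, loo in art.loo.items():
            loo.to_csv(d / f"leave_one_out_{out_id}.tsv", sep="\t", index=False)

    manifest = {
        "package": "mrscan",
        "version": __version__,
        "seed": scan.config.seed,
        "bonferroni_threshold": scan.results.attrs.get("bonferroni_threshold"),
        "config": scan.config.to_dict(),
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written
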