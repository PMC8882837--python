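"""GWAS summary-statistics containers and tab-separated I/O.

The canonical per-SNP record carries the fields needed for two-sample MR:
rsid, effect allele, other allele, effect-allele frequency (eaf), per-allele
effect size beta (SD units for continuous traits, log-odds for binary), its
standard error, p-value, and the GWAS sample size n.  Files are plain
tab-separated text with a header row; a column map supports dialects with
different header names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: Canonical column order of a summary-statistics table.
REQUIRED_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

TRAIT_TYPES = ("continuous", "binary")


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP-trait association from a GWAS summary-statistics table."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    @property
    def maf(self) -> float:
        """Minor-allele frequency, min(eaf, 1 - eaf)."""
        return min(self.eaf, 1.0 - self.eaf)

    def problems(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        out = []
        if not self.rsid:
            out.append("rsid is empty")
        if not self.effect_allele or not self.other_allele:
            out.append("allele is empty")
        elif self.effect_allele == self.other_allele:
            out.append("effect and other allele are identical")
        if not (0.0 <= self.eaf <= 1.0) or math.isnan(self.eaf):
            out.append("eaf outside [0, 1]")
        if math.isnan(self.beta):
            out.append("beta is missing")
        if not (self.se > 0) or math.isnan(self.se):
            out.append("se is not > 0")
        if not (0.0 < self.pvalue <= 1.0) or math.isnan(self.pvalue):
            out.append("pvalue outside (0, 1]")
        if not self.n > 0:
            out.append("n is not a positive integer")
        return out


@dataclass
class SummaryStatsTable:
    """One trait's GWAS summary statistics (ordered, rsid-unique)."""

    trait_id: str
    df: pd.DataFrame
    trait_type: str = "continuous"
    #: rows rejected while reading, as (line_number, rsid, reason)
    parse_log: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValidationError(
                f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}"
            )
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(
                f"summary-statistics table for {self.trait_id!r} is missing "
                f"columns: {', '.join(missing)}"
            )
        dup = self.df["rsid"][self.df["rsid"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(
                f"duplicate rsids in table {self.trait_id!r}: {', '.join(map(str, dup))}"
            )
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[SnpAssociation]:
        for row in self.df.itertuples(index=False):
            yield SnpAssociation(
                rsid=row.rsid,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=int(row.n),
            )


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "continuous",
) -> SummaryStatsTable:
    """Read a tab-separated summary-statistics file into a table.

    ``column_map`` maps canonical names (see :data:`REQUIRED_COLUMNS`) to the
    file's header names for non-canonical dialects.  Rows violating per-record
    invariants (se <= 0, p outside (0,1], identical alleles...) are dropped and
    reported, with 1-based file line numbers, in ``table.parse_log``.
    Duplicate rsids among the surviving rows raise :class:`ValidationError`.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if column_map:
        rename = {}
        for canonical in REQUIRED_COLUMNS:
            src = column_map.get(canonical, canonical)
            if src not in raw.columns:
                raise ConfigurationError(
                    f"{path.name}: required column {canonical!r} "
                    f"(file column {src!r}) not found"
                )
            rename[src] = canonical
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: required column(s) missing: {', '.join(missing)}"
        )
    raw = raw[list(REQUIRED_COLUMNS)]

    keep = np.ones(len(raw), dtype=bool)
    log: list[tuple[int, str, str]] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        try:
            rec = SnpAssociation(
                rsid=str(row.rsid),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=int(row.n) if not pd.isna(row.n) else 0,
            )
            issues = rec.problems()
        except (TypeError, ValueError) as exc:
            issues = [f"unparseable field: {exc}"]
        if pd.isna(row.eaf) or pd.isna(row.beta) or pd.isna(row.se) or pd.isna(row.pvalue):
            issues.append("missing required field")
        if issues:
            keep[i] = False
            # +2: one for the header row, one for 1-based numbering
            log.append((i + 2, str(row.rsid), "; ".join(sorted(set(issues)))))

    df = raw.loc[keep].copy()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    df["n"] = df["n"].astype(int)
    table = SummaryStatsTable(
        trait_id=trait_id or path.stem, df=df, trait_type=trait_type
    )
    table.parse_log = log
    return table


def write_summary_stats(table: SummaryStatsTable, path: str | Path) -> None:
    """Write a table in the canonical tab-separated form."""
    table.df[list(REQUIRED_COLUMNS)].to_csv(path, sep="\t", index=False)


@dataclass
class LdMatrix:
    """Pairwise linkage-disequilibrium (r²) matrix keyed by rsid."""

    rsids: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.rsids = list(self.rsids)
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.rsids)
        if self.r2.shape != (m, m):
            raise ValidationError(
                f"LD matrix shape {self.r2.shape} does not match {m} rsids"
            )
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValidationError("LD matrix diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T):
            raise ValidationError("LD matrix must be symmetric")
        if self.r2.min() < 0 or self.r2.max() > 1:
            raise ValidationError("LD r2 entries must lie in [0, 1]")
        self._index = {rs: i for i, rs in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, rsid_a: str, rsid_b: str) -> float:
        return float(self.r2[self._index[rsid_a], self._index[rsid_b]])

    def submatrix(self, rsids: Sequence[str]) -> "LdMatrix":
        idx = [self._index[rs] for rs in rsids]
        return LdMatrix(list(rsids), self.r2[np.ix_(idx, idx)])


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read a square tab-separated r² matrix with an rsid header row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LdMatrix(df.index.astype(str).tolist(), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.rsids, columns=ld.rsids).to_csv(
        path, sep="\t", index_label="rsid"
    )
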