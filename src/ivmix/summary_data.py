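"""Data model and TSV I/O for harmonized GWAS summary statistics.

Inputs are assumed pre-harmonized: both associations are reported relative to
the same (ideally exposure-increasing) allele, so no strand flipping or allele
matching is done here.  Tables are tab-separated with a header row; decimal
point only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .exceptions import SummaryDataError

#: default input column names, in file order
DEFAULT_COLUMNS = ("variant_id", "beta_exp", "se_exp", "beta_out", "se_out")
OPTIONAL_COLUMNS = ("effect_allele", "other_allele")

#: columns of the per-variant result table
RESULT_COLUMNS = (
    "variant_id",
    "ratio_estimate",
    "ratio_se",
    "cluster",
    "cluster_mean",
    "inclusion_probability",
)

#: significant digits used when formatting result tables (round-trip exact)
RESULT_FLOAT_FORMAT = "%.17g"

_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan"}


@dataclass(frozen=True)
class VariantSummary:
    """One variant's association estimates with exposure and outcome.

    Attributes
    ----------
    variant_id : str
        rsid or chr:pos identifier; non-empty, unique within a dataset.
    beta_exposure, se_exposure : float
        Per-allele association with the exposure and its standard error.
    beta_outcome, se_outcome : float
        Per-allele association with the outcome and its standard error.
    effect_allele, other_allele : str, optional
        Carried through untouched when present.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    effect_allele: Optional[str] = None
    other_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise SummaryDataError("variant_id must be non-empty")
        if not (self.se_exposure > 0):
            raise SummaryDataError(
                f"variant {self.variant_id!r}: se_exposure must be > 0, "
                f"got {self.se_exposure}"
            )
        if not (self.se_outcome > 0):
            raise SummaryDataError(
                f"variant {self.variant_id!r}: se_outcome must be > 0, "
                f"got {self.se_outcome}"
            )


def _default_column_map() -> dict:
    return {
        "variant_id": "variant_id",
        "beta_exposure": "beta_exp",
        "se_exposure": "se_exp",
        "beta_outcome": "beta_out",
        "se_outcome": "se_out",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
    }


def read_summary_table(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[VariantSummary]:
    """Read a tab-separated summary-statistic table into VariantSummary records.

    Parameters
    ----------
    path : path-like
        TSV file with a header row.
    column_map : mapping, optional
        Maps VariantSummary field names to column names in the file.  Defaults
        to ``variant_id, beta_exp, se_exp, beta_out, se_out`` plus the optional
        allele columns.  Only the mapped names matter; column order does not.

    Returns
    -------
    list of VariantSummary, in file order.

    Raises
    ------
    SummaryDataError
        Missing file or column, non-numeric or missing required values,
        non-positive SEs, duplicate variant ids.  Row-level problems are
        collected and reported together, indexed by data-row number (1-based).
    """
    path = Path(path)
    if not path.exists():
        raise SummaryDataError(f"input file not found: {path}")

    cmap = _default_column_map()
    if column_map:
        cmap.update(column_map)

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    required = ["variant_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]
    missing_cols = [cmap[f] for f in required if cmap[f] not in frame.columns]
    if missing_cols:
        raise SummaryDataError(
            f"missing mapped column(s) {missing_cols} in {path}; "
            f"found columns {list(frame.columns)}"
        )
    have_alleles = {
        f: cmap[f] in frame.columns for f in ("effect_allele", "other_allele")
    }

    records: list[VariantSummary] = []
    problems: list[str] = []
    seen_ids: set[str] = set()

    for i, row in enumerate(frame.itertuples(index=False), start=1):
        rowd = dict(zip(frame.columns, row))
        vid = rowd[cmap["variant_id"]].strip()
        if vid in _MISSING_TOKENS:
            problems.append(f"row {i}: missing variant_id")
            continue
        values = {}
        bad = False
        for fname in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            raw = rowd[cmap[fname]].strip()
            if raw in _MISSING_TOKENS:
                problems.append(f"row {i} ({vid}): missing value in field {fname}")
                bad = True
                continue
            try:
                val = float(raw)
            except ValueError:
                problems.append(
                    f"row {i} ({vid}): non-numeric value {raw!r} in field {fname}"
                )
                bad = True
                continue
            if not math.isfinite(val):
                problems.append(f"row {i} ({vid}): non-finite value in field {fname}")
                bad = True
                continue
            values[fname] = val
        if bad:
            continue
        if values["se_exposure"] <= 0:
            problems.append(f"row {i} ({vid}): non-positive SE in field se_exposure")
            continue
        if values["se_outcome"] <= 0:
            problems.append(f"row {i} ({vid}): non-positive SE in field se_outcome")
            continue
        if vid in seen_ids:
            problems.append(f"row {i}: duplicate variant_id {vid!r}")
            continue
        seen_ids.add(vid)

        alleles = {}
        for fname in ("effect_allele", "other_allele"):
            if have_alleles[fname]:
                raw = rowd[cmap[fname]].strip()
                alleles[fname] = None if raw in _MISSING_TOKENS else raw
            else:
                alleles[fname] = None

        records.append(
            VariantSummary(
                variant_id=vid,
                beta_exposure=values["beta_exposure"],
                se_exposure=values["se_exposure"],
                beta_outcome=values["beta_outcome"],
                se_outcome=values["se_outcome"],
                effect_allele=alleles["effect_allele"],
                other_allele=alleles["other_allele"],
            )
        )

    if problems:
        raise SummaryDataError(
            "invalid rows in " + str(path) + ":\n  " + "\n  ".join(problems)
        )
    if any(r.beta_exposure < 0 for r in records):
        warnings.warn(
            "some beta_exposure values are negative; inputs are expected to be "
            "harmonized to a consistent (e.g. exposure-increasing) allele",
            UserWarning,
            stacklevel=2,
        )
    return records


@dataclass
class VariantResult:
    """Per-variant clustering result row (mirrors the output table)."""

    variant_id: str
    ratio_estimate: float
    ratio_se: float
    cluster: str  # integer string, "null", "junk" or "unassigned"
    cluster_mean: Optional[float]
    inclusion_probability: float
    _extra: dict = field(default_factory=dict, repr=False)


def write_variant_results(records: Sequence[VariantResult], path: str | Path) -> None:
    """Write per-variant results as TSV; header is written even for no rows.

    Floats are formatted with 17 significant digits so that re-reading the
    file reproduces the records exactly.
    """
    path = Path(path)
    rows = []
    for rec in records:
        if not rec.variant_id:
            raise SummaryDataError("variant_id must be non-empty in results")
        rows.append(
            {
                "variant_id": rec.variant_id,
                "ratio_estimate": rec.ratio_estimate,
                "ratio_se": rec.ratio_se,
                "cluster": str(rec.cluster),
                "cluster_mean": rec.cluster_mean,
                "inclusion_probability": rec.inclusion_probability,
            }
        )
    frame = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, float_format=RESULT_FLOAT_FORMAT)


def read_variant_results(path: str | Path) -> list[VariantResult]:
    """Read back a table written by :func:`write_variant_results`."""
    path = Path(path)
    if not path.exists():
        raise SummaryDataError(f"results file not found: {path}")
    # "null" is a legitimate cluster label, so NA sniffing must stay off
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        mean = row.cluster_mean
        out.append(
            VariantResult(
                variant_id=row.variant_id,
                ratio_estimate=float(row.ratio_estimate),
                ratio_se=float(row.ratio_se),
                cluster=str(row.cluster),
                cluster_mean=None if mean == "" else float(mean),
                inclusion_probability=float(row.inclusion_probability),
            )
        )
    return out
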