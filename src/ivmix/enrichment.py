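"""Trait-enrichment scan for cluster interpretation.

Once a cluster of variants is identified, a hypothesis-generating question is
whether its members preferentially associate with some other trait — a hint
at the biological mechanism the cluster represents.  Given a long-format
variant x trait association table (variant_id, trait, p_value), for each
trait we report

* the true-positive rate: the fraction of in-cluster variants associated
  with the trait at p < threshold, and
* the false-positive rate: the same fraction among variants not in the
  cluster,

counting only variants with data for that trait, plus an exact hypergeometric
p-value for independence of trait association and cluster membership.  Raw
p-values are reported without multiplicity correction by default (trait lists
are typically full of repeats and synonyms, making a formal correction
ill-defined); a Benjamini-Hochberg column is available opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .exceptions import IvmixError

DEFAULT_THRESHOLDS = (1e-5, 1e-8)


@dataclass(frozen=True)
class EnrichmentResult:
    """Association rates and independence test for one (trait, threshold)."""

    trait: str
    threshold: float
    tp_count: int
    tp_denom: int
    fp_count: int
    fp_denom: int
    p_value: Optional[float] = None
    p_bh: Optional[float] = None

    @property
    def tp_rate(self) -> float:
        return self.tp_count / self.tp_denom

    @property
    def fp_rate(self) -> float:
        return self.fp_count / self.fp_denom if self.fp_denom else 0.0


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"variant_id", "trait", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise IvmixError(f"association table lacks column(s) {sorted(missing)}")
    if table.empty:
        raise IvmixError("association table is empty")
    p = table["p_value"].to_numpy(dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise IvmixError("p_value must lie in [0, 1]")
    if table.duplicated(["variant_id", "trait"]).any():
        raise IvmixError("duplicate (variant_id, trait) pairs in association table")
    return table


def association_rates(
    cluster_members: Iterable[str],
    all_variants: Iterable[str],
    table: pd.DataFrame,
    trait: str,
    threshold: float,
) -> EnrichmentResult:
    """True/false-positive association rates for one trait.

    A variant counts as associated iff its p-value is strictly below
    ``threshold``.  Variants with no entry for the trait are excluded from
    numerator and denominator alike (not imputed).
    """
    members = set(cluster_members)
    everyone = set(all_variants)
    if not members <= everyone:
        raise IvmixError("cluster_members must be a subset of all_variants")
    if not (0 < threshold < 1):
        raise IvmixError("threshold must be in (0, 1)")
    table = _validate_table(table)

    sub = table[table["trait"] == trait]
    present = set(sub["variant_id"]) & everyone
    in_cluster = present & members
    out_cluster = present - members
    if not in_cluster:
        raise IvmixError(
            f"no cluster member has data for trait {trait!r}"
        )
    assoc = set(sub.loc[sub["p_value"].astype(float) < threshold, "variant_id"])
    return EnrichmentResult(
        trait=trait,
        threshold=threshold,
        tp_count=len(in_cluster & assoc),
        tp_denom=len(in_cluster),
        fp_count=len(out_cluster & assoc),
        fp_denom=len(out_cluster),
    )


def hypergeom_independence_test(
    tp_count: int,
    tp_denom: int,
    fp_count: int,
    fp_denom: int,
    tail: str = "upper",
) -> float:
    """Exact hypergeometric test of trait-association vs cluster membership.

    Population: the tp_denom + fp_denom variants with data; successes: the
    tp_count + fp_count associated variants; draw: the tp_denom in-cluster
    variants.  ``"upper"`` (default) sums P(X >= tp_count) — enrichment of
    association inside the cluster; ``"two_sided"`` sums the probabilities of
    all tables no more probable than the observed one.
    """
    for name, val in (
        ("tp_count", tp_count),
        ("tp_denom", tp_denom),
        ("fp_count", fp_count),
        ("fp_denom", fp_denom),
    ):
        if val < 0 or val != int(val):
            raise IvmixError(f"{name} must be a non-negative integer")
    if tp_count > tp_denom or fp_count > fp_denom or tp_denom < 1:
        raise IvmixError("inconsistent contingency counts")

    M = tp_denom + fp_denom
    n_success = tp_count + fp_count
    dist = hypergeom(M, n_success, tp_denom)
    lo = max(0, n_success - fp_denom)
    hi = min(tp_denom, n_success)
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    if tail == "upper":
        p = float(pmf[support >= tp_count].sum())
    elif tail == "two_sided":
        p_obs = float(dist.pmf(tp_count))
        p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    else:
        raise IvmixError(f"tail must be 'upper' or 'two_sided', got {tail!r}")
    return min(p, 1.0)


def scan_traits(
    cluster_members: Iterable[str],
    all_variants: Iterable[str],
    table: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    tail: str = "upper",
    bh: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment scan over every trait in the table, at each threshold.

    Results are ranked by ascending p-value.  Traits for which no cluster
    member has data are skipped.  P-values are raw; with ``bh=True`` a
    Benjamini-Hochberg adjusted column is filled in per threshold (across
    traits).
    """
    table = _validate_table(table)
    members = set(cluster_members)
    everyone = set(all_variants)
    results: list[EnrichmentResult] = []
    for threshold in thresholds:
        batch: list[EnrichmentResult] = []
        for trait in sorted(table["trait"].unique()):
            try:
                rates = association_rates(members, everyone, table, trait, threshold)
            except IvmixError:
                continue
            p = hypergeom_independence_test(
                rates.tp_count, rates.tp_denom, rates.fp_count, rates.fp_denom, tail=tail
            )
            batch.append(replace(rates, p_value=p))
        if bh and batch:
            ps = np.array([r.p_value for r in batch])
            order = np.argsort(ps)
            m = len(ps)
            adj = np.empty(m)
            running = 1.0
            for rank_pos in range(m - 1, -1, -1):
                idx = order[rank_pos]
                running = min(running, ps[idx] * m / (rank_pos + 1))
                adj[idx] = running
            batch = [replace(r, p_bh=float(a)) for r, a in zip(batch, adj)]
        results.extend(batch)
    results.sort(key=lambda r: (r.p_value, r.trait, r.threshold))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view matching the output TSV schema."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "threshold": r.threshold,
                "tp": r.tp_count,
                "tp_denom": r.tp_denom,
                "fp": r.fp_count,
                "fp_denom": r.fp_denom,
                "tp_rate": r.tp_rate,
                "fp_rate": r.fp_rate,
                "p_value": r.p_value,
                **({"p_bh": r.p_bh} if r.p_bh is not None else {}),
            }
            for r in results
        ]
    )
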