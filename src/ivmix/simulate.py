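"""Synthetic GWAS summary statistics and the clustering benchmark.

The generator imitates per-allele coefficient estimates from linear
regression of a unit-variance trait on a SNP in a notional sample of size N.
Per variant j, independently:

    MAF_j        ~ Uniform(0.05, 0.5)
    mu_bX_j      ~ N(0, 1)
    v_j          = 1 / (N * MAF_j * (1 - MAF_j))      (sampling variance)
    beta_X_j     ~ N(mu_bX_j, v_j)
    beta_Y_j     ~ N(theta_j * beta_X_j, tau * v_j)
    reported SEs = sqrt(v_j) for both associations.

tau >= 1 is an overdispersion factor on the outcome associations that is
deliberately *not* reflected in the reported SEs — scenarios with tau > 1
probe robustness to unmodelled excess heterogeneity.  Junk variants draw
their own causal effect theta_j from a standard normal.

Four preset scenarios: 1 and 2 have 90 null variants (tau = 1 and 2); 3 and 4
add three substantive clusters (effects 0.4, -0.4, 0.8 with 10, 20 and 40
variants), 10 junk and 10 null variants (tau = 1 and 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .assignment import assign_version_a, assign_version_b
from .exceptions import IvmixError
from .ratio import build_ratio_dataset
from .selection import scan_cluster_number
from .summary_data import VariantSummary

EffectSpec = Union[float, str]  # a fixed effect, "null" (0) or "junk" (N(0,1) draw)


@dataclass(frozen=True)
class ClusterSpec:
    """A block of variants sharing one true-effect specification."""

    effect: EffectSpec
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise IvmixError("cluster count must be positive")
        if isinstance(self.effect, str) and self.effect not in ("null", "junk"):
            raise IvmixError(f"effect spec must be a number, 'null' or 'junk': {self.effect!r}")


@dataclass(frozen=True)
class SimScenario:
    """Scenario definition: cluster composition, overdispersion, sample size."""

    clusters: tuple[ClusterSpec, ...]
    tau: float
    N: int

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise IvmixError("tau must be >= 1")
        if self.N < 1:
            raise IvmixError("N must be positive")

    @property
    def J(self) -> int:
        return sum(c.count for c in self.clusters)


@dataclass
class SimDataset:
    """Simulated summaries with ground truth."""

    summaries: list[VariantSummary]
    true_labels: list[str]
    true_effects: np.ndarray


def scenario_preset(scenario_id: int, N: int) -> SimScenario:
    """The four benchmark scenarios (tau = 1 for 1/3, tau = 2 for 2/4)."""
    if scenario_id in (1, 2):
        clusters = (ClusterSpec("null", 90),)
    elif scenario_id in (3, 4):
        clusters = (
            ClusterSpec("null", 10),
            ClusterSpec("junk", 10),
            ClusterSpec(0.4, 10),
            ClusterSpec(-0.4, 20),
            ClusterSpec(0.8, 40),
        )
    else:
        raise IvmixError(f"unknown scenario id {scenario_id!r}; expected 1-4")
    tau = 1.0 if scenario_id in (1, 3) else 2.0
    return SimScenario(clusters=clusters, tau=tau, N=N)


def _true_label(spec: ClusterSpec) -> str:
    if isinstance(spec.effect, str):
        return spec.effect
    return f"effect={spec.effect:g}"


def simulate_summary_data(
    scenario: SimScenario, rng: np.random.Generator
) -> SimDataset:
    """Draw one dataset from the generative model above."""
    J = scenario.J
    effects = np.empty(J)
    labels: list[str] = []
    pos = 0
    for spec in scenario.clusters:
        if spec.effect == "null":
            effects[pos : pos + spec.count] = 0.0
        elif spec.effect == "junk":
            effects[pos : pos + spec.count] = rng.standard_normal(spec.count)
        else:
            effects[pos : pos + spec.count] = float(spec.effect)
        labels.extend([_true_label(spec)] * spec.count)
        pos += spec.count

    maf = rng.uniform(0.05, 0.5, size=J)
    mu_bx = rng.standard_normal(J)
    v = 1.0 / (scenario.N * maf * (1.0 - maf))
    se = np.sqrt(v)
    beta_x = rng.normal(mu_bx, se)
    beta_y = rng.normal(effects * beta_x, np.sqrt(scenario.tau * v))

    width = len(str(J))
    summaries = [
        VariantSummary(
            variant_id=f"v{j + 1:0{width}d}",
            beta_exposure=float(beta_x[j]),
            se_exposure=float(se[j]),
            beta_outcome=float(beta_y[j]),
            se_outcome=float(se[j]),
        )
        for j in range(J)
    ]
    return SimDataset(summaries=summaries, true_labels=labels, true_effects=effects)


def rand_index(
    labels_a: Sequence,
    labels_b: Sequence,
    exclude: Optional[Sequence[bool]] = None,
) -> float:
    """Rand index: fraction of unordered pairs on which two partitions agree.

    A pair agrees when both partitions put its elements in the same group, or
    both put them in different groups.  ``exclude`` is an optional boolean
    mask of elements to drop before counting (used to drop junk variants from
    the benchmark).  Invariant to relabelling; symmetric; in [0, 1].
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if a.shape != b.shape or a.ndim != 1:
        raise IvmixError("partitions must be 1-D and of equal length")
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        if keep.shape != a.shape:
            raise IvmixError("exclude mask length mismatch")
        a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise IvmixError("need at least 2 (unmasked) elements")

    # pair counting via the contingency table
    cont = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    sum_nij = sum(comb(int(x), 2) for x in cont.ravel())
    sum_ai = sum(comb(int(x), 2) for x in cont.sum(axis=1))
    sum_bj = sum(comb(int(x), 2) for x in cont.sum(axis=0))
    total = comb(n, 2)
    return (total + 2 * sum_nij - sum_ai - sum_bj) / total


def _evaluate_replicate(
    sim: SimDataset,
    n_starts: int,
    k_max: Optional[int],
    seed: int,
    prob_threshold: float = 0.8,
    min_cluster_size: int = 4,
) -> dict:
    """Fit one simulated dataset and score both reporting conventions."""
    data = build_ratio_dataset(sim.summaries, se_order="first")
    scan = scan_cluster_number(data, k_max=k_max, n_starts=n_starts, seed=seed)
    fit = scan.best_fit

    assign_a = assign_version_a(fit.responsibilities, data.variant_ids)
    assign_b = assign_version_b(
        fit.responsibilities,
        data.variant_ids,
        prob_threshold=prob_threshold,
        min_cluster_size=min_cluster_size,
    )
    true = np.asarray(sim.true_labels, dtype=object)
    est_a = np.asarray([a.label for a in assign_a], dtype=object)
    est_b = np.asarray([a.label for a in assign_b], dtype=object)

    true_junk = true == "junk"
    rand_a = rand_index(true, est_a, exclude=true_junk)
    excl_b = true_junk | (est_b == "unassigned")
    rand_b = rand_index(true, est_b, exclude=excl_b) if (~excl_b).sum() >= 2 else np.nan

    # version-A cluster sizes and the fitted means ranked by size (desc);
    # ties break toward the smaller cluster index (ascending mean)
    counts_a = np.array(
        [sum(1 for a in assign_a if a.label == k) for k in range(1, fit.K + 1)]
    )
    order = np.argsort(-counts_a, kind="stable") if fit.K else np.array([], dtype=int)
    means_by_size = fit.params.cluster_means[order]

    reported_b = sorted({a.label for a in assign_b if isinstance(a.label, int)})
    means_b = np.sort([fit.params.cluster_means[k - 1] for k in reported_b])
    n_substantive_b = len(reported_b)
    return {
        "best_k": scan.best_k,
        "rand_a": rand_a,
        "rand_b": rand_b,
        "n_clusters_a": scan.best_k + 1,  # substantive + 1 for the null cluster
        "n_substantive_b": n_substantive_b,
        "n_clusters_b": n_substantive_b + 1,
        "mean_rank1_a": means_by_size[0] if fit.K >= 1 else np.nan,
        "mean_rank2_a": means_by_size[1] if fit.K >= 2 else np.nan,
        "mean_rank3_a": means_by_size[2] if fit.K >= 3 else np.nan,
        # version-B reported cluster means, ascending, NaN-padded
        "mean_b_1": means_b[0] if n_substantive_b >= 1 else np.nan,
        "mean_b_2": means_b[1] if n_substantive_b >= 2 else np.nan,
        "mean_b_3": means_b[2] if n_substantive_b >= 3 else np.nan,
    }


def run_simulation_study(
    scenario_ids: Sequence[int],
    N: int,
    n_reps: int,
    seed: Optional[int] = None,
    n_starts: int = 25,
    k_max: Optional[int] = 5,
    prob_threshold: float = 0.8,
    min_cluster_size: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the benchmark: simulate, fit, score, summarize.

    Per replicate the full pipeline runs (ratio estimates with first-order
    SEs, BIC scan, assignment under versions A and B) and records the Rand
    index against the truth (junk variants excluded; under version B
    unassigned variants are excluded too), the number of reported clusters
    (substantive + 1 for the null) and the fitted means ranked by version-A
    cluster size.

    Returns
    -------
    summary : DataFrame
        Per scenario: medians and first/ninth deciles of the Rand indices and
        cluster counts, plus the share of replicates reporting at least one
        substantive cluster under version B.
    per_rep : DataFrame
        One row per replicate, including its sub-seed.
    """
    if n_reps < 1:
        raise IvmixError("n_reps must be >= 1")
    rows = []
    master = np.random.SeedSequence(seed)
    for sid in scenario_ids:
        scenario = scenario_preset(sid, N)
        for rep, child in enumerate(master.spawn(n_reps)):
            rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            rng = np.random.default_rng(child)
            sim = simulate_summary_data(scenario, rng)
            rec = _evaluate_replicate(
                sim,
                n_starts=n_starts,
                k_max=k_max,
                seed=rep_seed,
                prob_threshold=prob_threshold,
                min_cluster_size=min_cluster_size,
            )
            rec.update({"scenario": sid, "rep": rep, "seed": rep_seed})
            rows.append(rec)
    per_rep = pd.DataFrame(rows)

    summary_rows = []
    for sid in scenario_ids:
        g = per_rep[per_rep["scenario"] == sid]
        out: dict = {"scenario": sid}
        for col in ("rand_a", "rand_b", "n_clusters_a", "n_clusters_b"):
            out[f"{col}_median"] = g[col].median()
            out[f"{col}_d1"] = g[col].quantile(0.1)
            out[f"{col}_d9"] = g[col].quantile(0.9)
        out["frac_any_substantive_b"] = float((g["n_substantive_b"] >= 1).mean())
        out["n_reps"] = len(g)
        summary_rows.append(out)
    return pd.DataFrame(summary_rows), per_rep
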