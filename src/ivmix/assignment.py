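"""Cluster assignment rules and per-cluster summaries.

Two reporting conventions:

* version A assigns every variant to the component with the greatest
  responsibility;
* version B additionally requires that maximum to reach a probability
  threshold (default 0.8) and dissolves substantive clusters with fewer than
  ``min_cluster_size`` (default 4) confidently assigned variants, leaving
  their members unassigned.  Version B discourages reporting clusters
  evidenced by only a handful of variants.

Labels are ``"null"``, ``"junk"``, ``"unassigned"`` or an integer 1..K
(ascending cluster mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import IvmixError
from .mixture import EMFit
from .ratio import RatioDataset

Label = Union[int, str]


@dataclass(frozen=True)
class ClusterAssignment:
    """One variant's reported cluster and the responsibility backing it."""

    variant_id: str
    label: Label
    probability: float


@dataclass(frozen=True)
class ClusterSummary:
    """Reported size and (for substantive clusters) mean and SE of a cluster."""

    label: Label
    n_assigned: int
    mean: Optional[float]
    mean_se: Optional[float]


def _labels_from_columns(cols: np.ndarray, K: int) -> list[Label]:
    out: list[Label] = []
    for c in cols:
        if c == 0:
            out.append("null")
        elif c == K + 1:
            out.append("junk")
        else:
            out.append(int(c))
    return out


def _check(resp: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    resp = np.asarray(resp, dtype=float)
    if resp.ndim != 2 or resp.shape[1] < 2:
        raise IvmixError("responsibility matrix must be J x (K+2)")
    if resp.shape[0] != len(ids):
        raise IvmixError("ids do not match responsibility rows")
    if not np.allclose(resp.sum(axis=1), 1.0, atol=1e-6):
        raise IvmixError("responsibility rows must sum to 1")
    return resp


def assign_version_a(resp: np.ndarray, ids: Sequence[str]) -> list[ClusterAssignment]:
    """Assign each variant to its maximum-responsibility component.

    Ties break toward the lower column index (null first).  Every variant
    receives a label.
    """
    resp = _check(resp, ids)
    K = resp.shape[1] - 2
    cols = resp.argmax(axis=1)
    probs = resp[np.arange(resp.shape[0]), cols]
    labels = _labels_from_columns(cols, K)
    return [
        ClusterAssignment(variant_id=v, label=l, probability=float(p))
        for v, l, p in zip(ids, labels, probs)
    ]


def assign_version_b(
    resp: np.ndarray,
    ids: Sequence[str],
    prob_threshold: float = 0.8,
    min_cluster_size: int = 4,
) -> list[ClusterAssignment]:
    """Threshold-and-dissolve assignment.

    A variant keeps its argmax label only when the maximum responsibility is
    >= ``prob_threshold`` (ties at the threshold assign); substantive clusters
    with fewer than ``min_cluster_size`` assigned variants are then dissolved
    once (no iterative re-checking) and their members become unassigned.  The
    null and junk clusters are never dissolved.
    """
    if not (0 < prob_threshold <= 1):
        raise IvmixError("prob_threshold must be in (0, 1]")
    if min_cluster_size < 1:
        raise IvmixError("min_cluster_size must be >= 1")
    base = assign_version_a(resp, ids)
    assigned = [
        a if a.probability >= prob_threshold
        else ClusterAssignment(a.variant_id, "unassigned", a.probability)
        for a in base
    ]
    counts: dict[Label, int] = {}
    for a in assigned:
        if isinstance(a.label, int):
            counts[a.label] = counts.get(a.label, 0) + 1
    dissolved = {k for k, n in counts.items() if n < min_cluster_size}
    return [
        ClusterAssignment(a.variant_id, "unassigned", a.probability)
        if isinstance(a.label, int) and a.label in dissolved
        else a
        for a in assigned
    ]


def summarize_clusters(
    fit: EMFit,
    assignments: Sequence[ClusterAssignment],
    data: RatioDataset,
) -> list[ClusterSummary]:
    """Per-cluster counts, means and SEs.

    Substantive means come from the fitted parameters; their SE is the
    responsibility-weighted IVW standard error sqrt(1 / sum_j r_jk / sigma_j^2),
    mirroring the M-step estimator (a package convention — only the means are
    part of the model).  Counts cover null, each substantive cluster, junk
    and (when present) unassigned, and sum to J.
    """
    if len(assignments) != data.J:
        raise IvmixError("assignments do not match the dataset")
    K = fit.K
    counts: dict[Label, int] = {"null": 0, "junk": 0, "unassigned": 0}
    for k in range(1, K + 1):
        counts[k] = 0
    for a in assignments:
        if a.label not in counts:
            raise IvmixError(f"assignment label {a.label!r} not in fit")
        counts[a.label] += 1

    w = data.sigma_hat**-2
    out: list[ClusterSummary] = [
        ClusterSummary("null", counts["null"], mean=0.0, mean_se=None)
    ]
    for k in range(1, K + 1):
        info = float(np.sum(fit.responsibilities[:, k] * w))
        out.append(
            ClusterSummary(
                k,
                counts[k],
                mean=float(fit.params.cluster_means[k - 1]),
                mean_se=float(info**-0.5) if info > 0 else None,
            )
        )
    out.append(ClusterSummary("junk", counts["junk"], mean=None, mean_se=None))
    if counts["unassigned"]:
        out.append(ClusterSummary("unassigned", counts["unassigned"], None, None))
    return out
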