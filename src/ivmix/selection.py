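"""BIC scoring and selection of the number of substantive clusters.

A model with K substantive clusters has 2K + 1 free parameters (K means and
K + 2 proportions constrained to sum to one), so

    BIC(K) = (2K + 1) log J - 2 log-likelihood,

and the selected K* minimizes BIC.  Scanning starts at K = 0 and stops early
once the BIC has increased for ``patience`` consecutive K values, or at
``k_max``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import IvmixError
from .mixture import (
    DEFAULT_DELTA,
    DEFAULT_MAX_ITER,
    DEFAULT_N_STARTS,
    DEFAULT_NU,
    EMFit,
    fit_em_multistart,
)
from .ratio import RatioDataset

logger = logging.getLogger(__name__)

DEFAULT_PATIENCE = 2
DEFAULT_K_MAX = 10


@dataclass
class ModelScanResult:
    """Fits and BIC scores over a contiguous range of K starting at 0."""

    fits: dict[int, EMFit]
    bics: dict[int, float]
    best_k: int
    failures: dict[int, str]

    @property
    def best_fit(self) -> EMFit:
        return self.fits[self.best_k]


def bic(fit: EMFit, J: int) -> float:
    """(2K + 1) log J - 2 log-likelihood."""
    if J < 1:
        raise IvmixError("J must be >= 1")
    if not math.isfinite(fit.log_likelihood):
        raise IvmixError("fit log-likelihood is not finite")
    return (2 * fit.K + 1) * math.log(J) - 2.0 * fit.log_likelihood


def scan_cluster_number(
    data: RatioDataset,
    k_max: Optional[int] = None,
    patience: int = DEFAULT_PATIENCE,
    n_starts: int = DEFAULT_N_STARTS,
    delta: float = DEFAULT_DELTA,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: Optional[int] = None,
    nu: float = DEFAULT_NU,
) -> ModelScanResult:
    """Fit K = 0, 1, 2, ... and pick the BIC-minimizing number of clusters.

    Each K gets its own multi-start EM fit seeded from an independent
    sub-stream of ``seed``.  The scan stops once BIC has risen for
    ``patience`` consecutive K values (evidence it is increasing
    monotonically) or K reaches ``k_max`` (default min(J, 10)).  Per-K fit
    failures are recorded and skipped; at least one K must succeed.
    """
    if k_max is None:
        k_max = min(data.J, DEFAULT_K_MAX)
    if k_max < 0 or k_max > data.J:
        raise IvmixError(f"k_max must be in [0, J={data.J}], got {k_max}")
    if patience < 1:
        raise IvmixError("patience must be >= 1")

    # one sub-seed per K, drawn ahead so results do not depend on early stop
    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(k_max + 1)]

    fits: dict[int, EMFit] = {}
    bics: dict[int, float] = {}
    failures: dict[int, str] = {}
    n_increases = 0
    prev_bic = math.inf

    for K in range(k_max + 1):
        try:
            fit = fit_em_multistart(
                data,
                K,
                n_starts=n_starts,
                delta=delta,
                max_iter=max_iter,
                seed=sub_seeds[K],
                nu=nu,
            )
        except IvmixError as exc:
            failures[K] = str(exc)
            logger.warning("EM fit failed for K=%d: %s", K, exc)
            continue
        fits[K] = fit
        bics[K] = bic(fit, data.J)
        logger.info("K=%d: log-likelihood %.4f, BIC %.4f", K, fit.log_likelihood, bics[K])

        if bics[K] > prev_bic:
            n_increases += 1
            if n_increases >= patience:
                break
        else:
            n_increases = 0
        prev_bic = bics[K]

    if not bics:
        raise IvmixError("every K in the scan failed to fit")
    best_k = min(bics, key=lambda k: (bics[k], k))
    logger.info("selected K*=%d (BIC %.4f)", best_k, bics[best_k])
    return ModelScanResult(fits=fits, bics=bics, best_k=best_k, failures=failures)
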