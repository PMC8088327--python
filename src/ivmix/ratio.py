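"""Per-variant ratio (Wald) estimates and delta-method standard errors.

For a variant with exposure association beta_X and outcome association beta_Y,
the ratio estimate of the causal effect is theta = beta_Y / beta_X.  Its
standard error is obtained by the delta method, either to first order,

    se(theta) = se(beta_Y) / |beta_X|,

or to second order, which also propagates the uncertainty in beta_X and an
optional correlation rho between the two association estimates (rho = 0 in a
two-sample design, where exposure and outcome associations come from
non-overlapping samples).  Standard errors are treated as known constants
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import DegenerateInstrumentError, EmptyDatasetError, IvmixError
from .summary_data import VariantSummary

SEOrder = Literal["first", "second"]


@dataclass
class RatioDataset:
    """Vectors of ratio estimates and standard errors for J variants.

    Attributes
    ----------
    variant_ids : list of str
    theta_hat : ndarray, shape (J,)
        Ratio estimates beta_Y / beta_X.
    sigma_hat : ndarray, shape (J,)
        Delta-method standard errors, strictly positive.
    se_order : {"first", "second"}
    rho : float
        Correlation between the exposure and outcome association estimates
        used for second-order SEs.
    excluded : list of str
        Ids of variants dropped because beta_exposure was exactly zero.
    """

    variant_ids: list[str]
    theta_hat: np.ndarray
    sigma_hat: np.ndarray
    se_order: SEOrder = "first"
    rho: float = 0.0
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta_hat = np.asarray(self.theta_hat, dtype=float)
        self.sigma_hat = np.asarray(self.sigma_hat, dtype=float)
        J = len(self.variant_ids)
        if J < 1:
            raise EmptyDatasetError("RatioDataset needs at least one variant")
        if self.theta_hat.shape != (J,) or self.sigma_hat.shape != (J,):
            raise IvmixError("variant_ids, theta_hat and sigma_hat lengths differ")
        if not np.all(np.isfinite(self.theta_hat)):
            raise IvmixError("theta_hat contains non-finite values")
        if not (np.all(self.sigma_hat > 0) and np.all(np.isfinite(self.sigma_hat))):
            raise IvmixError("sigma_hat must be strictly positive and finite")

    @property
    def J(self) -> int:
        return len(self.variant_ids)


def ratio_estimate(beta_outcome: float, beta_exposure: float) -> float:
    """Ratio (Wald) estimate beta_outcome / beta_exposure."""
    if beta_exposure == 0:
        raise DegenerateInstrumentError(
            "beta_exposure is zero: ratio estimate undefined"
        )
    return beta_outcome / beta_exposure


def ratio_se_first_order(se_outcome: float, beta_exposure: float) -> float:
    """First-order delta-method SE: se(beta_Y) / |beta_X|."""
    if beta_exposure == 0:
        raise DegenerateInstrumentError("beta_exposure is zero: SE undefined")
    if se_outcome <= 0:
        raise IvmixError(f"se_outcome must be > 0, got {se_outcome}")
    return se_outcome / abs(beta_exposure)


def ratio_se_second_order(
    beta_exposure: float,
    beta_outcome: float,
    se_exposure: float,
    se_outcome: float,
    rho: float = 0.0,
) -> float:
    """Second-order delta-method SE of the ratio estimate.

    sqrt( se_Y^2/b_X^2 + b_Y^2 se_X^2/b_X^4 - 2 rho b_Y se_Y se_X/b_X^3 )

    With se_exposure = 0 this reduces to the first-order SE.  rho is the
    correlation between the two association estimates (zero when they come
    from non-overlapping samples).
    """
    if beta_exposure == 0:
        raise DegenerateInstrumentError("beta_exposure is zero: SE undefined")
    if se_outcome <= 0 or se_exposure < 0:
        raise IvmixError("standard errors must be positive (se_exposure may be 0)")
    if not -1.0 <= rho <= 1.0:
        raise IvmixError(f"rho must be in [-1, 1], got {rho}")
    bx2 = beta_exposure * beta_exposure
    var = (
        se_outcome**2 / bx2
        + beta_outcome**2 * se_exposure**2 / (bx2 * bx2)
        - 2.0 * rho * beta_outcome * se_outcome * se_exposure / beta_exposure**3
    )
    if var <= 0:
        raise IvmixError(
            "second-order variance is non-positive for these inputs; "
            "check the rho specification"
        )
    return math.sqrt(var)


def build_ratio_dataset(
    variants: Sequence[VariantSummary],
    se_order: SEOrder = "first",
    rho: float = 0.0,
) -> RatioDataset:
    """Apply the ratio and SE formulas variant-wise.

    Variants with beta_exposure exactly zero are excluded and listed on the
    returned dataset's ``excluded`` attribute.
    """
    if len(variants) == 0:
        raise EmptyDatasetError("no variants supplied")
    if se_order not in ("first", "second"):
        raise IvmixError(f"se_order must be 'first' or 'second', got {se_order!r}")

    ids: list[str] = []
    thetas: list[float] = []
    sigmas: list[float] = []
    excluded: list[str] = []
    for v in variants:
        if v.beta_exposure == 0:
            excluded.append(v.variant_id)
            continue
        ids.append(v.variant_id)
        thetas.append(ratio_estimate(v.beta_outcome, v.beta_exposure))
        if se_order == "first":
            sigmas.append(ratio_se_first_order(v.se_outcome, v.beta_exposure))
        else:
            sigmas.append(
                ratio_se_second_order(
                    v.beta_exposure, v.beta_outcome, v.se_exposure, v.se_outcome, rho
                )
            )
    if not ids:
        raise EmptyDatasetError(
            "all variants had beta_exposure == 0; nothing to analyse"
        )
    return RatioDataset(
        variant_ids=ids,
        theta_hat=np.array(thetas),
        sigma_hat=np.array(sigmas),
        se_order=se_order,
        rho=rho,
        excluded=excluded,
    )
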