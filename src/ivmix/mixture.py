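"""Mixture likelihood and EM engine for clustering ratio estimates.

The model has K + 2 components for J observed ratio estimates theta_hat_j
with known standard errors sigma_hat_j:

* a null component: normal with mean fixed at 0 and SD sigma_hat_j,
* K substantive components: normal with free mean theta_k and SD sigma_hat_j,
* a junk component: location-scale Student-t with nu = 4 degrees of freedom,
  location mu = mean(theta_hat) and scale
  psi = |max(theta_hat) - min(theta_hat)| + 2 max(sigma_hat),
  shared across observations and held fixed during estimation.

Each observation keeps its own variance, so precise estimates dominate the
cluster means: the M-step update for theta_k is a responsibility-weighted
inverse-variance weighted (IVW) average.  Mixture proportions pi_0..pi_{K+1}
update to mean responsibilities.  Estimation runs EM from multiple random
initializations (k-means centres plus random null/junk proportions) and keeps
the start with the highest log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import gammaln, logsumexp
from sklearn.cluster import KMeans

from .exceptions import EmptyClusterError, IvmixError, UnderflowError
from .ratio import RatioDataset

_LOG_2PI = math.log(2.0 * math.pi)

#: a substantive cluster is "empty" when its total responsibility drops below this
EMPTY_CLUSTER_TOL = 1e-3

#: default EM configuration
DEFAULT_DELTA = 1e-5
DEFAULT_MAX_ITER = 500
DEFAULT_N_STARTS = 25
DEFAULT_NU = 4.0


@dataclass(frozen=True)
class JunkComponent:
    """Heavy-tailed outlier component: location-scale Student-t.

    mu is the sample mean of all ratio estimates, psi the data range plus
    twice the largest SE, nu the degrees of freedom (4 unless overridden).
    """

    mu: float
    psi: float
    nu: float = DEFAULT_NU

    def __post_init__(self) -> None:
        if not (self.psi > 0):
            raise IvmixError(f"junk scale psi must be > 0, got {self.psi}")
        if not (self.nu > 0):
            raise IvmixError(f"junk df nu must be > 0, got {self.nu}")

    def log_density(self, x) -> np.ndarray:
        """Log density of the location-scale t: (1/psi) t_nu((x - mu)/psi)."""
        z = (np.asarray(x, dtype=float) - self.mu) / self.psi
        return (
            gammaln((self.nu + 1.0) / 2.0)
            - gammaln(self.nu / 2.0)
            - 0.5 * math.log(self.nu * math.pi)
            - math.log(self.psi)
            - 0.5 * (self.nu + 1.0) * np.log1p(z * z / self.nu)
        )


@dataclass
class MixtureParams:
    """Mixture parameters: K substantive means plus K+2 proportions.

    ``proportions`` is ordered (null, cluster 1..K, junk); the null mean is
    implicitly 0 and the junk component is ``junk``.  Canonical fits keep
    ``cluster_means`` sorted ascending.
    """

    cluster_means: np.ndarray
    proportions: np.ndarray
    junk: JunkComponent

    def __post_init__(self) -> None:
        self.cluster_means = np.atleast_1d(np.asarray(self.cluster_means, dtype=float))
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.cluster_means.size == 0:
            self.cluster_means = np.empty(0, dtype=float)
        K = self.cluster_means.size
        if self.proportions.shape != (K + 2,):
            raise IvmixError(
                f"expected {K + 2} proportions for K={K}, got {self.proportions.shape}"
            )
        if np.any(self.proportions < -1e-12):
            raise IvmixError("proportions must be non-negative")
        if abs(self.proportions.sum() - 1.0) > 1e-8:
            raise IvmixError(
                f"proportions must sum to 1, got {self.proportions.sum()!r}"
            )

    @property
    def K(self) -> int:
        return self.cluster_means.size

    def sorted_canonical(self) -> tuple["MixtureParams", np.ndarray]:
        """Return params with means sorted ascending plus the column permutation.

        The permutation maps old responsibility-matrix columns to new ones:
        ``resp[:, perm]`` reorders a (J, K+2) matrix to match.
        """
        K = self.K
        order = np.argsort(self.cluster_means, kind="stable")
        perm = np.concatenate(([0], order + 1, [K + 1])).astype(int)
        params = MixtureParams(
            cluster_means=self.cluster_means[order],
            proportions=self.proportions[perm],
            junk=self.junk,
        )
        return params, perm


@dataclass
class EMFit:
    """Result of one EM estimation (best start, canonical ordering)."""

    params: MixtureParams
    responsibilities: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_starts: int = 1
    seed: Optional[int] = None
    empty_clusters: tuple[int, ...] = ()
    #: log-likelihood at the initialization and after each EM iteration
    log_likelihood_history: tuple[float, ...] = ()

    @property
    def K(self) -> int:
        return self.params.K


def junk_component_params(
    theta_hat: np.ndarray, sigma_hat: np.ndarray, nu: float = DEFAULT_NU
) -> JunkComponent:
    """Fix the junk component from the data.

    mu = mean(theta_hat); psi = |max - min| of theta_hat + 2 max(sigma_hat).
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    if theta_hat.size == 0:
        raise IvmixError("cannot build junk component from empty data")
    if np.any(sigma_hat <= 0):
        raise IvmixError("sigma_hat must be strictly positive")
    mu = float(theta_hat.mean())
    psi = float(abs(theta_hat.max() - theta_hat.min()) + 2.0 * sigma_hat.max())
    return JunkComponent(mu=mu, psi=psi, nu=nu)


def _normal_logpdf(x, mean, sigma):
    z = (np.asarray(x, dtype=float) - mean) / sigma
    return -0.5 * (_LOG_2PI + z * z) - np.log(sigma)


def component_log_density(
    x: float,
    component: Union[str, float],
    sigma_j: Optional[float] = None,
    junk: Optional[JunkComponent] = None,
) -> float:
    """Log density of one observation under one mixture component.

    ``component`` is ``"null"`` (normal, mean 0), a float mean theta_k
    (normal), or ``"junk"`` (location-scale Student-t given by ``junk``).
    Normal components use the observation's own SD ``sigma_j``.
    """
    if not np.isfinite(x):
        raise IvmixError(f"x must be finite, got {x}")
    if isinstance(component, str) and component == "junk":
        if junk is None:
            raise IvmixError("junk component parameters required")
        return float(junk.log_density(x))
    mean = 0.0 if (isinstance(component, str) and component == "null") else float(component)
    if sigma_j is None or sigma_j <= 0:
        raise IvmixError("normal components need sigma_j > 0")
    return float(_normal_logpdf(x, mean, sigma_j))


def _log_density_matrix(data: RatioDataset, params: MixtureParams) -> np.ndarray:
    """J x (K+2) matrix of component log densities, columns (null, 1..K, junk)."""
    theta = data.theta_hat[:, None]
    sigma = data.sigma_hat[:, None]
    means = np.concatenate(([0.0], params.cluster_means))[None, :]
    log_norm = _normal_logpdf(theta, means, sigma)
    log_junk = params.junk.log_density(data.theta_hat)[:, None]
    return np.concatenate([log_norm, log_junk], axis=1)


def _log_weighted(data: RatioDataset, params: MixtureParams) -> np.ndarray:
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.clip(params.proportions, 0.0, None))
    return _log_density_matrix(data, params) + log_pi[None, :]


def mixture_log_likelihood(data: RatioDataset, params: MixtureParams) -> float:
    """Observed-data log-likelihood, accumulated with per-row log-sum-exp."""
    lw = _log_weighted(data, params)
    row = logsumexp(lw, axis=1)
    if not np.all(np.isfinite(row)):
        raise UnderflowError("log-likelihood is non-finite for some observation")
    return float(row.sum())


def initialize_parameters(
    data: RatioDataset,
    K: int,
    rng: np.random.Generator,
    nu: float = DEFAULT_NU,
    junk: Optional[JunkComponent] = None,
) -> MixtureParams:
    """Random initialization for one EM start.

    For K > 0 the cluster means are the centroids of a k-means run on the
    ratio estimates (uncertainty-blind).  The null and junk proportions are
    drawn independently uniform on (0.05, 0.4) — so together they cover at
    least 10% and at most 80% of prior mass — and the substantive proportions
    are the k-means occupancy fractions scaled by the remainder.  For K = 0
    the two draws are renormalized to sum to one.
    """
    if K < 0:
        raise IvmixError("K must be >= 0")
    if K > data.J:
        raise IvmixError(f"K={K} exceeds the number of variants J={data.J}")
    if junk is None:
        junk = junk_component_params(data.theta_hat, data.sigma_hat, nu=nu)

    pi_null, pi_junk = rng.uniform(0.05, 0.4, size=2)
    if K == 0:
        total = pi_null + pi_junk
        proportions = np.array([pi_null / total, pi_junk / total])
        return MixtureParams(
            cluster_means=np.empty(0), proportions=proportions, junk=junk
        )

    km_seed = int(rng.integers(0, 2**31 - 1))
    km = KMeans(n_clusters=K, n_init=1, random_state=km_seed)
    labels = km.fit_predict(data.theta_hat[:, None])
    centres = km.cluster_centers_.ravel()
    occupancy = np.bincount(labels, minlength=K) / data.J

    order = np.argsort(centres, kind="stable")
    centres = centres[order]
    occupancy = occupancy[order]

    remainder = 1.0 - pi_null - pi_junk
    proportions = np.concatenate(([pi_null], occupancy * remainder, [pi_junk]))
    proportions /= proportions.sum()
    return MixtureParams(cluster_means=centres, proportions=proportions, junk=junk)


def e_step(data: RatioDataset, params: MixtureParams) -> np.ndarray:
    """Responsibilities r_jk: posterior component membership per observation.

    Computed in log space with per-row log-sum-exp; rows sum to one.
    """
    lw = _log_weighted(data, params)
    norm = logsumexp(lw, axis=1)
    if not np.all(np.isfinite(norm)):
        bad = np.flatnonzero(~np.isfinite(norm))
        raise UnderflowError(
            f"all component densities underflowed for observation(s) {bad.tolist()}"
        )
    return np.exp(lw - norm[:, None])


def m_step(
    data: RatioDataset,
    resp: np.ndarray,
    junk: JunkComponent,
    prev_means: Optional[np.ndarray] = None,
) -> tuple[MixtureParams, tuple[int, ...]]:
    """Update cluster means and proportions from responsibilities.

    theta_k becomes the responsibility-weighted IVW average of the ratio
    estimates; pi_k becomes the mean responsibility of component k.  The junk
    parameters stay fixed.  A substantive cluster whose total responsibility
    falls below ``EMPTY_CLUSTER_TOL`` keeps its previous mean (``prev_means``
    required) and is reported in the returned tuple of empty cluster indices
    (1-based, matching column order).
    """
    resp = np.asarray(resp, dtype=float)
    J, ncomp = resp.shape
    if J != data.J:
        raise IvmixError("responsibility rows do not match the dataset")
    K = ncomp - 2
    if not np.allclose(resp.sum(axis=1), 1.0, atol=1e-8):
        raise IvmixError("responsibility rows must sum to 1")

    proportions = resp.sum(axis=0) / J
    w = data.sigma_hat**-2
    means = np.empty(K)
    empty: list[int] = []
    for k in range(K):
        r = resp[:, k + 1]
        if r.sum() < EMPTY_CLUSTER_TOL:
            empty.append(k + 1)
            if prev_means is None:
                raise EmptyClusterError(
                    f"substantive cluster {k + 1} has ~zero total responsibility"
                )
            means[k] = prev_means[k]
        else:
            means[k] = float(np.sum(r * w * data.theta_hat) / np.sum(r * w))
    params = MixtureParams(cluster_means=means, proportions=proportions, junk=junk)
    return params, tuple(empty)


def fit_em_single_start(
    data: RatioDataset,
    K: int,
    init: MixtureParams,
    delta: float = DEFAULT_DELTA,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EMFit:
    """Run EM from one initialization until the log-likelihood increment < delta.

    The log-likelihood sequence is non-decreasing (up to numerical slack);
    on return the cluster means are sorted ascending and the responsibility
    columns permuted to match.
    """
    if init.K != K:
        raise IvmixError(f"init has K={init.K}, expected {K}")
    if max_iter < 1:
        raise IvmixError("max_iter must be >= 1")

    theta = data.theta_hat
    sigma = data.sigma_hat
    w = sigma**-2
    J = data.J
    junk = init.junk
    # constant across iterations: junk column and normal normalization
    junk_col = junk.log_density(theta)
    norm_const = -0.5 * _LOG_2PI - np.log(sigma)

    def _eval(means: np.ndarray, props: np.ndarray):
        """lw -> (log-likelihood, responsibilities) in one fused pass."""
        with np.errstate(divide="ignore"):
            log_pi = np.log(np.clip(props, 0.0, None))
        mall = np.concatenate(([0.0], means))
        z = (theta[:, None] - mall[None, :]) / sigma[:, None]
        lw = np.empty((J, K + 2))
        lw[:, : K + 1] = norm_const[:, None] - 0.5 * z * z + log_pi[None, : K + 1]
        lw[:, K + 1] = junk_col + log_pi[K + 1]
        m = lw.max(axis=1)
        if not np.all(np.isfinite(m)):
            raise UnderflowError("all component densities underflowed during EM")
        resp = np.exp(lw - m[:, None])
        rowsum = resp.sum(axis=1)
        resp /= rowsum[:, None]
        ll = float((m + np.log(rowsum)).sum())
        return ll, resp

    means = init.cluster_means.copy()
    props = init.proportions.copy()
    ll_prev, resp = _eval(means, props)
    history = [ll_prev]
    converged = False
    n_iter = 0
    empty_seen: set[int] = set()

    for n_iter in range(1, max_iter + 1):
        # M-step: proportions to mean responsibilities, means to weighted IVW
        props = resp.sum(axis=0) / J
        rsub = resp[:, 1 : K + 1]
        rw = rsub * w[:, None]
        denom = rw.sum(axis=0)
        num = rw.T @ theta
        rtot = rsub.sum(axis=0)
        for k in np.flatnonzero(rtot < EMPTY_CLUSTER_TOL):
            empty_seen.add(int(k) + 1)
            num[k] = means[k]
            denom[k] = 1.0
        if K:
            means = num / denom
        ll, resp = _eval(means, props)
        if not np.isfinite(ll):
            raise UnderflowError("non-finite log-likelihood during EM")
        history.append(ll)
        if ll - ll_prev < delta:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    params = MixtureParams(cluster_means=means, proportions=props, junk=junk)
    params, perm = params.sorted_canonical()
    resp = resp[:, perm]
    # empty-cluster indices follow the same mean ordering
    inv = {old: new for new, old in enumerate(perm)}
    empty_sorted = tuple(sorted(inv[i] for i in empty_seen))
    return EMFit(
        params=params,
        responsibilities=resp,
        log_likelihood=ll_prev,
        n_iterations=n_iter,
        converged=converged,
        empty_clusters=empty_sorted,
        log_likelihood_history=tuple(history),
    )


def fit_em_multistart(
    data: RatioDataset,
    K: int,
    n_starts: int = DEFAULT_N_STARTS,
    delta: float = DEFAULT_DELTA,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: Optional[int] = None,
    nu: float = DEFAULT_NU,
) -> EMFit:
    """Best-of-``n_starts`` EM fit; fully reproducible given ``seed``.

    Each start draws an independent initialization from a sub-stream of the
    master seed; the fit with the largest final log-likelihood wins.
    """
    if n_starts < 1:
        raise IvmixError("n_starts must be >= 1")
    junk = junk_component_params(data.theta_hat, data.sigma_hat, nu=nu)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_starts)

    best: Optional[EMFit] = None
    failures: list[str] = []
    for child in children:
        rng = np.random.default_rng(child)
        try:
            init = initialize_parameters(data, K, rng, nu=nu, junk=junk)
            fit = fit_em_single_start(data, K, init, delta=delta, max_iter=max_iter)
        except IvmixError as exc:  # keep going; other starts may succeed
            failures.append(str(exc))
            continue
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        raise IvmixError(
            f"all {n_starts} EM starts failed for K={K}: {failures[:3]}"
        )
    return replace(best, n_starts=n_starts, seed=seed)
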