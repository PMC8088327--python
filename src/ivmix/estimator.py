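"""scikit-learn style front end for the whole pipeline.

:class:`RatioMixture` clusters Mendelian-randomization ratio estimates.  The
input ``X`` is a (J, 2) array whose first column holds the ratio estimates
and second column their standard errors; ``fit`` selects the number of
substantive clusters by BIC, and ``labels_`` reports the assignment under the
chosen convention.  Integer label codes: 0 = null cluster, 1..K = substantive
clusters in ascending order of mean, K + 1 = junk cluster, -1 = unassigned
(version B only).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .assignment import assign_version_a, assign_version_b, summarize_clusters
from .exceptions import IvmixError
from .mixture import (
    DEFAULT_DELTA,
    DEFAULT_MAX_ITER,
    DEFAULT_N_STARTS,
    DEFAULT_NU,
    e_step,
)
from .ratio import RatioDataset
from .selection import DEFAULT_PATIENCE, scan_cluster_number


def _label_code(label, K: int) -> int:
    if label == "null":
        return 0
    if label == "junk":
        return K + 1
    if label == "unassigned":
        return -1
    return int(label)


class RatioMixture(ClusterMixin, BaseEstimator):
    """Mixture-model clustering of ratio estimates with null and junk clusters.

    Parameters
    ----------
    k_max : int or None
        Largest number of substantive clusters scanned (None: min(J, 10)).
    patience : int
        Consecutive BIC increases that stop the scan early.
    n_starts : int
        Independent EM initializations per K; the best log-likelihood wins.
    delta : float
        EM stops when the log-likelihood increment falls below this.
    max_iter : int
        Iteration cap per EM start.
    nu : float
        Degrees of freedom of the heavy-tailed junk component.
    assignment : {"a", "b"}
        Reporting convention for ``labels_``: "a" assigns every variant to its
        maximum-responsibility component; "b" additionally requires that
        probability to reach ``prob_threshold`` and dissolves substantive
        clusters with fewer than ``min_cluster_size`` members.
    prob_threshold : float
        Minimum responsibility for a version-B assignment.
    min_cluster_size : int
        Smallest substantive cluster version B will report.
    random_state : int or None
        Master seed; fits are bit-reproducible given the same seed.

    Attributes
    ----------
    best_k_ : int
        Selected number of substantive clusters.
    cluster_means_ : ndarray, shape (best_k_,)
        Substantive cluster means, ascending.
    proportions_ : ndarray, shape (best_k_ + 2,)
        Mixture proportions (null, clusters, junk).
    responsibilities_ : ndarray, shape (J, best_k_ + 2)
    labels_ : ndarray of int, shape (J,)
    log_likelihood_ : float
    bic_ : dict mapping scanned K to BIC
    scan_ : ModelScanResult
    junk_ : JunkComponent

    Examples
    --------
    >>> import numpy as np
    >>> from ivmix import RatioMixture
    >>> theta = np.r_[np.full(20, -0.5), np.full(20, 0.5)]
    >>> X = np.c_[theta, np.full(40, 0.05)]
    >>> model = RatioMixture(random_state=0).fit(X)
    >>> model.best_k_
    2
    """

    def __init__(
        self,
        k_max: Optional[int] = None,
        patience: int = DEFAULT_PATIENCE,
        n_starts: int = DEFAULT_N_STARTS,
        delta: float = DEFAULT_DELTA,
        max_iter: int = DEFAULT_MAX_ITER,
        nu: float = DEFAULT_NU,
        assignment: str = "b",
        prob_threshold: float = 0.8,
        min_cluster_size: int = 4,
        random_state: Optional[int] = None,
    ):
        self.k_max = k_max
        self.patience = patience
        self.n_starts = n_starts
        self.delta = delta
        self.max_iter = max_iter
        self.nu = nu
        self.assignment = assignment
        self.prob_threshold = prob_threshold
        self.min_cluster_size = min_cluster_size
        self.random_state = random_state

    def _validate(self, X) -> RatioDataset:
        X = check_array(X, ensure_min_samples=1, ensure_min_features=2)
        if X.shape[1] != 2:
            raise ValueError(
                f"X must have exactly 2 columns (theta_hat, sigma_hat), "
                f"got {X.shape[1]}"
            )
        if np.any(X[:, 1] <= 0):
            raise ValueError("second column (sigma_hat) must be strictly positive")
        ids = [f"v{i}" for i in range(X.shape[0])]
        return RatioDataset(variant_ids=ids, theta_hat=X[:, 0], sigma_hat=X[:, 1])

    def fit(self, X, y=None):
        """Fit the mixture and select the number of clusters by BIC.

        Parameters
        ----------
        X : array-like, shape (J, 2)
            Columns (ratio estimate, standard error).
        y : ignored
        """
        if self.assignment not in ("a", "b"):
            raise ValueError(f"assignment must be 'a' or 'b', got {self.assignment!r}")
        data = self._validate(X)
        scan = scan_cluster_number(
            data,
            k_max=self.k_max,
            patience=self.patience,
            n_starts=self.n_starts,
            delta=self.delta,
            max_iter=self.max_iter,
            seed=self.random_state,
            nu=self.nu,
        )
        fit = scan.best_fit
        if self.assignment == "a":
            assignments = assign_version_a(fit.responsibilities, data.variant_ids)
        else:
            assignments = assign_version_b(
                fit.responsibilities,
                data.variant_ids,
                prob_threshold=self.prob_threshold,
                min_cluster_size=self.min_cluster_size,
            )
        K = fit.K
        self.scan_ = scan
        self.fit_ = fit
        self.best_k_ = scan.best_k
        self.cluster_means_ = fit.params.cluster_means.copy()
        self.proportions_ = fit.params.proportions.copy()
        self.junk_ = fit.params.junk
        self.responsibilities_ = fit.responsibilities.copy()
        self.log_likelihood_ = fit.log_likelihood
        self.bic_ = dict(scan.bics)
        self.assignments_ = assignments
        self.labels_ = np.array([_label_code(a.label, K) for a in assignments])
        self.cluster_summaries_ = summarize_clusters(fit, assignments, data)
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Responsibilities of the fitted components for new (theta, sigma) rows."""
        check_is_fitted(self, "fit_")
        data = self._validate(X)
        return e_step(data, self.fit_.params)

    def predict(self, X) -> np.ndarray:
        """Maximum-responsibility label codes for new (theta, sigma) rows."""
        resp = self.predict_proba(X)
        K = self.fit_.K
        assignments = assign_version_a(resp, [f"v{i}" for i in range(len(resp))])
        return np.array([_label_code(a.label, K) for a in assignments])

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).labels_
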