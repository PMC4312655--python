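"""Unsupervised instance clustering with GMMs and BIC/AIC order selection.

Instances (proximity features) are clustered with Gaussian mixture models
for k = 1..k_max, each fit restarted from random initializations. Model
order is selected by the minimum of the information criteria

    BIC = -2 ln(L) + k ln(n)        AIC = -2 ln(L) + 2 k

where L is the mixture likelihood, n the number of instances and k the
number of CLUSTERS — a deliberately light penalty counting clusters, not
free parameters. The textbook parameter-count penalty is available via
``penalty="parameters"``. Bag labels follow by majority vote over the
cluster assignments of a bag's instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.mixture import GaussianMixture


@dataclass
class ModelScanResult:
    """BIC/AIC curves over candidate cluster counts."""

    k_values: list[int]
    bic_mean: np.ndarray
    bic_std: np.ndarray
    aic_mean: np.ndarray
    aic_std: np.ndarray
    best_k_bic: int
    best_k_aic: int
    n: int
    penalty: str
    log_likelihoods: dict[int, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "k_values": list(self.k_values),
            "bic_mean": self.bic_mean.tolist(),
            "bic_std": self.bic_std.tolist(),
            "aic_mean": self.aic_mean.tolist(),
            "aic_std": self.aic_std.tolist(),
            "best_k_bic": self.best_k_bic,
            "best_k_aic": self.best_k_aic,
            "n": self.n,
            "penalty": self.penalty,
        }


def _n_free_params(k: int, d: int) -> int:
    """Free parameters of a k-component full-covariance Gaussian mixture."""
    return k - 1 + k * d + k * d * (d + 1) // 2


def bic(log_L: float, k: int, n: int, d: int | None = None, penalty: str = "clusters") -> float:
    """Bayesian information criterion -2 ln(L) + penalty * ln(n).

    With ``penalty="clusters"`` (default) the complexity term is k ln(n),
    counting clusters; ``penalty="parameters"`` uses the free-parameter
    count of a full-covariance mixture and requires the data dimension d.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    if penalty == "clusters":
        m = k
    elif penalty == "parameters":
        if d is None:
            raise ValueError("parameter penalty needs the data dimension d")
        m = _n_free_params(k, d)
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    return float(-2.0 * log_L + m * np.log(n))


def aic(log_L: float, k: int, d: int | None = None, penalty: str = "clusters") -> float:
    """Akaike information criterion -2 ln(L) + 2 * penalty term."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if penalty == "clusters":
        m = k
    elif penalty == "parameters":
        if d is None:
            raise ValueError("parameter penalty needs the data dimension d")
        m = _n_free_params(k, d)
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    return float(-2.0 * log_L + 2.0 * m)


def fit_gmm(
    instances: np.ndarray,
    k: int,
    restarts: int = 10,
    seed: int = 0,
    reg_covar: float = 1e-6,
) -> tuple[GaussianMixture, float]:
    """Best-of-restarts full-covariance GMM fit.

    Returns the fitted mixture with the highest total log-likelihood over
    ``restarts`` random initializations, together with that total
    log-likelihood ln(L). Deterministic given ``seed``.
    """
    X = np.asarray(instances, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] <= k:
        raise ValueError(f"need more than k={k} instances, got {X.shape[0]}")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=restarts,
        init_params="random_from_data",
        reg_covar=reg_covar,
        random_state=seed,
    ).fit(X)
    log_L = float(gm.score(X) * X.shape[0])
    return gm, log_L


def scan_model_order(
    instances: np.ndarray,
    k_range: range | list[int] = range(1, 11),
    restarts: int = 10,
    seed: int = 0,
    penalty: str = "clusters",
    reg_covar: float = 1e-6,
) -> ModelScanResult:
    """Fit GMMs over a range of k; report BIC/AIC curves and their minima.

    Every (k, restart) pair is fit separately so the curves carry a mean
    and standard deviation per k; the best k minimizes the mean criterion
    (ties to the smallest k). Restart seeds derive from ``seed`` only, so
    the scan is invariant to instance order up to EM's own tie structure.
    """
    X = np.asarray(instances, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    k_values = [int(k) for k in k_range]
    if not k_values or max(k_values) >= n:
        raise ValueError("k_range infeasible for the number of instances")

    bic_mean, bic_std, aic_mean, aic_std = [], [], [], []
    log_likelihoods: dict[int, list[float]] = {}
    for ki, k in enumerate(k_values):
        lls = []
        for r in range(restarts):
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=1,
                init_params="random_from_data",
                reg_covar=reg_covar,
                random_state=seed * 1009 + ki * 101 + r,
            ).fit(X)
            lls.append(float(gm.score(X) * n))
        log_likelihoods[k] = lls
        bics = [bic(ll, k, n, d=d, penalty=penalty) for ll in lls]
        aics = [aic(ll, k, d=d, penalty=penalty) for ll in lls]
        bic_mean.append(np.mean(bics))
        bic_std.append(np.std(bics))
        aic_mean.append(np.mean(aics))
        aic_std.append(np.std(aics))

    bic_mean = np.array(bic_mean)
    aic_mean = np.array(aic_mean)
    return ModelScanResult(
        k_values=k_values,
        bic_mean=bic_mean,
        bic_std=np.array(bic_std),
        aic_mean=aic_mean,
        aic_std=np.array(aic_std),
        best_k_bic=k_values[int(np.argmin(bic_mean))],
        best_k_aic=k_values[int(np.argmin(aic_mean))],
        n=n,
        penalty=penalty,
        log_likelihoods=log_likelihoods,
    )


def vote_bag_label(
    assignments: np.ndarray, bag_membership: np.ndarray
) -> dict[Any, int]:
    """Majority cluster per bag; ties break to the lowest cluster index."""
    assignments = np.asarray(assignments)
    bag_membership = np.asarray(bag_membership)
    if assignments.shape != bag_membership.shape:
        raise ValueError("assignments and bag membership must align")
    out: dict[Any, int] = {}
    for bag in np.unique(bag_membership):
        clusters = assignments[bag_membership == bag]
        if clusters.size == 0:
            raise ValueError(f"bag {bag!r} has no instances")
        values, counts = np.unique(clusters, return_counts=True)
        out[bag] = int(values[np.argmax(counts)])  # np.unique sorts ascending
    return out
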