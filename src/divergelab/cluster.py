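"""Phenotype clustering in (G_max, F_max) growth-rate space.

Genotypes are represented as 2-D points: maximum growth rate on galactose
(x) and on fructose (y).  Clusters are fitted with a Gaussian mixture under
the EVV covariance constraint — Equal component Volumes (covariance
determinants), Varying shapes and Varying orientations — the model family
used for ellipsoidal clusters of a shared size.  The number of components
(at most 3: the main strategies are fructose specialist, galactose
specialist and generalist) is selected by BIC.

The EVV M-step has a closed form: with W_k the responsibility-weighted
scatter matrix of component k, the constrained covariance is
``Sigma_k = lambda * W_k / det(W_k)^(1/d)`` with the shared volume
``lambda = (1/n) * sum_k det(W_k)^(1/d)``, so each EM iteration is a true
maximization and the log-likelihood is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

__all__ = [
    "MixtureModel",
    "em_fit",
    "select_model",
    "classify_strategy",
    "link_trajectories",
    "f_ratio",
    "F_THRESHOLD",
    "G_THRESHOLD",
]

# Midpoints of the interval of observed group-average growth rates (1/h),
# used to demarcate strategy quadrants in (G_max, F_max) space.
F_THRESHOLD = 0.703
G_THRESHOLD = 0.545

_RIDGE = 1e-6


@dataclass
class MixtureModel:
    """A fitted k-component EVV Gaussian mixture over 2-D phenotype space."""

    k: int
    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, 2)
    covariances: np.ndarray  # (k, 2, 2)
    loglik: float
    bic: float
    n: int
    converged: bool = True
    ridge_applied: bool = False
    loglik_path: list = field(default_factory=list, repr=False)
    constraint: str = "EVV"

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        """Posterior component probabilities, rows normalized to 1."""
        log_r = _log_component_densities(X, self.weights, self.means, self.covariances)
        log_r -= log_r.max(axis=1, keepdims=True)
        r = np.exp(log_r)
        return r / r.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.responsibilities(X), axis=1)


def _log_component_densities(X, weights, means, covs):
    """Weighted log-densities, (n, k); 2x2 covariances inverted analytically."""
    n, k = len(X), len(weights)
    out = np.empty((n, k))
    for j in range(k):
        a, b = covs[j][0]
        c, d = covs[j][1]
        det = a * d - b * c
        if det <= 0 or not np.isfinite(det):
            raise np.linalg.LinAlgError("covariance not positive-definite")
        dx = X[:, 0] - means[j][0]
        dy = X[:, 1] - means[j][1]
        quad = (d * dx * dx - (b + c) * dx * dy + a * dy * dy) / det
        out[:, j] = (
            np.log(weights[j] + 1e-300)
            - np.log(2.0 * np.pi)
            - 0.5 * np.log(det)
            - 0.5 * quad
        )
    return out


def _loglik(X, weights, means, covs) -> float:
    log_d = _log_component_densities(X, weights, means, covs)
    m = log_d.max(axis=1, keepdims=True)
    return float(np.sum(m.ravel() + np.log(np.exp(log_d - m).sum(axis=1))))


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding of component means."""
    n = len(X)
    centers = [X[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = np.min(
            [np.sum((X - c) ** 2, axis=1) for c in centers], axis=0
        )
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers.append(X[rng.choice(n, p=probs)])
    return np.array(centers)


def _evv_mstep(X, resp):
    """Closed-form M-step under the shared-volume (EVV) constraint."""
    n, d = X.shape
    nk = resp.sum(axis=0)  # (k,)
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    k = resp.shape[1]
    W = np.empty((k, d, d))
    ridge = False
    for j in range(k):
        diff = X - means[j]
        W[j] = (resp[:, j, None] * diff).T @ diff
        if np.linalg.det(W[j]) < 1e-300 or not np.all(np.isfinite(W[j])):
            W[j] += _RIDGE * np.eye(d)
            ridge = True
    dets = np.array([np.linalg.det(W[j]) for j in range(k)])
    lam = float(np.sum(dets ** (1.0 / d)) / n)  # shared volume
    covs = np.array([lam * W[j] / dets[j] ** (1.0 / d) for j in range(k)])
    # guard against numerically singular shapes
    for j in range(k):
        if np.linalg.det(covs[j]) < 1e-12 or np.linalg.cond(covs[j]) > 1e12:
            covs[j] = covs[j] + _RIDGE * np.eye(d)
            ridge = True
    return weights, means, covs, ridge


def _n_free_params(k: int, d: int = 2) -> int:
    """Free parameters of a k-component EVV mixture in d dimensions.

    weights (k-1) + means (k*d) + shared volume (1)
    + per-component shape (d-1 each) + orientation (d(d-1)/2 each).
    """
    return (k - 1) + k * d + 1 + k * ((d - 1) + d * (d - 1) // 2)


def em_fit(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_init: int = 10,
) -> MixtureModel:
    """Fit a k-component EVV Gaussian mixture by EM.

    Initialization is k-means++ with ``n_init`` seeded restarts; the fit
    with the best final log-likelihood is returned.  The log-likelihood is
    non-decreasing within every EM run.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(X)
    if n < 3 * k:
        raise ValueError(f"need at least {3 * k} points for k={k}, got {n}")
    rng = np.random.default_rng(seed)
    best: MixtureModel | None = None
    for _ in range(n_init):
        model = _em_single(X, k, rng, tol, max_iter)
        if best is None or model.loglik > best.loglik:
            best = model
    m = _n_free_params(best.k)
    best.bic = 2.0 * best.loglik - m * np.log(n)  # mclust sign convention
    return best


def _em_single(X, k, rng, tol, max_iter):
    n, d = X.shape
    means = _kmeanspp_init(X, k, rng)
    # initial responsibilities by nearest seed, then one constrained M-step
    dist = np.stack([np.sum((X - m) ** 2, axis=1) for m in means], axis=1)
    resp = np.zeros((n, k))
    resp[np.arange(n), np.argmin(dist, axis=1)] = 1.0
    resp = resp + 1e-3  # soften hard assignment to avoid empty components
    resp /= resp.sum(axis=1, keepdims=True)
    weights, means, covs, ridge = _evv_mstep(X, resp)

    ll = _loglik(X, weights, means, covs)
    path = [ll]
    converged = False
    for _ in range(max_iter):
        log_d = _log_component_densities(X, weights, means, covs)
        log_d -= log_d.max(axis=1, keepdims=True)
        resp = np.exp(log_d)
        resp /= resp.sum(axis=1, keepdims=True)
        new_w, new_mu, new_cov, r = _evv_mstep(X, resp)
        new_ll = _loglik(X, new_w, new_mu, new_cov)
        if new_ll < ll - 1e-10:
            # numerical guard: keep the previous (better) parameters
            converged = True
            break
        weights, means, covs = new_w, new_mu, new_cov
        ridge = ridge or r
        path.append(new_ll)
        if new_ll - ll < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return MixtureModel(
        k=k,
        weights=weights,
        means=means,
        covariances=covs,
        loglik=ll,
        bic=np.nan,
        n=n,
        converged=converged,
        ridge_applied=ridge,
        loglik_path=path,
    )


def select_model(points: np.ndarray, k_max: int = 3, seed: int = 0) -> MixtureModel:
    """Fit k = 1..k_max and return the model with the highest BIC.

    With fewer than 6 points only k=1 is attempted.  BIC uses the
    maximized-likelihood convention ``2*loglik - m*ln(n)`` (larger is
    better), with m the EVV free-parameter count.
    """
    X = np.asarray(points, dtype=float)
    n = len(X)
    ks = [1] if n < 6 else [k for k in range(1, k_max + 1) if n >= 3 * k]
    models = []
    for k in ks:
        try:
            models.append(em_fit(X, k, seed=seed))
        except (ValueError, np.linalg.LinAlgError):
            continue
    if not models:
        raise RuntimeError("all mixture fits failed")
    return max(models, key=lambda m: m.bic)


def classify_strategy(
    cluster_mean: tuple[float, float],
    f_thresh: float = F_THRESHOLD,
    g_thresh: float = G_THRESHOLD,
) -> str:
    """Quadrant label of a cluster mean (g, f) in growth-rate space.

    FS: fast on fructose only; GS: fast on galactose only; generalist:
    fast on both; low_both: fast on neither.  Boundary convention: >= on
    each axis.
    """
    g, f = cluster_mean
    fast_f = f >= f_thresh
    fast_g = g >= g_thresh
    if fast_f and not fast_g:
        return "FS"
    if fast_g and not fast_f:
        return "GS"
    if fast_f and fast_g:
        return "generalist"
    return "low_both"


def link_trajectories(
    models: list[MixtureModel], points_per_timepoint: list[np.ndarray]
) -> list[dict]:
    """Greedy nearest-centroid linking of clusters across timepoints.

    Returns lineage records ``{"lineage", "timepoint", "mean", "frequency"}``
    where frequency is the responsibility-weighted share of points.
    Unmatched clusters at a later timepoint open new lineages.
    """
    if len(models) != len(points_per_timepoint):
        raise ValueError("one point set required per fitted model")
    records: list[dict] = []
    next_lineage = 0
    prev_ids: list[int] = []
    prev_means: np.ndarray | None = None
    for t, (model, X) in enumerate(zip(models, points_per_timepoint)):
        freqs = model.responsibilities(np.asarray(X, float)).sum(axis=0) / len(X)
        ids = [-1] * model.k
        if prev_means is None:
            for j in range(model.k):
                ids[j] = next_lineage
                next_lineage += 1
        else:
            # greedy: repeatedly link the globally closest unmatched pair
            pairs = sorted(
                (
                    (np.linalg.norm(model.means[j] - prev_means[i]), j, i)
                    for j in range(model.k)
                    for i in range(len(prev_ids))
                ),
                key=lambda x: x[0],
            )
            used_prev: set[int] = set()
            for _, j, i in pairs:
                if ids[j] == -1 and i not in used_prev:
                    ids[j] = prev_ids[i]
                    used_prev.add(i)
            for j in range(model.k):
                if ids[j] == -1:
                    ids[j] = next_lineage
                    next_lineage += 1
        for j in range(model.k):
            records.append(
                {
                    "lineage": ids[j],
                    "timepoint": t,
                    "mean": tuple(model.means[j]),
                    "frequency": float(freqs[j]),
                }
            )
        prev_ids, prev_means = ids, model.means
    return records


def f_ratio(count_f: float, count_g: float) -> float | None:
    """F/(F+G) plating statistic; None when both counts are zero."""
    if count_f < 0 or count_g < 0:
        raise ValueError("counts must be non-negative")
    total = count_f + count_g
    if total == 0:
        return None
    return count_f / total
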