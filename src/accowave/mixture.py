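"""Two-component multivariate Gaussian ("bigaussian") generative model.

The K-dimensional eigen-wavefront scores of the cohort are fitted with a
mixture of two full-covariance multivariate Gaussians by
Expectation-Maximization.  Sampling the fitted mixture and mapping the
draws back through the eigenbasis (mean added back) yields synthetic
150-parameter accommodative wavefronts.

At any EM fixed point the mixture's pooled mean and second moment equal
the sample moments of the scores, so generated cohorts reproduce the
source cohort's first two moments up to sampling noise and basis
truncation.  A diagonal ridge keeps component covariances positive
definite; multiple seeded restarts guard against degenerate collapses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from accowave.pca import EigenBasis, reconstruct
from accowave.preprocess import STANDARD_PUPILS


@dataclass
class BigaussianModel:
    """Fitted 2-component Gaussian mixture over eigenvector scores."""

    weights: np.ndarray  # (2,)
    means: np.ndarray  # (2, K)
    covariances: np.ndarray  # (2, K, K)
    ridge: float
    seed: int | None = None
    log_likelihood_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("component weights must sum to 1")

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def k(self) -> int:
        return self.means.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "ridge": self.ridge,
            "seed": self.seed,
            "log_likelihood_trace": self.log_likelihood_trace.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "BigaussianModel":
        p = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(p["weights"]),
            means=np.array(p["means"]),
            covariances=np.array(p["covariances"]),
            ridge=float(p["ridge"]),
            seed=p["seed"],
            log_likelihood_trace=np.array(p["log_likelihood_trace"]),
        )


def mixture_mean(model: BigaussianModel) -> np.ndarray:
    """Closed-form mixture mean sum_i w_i mu_i."""
    return model.weights @ model.means


def mixture_covariance(model: BigaussianModel) -> np.ndarray:
    """Closed-form mixture covariance sum_i w_i (S_i + mu_i mu_i^T) - mu mu^T."""
    mu = mixture_mean(model)
    second = sum(
        w * (S + np.outer(m, m))
        for w, m, S in zip(model.weights, model.means, model.covariances)
    )
    return second - np.outer(mu, mu)


def _log_gaussians(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Per-component log densities, (N, 2), via Cholesky."""
    n, k = X.shape
    out = np.empty((n, means.shape[0]))
    for i, (m, S) in enumerate(zip(means, covs)):
        L = np.linalg.cholesky(S)
        z = solve_triangular(L, (X - m).T, lower=True)
        quad = np.sum(z**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, i] = -0.5 * (quad + logdet + k * np.log(2.0 * np.pi))
    return out


def _init_responsibilities(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style split: two far-apart centres, nearest-centre assignment."""
    n = X.shape[0]
    c0 = X[rng.integers(n)]
    d2 = np.sum((X - c0) ** 2, axis=1)
    p = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
    c1 = X[rng.choice(n, p=p)]
    r = np.zeros((n, 2))
    closer0 = np.sum((X - c0) ** 2, axis=1) <= np.sum((X - c1) ** 2, axis=1)
    r[closer0, 0] = 1.0
    r[~closer0, 1] = 1.0
    # soften so no component starts empty
    return 0.9 * r + 0.05


def _em_once(
    X: np.ndarray,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    ridge: float,
) -> tuple[float, dict] | None:
    n, k = X.shape
    resp = _init_responsibilities(X, rng)
    trace = []
    prev = -np.inf
    weights = means = covs = None
    for _ in range(max_iter):
        # M-step
        nk = resp.sum(axis=0)
        if nk.min() < 1e-6 * n:
            return None  # degenerate collapse; caller restarts
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = np.empty((2, k, k))
        for i in range(2):
            d = X - means[i]
            covs[i] = (d.T * resp[:, i]) @ d / nk[i] + ridge * np.eye(k)
        # E-step / log-likelihood
        logp = _log_gaussians(X, means, covs) + np.log(weights)
        ll = float(np.mean(logsumexp(logp, axis=1)))
        trace.append(ll)
        resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return trace[-1], {
        "weights": weights,
        "means": means,
        "covariances": covs,
        "trace": np.array(trace),
    }


def fit_em(
    scores: np.ndarray,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    restarts: int = 5,
    ridge_scale: float = 1e-6,
) -> BigaussianModel:
    """Fit the 2-component mixture by EM with seeded restarts.

    ``ridge_scale`` sets the diagonal ridge as a fraction of the mean
    score variance; the best (highest final mean log-likelihood)
    non-degenerate restart is kept.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValueError("scores must be an N x K matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("scores contain non-finite values")
    n, k = X.shape
    if n <= 2 * k:
        import warnings

        warnings.warn(
            f"only {n} samples for {k} dimensions; covariance estimates are weak",
            stacklevel=2,
        )
    ridge = ridge_scale * float(np.var(X, axis=0, ddof=1).mean())
    if ridge == 0.0:
        ridge = ridge_scale
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        result = _em_once(X, rng, tol, max_iter, ridge)
        if result is None:
            continue
        ll, params = result
        if best is None or ll > best[0]:
            best = (ll, params)
    if best is None:
        raise RuntimeError("all EM restarts collapsed to a degenerate component")
    _, p = best
    return BigaussianModel(
        weights=p["weights"],
        means=p["means"],
        covariances=p["covariances"],
        ridge=ridge,
        seed=seed,
        log_likelihood_trace=p["trace"],
    )


def sample_scores(model: BigaussianModel, n: int, seed: int | None = None) -> np.ndarray:
    """Draw n score vectors from the mixture (component per weights)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    comp = rng.choice(model.n_components, size=n, p=model.weights)
    out = np.empty((n, model.k))
    for i in range(model.n_components):
        idx = np.flatnonzero(comp == i)
        if idx.size:
            try:
                out[idx] = rng.multivariate_normal(
                    model.means[i], model.covariances[i], size=idx.size, method="cholesky"
                )
            except np.linalg.LinAlgError:
                # singular covariance (e.g. hand-built degenerate models)
                out[idx] = rng.multivariate_normal(
                    model.means[i], model.covariances[i], size=idx.size, method="svd"
                )
    return out


@dataclass
class SyntheticCohort:
    """Generated cohort: n x 150 Zernike parameters plus standard pupils."""

    data: np.ndarray
    standard_pupils: dict[int, float]

    @property
    def n(self) -> int:
        return self.data.shape[0]


def generate_cohort(
    basis: EigenBasis,
    model: BigaussianModel,
    n: int,
    seed: int | None = None,
    standard_pupils: dict[int, float] | None = None,
) -> SyntheticCohort:
    """Sample the mixture and back-transform to Zernike parameters.

    The cohort mean removed before PCA is added back by the
    reconstruction, so synthetic wavefronts live on the original scale.
    """
    if model.k != basis.k:
        raise ValueError(
            f"model dimension {model.k} does not match basis K={basis.k}"
        )
    scores = sample_scores(model, n, seed)
    data = reconstruct(scores, basis) if n else np.empty((0, basis.n_parameters))
    return SyntheticCohort(data, dict(standard_pupils or STANDARD_PUPILS))
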