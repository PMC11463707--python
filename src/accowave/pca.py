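"""Eigen-wavefront analysis: covariance PCA of the cohort matrix.

The cohort's 150 accommodative wavefront parameters are centred and the
orthonormal eigenvectors of the sample covariance matrix (N-1
denominator) are extracted, ordered by decreasing eigenvalue.  The
retained count K is the smallest number of leading eigenvectors whose
cumulative eigenvalue fraction reaches the cutoff (default 99.97%,
chosen to bridge the large amplitude gap between defocus and the
higher-order terms).  Eigenvector signs are fixed so the largest-|loading|
entry is positive, making reports and serializations reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from accowave.preprocess import PARAMETER_LABELS
from accowave.zernike import DEMANDS, MODES, N_PARAMETERS

DEFAULT_CUTOFF = 0.9997


@dataclass
class EigenBasis:
    """Centred orthonormal eigen-wavefront basis of a cohort."""

    mean: np.ndarray  # (P,) column means, µm
    eigenvectors: np.ndarray  # (P, K) orthonormal columns
    eigenvalues: np.ndarray  # (K,) descending variances
    cumulative_variance: np.ndarray  # (K,) fractions of total variance
    total_variance: float
    cutoff: float

    @property
    def n_parameters(self) -> int:
        return self.mean.size

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "cumulative_variance": self.cumulative_variance.tolist(),
            "total_variance": self.total_variance,
            "cutoff": self.cutoff,
            "column_order": list(PARAMETER_LABELS),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "EigenBasis":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(payload["mean"]),
            eigenvectors=np.array(payload["eigenvectors"]),
            eigenvalues=np.array(payload["eigenvalues"]),
            cumulative_variance=np.array(payload["cumulative_variance"]),
            total_variance=float(payload["total_variance"]),
            cutoff=float(payload["cutoff"]),
        )


def fit_basis(cohort: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> EigenBasis:
    """Centre the cohort and eigendecompose its sample covariance.

    Retains the smallest K leading eigenvectors whose cumulative variance
    fraction reaches ``cutoff``.
    """
    X = np.asarray(cohort, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("cohort matrix must be 2-D with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("cohort matrix contains non-finite entries")
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    mean = X.mean(axis=0)
    C = np.cov(X - mean, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w, kind="stable")[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    total = float(w.sum())
    if total == 0.0:
        raise ValueError("cohort has zero total variance; eigenbasis is undefined")
    cumfrac = np.cumsum(w) / total
    k = int(np.searchsorted(cumfrac, cutoff - 1e-12) + 1)
    k = min(k, w.size)
    # deterministic sign: largest-|loading| entry of each eigenvector positive
    for j in range(k):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return EigenBasis(
        mean=mean,
        eigenvectors=V[:, :k].copy(),
        eigenvalues=w[:k].copy(),
        cumulative_variance=cumfrac[:k].copy(),
        total_variance=total,
        cutoff=cutoff,
    )


def project(x: np.ndarray, basis: EigenBasis) -> np.ndarray:
    """Eigenvector scores of one or many parameter vectors: E^T (x - mean)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != basis.n_parameters:
        raise ValueError(
            f"expected vectors of length {basis.n_parameters}, got {x.shape[-1]}"
        )
    return (x - basis.mean) @ basis.eigenvectors


def reconstruct(scores: np.ndarray, basis: EigenBasis) -> np.ndarray:
    """Parameter vectors from scores: E s + mean."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[-1] != basis.k:
        raise ValueError(f"expected {basis.k} scores, got {scores.shape[-1]}")
    return scores @ basis.eigenvectors.T + basis.mean


def cumulative_variance_table(basis: EigenBasis, cohort: np.ndarray | None = None) -> pd.DataFrame:
    """Cumulative variance (%) per eigenvector, with colormap limits.

    When the cohort is given, the Max/Min columns are the extrema of each
    eigenvector's rank-1 contribution s_ik * e_k over subjects and
    parameters — the colour limits of an eigen-wavefront map.
    """
    rows = {
        "eigenvector": np.arange(1, basis.k + 1),
        "cumulative_variance_pct": 100.0 * basis.cumulative_variance,
    }
    if cohort is not None:
        scores = project(cohort, basis)
        maxs, mins = [], []
        for j in range(basis.k):
            contrib = np.outer(scores[:, j], basis.eigenvectors[:, j])
            maxs.append(contrib.max())
            mins.append(contrib.min())
        rows["max_um"] = np.array(maxs)
        rows["min_um"] = np.array(mins)
    return pd.DataFrame(rows)


def eigenvector_composition(basis: EigenBasis, k: int) -> pd.DataFrame:
    """Zernike decomposition of eigenvector k (1-based).

    The loading pattern is reshaped to 6 demands x 25 modes; the relative
    RMS contribution of mode (n, m) pools the squared loadings over
    demands.  The mode with the largest contribution is the fundamental
    component; a share above 40% marks an eigenvector dominated by a
    single aberration.
    """
    if not 1 <= k <= basis.k:
        raise ValueError(f"eigenvector index must lie in 1..{basis.k}, got {k}")
    if basis.n_parameters != N_PARAMETERS:
        raise ValueError("composition reporting requires the 6x25 parameter layout")
    loadings = basis.eigenvectors[:, k - 1].reshape(len(DEMANDS), len(MODES))
    power = (loadings**2).sum(axis=0)
    share = 100.0 * power / power.sum()
    df = pd.DataFrame(
        {
            "n": [n for n, _ in MODES],
            "m": [m for _, m in MODES],
            "rms_contribution_pct": share,
        }
    )
    fundamental = int(np.argmax(share))  # ties break toward the lower single index
    df.attrs["fundamental_mode"] = MODES[fundamental]
    df.attrs["fundamental_share_pct"] = float(share[fundamental])
    df.attrs["dominant"] = bool(share[fundamental] > 40.0)
    return df
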