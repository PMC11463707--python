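"""Synthetic clinical cohort emulator.

No accommodative-wavefront cohort is publicly released, so this module
generates one: N subjects x 6 demands x 25 Zernike modes with marginal
means/SDs matching the published per-parameter summary statistics for
the seven printed modes — C(2,-2), C(2,0), C(2,2), C(3,-1), C(3,1),
C(4,0), C(6,0) — and small zero-mean defaults for the unprinted modes
(SD = 0.01 * 0.7^(n-4) µm, decaying with radial order).  The same mode
is correlated across demands (constant correlation, default 0.9);
cross-mode correlation defaults to zero.  Natural pupil diameters are
drawn per demand from normals whose 5th percentiles sit at the standard
diameters, so the exclusion rule flags ~5% of cells per demand.
Left-eye subjects (default half the cohort) have the mirror transform
applied to their stored coefficients, which preprocessing must undo.

Every correlation here is a fixture parameter, not a claim about the
clinical population: the published tables print no covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from accowave.preprocess import PARAMETER_LABELS, STANDARD_PUPILS, preprocess_cohort
from accowave.zernike import (
    DEMANDS,
    LEFT,
    MODE_LABELS,
    MODES,
    N_PARAMETERS,
    RIGHT,
    mirror_sign_flips,
)

#: printed per-parameter (mean, SD) in µm, keyed by mode then demand order 0..5 D
TABLE3_MARGINALS: dict[tuple[int, int], list[tuple[float, float]]] = {
    (2, -2): [(0.017, 0.213), (0.021, 0.226), (0.015, 0.192),
              (0.014, 0.157), (0.007, 0.158), (0.005, 0.135)],
    (2, 0): [(1.249, 1.747), (1.544, 1.902), (1.826, 1.757),
             (1.948, 1.390), (2.335, 1.493), (2.278, 1.312)],
    (2, 2): [(-0.159, 0.362), (-0.129, 0.366), (-0.090, 0.318),
             (-0.066, 0.271), (-0.035, 0.271), (-0.020, 0.227)],
    (3, -1): [(0.024, 0.082), (0.026, 0.091), (0.026, 0.074),
              (0.023, 0.063), (0.025, 0.067), (0.022, 0.052)],
    (3, 1): [(0.000, 0.060), (-0.005, 0.067), (0.002, 0.059),
             (0.007, 0.057), (0.011, 0.066), (0.011, 0.060)],
    (4, 0): [(0.039, 0.050), (0.036, 0.056), (0.016, 0.049),
             (0.002, 0.041), (-0.004, 0.048), (-0.008, 0.041)],
    (6, 0): [(-0.001, 0.013), (-0.001, 0.014), (-0.001, 0.013),
             (-0.001, 0.009), (-0.002, 0.009), (-0.001, 0.006)],
}


def default_marginals() -> tuple[np.ndarray, np.ndarray]:
    """Demand-major (150,) mean and SD vectors of the default population."""
    mu = np.zeros(N_PARAMETERS)
    sd = np.zeros(N_PARAMETERS)
    for j, (n, m) in enumerate(MODES):
        for d in DEMANDS:
            col = d * len(MODES) + j
            if (n, m) in TABLE3_MARGINALS:
                mu[col], sd[col] = TABLE3_MARGINALS[(n, m)][d]
            else:
                mu[col], sd[col] = 0.0, 0.01 * 0.7 ** (n - 4)
    return mu, sd


def _default_pupil_means() -> dict[int, float]:
    # mean such that the 5th percentile of N(mean, 0.45) is the standard pupil
    z95 = float(stats.norm.ppf(0.95))
    return {d: STANDARD_PUPILS[d] + z95 * 0.45 for d in DEMANDS}


@dataclass
class PopulationSpec:
    """Tunable conditions of the synthetic cohort."""

    n_subjects: int = 191
    means: np.ndarray = field(default_factory=lambda: default_marginals()[0])
    sds: np.ndarray = field(default_factory=lambda: default_marginals()[1])
    r_within: float = 0.9  # same mode across demands
    r_cross_mode: float = 0.0
    pupil_means: dict[int, float] = field(default_factory=_default_pupil_means)
    pupil_sd: float = 0.45
    min_pupil: float = 2.0
    laterality_ratio: float = 0.5  # fraction of LE subjects
    seed: int = 0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != (N_PARAMETERS,) or self.sds.shape != (N_PARAMETERS,):
            raise ValueError(f"means and sds must have shape ({N_PARAMETERS},)")
        if np.any(self.sds < 0):
            raise ValueError("SDs must be non-negative")
        if not abs(self.r_within) < 1:
            raise ValueError("|r_within| must be < 1")


def build_covariance(spec: PopulationSpec) -> np.ndarray:
    """Structured 150 x 150 covariance of the population.

    Block construction: within each mode, a 6 x 6 cross-demand block with
    constant correlation ``r_within``; distinct modes share correlation
    ``r_cross_mode`` (default 0).  Repaired by eigenvalue clipping if the
    combination is indefinite.
    """
    n_modes = len(MODES)
    corr = np.empty((N_PARAMETERS, N_PARAMETERS))
    for a in range(N_PARAMETERS):
        for b in range(N_PARAMETERS):
            if a == b:
                corr[a, b] = 1.0
            elif a % n_modes == b % n_modes:
                corr[a, b] = spec.r_within
            else:
                corr[a, b] = spec.r_cross_mode
    cov = corr * np.outer(spec.sds, spec.sds)
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        ww, V = np.linalg.eigh(cov)
        cov = (V * np.clip(ww, 0.0, None)) @ V.T
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-8:
            raise ValueError("population covariance is not PSD even after clipping")
    return cov


def generate_population_matrix(
    spec: PopulationSpec | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    """Draw the cohort in the right-eye convention.

    Returns (subject_ids, X, pupils, lateralities) with X of shape
    (N, 150) demand-major and pupils of shape (N, 6) in mm.
    """
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(spec.seed)
    cov = build_covariance(spec)
    try:
        X = rng.multivariate_normal(spec.means, cov, size=spec.n_subjects, method="cholesky")
    except np.linalg.LinAlgError:
        # semi-definite covariance (e.g. zero SDs)
        X = rng.multivariate_normal(spec.means, cov, size=spec.n_subjects, method="svd")
    pupils = np.empty((spec.n_subjects, len(DEMANDS)))
    for d in DEMANDS:
        pupils[:, d] = rng.normal(spec.pupil_means[d], spec.pupil_sd, size=spec.n_subjects)
    pupils = np.maximum(pupils, spec.min_pupil)
    lateralities = [
        LEFT if u < spec.laterality_ratio else RIGHT
        for u in rng.random(spec.n_subjects)
    ]
    width = len(str(spec.n_subjects))
    ids = [f"S{i + 1:0{width}d}" for i in range(spec.n_subjects)]
    return ids, X, pupils, lateralities


def generate_population(spec: PopulationSpec | None = None) -> pd.DataFrame:
    """Raw measurement table (one row per subject x demand).

    Left-eye subjects are stored in the LE sign convention (the mirror
    transform, an involution, is applied to the RE-convention draw), so
    preprocessing recovers the RE-convention values exactly.
    """
    spec = spec or PopulationSpec()
    ids, X, pupils, lats = generate_population_matrix(spec)
    flips = mirror_sign_flips(MODES)
    n_modes = len(MODES)
    rows = []
    for i, sid in enumerate(ids):
        for d in DEMANDS:
            values = X[i, d * n_modes : (d + 1) * n_modes]
            if lats[i] == LEFT:
                values = values * flips
            rows.append(
                {
                    "subject_id": sid,
                    "eye": lats[i],
                    "demand_D": d,
                    "pupil_mm": pupils[i, d],
                    **dict(zip(MODE_LABELS, values)),
                }
            )
    return pd.DataFrame(rows)


def worked_reference_run(seed: int = 42, n_subjects: int = 20):
    """Deterministic miniature cohort plus its preprocessed matrix.

    Used as a self-contained fixture: the raw table, the assembled
    matrix, and the exclusion log are all regenerated from the seed at
    run time.
    """
    spec = PopulationSpec(n_subjects=n_subjects, seed=seed)
    raw = generate_population(spec)
    cohort, log = preprocess_cohort(raw)
    return raw, cohort, log


def population_parameter_labels() -> tuple[str, ...]:
    return PARAMETER_LABELS
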