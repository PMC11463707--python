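"""Cohort assembly: mirroring, pupil rules, exclusion, and the N x 150 matrix.

The preprocessing reproduces the measurement-harmonisation workflow of
accommodative aberrometry studies: left-eye data are mirrored to the
right-eye convention, a fixed standard pupil diameter is used per demand
(the 5th percentile of the cohort's natural pupils, so 95% of eyes reach
it), eyes with smaller pupils are excluded per vergence to avoid
extrapolation, eyes excluded at three or more vergences are dropped
altogether, and the remaining measurements are rescaled down to the
standard diameters.  Subjects are then rows of an N x 150 matrix
(demand-major: the 25 modes at 0 D, then at 1 D, ...).

Cells excluded at one or two vergences are imputed with the column mean;
the imputation mask is carried along
so validation statistics can ignore imputed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from accowave.rescale import build_rescale_matrix
from accowave.zernike import (
    DEMANDS,
    LATERALITIES,
    LEFT,
    MODE_LABELS,
    MODES,
    N_PARAMETERS,
    mirror_sign_flips,
)

#: per-demand standard pupil diameters (mm), 5th percentile of the cohort
STANDARD_PUPILS: dict[int, float] = {0: 4.66, 1: 4.76, 2: 4.40, 3: 4.09, 4: 4.07, 5: 3.68}

#: demand-major labels of the 150 model parameters, e.g. "d0_c_2_-2"
PARAMETER_LABELS: tuple[str, ...] = tuple(
    f"d{d}_{lab}" for d in DEMANDS for lab in MODE_LABELS
)


@dataclass
class CohortConfig:
    """Pupil and exclusion rules of the preprocessing stage."""

    standard_pupils: dict[int, float] = field(default_factory=lambda: dict(STANDARD_PUPILS))
    pupil_percentile: float = 5.0
    max_excluded_vergences: int = 2

    def __post_init__(self) -> None:
        if set(self.standard_pupils) != set(DEMANDS):
            raise ValueError(f"standard_pupils must cover demands {DEMANDS}")
        if not 0 < self.pupil_percentile < 100:
            raise ValueError("pupil percentile must lie in (0, 100)")


@dataclass
class CohortMatrix:
    """Assembled cohort: N x 150 parameter matrix plus imputation mask."""

    data: np.ndarray
    imputed: np.ndarray
    subject_ids: list[str]
    standard_pupils: dict[int, float]

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.subject_ids), N_PARAMETERS):
            raise ValueError(
                f"cohort matrix must be N x {N_PARAMETERS}, got {self.data.shape}"
            )
        if self.imputed.shape != self.data.shape:
            raise ValueError("imputation mask must match the data shape")


def standard_pupil_from_cohort(pupils, percentile: float = 5.0) -> float:
    """Percentile of the cohort's natural pupil diameters (linear quantile).

    The default 5th percentile is the largest diameter achievable by 95%
    of the eyes.
    """
    pupils = np.asarray(pupils, dtype=float)
    if pupils.size == 0:
        raise ValueError("cannot take a percentile of an empty pupil list")
    if pupils.size < 20:
        warnings.warn(
            f"only {pupils.size} pupil observations; percentile estimate is unstable",
            stacklevel=2,
        )
    return float(np.percentile(pupils, percentile, method="linear"))


def _validate_raw(raw: pd.DataFrame) -> None:
    required = ["subject_id", "eye", "demand_D", "pupil_mm", *MODE_LABELS]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"raw measurement table lacks columns: {missing}")
    bad_eye = set(raw["eye"].unique()) - set(LATERALITIES)
    if bad_eye:
        raise ValueError(f"column 'eye' contains invalid laterality tokens: {sorted(bad_eye)}")
    bad_dem = set(raw["demand_D"].unique()) - set(DEMANDS)
    if bad_dem:
        raise ValueError(f"column 'demand_D' contains off-grid demands: {sorted(bad_dem)}")
    dup = raw.duplicated(["subject_id", "demand_D"])
    if dup.any():
        raise ValueError("at most one measurement per (subject, demand) is allowed")


def apply_exclusion(
    raw: pd.DataFrame, config: CohortConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Flag small-pupil cells and drop subjects excluded at too many vergences.

    A (subject, demand) cell is flagged when the natural pupil is smaller
    than the standard pupil for that demand; a subject with more than
    ``max_excluded_vergences`` flags is dropped entirely.  Returns the
    kept rows with a boolean ``excluded_cell`` column and a log of every
    decision.
    """
    config = config or CohortConfig()
    _validate_raw(raw)
    raw = raw.copy()
    standards = raw["demand_D"].map(config.standard_pupils)
    raw["excluded_cell"] = raw["pupil_mm"] < standards
    log: list[dict] = []
    dropped: list[str] = []
    for sid, grp in raw.groupby("subject_id", sort=False):
        n_flagged = int(grp["excluded_cell"].sum())
        for _, row in grp[grp["excluded_cell"]].iterrows():
            log.append(
                {
                    "subject_id": str(sid),
                    "demand_D": int(row["demand_D"]),
                    "action": "cell_excluded",
                    "pupil_mm": float(row["pupil_mm"]),
                    "standard_mm": float(config.standard_pupils[int(row["demand_D"])]),
                }
            )
        if n_flagged > config.max_excluded_vergences:
            dropped.append(sid)
            log.append(
                {
                    "subject_id": str(sid),
                    "action": "subject_dropped",
                    "n_excluded_vergences": n_flagged,
                }
            )
    kept = raw[~raw["subject_id"].isin(dropped)].reset_index(drop=True)
    return kept, log


def _subject_vector(
    grp: pd.DataFrame, config: CohortConfig, rescale_cache: dict
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's demand-major 150-vector and missing-cell mask."""
    vec = np.full(N_PARAMETERS, np.nan)
    missing = np.ones((len(DEMANDS),), dtype=bool)
    flips = mirror_sign_flips(MODES)
    for _, row in grp.iterrows():
        if bool(row.get("excluded_cell", False)):
            continue
        d = int(row["demand_D"])
        values = row[list(MODE_LABELS)].to_numpy(dtype=float)
        if row["eye"] == LEFT:
            values = values * flips
        key = (round(float(row["pupil_mm"]), 12), config.standard_pupils[d])
        if key not in rescale_cache:
            rescale_cache[key] = build_rescale_matrix(key[0], key[1])
        values = rescale_cache[key].apply(values)
        vec[d * len(MODES) : (d + 1) * len(MODES)] = values
        missing[d] = False
    mask = np.repeat(missing, len(MODES))
    return vec, mask


def assemble_matrix(
    vectors: np.ndarray,
    missing: np.ndarray,
    subject_ids: list[str],
    standard_pupils: dict[int, float],
) -> CohortMatrix:
    """Stack subject vectors and mean-impute missing cells.

    Column means are computed over observed cells only and are unchanged
    by the imputation.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[1] != N_PARAMETERS:
        raise ValueError(f"subject vectors must be N x {N_PARAMETERS}, got {vectors.shape}")
    missing = np.asarray(missing, dtype=bool)
    data = vectors.copy()
    for c in range(data.shape[1]):
        col_missing = missing[:, c]
        if col_missing.any():
            observed = data[~col_missing, c]
            if observed.size == 0:
                raise ValueError(f"parameter column {c} has no observed values to impute from")
            data[col_missing, c] = observed.mean()
    if np.isnan(data).any():
        raise ValueError("assembled matrix contains NaNs outside the missing mask")
    return CohortMatrix(data, missing, list(subject_ids), dict(standard_pupils))


def preprocess_cohort(
    raw: pd.DataFrame, config: CohortConfig | None = None
) -> tuple[CohortMatrix, list[dict]]:
    """Full preprocessing: exclusion, mirroring, rescaling, assembly.

    Input is the raw measurement table (one row per subject x demand,
    coefficients at the natural pupil).  Output rows are subjects in
    first-appearance order.
    """
    config = config or CohortConfig()
    kept, log = apply_exclusion(raw, config)
    cache: dict = {}
    ids, vecs, masks = [], [], []
    for sid, grp in kept.groupby("subject_id", sort=False):
        vec, mask = _subject_vector(grp, config, cache)
        ids.append(str(sid))
        vecs.append(vec)
        masks.append(mask)
    if not ids:
        raise ValueError("no subjects left after exclusion")
    return assemble_matrix(np.array(vecs), np.array(masks), ids, config.standard_pupils), log
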