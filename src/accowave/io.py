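"""CSV/JSON/YAML serialization of cohorts, bases, models and reports.

The cohort CSV schema is one row per subject x demand:
``subject_id, eye, demand_D, pupil_mm, c_2_-2 ... c_6_6`` (25 coefficient
columns in single-index order).  Floats are written with 17 significant
digits so write/read round trips are exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from accowave.mixture import SyntheticCohort
from accowave.preprocess import STANDARD_PUPILS
from accowave.zernike import DEMANDS, LATERALITIES, MODE_LABELS, RIGHT

COHORT_COLUMNS = ["subject_id", "eye", "demand_D", "pupil_mm", *MODE_LABELS]


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a raw/synthetic cohort table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file is not a cohort") from None
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: cohort table has no rows")
    bad = df[~df["eye"].isin(LATERALITIES)]
    if not bad.empty:
        line = int(bad.index[0]) + 2  # header is line 1
        raise ValueError(
            f"{path}: line {line}: column 'eye' must be one of {LATERALITIES}, "
            f"got {bad['eye'].iloc[0]!r}"
        )
    bad = df[~df["demand_D"].isin(DEMANDS)]
    if not bad.empty:
        line = int(bad.index[0]) + 2
        raise ValueError(
            f"{path}: line {line}: column 'demand_D' must be one of {DEMANDS}, "
            f"got {bad['demand_D'].iloc[0]!r}"
        )
    for col in ["pupil_mm", *MODE_LABELS]:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            line = int(values.index[values.isna()][0]) + 2
            raise ValueError(f"{path}: line {line}: non-numeric value in column {col!r}")
        df[col] = values
    df["demand_D"] = df["demand_D"].astype(int)
    return df[COHORT_COLUMNS]


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table with round-trip-exact floats."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    table[COHORT_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def cohort_to_table(cohort: SyntheticCohort, prefix: str = "G") -> pd.DataFrame:
    """Long-format table of a generated cohort (RE convention).

    Generated wavefronts are defined at the per-demand standard pupil
    diameters.
    """
    n_modes = len(MODE_LABELS)
    width = max(4, len(str(cohort.n)))
    rows = []
    for i in range(cohort.n):
        sid = f"{prefix}{i + 1:0{width}d}"
        for d in DEMANDS:
            values = cohort.data[i, d * n_modes : (d + 1) * n_modes]
            rows.append(
                {
                    "subject_id": sid,
                    "eye": RIGHT,
                    "demand_D": d,
                    "pupil_mm": cohort.standard_pupils[d],
                    **dict(zip(MODE_LABELS, values)),
                }
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def table_to_cohort(table: pd.DataFrame) -> SyntheticCohort:
    """Inverse of :func:`cohort_to_table` for already-standardised tables.

    Assumes one row per (subject, demand) at the standard pupils, RE
    convention (i.e. a generated cohort read back from CSV).
    """
    n_modes = len(MODE_LABELS)
    subjects = list(dict.fromkeys(table["subject_id"]))
    data = np.zeros((len(subjects), n_modes * len(DEMANDS)))
    pupils = dict(STANDARD_PUPILS)
    for i, sid in enumerate(subjects):
        grp = table[table["subject_id"] == sid]
        if len(grp) != len(DEMANDS):
            raise ValueError(f"subject {sid}: expected {len(DEMANDS)} demand rows")
        for _, row in grp.iterrows():
            d = int(row["demand_D"])
            data[i, d * n_modes : (d + 1) * n_modes] = row[list(MODE_LABELS)].to_numpy(float)
            pupils[d] = float(row["pupil_mm"])
    return SyntheticCohort(data, pupils)
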