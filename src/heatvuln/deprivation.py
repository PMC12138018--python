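"""Area-level social-deprivation score (FDep-style).

The French Deprivation Index (FDep) summarises four commune-level
socioeconomic variables — unemployment rate, share of blue-collar
workers among the active population aged 15–64, share of high-school
graduates among residents aged ≥ 15, and median household income — as
the first principal component of their correlation matrix.  Higher
score = more deprived; the eigenvector sign is anchored so the score
correlates positively with unemployment.

This module recomputes the construction from the component variables
(fdep-like score); it does not reproduce any official national release,
which is external data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import IndicatorColumn
from .errors import DegenerateVarianceError, InstabilityError, SchemaError

SOCIO_COLUMNS = (
    "unemployment_rate",
    "blue_collar_pct",
    "graduates_pct",
    "median_income",
)

MIN_COMPLETE_CASES = 5


def read_socio_table(path: str | Path) -> pd.DataFrame:
    """Read the per-unit socioeconomic CSV, indexed by ``unit_id``.

    Percentages must lie in [0, 100] and income must be positive where
    present; missing entries stay NaN, never zero-filled.
    """
    df = pd.read_csv(path, dtype={"unit_id": str})
    required = ("unit_id",) + SOCIO_COLUMNS
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"socioeconomic table missing column {col!r}")
    df = df.set_index("unit_id")
    for col in ("unemployment_rate", "blue_collar_pct", "graduates_pct"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise SchemaError(f"{col}: percentages must lie in [0, 100]")
    income = df["median_income"].dropna()
    if (income <= 0).any():
        raise SchemaError("median_income must be > 0")
    return df[list(SOCIO_COLUMNS)]


def standardise_components(table: pd.DataFrame) -> pd.DataFrame:
    """Centre and scale each component to unit population variance.

    Operates on complete cases only; incomplete rows are dropped here
    and handled by the index module's imputation policy downstream.
    """
    complete = table.dropna()
    if len(complete) < MIN_COMPLETE_CASES:
        raise SchemaError(
            f"need at least {MIN_COMPLETE_CASES} complete cases, "
            f"found {len(complete)}"
        )
    out = {}
    for col in table.columns:
        x = complete[col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise DegenerateVarianceError(f"component {col!r} is constant")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=complete.index)


def fdep_score(table: pd.DataFrame) -> IndicatorColumn:
    """First principal component of the four standardised components.

    The correlation-matrix (not covariance) component is used because
    the variables have incommensurable units; scores are therefore
    invariant to any positive rescaling of a component.  Incomplete
    units are flagged missing.
    """
    z = standardise_components(table[list(SOCIO_COLUMNS)])
    n = len(z)
    zm = z.to_numpy(dtype=float)
    corr = zm.T @ zm / n
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[-1] - eigvals[-2] < 1e-9:
        raise InstabilityError(
            "leading eigenvalue is not unique; deprivation axis undefined"
        )
    vec = eigvecs[:, -1]
    scores = zm @ vec
    # sign convention: more deprived (higher unemployment) scores higher
    anchor = np.corrcoef(scores, zm[:, 0])[0, 1]
    if anchor < 0:
        scores = -scores
    elif anchor == 0 and vec[0] < 0:
        scores = -scores
    missing = set(table.index) - set(z.index)
    return IndicatorColumn(
        name="fdep",
        values=dict(zip(z.index, scores.astype(float))),
        orientation="risk",
        missing=missing,
        units_label="unitless score",
    )
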