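"""Size correction and summary statistics for single-cell fluorescence.

Flow-cytometry fluorescence (FL1) scales with cell size and granulometry,
which the forward- and side-scatter channels (FSC, SSC) report. Before any
variability statistic is computed, FL1 is conditioned on log(FSC) and
log(SSC) within each acquisition sample so that the remaining cell-to-cell
variation reflects expression, not cell geometry. Variability is then
summarised per sample as the coefficient of variation (CV = s.d. / mean)
of the corrected intensities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of a per-cell table.
CELL_COLUMNS = ["sample_id", "strain", "methionine_uM", "FSC", "SSC", "FL1"]

#: Columns of a per-sample statistics table.
STATS_COLUMNS = ["sample_id", "strain", "methionine_uM", "n_cells", "mean", "sd", "cv"]


@dataclass
class SampleStats:
    """Per-sample summary of corrected fluorescence.

    ``cv`` is exactly ``sd / mean``; it is undefined (NaN, with
    ``cv_defined=False``) when the mean is not strictly positive.
    """

    sample_id: str
    mean: float
    sd: float
    cv: float
    n_cells: int
    strain: str = ""
    methionine_uM: float = float("nan")
    cv_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "strain": self.strain,
            "methionine_uM": self.methionine_uM,
            "n_cells": self.n_cells,
            "mean": self.mean,
            "sd": self.sd,
            "cv": self.cv,
        }


def _validate_cells(cells: pd.DataFrame, min_rows: int) -> None:
    for col in ("FSC", "SSC", "FL1"):
        if col not in cells.columns:
            raise ValueError(f"cell table lacks required column {col!r}")
    if len(cells) < min_rows:
        raise ValueError(f"cell table has {len(cells)} rows; need >= {min_rows}")


def size_correct(cells: pd.DataFrame, *, pooled: bool = False) -> pd.DataFrame:
    """Condition FL1 on log(FSC) and log(SSC) by linear regression.

    An ordinary least-squares fit of FL1 on the two log-scatter covariates
    is computed per sample (or once across all samples if ``pooled``), and
    FL1 is replaced by its residual plus the sample mean, so the correction
    is mean-preserving and the corrected FL1 is uncorrelated with both
    covariates within the fitted sample.

    A degenerate design (both scatter channels constant) falls back to the
    identity correction with a warning.

    Parameters
    ----------
    cells:
        Per-cell table with positive FSC and SSC and an FL1 column. If a
        ``sample_id`` column is present the fit is per sample.
    pooled:
        Fit a single regression across all rows instead of per sample.

    Returns
    -------
    A copy of ``cells`` with FL1 replaced by the corrected values.
    """
    _validate_cells(cells, min_rows=3)
    if (cells["FSC"] <= 0).any() or (cells["SSC"] <= 0).any():
        raise ValueError("FSC and SSC must be strictly positive (log is taken)")

    out = cells.copy()
    if pooled or "sample_id" not in cells.columns:
        out["FL1"] = _correct_one(out)
    else:
        for _, group in out.groupby("sample_id", sort=False):
            out.loc[group.index, "FL1"] = _correct_one(group)
    return out


def _correct_one(group: pd.DataFrame) -> pd.Series:
    fl1 = group["FL1"].to_numpy(dtype=float)
    x1 = np.log(group["FSC"].to_numpy(dtype=float))
    x2 = np.log(group["SSC"].to_numpy(dtype=float))
    design = np.column_stack([np.ones_like(x1), x1, x2])
    # rank-deficient when both covariates are constant: identity fallback
    if np.ptp(x1) == 0.0 and np.ptp(x2) == 0.0:
        warnings.warn(
            "constant FSC and SSC: size correction degenerate, returning FL1 unchanged",
            stacklevel=3,
        )
        return pd.Series(fl1, index=group.index)
    coef, *_ = np.linalg.lstsq(design, fl1, rcond=None)
    residual = fl1 - design @ coef
    return pd.Series(residual + fl1.mean(), index=group.index)


def sample_stats(cells: pd.DataFrame) -> SampleStats:
    """Mean, sample s.d. (n-1 denominator) and CV of FL1 for one sample."""
    _validate_cells(cells, min_rows=2)
    fl1 = cells["FL1"].to_numpy(dtype=float)
    mean = float(fl1.mean())
    sd = float(fl1.std(ddof=1))
    cv_defined = mean > 0
    if not cv_defined:
        logger.warning("sample mean %.4g <= 0: CV undefined", mean)
    cv = sd / mean if cv_defined else float("nan")

    def _meta(col, default):
        return cells[col].iloc[0] if col in cells.columns else default

    return SampleStats(
        sample_id=str(_meta("sample_id", "")),
        mean=mean,
        sd=sd,
        cv=cv,
        n_cells=len(cells),
        strain=str(_meta("strain", "")),
        methionine_uM=float(_meta("methionine_uM", float("nan"))),
        cv_defined=cv_defined,
    )


def stats_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-sample statistics for every ``sample_id`` in a cell table."""
    if "sample_id" not in cells.columns:
        return pd.DataFrame([sample_stats(cells).as_dict()])
    rows = [
        sample_stats(group).as_dict()
        for _, group in cells.groupby("sample_id", sort=False)
    ]
    return pd.DataFrame(rows, columns=STATS_COLUMNS)
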