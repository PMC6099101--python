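"""Convergent-validity descriptives: means, SDs, Pearson correlation matrix.

Operates on per-person composite scores (one column per scoring-system x
item or x family variable).  Complete cases only; the sample SD uses the
n-1 denominator.  A zero-variance variable makes its correlations
undefined — those entries are reported as missing with a warning rather
than as a silent NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ValidityReport", "validity_report", "report_frame"]


@dataclass(frozen=True)
class ValidityReport:
    """Descriptives and correlations across scoring variables."""

    means: pd.Series
    sds: pd.Series
    correlations: pd.DataFrame
    n: int

    @property
    def variables(self) -> list[str]:
        return list(self.means.index)


def _wide(composites: pd.DataFrame) -> pd.DataFrame:
    wide = composites.pivot_table(
        index="person_id", columns="variable_name", values="value", sort=True
    )
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"complete cases required; variables with gaps: {missing}")
    # order: system prefix, then item/family label
    return wide[sorted(wide.columns)]


def validity_report(composites: pd.DataFrame) -> ValidityReport:
    """Compute per-variable mean/SD and the pairwise Pearson matrix.

    Parameters
    ----------
    composites
        Long table ``person_id, variable_name, value`` with one value per
        (person, variable); at least 3 persons.
    """
    wide = _wide(composites)
    n = len(wide)
    if n < 3:
        raise ValueError(f"need >= 3 persons for correlations, got {n}")
    sds = wide.std(ddof=1)
    degenerate = sds[sds == 0].index.tolist()
    if degenerate:
        warnings.warn(
            f"zero-variance variable(s) {degenerate}: their correlations are "
            "undefined and reported as missing",
            stacklevel=2,
        )
    corr = wide.corr(method="pearson")
    # pandas leaves a unit diagonal even for constant columns; blank the
    # whole row/column instead, keeping the diagonal of valid variables 1
    for var in degenerate:
        corr.loc[var, :] = np.nan
        corr.loc[:, var] = np.nan
    return ValidityReport(means=wide.mean(), sds=sds, correlations=corr, n=n)


def report_frame(report: ValidityReport, decimals: int = 2) -> pd.DataFrame:
    """Format a report as variable, M, SD plus lower-triangular correlations."""
    variables = report.variables
    out = pd.DataFrame(
        {
            "variable": variables,
            "M": report.means.round(decimals).values,
            "SD": report.sds.round(decimals).values,
        }
    )
    for j, col in enumerate(variables):
        vals = []
        for i in range(len(variables)):
            vals.append(report.correlations.iloc[i, j] if i > j else np.nan)
        out[str(j + 1)] = np.round(vals, decimals)
    return out
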