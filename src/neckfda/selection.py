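"""Choice of the Fourier basis dimension for the coefficient function.

Three criteria are tabulated for each candidate odd dimension K, always
on the single-functional-predictor angular-velocity model: the multiple
correlation r (higher is better but always non-decreasing in K), the
overall F statistic with its p-value (a robustness check), and the AIC
(lower is better).  A documented compromise rule turns the visual
"pick a K with high r, comparable AIC and a decent F" judgment into a
reproducible procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import NeckFDAError
from .fourier_basis import BasisCurve
from .sofr import ModelSpec, build_design, fit_sofr

__all__ = ["CriteriaRow", "criteria_table", "select_n_basis", "table_to_frame"]

#: r within this of the table maximum counts as "high correlation".
R_TOL = 0.01
#: AIC within this of the table minimum counts as "comparable support".
AIC_TOL = 4.0
#: Overall-model significance required by the compromise rule.
P_MAX = 0.05


@dataclass(frozen=True)
class CriteriaRow:
    """Selection criteria for one candidate basis dimension."""

    n_basis: int
    r: float
    aic: float
    F: float
    p_value: float


class InfeasibleDimensionError(NeckFDAError, ValueError):
    """Candidate basis dimension too large for the sample size."""


def criteria_table(
    curves: list[BasisCurve],
    response: np.ndarray,
    candidates: list[int] = (5, 7, 9, 11),
    predictor_name: str = "omega",
) -> list[CriteriaRow]:
    """Fit the velocity functional model at each candidate dimension.

    Each row fits ``response ~ predictor(t)`` with a coefficient-function
    basis of size K and records r, AIC, F and p.
    """
    y = np.asarray(response, dtype=float)
    n = len(curves)
    rows = []
    for k in sorted(candidates):
        if k % 2 == 0 or k < 3:
            raise InfeasibleDimensionError(
                f"candidate dimensions must be odd and >= 3, got {k}"
            )
        if k >= n - 2:
            raise InfeasibleDimensionError(
                f"candidate K={k} infeasible for n={n} observations"
            )
        spec = ModelSpec(response="y", functional_terms=((predictor_name, k),))
        design = build_design({predictor_name: curves}, None, spec)
        fit = fit_sofr(design, y)
        rows.append(
            CriteriaRow(
                n_basis=k,
                r=fit.stats.r,
                aic=fit.stats.aic,
                F=fit.stats.F,
                p_value=fit.stats.p_value,
            )
        )
    return rows


def select_n_basis(table: list[CriteriaRow], rule: str = "compromise") -> int:
    """Pick a basis dimension from a criteria table.

    ``compromise`` (default): among rows with p < 0.05, the smallest K
    whose r is within 0.01 of the table maximum and whose AIC is within
    4 of the table minimum; if no row qualifies, fall back to the
    minimum-AIC row.  ``min_aic``: the minimum-AIC row (ties go to the
    smaller K).
    """
    if not table:
        raise ValueError("empty criteria table")
    rows = sorted(table, key=lambda row: row.n_basis)
    best_aic = min(row.aic for row in rows)
    if rule == "min_aic":
        return min(rows, key=lambda row: (row.aic, row.n_basis)).n_basis
    if rule != "compromise":
        raise ValueError(f"unknown selection rule {rule!r}")
    best_r = max(row.r for row in rows)
    for row in rows:
        if (
            row.p_value < P_MAX
            and row.r >= best_r - R_TOL
            and row.aic <= best_aic + AIC_TOL
        ):
            return row.n_basis
    return min(rows, key=lambda row: (row.aic, row.n_basis)).n_basis


def table_to_frame(table: list[CriteriaRow]) -> pd.DataFrame:
    """Criteria table as a DataFrame with the conventional column layout."""
    return pd.DataFrame(
        {
            "n_basis": [row.n_basis for row in table],
            "r": [row.r for row in table],
            "AIC": [row.aic for row in table],
            "F": [row.F for row in table],
            "p_value": [row.p_value for row in table],
        }
    )
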