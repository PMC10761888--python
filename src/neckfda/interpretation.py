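"""Phase-wise interpretation of a fitted coefficient function.

For an observation with velocity curve x(t), the fitted model predicts
``beta0 + integral(beta1(t) x(t) dt) + scalar terms``.  The product curve
``beta1(t) x(t)`` shows which phases of the movement cycle push the
predicted disability score up (positive regions) or down (negative
regions); the signed areas of those regions decompose the functional
contribution exactly, so the region table is a complete account of the
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from ._exceptions import ConformanceError
from .fourier_basis import BasisCurve, eval_basis, gram_matrix
from .sofr import SOFRFit, predict

__all__ = [
    "Region",
    "ContributionProfile",
    "ProfileComparison",
    "contribution_profile",
    "compare_observations",
    "regions_to_frame",
]

#: Bisection tolerance (in normalized time) for zero-crossing location.
CROSSING_XTOL = 1e-10
#: Default evaluation grid density for crossing bracketing.
DEFAULT_GRID_SIZE = 2001


@dataclass(frozen=True)
class Region:
    """One maximal constant-sign stretch of the product curve."""

    t_start: float
    t_end: float
    signed_area: float
    sign: str  # "positive" | "negative"


@dataclass
class ContributionProfile:
    """Signed-area decomposition of one observation's functional contribution."""

    term: str
    grid: np.ndarray
    product: np.ndarray
    regions: list[Region]
    total_integral: float
    beta0: float
    scalar_contribution: float
    predicted: float

    def product_function(self, t: np.ndarray) -> np.ndarray:
        """Analytic product curve evaluated at arbitrary times."""
        return self._product_fn(np.asarray(t, dtype=float))

    # populated by contribution_profile
    _product_fn: callable = None


def _make_product_fn(fit: SOFRFit, term: str, curve: BasisCurve):
    coef_basis = fit.design.coef_bases[term]
    b = fit.b(term)

    def product(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        beta_vals = eval_basis(coef_basis, t) @ b
        x_vals = eval_basis(curve.basis, t) @ curve.coefs
        return beta_vals * x_vals

    return product


def _find_regions(product, grid: np.ndarray) -> list[Region]:
    """Sign-region decomposition with bisection-refined boundaries.

    Boundaries are the zero crossings of the product curve bracketed on
    the evaluation grid; each region's signed area comes from adaptive
    quadrature of the analytic product.
    """
    vals = product(grid)
    if np.allclose(vals, 0.0, atol=1e-14):
        return []
    # locate crossings between grid points with a strict sign change
    crossings = []
    for i in range(len(grid) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v0 == 0.0:
            crossings.append(grid[i])
        elif v0 * v1 < 0:
            crossings.append(
                brentq(lambda t: float(product(t)[0]), grid[i], grid[i + 1],
                       xtol=CROSSING_XTOL)
            )
    if vals[-1] == 0.0:
        crossings.append(grid[-1])
    bounds = np.unique(np.concatenate([[grid[0]], crossings, [grid[-1]]]))
    regions: list[Region] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < CROSSING_XTOL:
            continue
        area, _ = quad(lambda t: float(product(np.array([t]))[0]), lo, hi,
                       epsabs=1e-12, epsrel=1e-12, limit=200)
        mid_val = float(product(np.array([(lo + hi) / 2.0]))[0])
        regions.append(
            Region(
                t_start=float(lo),
                t_end=float(hi),
                signed_area=float(area),
                sign="positive" if mid_val >= 0 else "negative",
            )
        )
    return regions


def contribution_profile(
    fit: SOFRFit,
    curves: dict[str, BasisCurve],
    scalars: pd.Series | dict | None = None,
    term: str | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> ContributionProfile:
    """Decompose one observation's prediction into signed phase areas.

    ``curves`` maps each functional term's name to that observation's
    curve; ``term`` selects which functional term to profile (defaults
    to the only one).  The scalar contribution (and any other functional
    terms) is reported as a single additive remainder, not folded into
    the curve regions.
    """
    names = list(fit.design.term_slices)
    if term is None:
        if len(names) != 1:
            raise ConformanceError(
                f"fit has functional terms {names}; specify which to profile"
            )
        term = names[0]
    if term not in names:
        raise ConformanceError(f"fit has no functional term {term!r}")
    for name in names:
        if name not in curves:
            raise ConformanceError(f"missing curve for functional term {name!r}")

    scalar_df = None
    if fit.design.spec.scalar_terms:
        if scalars is None:
            raise ConformanceError("fit has scalar terms; scalar values required")
        scalar_df = pd.DataFrame([dict(scalars)])
    predicted = float(
        predict(fit, {name: [curves[name]] for name in names}, scalar_df)[0]
    )

    # additive remainder computed directly from the fitted coefficients:
    # scalar terms plus the exact integrals of any *other* functional terms
    remainder = 0.0
    for sterm, coef in fit.scalar_coefs.items():
        if ":" in sterm:
            a, b_name = sterm.split(":", 1)
            remainder += coef * float(scalars[a]) * float(scalars[b_name])
        else:
            remainder += coef * float(scalars[sterm])
    for other in names:
        if other == term:
            continue
        J = gram_matrix(
            fit.design.coef_bases[other], curves[other].basis
        ).entries
        remainder += float(fit.b(other) @ J @ curves[other].coefs)

    product = _make_product_fn(fit, term, curves[term])
    grid = np.linspace(0.0, 1.0, grid_size)
    regions = _find_regions(product, grid)
    total = float(sum(r.signed_area for r in regions))
    profile = ContributionProfile(
        term=term,
        grid=grid,
        product=product(grid),
        regions=regions,
        total_integral=total,
        beta0=fit.beta0,
        scalar_contribution=remainder,
        predicted=predicted,
    )
    profile._product_fn = product
    return profile


@dataclass
class ProfileComparison:
    """Two observations' profiles with the high-NDI product rescaled."""

    low: ContributionProfile
    high: ContributionProfile
    scale: float
    scaled_high_product: np.ndarray
    #: per-region signed-area differences (low minus scaled high),
    #: integrated over the low observation's regions
    area_differences: list[float]


def compare_observations(
    fit: SOFRFit,
    curves_low: dict[str, BasisCurve],
    curves_high: dict[str, BasisCurve],
    scalars_low=None,
    scalars_high=None,
    scaling: str = "rov_ratio",
    term: str | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> ProfileComparison:
    """Pair two observations' contribution profiles on a common scale.

    With ``scaling="rov_ratio"`` the second (high) observation's product
    curve and areas are multiplied by the ratio of the two velocity
    ranges, so curves of different overall amplitude become comparable
    in shape; ``scaling="none"`` leaves both unscaled.
    """
    low = contribution_profile(fit, curves_low, scalars_low, term, grid_size)
    high = contribution_profile(fit, curves_high, scalars_high, term, grid_size)
    if scaling == "rov_ratio":
        grid = np.linspace(0.0, 1.0, grid_size)
        range_low = np.ptp(curves_low[low.term](grid))
        range_high = np.ptp(curves_high[high.term](grid))
        scale = float(range_low / range_high) if range_high > 0 else 1.0
    elif scaling == "none":
        scale = 1.0
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    scaled_high = scale * high.product
    high_fn = high._product_fn
    diffs = []
    for region in low.regions:
        area, _ = quad(
            lambda t: float(low._product_fn(np.array([t]))[0])
            - scale * float(high_fn(np.array([t]))[0]),
            region.t_start,
            region.t_end,
            epsabs=1e-12,
            epsrel=1e-12,
            limit=200,
        )
        diffs.append(float(area))
    return ProfileComparison(
        low=low,
        high=high,
        scale=scale,
        scaled_high_product=scaled_high,
        area_differences=diffs,
    )


def regions_to_frame(profile: ContributionProfile) -> pd.DataFrame:
    """Region table (t_start, t_end, signed_area, sign) as a DataFrame."""
    return pd.DataFrame(
        {
            "t_start": [r.t_start for r in profile.regions],
            "t_end": [r.t_end for r in profile.regions],
            "signed_area": [r.signed_area for r in profile.regions],
            "sign": [r.sign for r in profile.regions],
        }
    )
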