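"""Scalar-on-function regression by reduction to multiple regression.

The functional linear model with scalar response is

.. math::

    Y_i = \\beta_0 + \\sum_s \\int \\beta_s(t)\\, x_i^{(s)}(t)\\, dt
        + \\sum_r \\beta_r^{(u)} u_{ir} + \\epsilon_i,
    \\qquad \\epsilon_i \\sim N(0, \\sigma^2).

Each functional predictor :math:`x_i(t) = \\sum_r c_{ir}\\psi_r(t)` and each
coefficient function :math:`\\beta(t) = \\sum_s b_s\\theta_s(t)` are expanded
in (possibly different) Fourier bases, so the integral collapses to
:math:`\\sum_{k_1} v_{k_1} b_{k_1}` with v-scores
:math:`v_{k_1} = \\sum_{k_2} c_{ik_2} J_{k_1 k_2}` built from the Gram
matrix :math:`J`.  The model is then an ordinary multiple regression on
``[1, v-scores..., scalar predictors...]`` and is fitted by least
squares.

Model formulas follow the R convention extended with functional terms
written ``name(t)``, e.g. ``"ndi ~ omega(t) + RoV + RoM"`` or
``"ndi ~ RoM + RoV + RoM:RoV"`` (``:`` denotes a pairwise interaction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import (
    CollinearityError,
    ConformanceError,
    FormulaError,
    IncompleteDataError,
    NotNestedError,
    UnderdeterminedFitError,
)
from .fourier_basis import BasisCurve, FourierBasis, SampledCurve, eval_basis, gram_matrix

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "FitStats",
    "SOFRFit",
    "NestedTestResult",
    "parse_formula",
    "build_design",
    "fit_sofr",
    "fit_formula",
    "coefficient_function",
    "predict",
    "nested_f_test",
]

#: Condition number beyond which the design is treated as rank deficient.
COLLINEARITY_COND_MAX = 1e10

#: RSS below this fraction of TSS is numerically a perfect fit.
PERFECT_FIT_RTOL = 1e-12

DEFAULT_COEF_BASIS_SIZE = 9


@dataclass(frozen=True)
class ModelSpec:
    """Which predictors enter the model.

    ``functional_terms`` maps each functional predictor's name to the
    size of the Fourier basis used for its coefficient function.
    ``scalar_terms`` are column names of the scalar table; a name
    containing ``:`` denotes the product of the two named columns.
    """

    response: str
    functional_terms: tuple[tuple[str, int], ...] = ()
    scalar_terms: tuple[str, ...] = ()
    intercept: bool = True

    def __post_init__(self) -> None:
        for term in self.scalar_terms:
            if ":" in term:
                a, b = term.split(":", 1)
                plain = [s for s in self.scalar_terms if ":" not in s]
                if a not in plain or b not in plain:
                    raise FormulaError(
                        f"interaction {term!r} requires both {a!r} and {b!r} "
                        "as main-effect terms"
                    )

    @property
    def label(self) -> str:
        parts = [f"{name}(t)" for name, _ in self.functional_terms]
        parts += list(self.scalar_terms)
        rhs = " + ".join(parts) if parts else "1"
        return f"{self.response} ~ {rhs}"


def parse_formula(
    formula: str, coef_basis_size: int = DEFAULT_COEF_BASIS_SIZE
) -> ModelSpec:
    """Parse an R-style formula with functional terms written ``name(t)``.

    Examples
    --------
    >>> parse_formula("ndi ~ omega(t) + RoV").label
    'ndi ~ omega(t) + RoV'
    """
    if formula.count("~") != 1:
        raise FormulaError(f"formula needs exactly one '~': {formula!r}")
    lhs, rhs = (side.strip() for side in formula.split("~"))
    if not lhs:
        raise FormulaError(f"missing response in {formula!r}")
    functional: list[tuple[str, int]] = []
    scalars: list[str] = []
    rhs = rhs.strip()
    if rhs not in ("", "1"):
        for raw in rhs.split("+"):
            term = raw.strip()
            if not term:
                raise FormulaError(f"empty term in {formula!r}")
            if term.endswith("(t)"):
                functional.append((term[: -len("(t)")], coef_basis_size))
            else:
                scalars.append(term)
    return ModelSpec(
        response=lhs,
        functional_terms=tuple(functional),
        scalar_terms=tuple(scalars),
    )


@dataclass
class DesignMatrix:
    """Regression design: intercept, v-score blocks, scalar columns."""

    X: np.ndarray
    labels: list[str]
    spec: ModelSpec
    coef_bases: dict[str, FourierBasis]
    #: column slice of each functional term's v-score block
    term_slices: dict[str, slice]


def _scalar_column(scalars: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":", 1)
        for name in (a, b):
            if name not in scalars.columns:
                raise IncompleteDataError(f"scalar column {name!r} not found")
        return scalars[a].to_numpy(float) * scalars[b].to_numpy(float)
    if term not in scalars.columns:
        raise IncompleteDataError(f"scalar column {term!r} not found")
    return scalars[term].to_numpy(float)


def build_design(
    curves: dict[str, list[BasisCurve]],
    scalars: pd.DataFrame | None,
    spec: ModelSpec,
    coef_bases: dict[str, FourierBasis] | None = None,
) -> DesignMatrix:
    """Assemble the multiple-regression design from curves and scalars.

    For each functional term the v-scores are ``c @ J.T`` where ``c``
    stacks the observations' curve coefficients and ``J`` is the Gram
    matrix between the coefficient basis and the curve basis.
    """
    n = None
    if spec.functional_terms:
        name0 = spec.functional_terms[0][0]
        if name0 not in curves:
            raise IncompleteDataError(f"functional predictor {name0!r} not supplied")
        n = len(curves[name0])
    if n is None and scalars is not None:
        n = len(scalars)
    if n is None:
        raise IncompleteDataError("no data supplied")

    coef_bases = dict(coef_bases or {})
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    labels = ["(Intercept)"]
    term_slices: dict[str, slice] = {}
    col = 1
    for name, k_beta in spec.functional_terms:
        if name not in curves:
            raise IncompleteDataError(f"functional predictor {name!r} not supplied")
        obs = curves[name]
        if len(obs) != n:
            raise IncompleteDataError(
                f"functional predictor {name!r} has {len(obs)} observations, "
                f"expected {n}"
            )
        curve_basis = obs[0].basis
        coef_basis = coef_bases.setdefault(
            name, FourierBasis(k_beta, curve_basis.period)
        )
        J = gram_matrix(coef_basis, curve_basis).entries
        C = np.stack([bc.coefs for bc in obs])  # (n, K_x)
        V = C @ J.T  # (n, K_beta)
        blocks.append(V)
        labels += [f"{name}.v{j + 1}" for j in range(coef_basis.n_funcs)]
        term_slices[name] = slice(col, col + coef_basis.n_funcs)
        col += coef_basis.n_funcs
    for term in spec.scalar_terms:
        if scalars is None:
            raise IncompleteDataError(f"scalar table required for term {term!r}")
        if len(scalars) != n:
            raise IncompleteDataError(
                f"scalar table has {len(scalars)} rows, expected {n}"
            )
        colvals = _scalar_column(scalars, term)
        if np.any(~np.isfinite(colvals)):
            raise IncompleteDataError(f"non-finite values in scalar term {term!r}")
        blocks.append(colvals[:, None])
        labels.append(term)
        col += 1
    X = np.hstack(blocks)
    if not np.all(np.isfinite(X)):
        raise IncompleteDataError("design matrix contains non-finite entries")
    return DesignMatrix(
        X=X, labels=labels, spec=spec, coef_bases=coef_bases, term_slices=term_slices
    )


@dataclass(frozen=True)
class FitStats:
    """Goodness-of-fit summary of one model."""

    r: float
    r2: float
    F: float
    df1: int
    df2: int
    p_value: float
    aic: float
    loglik: float
    n: int
    n_params: int

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "R2": self.r2,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "AIC": self.aic,
            "loglik": self.loglik,
            "n": self.n,
            "n_params": self.n_params,
        }


@dataclass
class SOFRFit:
    """A fitted scalar-on-function regression model."""

    design: DesignMatrix
    response: np.ndarray
    coefs: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    sigma2_hat: float
    stats: FitStats

    @property
    def beta0(self) -> float:
        """Intercept, in response (NDI) units."""
        return float(self.coefs[0])

    def b(self, term: str) -> np.ndarray:
        """Coefficient-function basis coefficients of a functional term."""
        if term not in self.design.term_slices:
            raise KeyError(f"no functional term {term!r} in this fit")
        return self.coefs[self.design.term_slices[term]]

    @property
    def scalar_coefs(self) -> dict[str, float]:
        out = {}
        for term in self.design.spec.scalar_terms:
            j = self.design.labels.index(term)
            out[term] = float(self.coefs[j])
        return out

    def summary(self) -> dict:
        """JSON-serializable fit summary."""
        return {
            "model": self.design.spec.label,
            "beta0": self.beta0,
            "scalar_coefs": self.scalar_coefs,
            "functional_terms": {
                name: self.b(name).tolist() for name in self.design.term_slices
            },
            "sigma2_hat": self.sigma2_hat,
            **self.stats.to_dict(),
        }


def _gaussian_ml_loglik(n: int, rss: float) -> float:
    """Maximized Gaussian log-likelihood with the ML variance RSS/n."""
    if rss <= 0:  # perfect fit: likelihood unbounded; report +inf loglik
        return math.inf
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def fit_sofr(design: DesignMatrix, response: np.ndarray) -> SOFRFit:
    """Ordinary least squares on the reduced design, with all fit statistics.

    AIC follows the Gaussian maximum-likelihood convention: minus twice
    the maximized log-likelihood (variance estimated as RSS/n) plus twice
    the number of parameters, counting the variance as one parameter.
    """
    y = np.asarray(response, dtype=float)
    X = design.X
    n, p_full = X.shape
    if y.shape != (n,):
        raise ConformanceError(f"response has shape {y.shape}, expected ({n},)")
    # Columns that are numerically zero carry no information and make the
    # model unidentifiable in that coordinate (e.g. the constant Fourier
    # component of a periodic velocity, which is structurally zero).  As
    # R's lm does with aliased terms, drop them and base every degree of
    # freedom on the effective parameter count; their coefficients are 0.
    norms = np.linalg.norm(X, axis=0)
    keep = norms > 1e-10 * norms.max()
    keep[0] = True  # intercept always stays
    Xk = X[:, keep]
    p = Xk.shape[1]
    if n <= p:
        raise UnderdeterminedFitError(
            f"{n} observations cannot identify {p} regression coefficients"
        )
    cond = np.linalg.cond(Xk)
    if cond > COLLINEARITY_COND_MAX:
        # locate dependent columns for the error message
        kept_labels = [l for l, k in zip(design.labels, keep) if k]
        _, R = np.linalg.qr(Xk)
        diag = np.abs(np.diag(R))
        bad = [kept_labels[j] for j in np.nonzero(diag < 1e-8 * diag.max())[0]]
        raise CollinearityError(
            f"design matrix is ill conditioned (cond={cond:.3g}); "
            f"suspect columns: {bad or 'unknown'}"
        )
    coefs_k, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    coefs = np.zeros(p_full)
    coefs[keep] = coefs_k
    fitted = X @ coefs
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    q = p - 1  # non-intercept parameters
    df2 = n - p
    perfect = tss > 0 and rss <= PERFECT_FIT_RTOL * tss
    if tss > 0:
        r2 = 1.0 if perfect else max(0.0, 1.0 - rss / tss)
    else:
        r2 = 0.0
    if q == 0 or tss == 0:
        F, pval = 0.0, 1.0
    elif perfect:
        F, pval = math.inf, 0.0
    else:
        F = (r2 / q) / ((1.0 - r2) / df2)
        pval = float(stats.f.sf(F, q, df2))
    loglik = _gaussian_ml_loglik(n, 0.0 if perfect else rss)
    aic = -2.0 * loglik + 2.0 * (p + 1)
    return SOFRFit(
        design=design,
        response=y,
        coefs=coefs,
        fitted=fitted,
        residuals=resid,
        rss=rss,
        sigma2_hat=rss / df2 if df2 > 0 else math.nan,
        stats=FitStats(
            r=math.sqrt(r2),
            r2=r2,
            F=F,
            df1=q,
            df2=df2,
            p_value=pval,
            aic=aic,
            loglik=loglik,
            n=n,
            n_params=p,
        ),
    )


def fit_formula(
    formula: str,
    curves: dict[str, list[BasisCurve]],
    scalars: pd.DataFrame,
    coef_basis_size: int = DEFAULT_COEF_BASIS_SIZE,
    coef_bases: dict[str, FourierBasis] | None = None,
) -> SOFRFit:
    """Convenience wrapper: parse, build the design, and fit."""
    spec = parse_formula(formula, coef_basis_size)
    if spec.response not in scalars.columns:
        raise IncompleteDataError(f"response column {spec.response!r} not found")
    design = build_design(curves, scalars, spec, coef_bases)
    return fit_sofr(design, scalars[spec.response].to_numpy(float))


def coefficient_function(
    fit: SOFRFit, term: str, grid: np.ndarray
) -> SampledCurve:
    """Reconstruct the coefficient function beta(t) of a functional term."""
    b = fit.b(term)  # raises KeyError for unknown terms
    basis = fit.design.coef_bases[term]
    values = eval_basis(basis, grid) @ b
    return SampledCurve(
        grid=np.asarray(grid, dtype=float), values=values, role="coefficient"
    )


def predict(
    fit: SOFRFit,
    new_curves: dict[str, list[BasisCurve]] | None = None,
    new_scalars: pd.DataFrame | None = None,
) -> np.ndarray:
    """Predicted response for new observations under the fitted model."""
    try:
        design = build_design(
            new_curves or {}, new_scalars, fit.design.spec, fit.design.coef_bases
        )
    except IncompleteDataError as exc:
        raise ConformanceError(str(exc)) from exc
    if design.X.shape[1] != fit.design.X.shape[1]:
        raise ConformanceError("new data produce a different design width")
    return design.X @ fit.coefs


@dataclass(frozen=True)
class NestedTestResult:
    """F test of a simple model against a nesting complex model."""

    F: float
    df1: int
    df2: int
    p_value: float
    simple_label: str
    complex_label: str

    def to_dict(self) -> dict:
        return {
            "simple": self.simple_label,
            "complex": self.complex_label,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
        }


def nested_f_test(simple: SOFRFit, complex: SOFRFit) -> NestedTestResult:
    """Extra-sum-of-squares F test between two nested OLS fits.

    The null hypothesis is that every coefficient present in the complex
    model but not in the simple one is zero;
    ``F = ((RSS_0 - RSS_1)/df1) / (RSS_1/df2)`` with
    ``df1`` the parameter-count difference and ``df2 = n - p_complex``.
    """
    if simple.stats.n != complex.stats.n or not np.allclose(
        simple.response, complex.response
    ):
        raise NotNestedError("models were fitted to different responses")
    simple_cols = set(simple.design.labels)
    complex_cols = set(complex.design.labels)
    if not simple_cols < complex_cols:
        raise NotNestedError(
            f"{simple.design.spec.label!r} is not strictly nested in "
            f"{complex.design.spec.label!r}"
        )
    n = complex.stats.n
    df1 = complex.stats.n_params - simple.stats.n_params
    df2 = n - complex.stats.n_params
    if complex.rss == 0.0:
        F, p = math.inf, 0.0
    else:
        F = ((simple.rss - complex.rss) / df1) / (complex.rss / df2)
        F = max(0.0, F)
        p = float(stats.f.sf(F, df1, df2))
    return NestedTestResult(
        F=F,
        df1=df1,
        df2=df2,
        p_value=p,
        simple_label=simple.design.spec.label,
        complex_label=complex.design.spec.label,
    )
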