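"""Truncated Fourier bases on the normalized movement cycle.

A periodic kinematic curve sampled over one flexion-extension cycle is
represented by a small number of Fourier coefficients.  The basis is the
orthonormal system on ``[0, period]``

.. math::

    \\left\\{ \\tfrac{1}{\\sqrt{P}},\\;
    \\sqrt{\\tfrac{2}{P}}\\sin(k\\omega t),\\;
    \\sqrt{\\tfrac{2}{P}}\\cos(k\\omega t) \\right\\}_{k \\ge 1},
    \\qquad \\omega = 2\\pi / P,

ordered ``[constant, sin(1), cos(1), sin(2), cos(2), ...]``.  Orthonormal
scaling makes the self inner-product (Gram) matrix the identity, which
collapses the functional-regression inner products to plain dot products
of coefficient vectors.  The unnormalized listing ``{1, sin, cos, ...}``
common in textbooks differs only by an invertible diagonal rescaling of
the coefficients; any reconstructed *function* is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import (
    DomainMismatchError,
    InvalidBasisError,
    UnderdeterminedFitError,
    UnsupportedDerivativeError,
)

__all__ = [
    "FourierBasis",
    "SampledCurve",
    "BasisCurve",
    "GramMatrix",
    "make_basis",
    "eval_basis",
    "gram_matrix",
    "expand_curve",
    "reconstruct",
    "inner_product",
]


@dataclass(frozen=True)
class FourierBasis:
    """Orthonormal truncated Fourier system: constant plus sine/cosine pairs.

    Parameters
    ----------
    n_funcs
        Odd number of basis functions ``K`` (1 constant + (K-1)/2 pairs).
    period
        Length of the fundamental cycle; 1.0 for time-normalized cycles.
    """

    n_funcs: int
    period: float = 1.0

    def __post_init__(self) -> None:
        if int(self.n_funcs) != self.n_funcs or self.n_funcs < 1:
            raise InvalidBasisError(
                f"n_funcs must be a positive integer, got {self.n_funcs!r}"
            )
        if self.n_funcs % 2 == 0:
            raise InvalidBasisError(
                f"n_funcs must be odd (a constant plus whole sine/cosine "
                f"pairs), got {self.n_funcs}"
            )
        if not (self.period > 0):
            raise InvalidBasisError(f"period must be positive, got {self.period!r}")

    @property
    def fundamental_freq(self) -> float:
        """Angular frequency of the first harmonic, ``2*pi/period``."""
        return 2.0 * np.pi / self.period

    @property
    def n_pairs(self) -> int:
        return (self.n_funcs - 1) // 2


@dataclass
class SampledCurve:
    """A function observed on a (normalized) time grid.

    ``role`` tags the physical quantity: ``"angle"`` (degrees) or
    ``"angular_velocity"`` (degrees/second).
    """

    grid: np.ndarray
    values: np.ndarray
    role: str = "angle"
    units: str = "deg"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.values.ndim != 1:
            raise ValueError("grid and values must be 1-D")
        if self.grid.size != self.values.size:
            raise ValueError(
                f"grid ({self.grid.size}) and values ({self.values.size}) "
                "must have equal length"
            )
        if self.grid.size < 2:
            raise ValueError("a sampled curve needs at least 2 points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def range(self) -> float:
        """Max-minus-min of the values (RoM for angle, RoV for velocity)."""
        return float(np.max(self.values) - np.min(self.values))


@dataclass
class BasisCurve:
    """A curve represented by coefficients in a :class:`FourierBasis`."""

    basis: FourierBasis
    coefs: np.ndarray
    role: str = "angle"

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float)
        if self.coefs.shape != (self.basis.n_funcs,):
            raise ValueError(
                f"coefs must have length {self.basis.n_funcs}, "
                f"got shape {self.coefs.shape}"
            )

    def __call__(self, grid: np.ndarray, deriv_order: int = 0) -> np.ndarray:
        return eval_basis(self.basis, grid, deriv_order) @ self.coefs


@dataclass(frozen=True)
class GramMatrix:
    """Pairwise inner products between two Fourier systems on one period."""

    row_basis: FourierBasis
    col_basis: FourierBasis
    entries: np.ndarray = field(repr=False)


def make_basis(n_funcs: int, period: float = 1.0) -> FourierBasis:
    """Construct an orthonormal Fourier basis.

    Examples
    --------
    >>> b = make_basis(9, 1.0)   # constant + four sine/cosine pairs
    >>> b.n_pairs
    4
    """
    return FourierBasis(n_funcs=n_funcs, period=period)


def eval_basis(
    basis: FourierBasis, grid: np.ndarray, deriv_order: int = 0
) -> np.ndarray:
    """Evaluate all basis functions (or their first derivative) on a grid.

    Returns an ``(len(grid), n_funcs)`` matrix, one column per basis
    function in the fixed ordering ``[const, sin1, cos1, sin2, cos2, ...]``.
    """
    if deriv_order not in (0, 1):
        raise UnsupportedDerivativeError(
            f"deriv_order must be 0 or 1, got {deriv_order}"
        )
    t = np.atleast_1d(np.asarray(grid, dtype=float))
    P = basis.period
    out = np.empty((t.size, basis.n_funcs))
    amp = np.sqrt(2.0 / P)
    if deriv_order == 0:
        out[:, 0] = 1.0 / np.sqrt(P)
    else:
        out[:, 0] = 0.0
    for k in range(1, basis.n_pairs + 1):
        w = k * basis.fundamental_freq
        if deriv_order == 0:
            out[:, 2 * k - 1] = amp * np.sin(w * t)
            out[:, 2 * k] = amp * np.cos(w * t)
        else:
            out[:, 2 * k - 1] = amp * w * np.cos(w * t)
            out[:, 2 * k] = -amp * w * np.sin(w * t)
    return out


def gram_matrix(row_basis: FourierBasis, col_basis: FourierBasis) -> GramMatrix:
    """Inner-product matrix between two orthonormal Fourier bases.

    For orthonormal systems sharing a period the closed form is the
    identity padded with zeros to shape ``(Ka, Kb)``.
    """
    if row_basis.period != col_basis.period:
        raise DomainMismatchError(
            f"incompatible periods {row_basis.period} != {col_basis.period}"
        )
    entries = np.eye(row_basis.n_funcs, col_basis.n_funcs)
    return GramMatrix(row_basis=row_basis, col_basis=col_basis, entries=entries)


def expand_curve(curve: SampledCurve, basis: FourierBasis) -> BasisCurve:
    """Least-squares expansion of a sampled curve into basis coefficients.

    The coefficients minimize the sum of squared residuals between the
    basis reconstruction and the samples on the curve's own grid; no
    roughness penalty is applied (a low-dimensional basis controls
    smoothness instead).
    """
    if curve.grid.size <= basis.n_funcs:
        raise UnderdeterminedFitError(
            f"{curve.grid.size} samples cannot determine {basis.n_funcs} "
            "coefficients; supply more samples or a smaller basis"
        )
    Phi = eval_basis(basis, curve.grid)
    coefs, *_ = np.linalg.lstsq(Phi, curve.values, rcond=None)
    return BasisCurve(basis=basis, coefs=coefs, role=curve.role)


def reconstruct(
    curve: BasisCurve, grid: np.ndarray, deriv_order: int = 0
) -> SampledCurve:
    """Evaluate a basis-represented curve (or its derivative) on a grid."""
    values = eval_basis(curve.basis, grid, deriv_order) @ curve.coefs
    role = curve.role
    return SampledCurve(
        grid=np.asarray(grid, dtype=float), values=values, role=role
    )


def inner_product(f: BasisCurve, g: BasisCurve) -> float:
    """:math:`\\int f(t) g(t)\\,dt` over one period via the Gram matrix."""
    J = gram_matrix(f.basis, g.basis).entries
    return float(f.coefs @ J @ g.coefs)
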