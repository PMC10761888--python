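"""Cycle segmentation and per-observation curve preprocessing.

A measurement session yields one continuous multi-cycle record of the
neck flexion-extension angle.  The record is segmented into complete
cycles at successive maxima of extension (with flexion positive, these
are local minima of the angle), the first and last complete cycles are
discarded as warm-up/wind-down, each retained cycle is linearly
time-normalized to the unit interval and resampled onto a common uniform
grid, angular velocity is obtained by analytic differentiation of a
Fourier expansion of the angle, and the functional mean over retained
cycles produces the observation's angle and velocity curves.  RoM and
RoV are the max-minus-min of those mean curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._exceptions import (
    DegenerateCycleError,
    GridMismatchError,
    InsufficientCyclesError,
)
from .fourier_basis import FourierBasis, SampledCurve, expand_curve, reconstruct

__all__ = [
    "ContinuousRecord",
    "CycleSet",
    "ObservationKinematics",
    "segment_cycles",
    "normalize_time",
    "compute_velocity",
    "functional_mean",
    "compute_ranges",
    "preprocess_record",
    "DEFAULT_GRID_SIZE",
    "DEFAULT_EXPANSION_SIZE",
]

#: Points on the common normalized grid (percent-of-cycle resolution).
DEFAULT_GRID_SIZE = 101
#: Fourier functions used to expand each angle cycle before differentiation.
DEFAULT_EXPANSION_SIZE = 21

#: Minimum peak separation, as a fraction of the median inter-peak interval.
MIN_SEPARATION_FRAC = 0.25
#: Minimum peak prominence, as a fraction of the record's angle range.
PROMINENCE_FRAC = 0.10


@dataclass
class ContinuousRecord:
    """One continuous multi-cycle angle record for a subject/session."""

    subject_id: str
    session: str
    time_s: np.ndarray
    angle_deg: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if self.time_s.shape != self.angle_deg.shape:
            raise ValueError("time_s and angle_deg must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")


@dataclass
class CycleSet:
    """Retained, normalized cycles extracted from one continuous record."""

    cycles: list[SampledCurve]
    durations_s: np.ndarray
    n_recorded: int
    n_retained: int


@dataclass
class ObservationKinematics:
    """Per-observation functional means and scalar range summaries."""

    subject_id: str
    session: str
    mean_angle: SampledCurve
    mean_velocity: SampledCurve
    rom_deg: float = field(default=np.nan)
    rov_dps: float = field(default=np.nan)


def _cycle_boundaries(record: ContinuousRecord) -> np.ndarray:
    """Sample indices of cycle starts (maxima of extension = angle minima)."""
    a = record.angle_deg
    rng = np.max(a) - np.min(a)
    prominence = PROMINENCE_FRAC * rng
    # Two passes: a first detection fixes the typical inter-peak interval,
    # the second enforces the minimum separation derived from it.
    idx, _ = find_peaks(-a, prominence=prominence)
    if idx.size >= 3:
        median_gap = np.median(np.diff(idx))
        distance = max(1, int(round(MIN_SEPARATION_FRAC * median_gap)))
        idx, _ = find_peaks(-a, prominence=prominence, distance=distance)
    if idx.size == 0:
        return idx
    # A record that starts or ends at maximum extension has boundary
    # samples at its endpoints, which find_peaks cannot flag; accept them
    # when their angle sits at the level of the detected minima.
    level = np.median(a[idx]) + PROMINENCE_FRAC * rng
    if a[0] <= level and idx[0] > 1:
        idx = np.concatenate([[0], idx])
    if a[-1] <= level and idx[-1] < a.size - 2:
        idx = np.concatenate([idx, [a.size - 1]])
    return idx


def segment_cycles(
    record: ContinuousRecord,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> CycleSet:
    """Split a continuous record into cycles and drop the first and last.

    A record with ``k`` complete detected cycles retains ``k - 2``; fewer
    than 3 detected cycles is an error.  Each retained cycle is returned
    already time-normalized onto the common uniform grid.
    """
    idx = _cycle_boundaries(record)
    n_recorded = max(0, idx.size - 1)
    if n_recorded < 3:
        raise InsufficientCyclesError(n_recorded)
    cycles: list[SampledCurve] = []
    durations: list[float] = []
    for i in range(1, n_recorded - 1):  # discard first and last complete cycle
        lo, hi = idx[i], idx[i + 1]
        t = record.time_s[lo : hi + 1]
        a = record.angle_deg[lo : hi + 1]
        cycles.append(normalize_time(t, a, grid_size=grid_size))
        durations.append(float(t[-1] - t[0]))
    return CycleSet(
        cycles=cycles,
        durations_s=np.asarray(durations),
        n_recorded=n_recorded,
        n_retained=n_recorded - 2,
    )


def normalize_time(
    time_s: np.ndarray,
    angle_deg: np.ndarray,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> SampledCurve:
    """Affinely map one cycle's time axis to [0, 1] and resample.

    Values are unchanged; the curve is linearly interpolated onto a
    uniform grid of ``grid_size`` points spanning exactly [0, 1].
    """
    t = np.asarray(time_s, dtype=float)
    a = np.asarray(angle_deg, dtype=float)
    duration = t[-1] - t[0]
    if duration <= 0:
        raise DegenerateCycleError(f"cycle duration must be positive, got {duration}")
    t_norm = (t - t[0]) / duration
    grid = np.linspace(0.0, 1.0, grid_size)
    return SampledCurve(grid=grid, values=np.interp(grid, t_norm, a), role="angle")


def compute_velocity(
    cycle: SampledCurve,
    duration_s: float,
    expansion_basis: FourierBasis | None = None,
) -> SampledCurve:
    """Angular velocity of a normalized angle cycle, in degrees/second.

    The angle is expanded in a Fourier basis and differentiated
    analytically with respect to normalized time; dividing by the cycle
    duration restores physical units (chain rule).
    """
    if duration_s <= 0:
        raise DegenerateCycleError(
            f"duration_s must be positive, got {duration_s}"
        )
    basis = expansion_basis or FourierBasis(DEFAULT_EXPANSION_SIZE)
    bc = expand_curve(cycle, basis)
    deriv = reconstruct(bc, cycle.grid, deriv_order=1)
    return SampledCurve(
        grid=cycle.grid,
        values=deriv.values / duration_s,
        role="angular_velocity",
        units="deg/s",
    )


def functional_mean(cycles: list[SampledCurve]) -> SampledCurve:
    """Pointwise arithmetic mean of curves sharing an identical grid."""
    if not cycles:
        raise ValueError("functional_mean needs at least one curve")
    grid = cycles[0].grid
    for c in cycles[1:]:
        if c.grid.shape != grid.shape or not np.array_equal(c.grid, grid):
            raise GridMismatchError("curves are not on a common grid")
    values = np.mean([c.values for c in cycles], axis=0)
    return SampledCurve(
        grid=grid, values=values, role=cycles[0].role, units=cycles[0].units
    )


def compute_ranges(
    mean_angle: SampledCurve, mean_velocity: SampledCurve
) -> tuple[float, float]:
    """(RoM, RoV): max-minus-min of the mean angle and velocity curves."""
    return mean_angle.range, mean_velocity.range


def preprocess_record(
    record: ContinuousRecord,
    grid_size: int = DEFAULT_GRID_SIZE,
    expansion_basis: FourierBasis | None = None,
) -> ObservationKinematics:
    """Full per-observation chain: segment, normalize, differentiate, average.

    Velocity is computed per retained cycle with that cycle's own
    duration before averaging, so duration jitter between cycles does not
    bias the mean velocity curve.
    """
    cs = segment_cycles(record, grid_size=grid_size)
    velocities = [
        compute_velocity(c, d, expansion_basis)
        for c, d in zip(cs.cycles, cs.durations_s)
    ]
    mean_angle = functional_mean(cs.cycles)
    mean_velocity = functional_mean(velocities)
    rom, rov = compute_ranges(mean_angle, mean_velocity)
    return ObservationKinematics(
        subject_id=record.subject_id,
        session=record.session,
        mean_angle=mean_angle,
        mean_velocity=mean_velocity,
        rom_deg=rom,
        rov_dps=rov,
    )
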