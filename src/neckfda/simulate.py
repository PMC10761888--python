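"""Synthetic flexion-extension kinematics with a known functional signal.

Real cyclic neck movement records are not publicly deposited, so this
module generates records with the statistical structure the analysis
assumes and with exact ground truth for recovery and calibration tests.

Each observation (a subject/session) has a smooth periodic angle cycle

.. math::

    s(\\tau) = \\tfrac{ROM_i}{2}\\Big[-\\cos(2\\pi\\tau)
        + \\sum_{k=2}^{4} d_{ik} \\sin(2\\pi k\\tau + \\phi_{ik})\\Big],

a fundamental cosine (maximum extension at the cycle start, flexion
positive) distorted by three small random harmonics that give every
subject an individual movement shape.  The continuous record repeats
this cycle with per-cycle duration jitter and additive measurement
noise.  The disability response follows the functional linear model

.. math::

    NDI_i = \\beta_0 + \\int \\beta_1(t)\\,\\omega_i(t)\\,dt + \\epsilon_i,

where :math:`\\omega_i` is the noiseless angular-velocity curve
(computed analytically, never from the sampled record), and the score
is rounded to an integer and clipped to the instrument's 0-50 range.
Because both :math:`\\omega_i` and :math:`\\beta_1` live in the K=9
orthonormal Fourier span, the integral is an exact dot product of
coefficient vectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fourier_basis import BasisCurve, FourierBasis
from .preprocess import (
    DEFAULT_GRID_SIZE,
    ContinuousRecord,
    ObservationKinematics,
    preprocess_record,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_record",
    "generate_dataset",
    "generate_null_dataset",
    "expand_observations",
    "DEFAULT_TRUE_B",
]

logger = logging.getLogger(__name__)

N_GEN_BASIS = 9  # generating harmonics 1..4 live in the K=9 span

#: Default generating coefficient function beta1 in the orthonormal K=9
#: basis (ordering const, sin1, cos1, sin2, cos2, sin3, cos3, sin4, cos4).
#: Weight sits on the distortion harmonics (2 and 3), so the signal comes
#: from individual movement *shape*, not overall amplitude; the implied
#: contribution spread is several NDI points.
DEFAULT_TRUE_B = np.array([0.0, 0.0, 0.0, 0.25, 0.25, 0.10, 0.10, 0.0, 0.0])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a two-session cohort of 28 subjects (56
    observations), ~120 degree flexion-extension amplitude, ~2 s
    self-paced cycles, 7 recorded cycles per session at 100 Hz, and a
    response centered at the fitted intercept scale of the disability
    index.
    """

    n_subjects: int = 28
    sessions_per_subject: int = 2
    cycles_per_record: int = 7
    sample_rate_hz: float = 100.0
    mean_rom_deg: float = 120.0
    rom_sd_deg: float = 15.0
    cycle_duration_s: float = 2.0
    cycle_duration_sd_s: float = 0.3
    cycle_jitter_rel: float = 0.02
    harmonic_distortion_sd: float = 0.05
    measurement_noise_sd_deg: float = 0.5
    true_beta0: float = 14.95
    true_b: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_B.copy())
    response_noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_b", np.asarray(self.true_b, dtype=float))
        if self.true_b.shape != (N_GEN_BASIS,):
            raise ValueError(f"true_b must have length {N_GEN_BASIS}")
        for name in (
            "rom_sd_deg",
            "cycle_duration_sd_s",
            "cycle_jitter_rel",
            "harmonic_distortion_sd",
            "measurement_noise_sd_deg",
            "response_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cycles_per_record < 3:
            raise ValueError("cycles_per_record must be >= 3")
        if self.n_subjects < 1 or self.sessions_per_subject not in (1, 2):
            raise ValueError("need n_subjects >= 1 and 1 or 2 sessions")
        if self.sample_rate_hz <= 0 or self.cycle_duration_s <= 0:
            raise ValueError("sample_rate_hz and cycle_duration_s must be > 0")

    @property
    def n_observations(self) -> int:
        return self.n_subjects * self.sessions_per_subject


@dataclass
class _ObsParams:
    """Latent per-observation movement parameters."""

    subject_id: str
    session: str
    rom: float
    duration: float
    d: np.ndarray  # distortion amplitudes, harmonics 2..4
    phi: np.ndarray  # distortion phases, harmonics 2..4
    eps: float  # response noise draw


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would estimate."""

    true_beta0: float
    true_b: np.ndarray
    basis: FourierBasis
    true_integrals: np.ndarray  # per-observation integral beta1*omega
    linear_predictor: np.ndarray  # beta0 + integral, before noise/rounding
    omega_coefs: np.ndarray  # (n, 9) noiseless velocity coefficients
    angle_coefs: np.ndarray  # (n, 9) noiseless angle coefficients


@dataclass
class SyntheticStudy:
    """A generated cohort, with or without raw records."""

    config: GeneratorConfig
    scalars: pd.DataFrame  # subject_id, session, ndi, RoM, RoV
    curves: dict[str, list[BasisCurve]]  # analytic "omega" and "phi"
    ground_truth: GroundTruth
    records: list[ContinuousRecord] | None = None
    observations: list[ObservationKinematics] | None = None


def _angle_shape(rom: float, d: np.ndarray, phi: np.ndarray, tau: np.ndarray):
    """Noiseless within-cycle angle at phase tau in [0, 1]."""
    a = -np.cos(2.0 * np.pi * tau)
    for j, k in enumerate(range(2, 5)):
        a = a + d[j] * np.sin(2.0 * np.pi * k * tau + phi[j])
    return 0.5 * rom * a


def _analytic_coefs(p: _ObsParams) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal K=9 coefficients of the angle and velocity curves.

    In the orthonormal basis on [0,1] a value-amplitude A on sin(2*pi*k*t)
    or cos(2*pi*k*t) corresponds to a coefficient A/sqrt(2).
    """
    half = 0.5 * p.rom
    angle = np.zeros(N_GEN_BASIS)
    omega = np.zeros(N_GEN_BASIS)
    s2 = math.sqrt(2.0)
    # fundamental: angle -half*cos(2 pi t); velocity half*2*pi*sin(2 pi t)/T
    angle[2] = -half / s2
    omega[1] = half * 2.0 * math.pi / (p.duration * s2)
    for j, k in enumerate(range(2, 5)):
        amp = half * p.d[j]
        # angle: amp*sin(2 pi k t + phi) = amp*cos(phi)*sin + amp*sin(phi)*cos
        angle[2 * k - 1] = amp * math.cos(p.phi[j]) / s2
        angle[2 * k] = amp * math.sin(p.phi[j]) / s2
        # velocity: amp*2*pi*k*cos(2 pi k t + phi)/T
        w = amp * 2.0 * math.pi * k / p.duration
        omega[2 * k] = w * math.cos(p.phi[j]) / s2
        omega[2 * k - 1] = -w * math.sin(p.phi[j]) / s2
    return angle, omega


def _draw_params(config: GeneratorConfig, rng: np.random.Generator):
    params: list[_ObsParams] = []
    sessions = ["before", "after"][: config.sessions_per_subject]
    for s in range(config.n_subjects):
        for sess in sessions:
            rom = max(10.0, rng.normal(config.mean_rom_deg, config.rom_sd_deg))
            dur = max(0.5, rng.normal(config.cycle_duration_s, config.cycle_duration_sd_s))
            d = rng.normal(0.0, config.harmonic_distortion_sd, size=3)
            phi = rng.uniform(0.0, 2.0 * np.pi, size=3)
            eps = rng.normal(0.0, config.response_noise_sd)
            params.append(
                _ObsParams(
                    subject_id=f"S{s + 1:02d}",
                    session=sess,
                    rom=rom,
                    duration=dur,
                    d=d,
                    phi=phi,
                    eps=eps,
                )
            )
    return params


def generate_record(
    p: _ObsParams, config: GeneratorConfig, rng: np.random.Generator
) -> ContinuousRecord:
    """Sample one continuous multi-cycle record for an observation.

    Cycles share the observation's shape; durations jitter around the
    observation's nominal cycle duration, and i.i.d. Gaussian measurement
    noise is added to every sample.
    """
    dt = 1.0 / config.sample_rate_hz
    durations = p.duration * (
        1.0 + rng.normal(0.0, config.cycle_jitter_rel, size=config.cycles_per_record)
    )
    durations = np.maximum(durations, 0.2)
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    total = starts[-1]
    t = np.arange(0.0, total, dt)
    cycle_idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0,
                        config.cycles_per_record - 1)
    tau = (t - starts[cycle_idx]) / durations[cycle_idx]
    angle = _angle_shape(p.rom, p.d, p.phi, tau)
    if config.measurement_noise_sd_deg > 0:
        angle = angle + rng.normal(0.0, config.measurement_noise_sd_deg, size=t.size)
    return ContinuousRecord(
        subject_id=p.subject_id, session=p.session, time_s=t, angle_deg=angle
    )


def generate_dataset(
    config: GeneratorConfig,
    curves_only: bool = False,
    round_scores: bool = True,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> SyntheticStudy:
    """Generate a full synthetic cohort.

    Parameters
    ----------
    curves_only
        Skip raw-record synthesis and preprocessing; the study then
        carries only the analytic basis curves (much faster — used for
        large calibration studies).
    round_scores
        Round responses to integers and clip to [0, 50] as the real
        instrument does; disable for exact-recovery experiments.

    The observation-level draws happen before any record sampling, so
    the analytic curves and responses are identical for a given seed
    whether or not records are generated.
    """
    rng = np.random.default_rng(config.seed)
    params = _draw_params(config, rng)
    basis = FourierBasis(N_GEN_BASIS)
    n = len(params)
    angle_coefs = np.zeros((n, N_GEN_BASIS))
    omega_coefs = np.zeros((n, N_GEN_BASIS))
    for i, p in enumerate(params):
        angle_coefs[i], omega_coefs[i] = _analytic_coefs(p)
    integrals = omega_coefs @ config.true_b
    linpred = config.true_beta0 + integrals
    raw = linpred + np.array([p.eps for p in params])
    if round_scores:
        ndi = np.clip(np.round(raw), 0.0, 50.0)
        n_clipped = int(np.sum((raw < -0.5) | (raw > 50.5)))
        if n_clipped > 0.2 * n:
            logger.warning(
                "%d/%d responses clipped to [0, 50]; the response "
                "distribution is badly placed", n_clipped, n,
            )
    else:
        ndi = raw

    curves = {
        "omega": [
            BasisCurve(basis=basis, coefs=omega_coefs[i], role="angular_velocity")
            for i in range(n)
        ],
        "phi": [
            BasisCurve(basis=basis, coefs=angle_coefs[i], role="angle")
            for i in range(n)
        ],
    }
    truth = GroundTruth(
        true_beta0=config.true_beta0,
        true_b=config.true_b.copy(),
        basis=basis,
        true_integrals=integrals,
        linear_predictor=linpred,
        omega_coefs=omega_coefs,
        angle_coefs=angle_coefs,
    )

    records = None
    observations = None
    grid = np.linspace(0.0, 1.0, grid_size)
    if curves_only:
        rom = np.array([np.ptp(c(grid)) for c in curves["phi"]])
        rov = np.array([np.ptp(c(grid)) for c in curves["omega"]])
    else:
        records = [generate_record(p, config, rng) for p in params]
        observations = [preprocess_record(r, grid_size=grid_size) for r in records]
        rom = np.array([o.rom_deg for o in observations])
        rov = np.array([o.rov_dps for o in observations])

    scalars = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in params],
            "session": [p.session for p in params],
            "ndi": ndi,
            "RoM": rom,
            "RoV": rov,
        }
    )
    return SyntheticStudy(
        config=config,
        scalars=scalars,
        curves=curves,
        ground_truth=truth,
        records=records,
        observations=observations,
    )


def generate_null_dataset(
    config: GeneratorConfig, curves_only: bool = True, round_scores: bool = False
) -> SyntheticStudy:
    """Same cohort structure with beta1 identically zero (null signal)."""
    null_config = replace(config, true_b=np.zeros(N_GEN_BASIS))
    return generate_dataset(
        null_config, curves_only=curves_only, round_scores=round_scores
    )


def expand_observations(
    observations: list[ObservationKinematics], n_funcs: int = 21
) -> dict[str, list[BasisCurve]]:
    """Expand preprocessed mean curves into Fourier coefficients.

    Returns the ``{"omega": ..., "phi": ...}`` mapping the model-fitting
    layer expects; the curve-expansion basis (default 21 functions) is
    finer than the coefficient-function basis so the curves themselves
    are not the smoothing bottleneck.
    """
    from .fourier_basis import expand_curve

    basis = FourierBasis(n_funcs)
    return {
        "omega": [expand_curve(o.mean_velocity, basis) for o in observations],
        "phi": [expand_curve(o.mean_angle, basis) for o in observations],
    }
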