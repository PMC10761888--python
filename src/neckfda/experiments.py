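"""Simulation studies validating the statistical machinery.

Each function runs a self-contained experiment on synthetic cohorts and
returns summary numbers: type-I error calibration of the overall F test,
coefficient-function recovery error as the sample grows, exactness of
the noiseless refit, equivalence of the Gram-matrix reduction with
brute-force quadrature, and conservation of the signed-area
decomposition.  All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fourier_basis import eval_basis, make_basis
from .interpretation import contribution_profile
from .simulate import GeneratorConfig, generate_dataset, generate_null_dataset
from .sofr import ModelSpec, build_design, coefficient_function, fit_formula, fit_sofr, predict

__all__ = [
    "type_i_error_study",
    "rmise_study",
    "noiseless_recovery_study",
    "reduction_equivalence_study",
    "conservation_study",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def type_i_error_study(
    seed: int, n_reps: int = 2000, n: int = 55, alpha: float = 0.05
) -> dict:
    """Size of the overall F test of the velocity functional model under H0.

    Generates ``n_reps`` null cohorts (coefficient function identically
    zero), refits ``ndi ~ omega(t)`` with the K=9 coefficient basis, and
    reports the rejection rate at ``alpha`` plus a Kolmogorov-Smirnov
    uniformity p-value of the p-value distribution.
    """
    pvals = np.empty(n_reps)
    for rep, s in enumerate(_child_seeds(seed, n_reps)):
        cfg = GeneratorConfig(seed=s, n_subjects=n, sessions_per_subject=1)
        study = generate_null_dataset(cfg)
        fit = fit_formula("ndi ~ omega(t)", study.curves, study.scalars)
        pvals[rep] = fit.stats.p_value
    return {
        "rejection_rate": float(np.mean(pvals < alpha)),
        "ks_pvalue": float(sps.kstest(pvals, "uniform").pvalue),
        "n_reps": n_reps,
        "n": n,
    }


def rmise_study(
    seed: int, sample_sizes: tuple[int, ...] = (50, 400), n_reps: int = 100
) -> dict:
    """Root mean integrated squared error of the estimated beta1(t).

    At fixed response noise, the median RMISE over replicates should
    shrink as the cohort grows.
    """
    grid = np.linspace(0.0, 1.0, 1001)
    truth_basis = make_basis(9)
    out: dict = {"n_reps": n_reps}
    seeds = _child_seeds(seed, n_reps * len(sample_sizes))
    idx = 0
    for n in sample_sizes:
        errs = []
        for _ in range(n_reps):
            cfg = GeneratorConfig(seed=seeds[idx], n_subjects=n,
                                  sessions_per_subject=1)
            idx += 1
            study = generate_dataset(cfg, curves_only=True)
            fit = fit_formula("ndi ~ omega(t)", study.curves, study.scalars)
            est = coefficient_function(fit, "omega", grid).values
            true_vals = eval_basis(truth_basis, grid) @ study.ground_truth.true_b
            errs.append(np.sqrt(np.trapezoid((est - true_vals) ** 2, grid)))
        out[f"median_rmise_n{n}"] = float(np.median(errs))
    return out


def noiseless_recovery_study(seed: int, n: int = 60) -> dict:
    """Refit of a zero-noise, unrounded cohort: r must be exactly 1 and
    the coefficient-function coefficients recovered to numerical noise."""
    cfg = GeneratorConfig(seed=seed, n_subjects=n, sessions_per_subject=1,
                          response_noise_sd=0.0)
    study = generate_dataset(cfg, curves_only=True, round_scores=False)
    fit = fit_formula("ndi ~ omega(t)", study.curves, study.scalars)
    return {
        "r": float(fit.stats.r),
        "max_b_error": float(
            np.max(np.abs(fit.b("omega") - study.ground_truth.true_b))
        ),
        "beta0_error": float(abs(fit.beta0 - cfg.true_beta0)),
        "n": n,
    }


def reduction_equivalence_study(
    seed: int, n_datasets: int = 20, n: int = 55,
    k_betas: tuple[int, ...] = (5, 9), grid_points: int = 10_001,
) -> dict:
    """Worst coefficient discrepancy between the Gram-matrix reduction and
    brute-force functional OLS with quadrature inner products."""
    fine = np.linspace(0.0, 1.0, grid_points)
    worst = 0.0
    for i, s in enumerate(_child_seeds(seed, n_datasets)):
        k_beta = k_betas[i % len(k_betas)]
        cfg = GeneratorConfig(seed=s, n_subjects=n, sessions_per_subject=1)
        study = generate_dataset(cfg, curves_only=True)
        y = study.scalars["ndi"].to_numpy(float)
        spec = ModelSpec("ndi", functional_terms=(("omega", k_beta),))
        fit = fit_sofr(build_design(study.curves, None, spec), y)
        theta = eval_basis(make_basis(k_beta), fine)
        V = np.stack([
            np.trapezoid(theta * c(fine)[:, None], fine, axis=0)
            for c in study.curves["omega"]
        ])
        Xq = np.hstack([np.ones((len(y), 1)), V])
        norms = np.linalg.norm(Xq, axis=0)
        keep = norms > 1e-10 * norms.max()
        ref = np.zeros(Xq.shape[1])
        ref[keep], *_ = np.linalg.lstsq(Xq[:, keep], y, rcond=None)
        worst = max(worst, float(np.max(np.abs(fit.coefs - ref))))
    return {"max_coef_discrepancy": worst, "n_datasets": n_datasets}


def conservation_study(seed: int, n_obs: int = 100) -> dict:
    """Worst violation of beta0 + signed areas + scalars = prediction."""
    cfg = GeneratorConfig(seed=seed, n_subjects=(n_obs + 1) // 2,
                          sessions_per_subject=2)
    study = generate_dataset(cfg, curves_only=True)
    fit = fit_formula("ndi ~ omega(t) + RoV", study.curves, study.scalars)
    worst = 0.0
    for i in range(min(n_obs, len(study.scalars))):
        prof = contribution_profile(
            fit, {"omega": study.curves["omega"][i]},
            scalars=study.scalars.iloc[i],
        )
        reference = predict(
            fit, {"omega": [study.curves["omega"][i]]},
            pd.DataFrame([study.scalars.iloc[i][["RoV", "RoM"]]]),
        )[0]
        err = abs(prof.beta0 + prof.total_integral + prof.scalar_contribution
                  - reference)
        worst = max(worst, float(err))
    return {"max_conservation_error": worst, "n_obs": n_obs}
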