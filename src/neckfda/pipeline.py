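"""End-to-end analysis orchestration.

One call runs: data acquisition (simulate or read) -> preprocessing ->
basis-dimension selection -> the full battery of regression models ->
nested-model tests -> contribution profiles for representative
observations, and writes a machine-readable report bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .fourier_basis import BasisCurve
from .interpretation import contribution_profile, regions_to_frame
from .preprocess import preprocess_record
from .selection import criteria_table, select_n_basis, table_to_frame
from .simulate import GeneratorConfig, generate_dataset, expand_observations
from .sofr import SOFRFit, fit_formula, nested_f_test

__all__ = ["RunConfig", "ReportBundle", "DEFAULT_FORMULAS", "DEFAULT_NESTED", "run_pipeline"]

logger = logging.getLogger(__name__)

#: The standard model battery: four scalar-on-scalar models, two
#: scalar-on-function models (angle and angular velocity), and two mixed
#: models keeping the angular-velocity curve.
DEFAULT_FORMULAS = (
    "ndi ~ RoM",
    "ndi ~ RoV",
    "ndi ~ RoM + RoV",
    "ndi ~ RoM + RoV + RoM:RoV",
    "ndi ~ phi(t)",
    "ndi ~ omega(t)",
    "ndi ~ omega(t) + RoV",
    "ndi ~ omega(t) + RoV + RoM",
)

#: Nested comparisons: does adding scalars improve the functional model,
#: and does adding the functional term improve the scalar model?
DEFAULT_NESTED = (
    ("ndi ~ omega(t)", "ndi ~ omega(t) + RoV + RoM"),
    ("ndi ~ RoM + RoV", "ndi ~ omega(t) + RoV + RoM"),
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    simulate: bool = True
    records_path: str | None = None
    scalars_path: str | None = None
    formulas: tuple[str, ...] = DEFAULT_FORMULAS
    nested: tuple[tuple[str, str], ...] = DEFAULT_NESTED
    candidates: tuple[int, ...] = (5, 7, 9, 11)
    selection_rule: str = "compromise"
    out_dir: str | None = None
    seed: int = 0
    grid_size: int = 101
    expansion_size: int = 21
    generator: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        for k in self.candidates:
            if k % 2 == 0:
                raise ValueError(f"candidate basis sizes must be odd, got {k}")
        if not self.simulate and not (self.records_path and self.scalars_path):
            raise ValueError(
                "either set simulate=True or provide records_path and scalars_path"
            )


@dataclass
class ReportBundle:
    """All numeric results of one run, ready for serialization."""

    config: RunConfig
    criteria: pd.DataFrame
    selected_n_basis: int | None
    models: pd.DataFrame
    nested: pd.DataFrame
    fits: dict[str, SOFRFit]
    profiles: dict[str, pd.DataFrame]
    scalars: pd.DataFrame

    def to_json_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        gen = cfg.pop("generator", None)
        if gen is not None:
            gen["true_b"] = list(np.asarray(gen["true_b"], dtype=float))
        return {
            "config": cfg,
            "generator": gen,
            "selected_n_basis": self.selected_n_basis,
            "criteria": self.criteria.to_dict(orient="records"),
            "models": self.models.to_dict(orient="records"),
            "nested": self.nested.to_dict(orient="records"),
            "fits": {label: fit.summary() for label, fit in self.fits.items()},
        }


def _acquire_data(config: RunConfig):
    """Return (curves dict, scalar table, observations or None)."""
    if config.simulate:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        if gen.seed != config.seed:
            gen = dataclasses.replace(gen, seed=config.seed)
        study = generate_dataset(gen, grid_size=config.grid_size)
        observations = study.observations
        scalars = study.scalars
    else:
        records = nio.read_records(config.records_path)
        scalars = nio.read_scalars(config.scalars_path)
        observations = [
            preprocess_record(r, grid_size=config.grid_size) for r in records
        ]
        key = lambda o: (o.subject_id, o.session)  # noqa: E731
        order = {
            (str(row.subject_id), str(row.session)): i
            for i, row in enumerate(scalars.itertuples())
        }
        missing = [key(o) for o in observations if key(o) not in order]
        if missing or len(observations) != len(scalars):
            raise nio.SchemaError(
                f"records and scalar table disagree on observations: {missing}"
            )
        observations = sorted(observations, key=lambda o: order[key(o)])
    curves = expand_observations(observations, n_funcs=config.expansion_size)
    return curves, scalars, observations


def _pick_representatives(
    scalars: pd.DataFrame, fit: SOFRFit, n_bins: int = 3
) -> list[int]:
    """Lowest-residual observation within each NDI tertile."""
    ndi = scalars["ndi"].to_numpy(float)
    resid = np.abs(fit.residuals)
    edges = np.quantile(ndi, np.linspace(0, 1, n_bins + 1))
    picks = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (ndi >= lo) & (ndi <= hi)
        if mask.any():
            idx = np.flatnonzero(mask)
            picks.append(int(idx[np.argmin(resid[idx])]))
    return sorted(set(picks))


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and (optionally) write the report bundle."""
    logger.info("pipeline start: seed=%d simulate=%s", config.seed, config.simulate)
    curves, scalars, observations = _acquire_data(config)
    y = scalars["ndi"].to_numpy(float)

    selected = None
    criteria_df = pd.DataFrame(
        columns=["n_basis", "r", "AIC", "F", "p_value"]
    )
    if config.candidates:
        table = criteria_table(curves["omega"], y, list(config.candidates))
        criteria_df = table_to_frame(table)
        selected = select_n_basis(table, rule=config.selection_rule)
        logger.info("selected basis dimension K=%d", selected)

    fits: dict[str, SOFRFit] = {}
    rows = []
    for formula in config.formulas:
        fit = fit_formula(
            formula, curves, scalars, coef_basis_size=selected or 9
        )
        fits[formula] = fit
        rows.append(
            {
                "model": formula,
                "r": fit.stats.r,
                "R2": fit.stats.r2,
                "F": fit.stats.F,
                "p_value": fit.stats.p_value,
                "AIC": fit.stats.aic,
            }
        )
    models_df = pd.DataFrame(rows, columns=["model", "r", "R2", "F", "p_value", "AIC"])

    nested_rows = []
    for simple_f, complex_f in config.nested:
        for f in (simple_f, complex_f):
            if f not in fits:
                fits[f] = fit_formula(f, curves, scalars, coef_basis_size=selected or 9)
        res = nested_f_test(fits[simple_f], fits[complex_f])
        nested_rows.append(res.to_dict())
    nested_df = pd.DataFrame(
        nested_rows, columns=["simple", "complex", "F", "df1", "df2", "p_value"]
    )

    profiles: dict[str, pd.DataFrame] = {}
    best_functional = "ndi ~ omega(t)"
    if best_functional in fits:
        fit = fits[best_functional]
        for i in _pick_representatives(scalars, fit):
            obs_curves = {"omega": curves["omega"][i]}
            prof = contribution_profile(fit, obs_curves)
            frame = regions_to_frame(prof)
            frame.insert(0, "observation", i)
            frame["predicted"] = prof.predicted
            frame["ndi"] = y[i]
            profiles[f"obs{i}"] = frame

    bundle = ReportBundle(
        config=config,
        criteria=criteria_df,
        selected_n_basis=selected,
        models=models_df,
        nested=nested_df,
        fits=fits,
        profiles=profiles,
        scalars=scalars,
    )
    if config.out_dir:
        write_report(bundle, config.out_dir, observations)
    return bundle


def write_report(
    bundle: ReportBundle, out_dir: str | Path, observations=None
) -> None:
    """Write the bundle as CSV tables plus a JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.criteria.to_csv(out / "criteria.csv", index=False, float_format="%.12g")
    bundle.models.to_csv(out / "models.csv", index=False, float_format="%.12g")
    bundle.nested.to_csv(out / "nested.csv", index=False, float_format="%.12g")
    nio.write_scalars(bundle.scalars, out / "scalars.csv")
    if observations:
        nio.write_curves(observations, out / "curves.csv")
    if bundle.profiles:
        pd.concat(bundle.profiles.values(), ignore_index=True).to_csv(
            out / "regions.csv", index=False, float_format="%.12g"
        )
    (out / "report.json").write_text(
        json.dumps(bundle.to_json_dict(), indent=2, sort_keys=True, default=float)
    )
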