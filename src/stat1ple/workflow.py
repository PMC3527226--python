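"""End-to-end orchestration: generate/load data, fit, profile every free
parameter, overfitting analysis, sensitivity bands, trajectory bands.

Every stage writes diff-able artifacts (JSON for derived results, CSV for
time-indexed tables) under the configured output directory, and a manifest
records seeds, stage timings and content hashes so that re-running a config
reproduces the outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import data as data_mod
from .data import (
    SamplingDesign,
    TimeSeriesDataset,
    default_design,
    generate_dataset,
    load_dataset,
    make_preset,
    save_dataset,
)
from .fitting import FitSettings, ParameterSpec, PathwayProblem, fit
from .mcc import default_mcc_grid, mcc_band
from .model import STATE_NAMES, simulate
from .params import PathwayParameters
from .profiles import (
    ProfileOptions,
    ThresholdSpec,
    ci_threshold,
    profile,
    trajectory_band,
)
from .overfit import effective_dof, overfit_samples

__all__ = ["WorkflowConfig", "run_workflow", "demo_config", "WorkflowError"]

logger = logging.getLogger("stat1ple")


class WorkflowError(RuntimeError):
    """Stage failure with a machine-readable error record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.record = {"stage": stage, "error": message}


@dataclass
class WorkflowConfig:
    """Fully explicit description of one analysis run (no hidden seeds)."""

    output_dir: str
    # data: either a CSV path or a preset + generator seed
    dataset_path: str | None = None
    preset: str = "PSC_like"
    data_seed: int = 11
    design: SamplingDesign | None = None
    # estimation
    free_parameters: list[str] = field(
        default_factory=lambda: ["k_act", "k_impD", "k_deph"]
    )
    bounds_decades: float = 2.0
    restarts: int = 5
    anneal_steps: int = 60
    fit_seed: int = 12
    # identifiability
    alpha: float = 0.95
    profile_parameters: list[str] | str = "all"
    profile_seed: int = 13
    profile_max_steps: int = 60
    # overfitting
    n_random: int = 30
    overfit_restarts: int = 2
    overfit_seed: int = 14
    # sensitivity
    sensitivity_parameters: list[str] = field(
        default_factory=lambda: ["k_deph", "k_impD"]
    )
    sensitivity_variable: str = "STAT1Dn"
    mcc_sets: int = 20
    # trajectory bands
    band_variable: str = "STAT1Dn"
    band_sets: int = 11
    dose: float = 100.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def validate(self) -> None:
        if self.dataset_path is not None and not Path(self.dataset_path).exists():
            raise WorkflowError("config", f"dataset path not found: {self.dataset_path}")
        if self.dataset_path is None and self.preset not in ("PSC_like", "PC_like"):
            raise WorkflowError("config", f"unknown preset {self.preset!r}")


def demo_config(output_dir: str, **overrides) -> WorkflowConfig:
    """Reduced PSC-like demonstration run (small multistart, few profiles)."""
    return WorkflowConfig(output_dir=output_dir, **overrides)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_workflow(config: WorkflowConfig) -> dict:
    """Execute generate/load -> fit -> profile-all -> overfit -> sensitivity
    -> bands; halt on the first failing stage (downstream stages never run).

    Returns the manifest (also written to ``manifest.json``): per-stage
    timings, seeds and output hashes.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seeds": {}, "versions": _versions()}
    reference = make_preset(config.preset)

    def finish_stage(name: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        logger.info("stage %s done in %.1fs", name, time.time() - t0)

    # -- data ---------------------------------------------------------------
    t0 = time.time()
    try:
        if config.dataset_path is not None:
            dataset = load_dataset(config.dataset_path)
        else:
            design = config.design or default_design()
            dataset = generate_dataset(
                reference, design, config.data_seed, cell_type=config.preset
            )
        data_path = out / "dataset.csv"
        save_dataset(dataset, data_path)
    except WorkflowError:
        raise
    except Exception as exc:
        raise WorkflowError("data", str(exc)) from exc
    manifest["seeds"]["data"] = config.data_seed
    finish_stage("data", t0, [data_path])

    # -- fit ----------------------------------------------------------------
    t0 = time.time()
    try:
        specs = _parameter_specs(
            reference, config.free_parameters, config.bounds_decades
        )
        problem = PathwayProblem(dataset, specs)
        settings = FitSettings(
            restarts=config.restarts,
            seed=config.fit_seed,
            anneal_steps=config.anneal_steps,
        )
        fit_result = fit(problem, settings)
        if not fit_result.success:
            raise WorkflowError("fit", "no restart converged")
        fit_path = out / "fit_result.json"
        fit_result.to_json(fit_path)
    except WorkflowError:
        raise
    except Exception as exc:
        raise WorkflowError("fit", str(exc)) from exc
    manifest["seeds"]["fit"] = config.fit_seed
    finish_stage("fit", t0, [fit_path])

    # -- profiles -----------------------------------------------------------
    t0 = time.time()
    thresholds = [
        ThresholdSpec(config.alpha, 1),
        ThresholdSpec(config.alpha, max(1, len(problem.free_names))),
    ]
    names = (
        problem.free_names
        if config.profile_parameters == "all"
        else list(config.profile_parameters)
    )
    profiles = {}
    profile_paths = []
    try:
        for name in names:
            prof = profile(
                name,
                fit_result,
                problem,
                thresholds,
                FitSettings(seed=config.profile_seed, anneal_steps=0),
                ProfileOptions(max_steps=config.profile_max_steps),
            )
            profiles[name] = prof
            path = out / f"profile_{name}.json"
            prof.to_json(path)
            profile_paths.append(path)
    except Exception as exc:
        raise WorkflowError("profiles", str(exc)) from exc
    manifest["seeds"]["profiles"] = config.profile_seed
    finish_stage("profiles", t0, profile_paths)

    # -- overfitting --------------------------------------------------------
    t0 = time.time()
    try:
        dist = overfit_samples(
            problem,
            fit_result,
            FitSettings(restarts=config.overfit_restarts, anneal_steps=0),
            n_random=config.n_random,
            seed=config.overfit_seed,
        )
        if len(dist.samples) >= 100:
            effective_dof(dist, range(1, len(problem.free_names) + 1))
        over_path = out / "overfit.json"
        dist.to_json(over_path)
    except Exception as exc:
        raise WorkflowError("overfit", str(exc)) from exc
    manifest["seeds"]["overfit"] = config.overfit_seed
    finish_stage("overfit", t0, [over_path])

    # -- sensitivity --------------------------------------------------------
    t0 = time.time()
    try:
        threshold = ci_threshold(thresholds[-1])
        rows = []
        for name in config.sensitivity_parameters:
            if name not in profiles:
                raise ValueError(f"no profile available for {name!r}")
            series = mcc_band(
                profiles[name],
                name,
                config.sensitivity_variable,
                config.dose,
                default_mcc_grid(),
                threshold=threshold,
                n_sets=config.mcc_sets,
            )
            for i, t in enumerate(series.time_grid):
                rows.append(
                    {
                        "time_min": t,
                        "parameter": name,
                        "coefficient": series.coefficient[i],
                        "band_lower": series.band_lower[i],
                        "band_upper": series.band_upper[i],
                    }
                )
        import pandas as pd

        mcc_path = out / "mcc.csv"
        pd.DataFrame(rows).to_csv(mcc_path, index=False)
    except Exception as exc:
        raise WorkflowError("sensitivity", str(exc)) from exc
    finish_stage("sensitivity", t0, [mcc_path])

    # -- trajectory bands ---------------------------------------------------
    t0 = time.time()
    try:
        grid = np.linspace(0.0, 540.0, 55)
        var_index = STATE_NAMES.index(config.band_variable)

        def simulate_fn(mapping):
            params = PathwayParameters.from_dict(mapping)
            return simulate(params, config.dose, grid).states[:, var_index]

        import pandas as pd

        rows = []
        for name in names:
            band = trajectory_band(
                profiles[name], simulate_fn, grid, threshold, n_sets=config.band_sets
            )
            for m, member in enumerate(band.members):
                for t, v in zip(grid, member):
                    rows.append(
                        {
                            "time_min": t,
                            "variable": config.band_variable,
                            "parameter": name,
                            "member_index": m,
                            "value": v,
                        }
                    )
        band_path = out / "bands.csv"
        pd.DataFrame(rows).to_csv(band_path, index=False)
    except Exception as exc:
        raise WorkflowError("bands", str(exc)) from exc
    finish_stage("bands", t0, [band_path])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _parameter_specs(
    reference: PathwayParameters, free: list[str], decades: float
) -> list[ParameterSpec]:
    """Free parameters get a symmetric log box around the reference value;
    everything else is fixed at the reference (delays stay linear)."""
    specs = []
    factor = 10.0**decades
    for name, value in reference.items():
        if name in free:
            if name in ("tau_socs", "tau_stat"):
                specs.append(
                    ParameterSpec(name, value, 0.0, max(4 * value, 120.0), log10=False)
                )
            else:
                if value <= 0:
                    raise ValueError(f"cannot free {name}: reference value is 0")
                specs.append(ParameterSpec(name, value, value / factor, value * factor))
        else:
            specs.append(
                ParameterSpec(name, value, 0.0, np.inf, log10=False, fixed=True)
            )
    unknown = set(free) - set(reference.field_names())
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    return specs


def _versions() -> dict:
    import scipy
    import pandas

    from . import __version__

    return {
        "stat1ple": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
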