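"""End-to-end experiment runner: simulate, analyze, calibrate, estimate, test.

An :class:`ExperimentConfig` names the modality, the per-condition generating
statistics (label, mean, SD, n), the calibration table, explicit seeds and
any pipeline overrides; :func:`run_experiment` executes the whole chain and
writes every intermediate plus a :class:`RunManifest` so the run is exactly
reproducible.  Per-condition record CSVs act as checkpoints: re-running with
an unchanged config resumes after the last completed condition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .calibration import LinearCalibration, estimate_conditions
from .flim import run_flim_pipeline
from .io import save_model, save_table
from .phantoms import simulate_condition_batch, simulate_decay, simulate_spectral_stack
from .spectral_gp import run_gp_pipeline


@dataclass(frozen=True)
class Condition:
    label: str
    readout_mean: float
    readout_sd: float
    n_vesicles: int

    def __post_init__(self) -> None:
        if self.n_vesicles < 1:
            raise ValueError("every condition needs n_vesicles >= 1")


@dataclass(frozen=True)
class ExperimentConfig:
    modality: str  # "GP" | "lifetime"
    conditions: tuple[Condition, ...]
    seed: int  # explicit; no wall-clock defaults
    calibration_table: str = "gel_swelling"  # bundled table, or a CSV path
    pipeline_overrides: dict = field(default_factory=dict)
    out_dir: str = "guvchol_run"

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    parameters: dict
    files: list[str] = field(default_factory=list)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))


def analyze_gp_batch(specs, condition: str = "", **pipeline_kwargs) -> pd.DataFrame:
    """Run the full GP pipeline on a batch of spectral phantom specs."""
    rows = []
    for i, spec in enumerate(specs):
        stack, truth = simulate_spectral_stack(spec)
        record, _, log = run_gp_pipeline(
            stack, vesicle_id=f"guv{i:03d}", condition=condition, **pipeline_kwargs
        )
        rows.append(
            {
                "vesicle_id": record.vesicle_id,
                "condition": condition,
                "modality": "GP",
                "value": record.value,
                "n_pixels": record.n_pixels,
                "true_value": truth.true_value,
            }
        )
    return pd.DataFrame(rows)


def analyze_decay_batch(specs, condition: str = "", **fit_kwargs) -> pd.DataFrame:
    """Simulate and reconvolution-fit a batch of decay phantom specs."""
    pairs = []
    truths = []
    for i, spec in enumerate(specs):
        hist, truth = simulate_decay(spec)
        pairs.append((f"guv{i:03d}", hist))
        truths.append(truth.true_value)
    records, fits, flagged = run_flim_pipeline(pairs, condition=condition, **fit_kwargs)
    kept = {r.vesicle_id for r in records}
    rows = [
        {
            "vesicle_id": r.vesicle_id,
            "condition": condition,
            "modality": "lifetime",
            "value": r.value,
            "n_photons": r.n_photons,
            "true_value": t,
        }
        for r, t in zip(records, [t for (vid, _), t in zip(pairs, truths) if vid in kept])
    ]
    return pd.DataFrame(rows)


def recover_condition_mean(
    modality: str,
    readout_mean: float,
    readout_sd: float,
    n_vesicles: int,
    seed: int,
    **overrides,
) -> tuple[float, pd.DataFrame]:
    """Generate one condition's phantom batch, run the full pipeline, and
    return (grand mean of the recovered per-vesicle readouts, records)."""
    specs, _ = simulate_condition_batch(
        n_vesicles, readout_mean, readout_sd, modality, seed,
        **overrides.pop("phantom_overrides", {}),
    )
    if modality == "GP":
        df = analyze_gp_batch(specs, **overrides)
    else:
        df = analyze_decay_batch(specs, **overrides)
    return float(df["value"].mean()), df


def simulate_and_analyze_condition(
    cond: Condition, modality: str, seed: int, **overrides
) -> pd.DataFrame:
    """One condition end to end: phantom batch -> per-vesicle records."""
    specs, _ = simulate_condition_batch(
        cond.n_vesicles, cond.readout_mean, cond.readout_sd, modality, seed,
        **overrides.pop("phantom_overrides", {}),
    )
    if modality == "GP":
        return analyze_gp_batch(specs, condition=cond.label, **overrides)
    return analyze_decay_batch(specs, condition=cond.label, **overrides)


def _calibration_model(config: ExperimentConfig):
    if config.calibration_table == "gel_swelling":
        points = datasets.calibration_points(config.modality)
        return LinearCalibration(points, modality=config.modality).fit()
    df = pd.read_csv(config.calibration_table)
    return LinearCalibration.from_dataframe(df, modality=config.modality).fit()


def run_experiment(config: ExperimentConfig) -> tuple[RunManifest, dict]:
    """Execute the configured experiment; returns (manifest, results).

    ``results`` holds the per-condition records, the fitted calibration, the
    condition-level estimates and the Kruskal-Wallis test across conditions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    chash = config.hash()
    manifest = RunManifest(
        config_hash=chash,
        package_version=__version__,
        parameters={
            "config": dataclasses.asdict(config),
            "seed_expansion": "SeedSequence([seed, condition_index, vesicle_index])",
        },
    )

    all_records = []
    for ci, cond in enumerate(config.conditions):
        ckpt = out / f"records_{ci:02d}_{_slug(cond.label)}.csv"
        stamp = ckpt.with_suffix(".hash")
        if ckpt.exists() and stamp.exists() and stamp.read_text() == chash:
            df = pd.read_csv(ckpt)  # resume from checkpoint
        else:
            cond_seed = int(
                np.random.SeedSequence([config.seed, ci]).generate_state(1)[0] % (2**31)
            )
            df = simulate_and_analyze_condition(
                cond, config.modality, cond_seed, **dict(config.pipeline_overrides)
            )
            save_table(df, ckpt)
            stamp.write_text(chash)
        manifest.files.append(ckpt.name)
        all_records.append(df)
    records = pd.concat(all_records, ignore_index=True)
    save_table(records, out / "records_all.csv")

    model = _calibration_model(config)
    save_model(model, out / "calibration_model.json")

    table, per_guv, tests = estimate_conditions(records, model)
    save_table(table, out / "condition_estimates.csv")
    save_table(per_guv, out / "per_guv_estimates.csv")
    (out / "significance.json").write_text(json.dumps(tests, indent=1))
    manifest.files += [
        "records_all.csv", "calibration_model.json", "condition_estimates.csv",
        "per_guv_estimates.csv", "significance.json",
    ]
    manifest.save(out / "manifest.json")
    return manifest, {
        "records": records,
        "calibration": model,
        "condition_estimates": table,
        "per_guv_estimates": per_guv,
        "tests": tests,
    }


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in label)
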