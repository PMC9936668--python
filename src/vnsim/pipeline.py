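"""End-to-end reproduction driver.

Chains the pipeline stages -- design enumeration, synthetic cohort
generation, signal quantification, SAN-model density calibration, muscle
model fitting, the ganglionic-filtering knockout, and the effect-size
partition -- under one seeded configuration, and scores simulated
against quantified responses by the fraction of conditions whose model
mean lies within one standard deviation of the cohort mean.

Problem sizes (cohort size, trial protocol, HR-model runs, swarm
iterations) are configuration, so the driver runs anywhere from a quick
desk-scale smoke run to the full factorial study.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effects as effects_mod
from .hr.model import SinoatrialNetworkModel, run_hr_trial
from .patterns import Condition, TrialProtocol, enumerate_design
from .pso import MuscleActivationModel
from .quant import quantify_cohort
from .synth import ResponseSurface, generate_cohort

__all__ = ["RunConfig", "reproduce_trends"]


@dataclass
class RunConfig:
    """Seeds, grids and sizes for a full reproduction run."""

    seed_design: int = 1
    seed_cohort: int = 2
    seed_hr_model: int = 3
    seed_pso: int = 4
    rate_grid: tuple = (2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 100.0)
    amplitudes: tuple = (0.8, 1.0, 1.2)
    n_animals: int = 10
    noise_sd: float = 0.02
    # trial protocol (shorter values give scaled-down runs)
    baseline_s: float = 10.0
    stim_s: float = 30.0
    recovery_s: float = 30.0
    analysis_start_offset_s: float = 5.0
    # HR model
    hr_runs: int = 10
    hr_frequencies: tuple = (5.0, 20.0, 50.0)
    # muscle fit
    pso_runs: int = 5
    pso_iterations: int = 50
    pso_particles: int = 100
    pso_window_s: float = 30.0
    pso_dt_ms: float = 0.1
    out_dir: str = "results/run"

    def protocol(self) -> TrialProtocol:
        return TrialProtocol(
            baseline_s=self.baseline_s,
            stim_s=self.stim_s,
            recovery_s=self.recovery_s,
            analysis_start_offset_s=self.analysis_start_offset_s,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("rate_grid", "amplitudes", "hr_frequencies"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _within_one_sd(model_means: pd.Series, cohort: pd.DataFrame, col: str) -> float:
    """Fraction of conditions with the model mean within one SD of the
    cohort mean (the agreement metric)."""
    agree, total = 0, 0
    for key, mval in model_means.items():
        sel = cohort.loc[[key]] if key in cohort.index else None
        if sel is None:
            continue
        mu, sd = sel[col].iloc[0], sel[f"{col}_sd"].iloc[0]
        if sd == 0:
            continue
        total += 1
        agree += int(abs(mval - mu) <= sd)
    return agree / total if total else float("nan")


def reproduce_trends(config: RunConfig) -> dict:
    """Run the full chain and write the report artifacts.

    Returns a report dictionary with stage timings, output paths, the
    calibrated densities, fit errors, knockout comparison, and the
    effect-size partitions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "stages": {}}

    def _stage(name):
        t0 = time.time()

        def _done(**info):
            report["stages"][name] = {"seconds": round(time.time() - t0, 2), **info}

        return _done

    # (1) design
    done = _stage("design")
    design = enumerate_design(config.rate_grid, config.amplitudes)
    design_records = [
        {
            "amplitude": c.amplitude,
            "intra_burst_frequency": c.intra_burst_frequency,
            "mean_pulse_rate": c.mean_pulse_rate,
            "pattern_kind": c.pattern_kind,
        }
        for c in design
    ]
    (out / "design.json").write_text(json.dumps(design_records, indent=1))
    done(n_conditions=len(design))

    # (2) synthetic cohort + quantification
    done = _stage("cohort")
    cohort = generate_cohort(
        config.n_animals,
        design,
        seed=config.seed_cohort,
        noise_sd=config.noise_sd,
        protocol=config.protocol(),
    )
    quantified = quantify_cohort(cohort)
    quantified.to_csv(out / "quantified.csv", index=False)
    done(n_trials=len(quantified))

    keys = ["amplitude", "intra_burst_frequency", "mean_pulse_rate"]
    summary = (
        quantified.groupby(keys)
        .agg(
            hr_norm=("hr_norm", "mean"),
            hr_norm_sd=("hr_norm", "std"),
            emg_norm=("emg_norm", "mean"),
            emg_norm_sd=("emg_norm", "std"),
        )
    )
    summary.to_csv(out / "response_summary.csv")

    # (3) HR-model calibration per amplitude
    done = _stage("hr_calibration")
    const = quantified[quantified["pattern_kind"] == "constant"]
    targets = (
        const[const["intra_burst_frequency"].isin(config.hr_frequencies)]
        .groupby(["amplitude", "intra_burst_frequency"])["hr_norm"]
        .mean()
        .reset_index()
        .rename(columns={"intra_burst_frequency": "frequency"})
    )
    hr_model = SinoatrialNetworkModel(targets, protocol=config.protocol())
    calib = hr_model.fit(n_runs=config.hr_runs, seed=config.seed_hr_model)
    (out / "densities.json").write_text(
        json.dumps({str(a): d for a, d in calib.densities.items()}, indent=1)
    )
    done(densities=calib.densities)
    report["densities"] = calib.densities

    # (4) muscle model fit (1.0xBCT patterns)
    done = _stage("muscle_fit")
    muscle_model = MuscleActivationModel.from_quantified(
        quantified.dropna(subset=["emg_norm"]),
        window_s=config.pso_window_s,
        dt_ms=config.pso_dt_ms,
    )
    fit = muscle_model.fit(
        runs=config.pso_runs,
        init_seed=config.seed_pso,
        n_iterations=config.pso_iterations,
        n_particles=config.pso_particles,
    )
    fit_payload = {
        "params": fit.params.to_dict(),
        "runs": fit.summary().to_dict(orient="records"),
    }
    (out / "fit.json").write_text(json.dumps(fit_payload, indent=1))
    done(total_rmse=fit.total_rmse)
    report["muscle_fit_rmse"] = fit.total_rmse

    # (5) filtering knockout comparison
    done = _stage("knockout")
    density_ref = calib.densities.get(1.0, 30)
    rows = []
    for freq in config.hr_frequencies:
        cond = Condition(
            amplitude=1.0, intra_burst_frequency=freq, mean_pulse_rate=freq
        )
        for filtering in (True, False):
            vals = [
                run_hr_trial(
                    cond,
                    density_ref,
                    filtering=filtering,
                    seed=config.seed_hr_model + 7919 * r,
                    protocol=config.protocol(),
                ).hr_norm
                for r in range(max(1, config.hr_runs // 2))
            ]
            rows.append(
                {
                    "frequency": freq,
                    "filtering": filtering,
                    "hr_norm": float(np.mean(vals)),
                }
            )
    knockout = pd.DataFrame(rows)
    knockout.to_csv(out / "knockout.csv", index=False)
    done()
    report["knockout"] = rows

    # (6) effect-size partition
    done = _stage("effects")
    partitions = {}
    for response in ("hr_norm", "emg_norm", "effect_score"):
        try:
            part = effects_mod.variance_partition(
                quantified[quantified["pattern_kind"].isin(["constant", "burst"])],
                response,
            )
            partitions[response] = part.to_dict(orient="records")
        except ValueError as err:
            warnings.warn(f"effects partition for {response}: {err}", stacklevel=2)
    (out / "effects.json").write_text(json.dumps(partitions, indent=1))
    done()
    report["effects"] = partitions

    # (7) agreement: model vs quantified, within one SD
    done = _stage("agreement")
    model_hr = {}
    for amp, density in calib.densities.items():
        for freq in config.hr_frequencies:
            cond = Condition(
                amplitude=amp, intra_burst_frequency=freq, mean_pulse_rate=freq
            )
            vals = [
                run_hr_trial(
                    cond,
                    density,
                    seed=config.seed_hr_model + 104729 * r,
                    protocol=config.protocol(),
                ).hr_norm
                for r in range(max(1, config.hr_runs // 2))
            ]
            model_hr[(amp, freq, freq)] = float(np.mean(vals))
    agreement = _within_one_sd(pd.Series(model_hr), summary, "hr_norm")
    done(fraction_within_1sd=agreement)
    report["hr_agreement_within_1sd"] = agreement

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
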