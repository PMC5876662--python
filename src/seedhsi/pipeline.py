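"""End-to-end orchestration: simulate -> build -> preprocess -> select ->
train -> evaluate -> report, as a pure function of one run configuration.

Stages communicate via plain files (CSV spectra tables, JSON reports); a
manifest records every artifact with a checksum so reruns can be verified
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import spectra_to_frame
from .datasets import MixtureConfig
from .evaluate import ExperimentConfig, run_experiment, run_mixture_proportions
from .synthetic import NoiseSpec, Population, PopulationSpec, generate_population


@dataclass
class RunConfig:
    rng_seed: int = 42
    n_cal_viable: int = 75
    n_cal_nonviable: int = 31
    n_pred_viable: int = 38
    n_pred_nonviable: int = 16
    separation: float = 0.05
    gain_sd: float = 0.08
    offset_sd: float = 0.01
    baseline_amp: float = 0.01
    white_sd: float = 0.005
    kinds: tuple[str, ...] = ("ventral", "reverse", "mean", "mixture")
    methods: tuple[str, ...] = ("raw", "snv", "msc", "sg")
    selectors: tuple[bool, ...] = (False, True)
    models: tuple[str, ...] = ("plsda", "svm")
    k_min: int = 5
    k_max: int | None = None
    max_lv: int = 20
    mixture_proportions: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kinds", "methods", "selectors", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("kinds", "methods", "selectors", "models"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def population_spec(self) -> PopulationSpec:
        return PopulationSpec(
            n_cal_viable=self.n_cal_viable,
            n_cal_nonviable=self.n_cal_nonviable,
            n_pred_viable=self.n_pred_viable,
            n_pred_nonviable=self.n_pred_nonviable,
            separation=self.separation,
            noise=NoiseSpec(
                gain_sd=self.gain_sd, offset_sd=self.offset_sd,
                baseline_amp=self.baseline_amp, white_sd=self.white_sd,
                rng_seed=self.rng_seed,
            ),
        )

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            kinds=self.kinds, methods=self.methods, selectors=self.selectors,
            models=self.models, k_min=self.k_min, k_max=self.k_max,
            max_lv=self.max_lv, rng_seed=self.rng_seed,
            mixture_config=MixtureConfig(27, 27, self.rng_seed),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.6g")
        artifacts.append(p)

    stage = "simulate"
    try:
        population = generate_population(config.population_spec())
        save_df(spectra_to_frame(population.spectra), "spectra.csv")

        stage = "experiment-grid"
        report = run_experiment(population, config.experiment_config())
        save_df(report, "grid_report.csv")
        (outdir / "grid_report.json").write_text(report.to_json(orient="records", indent=2))
        artifacts.append(outdir / "grid_report.json")

        if config.mixture_proportions:
            stage = "mixture-proportions"
            mix = run_mixture_proportions(
                population, rng_seed=config.rng_seed,
                k_min=config.k_min, k_max=config.k_max, max_lv=config.max_lv,
            )
            save_df(mix, "mixture_proportions.csv")
    except Exception as exc:  # re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config.to_yaml(outdir / "run_config.yaml")
    artifacts.append(outdir / "run_config.yaml")
    manifest = {p.name: _sha256(p) for p in artifacts}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def population_from_config(config: RunConfig) -> Population:
    return generate_population(config.population_spec())
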