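"""End-to-end pipeline: simulate -> estimate -> predict -> validate.

A single :class:`RunConfig` drives the whole chain; every run writes a
provenance record (configuration, package version, seed) next to its
outputs so a result bundle can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .estimation import calibrate_group, delta_F_LGPL, pathway_ratios
from .exceptions import ModelError, ParameterError
from .io import (
    write_agreement_json,
    write_estimates_csv,
    write_isometric_csv,
    write_prediction_csv,
    write_stiffness_yaml,
)
from .prediction import bland_altman, predict_delta_F
from .reference import scale_factor_r, stiffness_for_group
from .synthetic import SyntheticSpec, generate_calibration_dataset, generate_testing_dataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (validated before any work)."""

    out_dir: str = "results"
    group: str = "NO"
    c: float = 0.9
    window_ms: float = 50.0
    symmetry: bool = True
    seed: int = 0
    n_animals: int = 7
    noise_sd_N: float = 0.0
    r: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.c <= 1.0):
            raise ParameterError(f"c must lie in (0, 1], got {self.c}")
        if self.window_ms <= 0:
            raise ParameterError("window_ms must be positive")
        if self.group not in ("NO", "TI"):
            raise ParameterError(f"group must be 'NO' or 'TI', got {self.group!r}")
        if self.n_animals < 1:
            raise ParameterError("n_animals must be >= 1")
        if self.noise_sd_N < 0:
            raise ParameterError("noise_sd_N must be non-negative")
        if self.r is not None:
            object.__setattr__(self, "r", tuple(float(v) for v in self.r))

    @classmethod
    def from_yaml(cls, path: "str | Path", **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)


def write_provenance(config: RunConfig, out_dir: Path) -> None:
    record = {
        "package": "epimuscular",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(record, indent=2, sort_keys=True) + "\n"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-experiment pipeline and write a result bundle.

    Stages: (1) simulate calibration and testing datasets from the bundled
    ground truth for the configured group; (2) calibrate pathway
    stiffnesses from the calibration data; (3) predict the proximal-only
    force difference with the scale factors r; (4) validate the prediction
    against the simulated testing measurements.  Deterministic given the
    seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = stiffness_for_group(config.group)
    r = config.r if config.r is not None else scale_factor_r()
    spec = SyntheticSpec(
        truth=truth,
        r=r,
        n_animals=config.n_animals,
        noise_sd_N=config.noise_sd_N,
        seed=config.seed,
    )

    log.info("stage simulate: group=%s animals=%d noise=%g seed=%d",
             config.group, config.n_animals, config.noise_sd_N, config.seed)
    calibration = generate_calibration_dataset(spec)
    testing = generate_testing_dataset(spec)
    write_isometric_csv(calibration, out_dir / "calibration.csv")
    write_isometric_csv(testing, out_dir / "testing.csv")

    log.info("stage estimate: c=%g symmetry=%s", config.c, config.symmetry)
    result = calibrate_group(calibration, c=config.c, symmetry=config.symmetry)
    write_stiffness_yaml(result.stiffness, out_dir / "stiffness.yaml")
    first_animal = sorted(result.estimates)[0]
    estimates = result.estimates[first_animal]
    write_estimates_csv(
        pathway_ratios(estimates, result.f_prox_mean_N),
        out_dir / "pathway_ratios_pct.csv",
    )

    log.info("stage predict: r=%s", r)
    grid = np.asarray(spec.protocol.positions)
    prediction = predict_delta_F(result.stiffness, r, grid)
    write_prediction_csv(prediction, out_dir / "prediction.csv")

    log.info("stage validate: %d testing tables", len(testing))
    measured = np.concatenate(
        [delta_F_LGPL(t).to_numpy() for t in testing]
    )
    predicted = np.tile(prediction.delta_f_N, len(testing))
    agreement = bland_altman(measured, predicted)
    write_agreement_json(agreement, out_dir / "agreement.json")

    write_provenance(config, out_dir)
    return {
        "stiffness": result.stiffness,
        "prediction": prediction,
        "agreement": agreement,
        "out_dir": out_dir,
    }


def run_pipeline_checked(config: RunConfig) -> int:
    """CLI-facing wrapper: returns a process exit status instead of raising
    on stage errors."""
    try:
        run_pipeline(config)
    except ModelError as exc:
        log.error("pipeline failed: %s", exc)
        return 1
    return 0
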