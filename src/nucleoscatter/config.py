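"""Experiment configuration: strict parsing, YAML round trip, stable hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError

__all__ = [
    "DatasetSection",
    "ForwardSection",
    "PreprocessSection",
    "RegressorSection",
    "CVSection",
    "ExperimentConfig",
    "load_config",
    "save_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DatasetSection(_Strict):
    shapes: list[Literal["sphere", "ellipsoid"]] = ["sphere", "ellipsoid"]
    corr_lengths_um: Optional[list[float]] = [0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
    fluct_stds: Optional[list[float]] = [0.005, 0.010, 0.015, 0.020, 0.025, 0.030, 0.035]
    pairs: Optional[list[tuple[float, float]]] = None
    replicates: int = Field(3, ge=1)
    voxel_um: float = Field(0.1, gt=0)
    radius_um: float = Field(4.0, gt=0)
    semiaxes_um: tuple[float, float, float] = (3.0, 4.0, 5.0)
    n_mean: float = 1.40
    n_cyto: float = 1.36
    base_seed: int = 0
    padding_um: float = Field(1.0, ge=0)

    @field_validator("corr_lengths_um")
    @classmethod
    def _positive_lc(cls, v):
        if v is not None and any(x <= 0 for x in v):
            raise ValueError("corr_lengths_um entries must be > 0")
        return v

    @field_validator("fluct_stds")
    @classmethod
    def _nonneg_dn(cls, v):
        if v is not None and any(x < 0 for x in v):
            raise ValueError("fluct_stds entries must be >= 0")
        return v


class ForwardSection(_Strict):
    wavelength_nm: float = Field(800.0, gt=0)
    pad_factor: int = Field(2, ge=1)


class PreprocessSection(_Strict):
    # either one (min, max) range for all targets, or one range per target
    # keyed by "corr_length" / "fluct_std"
    crop_theta: Optional[tuple[int, int] | dict[str, tuple[int, int]]] = None
    noise_snr_db: list[float] = []

    @field_validator("crop_theta")
    @classmethod
    def _valid_crop(cls, v):
        if v is None:
            return v
        ranges = v.values() if isinstance(v, dict) else [v]
        for tmin, tmax in ranges:
            if not (0 <= tmin < tmax <= 180):
                raise ValueError("crop_theta must satisfy 0 <= min < max <= 180")
        if isinstance(v, dict):
            bad = set(v) - {"corr_length", "fluct_std"}
            if bad:
                raise ValueError(f"unknown crop_theta targets: {sorted(bad)}")
        return v

    def crop_for(self, target: str):
        if isinstance(self.crop_theta, dict):
            return self.crop_theta.get(target)
        return self.crop_theta


class RegressorSection(_Strict):
    # epochs may be one integer or one per target ("corr_length"/"fluct_std")
    epochs: int | dict[str, int] = Field(200)
    batch_size: int = Field(16, ge=1)
    learning_rate: float = Field(5e-4, gt=0)
    dropout_rate: float = Field(0.5, ge=0, lt=1)

    @field_validator("epochs")
    @classmethod
    def _valid_epochs(cls, v):
        values = v.values() if isinstance(v, dict) else [v]
        if any(int(e) < 1 for e in values):
            raise ValueError("epochs must be >= 1")
        if isinstance(v, dict):
            bad = set(v) - {"corr_length", "fluct_std"}
            if bad:
                raise ValueError(f"unknown epochs targets: {sorted(bad)}")
        return v

    def epochs_for(self, target: str) -> int:
        if isinstance(self.epochs, dict):
            return int(self.epochs[target])
        return int(self.epochs)


class CVSection(_Strict):
    n_folds: int = Field(5, ge=2)
    seed: int = 0


class ExperimentConfig(_Strict):
    dataset: DatasetSection = DatasetSection()
    forward: ForwardSection = ForwardSection()
    preprocess: PreprocessSection = PreprocessSection()
    regressor: RegressorSection = RegressorSection()
    cv: CVSection = CVSection()
    targets: list[Literal["corr_length", "fluct_std"]] = ["corr_length", "fluct_std"]

    def config_hash(self) -> str:
        """Stable content hash of the full configuration."""
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse a YAML (or JSON) experiment config with strict validation."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"),
                                         sort_keys=True))
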