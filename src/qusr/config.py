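"""Schema-validated pipeline configuration (YAML).

Unknown keys are rejected everywhere (``extra="forbid"``), so a typo in a
config file fails loudly before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .rf_synth import (
    EffectSizes,
    FrameGeometry,
    PulseModel,
    SyntheticCohortConfig,
)
from .spectra import SpectralConfig
from .texture import GLCMConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PulseSection(_Strict):
    centre_frequency: float = 6.5
    fractional_bandwidth: float = 0.85
    sampling_rate: float = 40.0
    sound_speed: float = 1540.0

    def build(self) -> PulseModel:
        return PulseModel(**self.model_dump())


class GeometrySection(_Strict):
    depth_mm: float = 40.0
    n_lines: int = 256
    line_pitch_mm: float = 0.23
    n_frames: int = 3
    plane_spacing_cm: float = 0.5

    def build(self) -> FrameGeometry:
        return FrameGeometry(**self.model_dump())


class EffectSection(_Strict):
    amp_scale_factor: float = 1.25
    cluster_fraction_increase: float = 0.2
    cluster_std_mm: float = 0.45
    radius_factor: float = 1.12

    def build(self) -> EffectSizes:
        return EffectSizes(**self.model_dump())


class CohortSection(_Strict):
    n_patients: int = 100
    nonresponder_fraction: float = Field(0.19, ge=0.0, le=1.0)
    noise_sd: float = 0.5
    base_density_per_mm2: float = 3.0
    base_amp_std: float = 1.0
    base_radius_um: float = 35.0
    attenuation: float = 0.5
    heterogeneity: float = 0.25
    roi_semiaxes_mm: tuple[float, float] = (8.0, 10.0)
    effects: EffectSection = Field(default_factory=EffectSection)

    def build(self, seed: int, geometry: FrameGeometry, pulse: PulseModel) -> SyntheticCohortConfig:
        d = self.model_dump()
        eff = d.pop("effects")
        return SyntheticCohortConfig(
            seed=seed,
            geometry=geometry,
            pulse=pulse,
            effect_sizes=EffectSizes(**eff),
            **d,
        )


class SpectralSection(_Strict):
    window_length_mm: float = 2.0
    window_width_mm: float = 2.0
    axial_overlap: float = 0.8
    lateral_overlap: float = 0.8
    analysis_band: tuple[float, float] = (3.0, 8.5)

    def build(self) -> SpectralConfig:
        return SpectralConfig(**self.model_dump())


class GLCMSection(_Strict):
    n_levels: int = 16
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    quantization: str = "minmax"

    def build(self) -> GLCMConfig:
        return GLCMConfig(**self.model_dump())


class ModelSection(_Strict):
    n_features: int = 3
    class_weight: str | None = "balanced"
    cv_folds: int = 5
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float | str, ...] = ("scale", 0.01, 0.1, 1.0)
    indeterminate_margin: float = 0.25


class PipelineConfig(_Strict):
    seed: int = 0
    development: CohortSection = Field(default_factory=CohortSection)
    validation: CohortSection = Field(
        default_factory=lambda: CohortSection(n_patients=51, nonresponder_fraction=0.12)
    )
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    pulse: PulseSection = Field(default_factory=PulseSection)
    reference_density_per_mm2: float = 4.0
    reference_attenuation: float = 0.3
    spectral: SpectralSection = Field(default_factory=SpectralSection)
    glcm: GLCMSection = Field(default_factory=GLCMSection)
    model: ModelSection = Field(default_factory=ModelSection)
    exclude: tuple[str, ...] = ()

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)
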