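"""Validated pipeline configuration (YAML/JSON), with schema rejection of
unknown keys so typos fail loudly rather than silently using defaults."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessCfg(_Strict):
    median_size: int = 3
    log_sigma_px: float = 0.7
    log_mode: str = "sharpen"  # "sharpen" (image - LoG) or "response" (raw LoG)
    apply_to_planning_ct: bool = False


class RegistrationCfg(_Strict):
    coarse_spacing_mm: float = 5.0
    dilation_px: int = 20


class EnhanceCfg(_Strict):
    gamma: float = 1.0
    sigma_mm: float | None = None  # None -> auto = d/4 from the GTV


class PhantomCfg(_Strict):
    experiment: str = "phantom"  # "phantom" (3 stations) or "clinical" (10 x 4)
    n_cases: int = 10
    n_fractions: int = 4
    tumor_diameter_mm: float = 10.0  # validation-phantom sphere size
    blur_fwhm_mm: float = 3.0
    noise_sd: float = 20.0
    contrast_scale: float = 0.6
    fov_mm: float = 128.0
    max_shift_mm: float = 6.0
    shift_mm: tuple[float, float, float] | None = None  # fixed shift (phantom runs)


class PipelineConfig(_Strict):
    """Top-level configuration for `run-all` experiments."""

    seed: int = 0
    modes: list[str] = Field(default_factory=lambda: ["none", "sobel", "bse"])
    outdir: str = "tumorloc_out"
    preprocess: PreprocessCfg = Field(default_factory=PreprocessCfg)
    registration: RegistrationCfg = Field(default_factory=RegistrationCfg)
    enhance: EnhanceCfg = Field(default_factory=EnhanceCfg)
    phantom: PhantomCfg = Field(default_factory=PhantomCfg)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML or JSON config file; keyword overrides win."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    data.update(overrides)
    return PipelineConfig.model_validate(data)
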