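"""Study configuration: validated parameter schema with lossless file I/O.

All tunables of the pipeline live in one :class:`StudyConfig`; defaults are
the reference study conditions (256 Hz, 1200 ms trials with 200 ms baseline,
source SNR 20, scalp SNR grid {1,3,5,10}, trial grid up to 100, MVAR order 8,
update constant 0.02, 1-40 Hz analysis band).  Configs round-trip through
YAML or JSON; unknown keys are rejected by name.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["StudyConfig", "load_config", "save_config"]


class StudyConfig(BaseModel):
    """Validated configuration for the full pipeline and factorial study."""

    model_config = ConfigDict(extra="forbid")

    # ground truth
    fs: float = 256.0
    duration_ms: float = 1200.0
    baseline_ms: float = 200.0
    source_snr: float = 20.0
    n_trials: int = 100

    # forward model
    n_vertices: int = 2000
    n_electrodes: int = 64
    fold_amplitude_mm: float = 6.0
    scalp_snr: float = 10.0
    target_peak_amplitude: float = 50.0

    # inverse
    noise_cov_reg: float = 0.1

    # selection
    roi_size: int = 45
    selection_strategies: list[str] = Field(
        default_factory=lambda: ["GT1", "GT2", "DD1", "DD2", "DD3", "DD4", "DD5"]
    )

    # time-varying MVAR / PDC
    order: int = 8
    uc: float = 0.02
    freq_min_hz: float = 1.0
    freq_max_hz: float = 40.0
    freq_step_hz: float = 1.0
    fit_method: str = "glkf"
    pdc_strategy: str = "GLKF"
    fit_selection: str = "DD1"

    # factorial study
    snr_levels: list[float] = Field(default_factory=lambda: [1, 3, 5, 10])
    trial_counts: list[int] = Field(
        default_factory=lambda: [3, 5, 10, 20, 40, 60, 80, 100]
    )
    n_realizations: int = 100

    seed: int = 0

    @field_validator("uc")
    @classmethod
    def _uc_range(cls, v):
        if not 0 < v < 1:
            raise ValueError("uc must lie in (0, 1)")
        return v

    @field_validator("fit_method")
    @classmethod
    def _method(cls, v):
        if v not in ("ckf", "glkf"):
            raise ValueError("fit_method must be 'ckf' or 'glkf'")
        return v

    def freqs_hz(self):
        import numpy as np

        return np.arange(
            self.freq_min_hz, self.freq_max_hz + self.freq_step_hz / 2,
            self.freq_step_hz,
        )

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> StudyConfig:
    """Load a YAML or JSON config; an empty file yields all defaults.

    Raises a ``ValueError`` naming any unknown key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    try:
        return StudyConfig(**data)
    except Exception as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def save_config(config: StudyConfig, path) -> None:
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
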