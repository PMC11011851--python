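"""Run configuration: a documented, strictly-validated schema.

Every pipeline run is described by a YAML file parsed into
:class:`RunConfig`.  Unknown keys are rejected (typos must not silently
fall back to defaults), every default is visible in the model, and the
configuration actually used is serialised into the run's output
directory so any result can be replayed exactly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Section):
    """Synthetic study design (images, spectra, assays)."""

    meat_type: Literal["lamb", "beef", "buffalo", "custom"] = "lamb"
    days: list[int] = [1, 4, 8, 11, 14, 16]
    slices_per_day: int = 8
    image_size: tuple[int, int] = (512, 512)
    base_lab: tuple[float, float, float] = (42.0, 25.0, 9.3)
    fade_rates: tuple[float, float] = (-0.5, -0.35)
    marbling_scale: float = 24.0
    marbling_amplitude: float = 5.0
    fragmentation_rate: float = 0.4
    noise_sd: float = 0.8
    spectrum_noise_sd: float = 0.0
    assay_replicates: int = 8


class ImagingSection(_Section):
    n_rois: int = 8
    roi_size: tuple[int, int] = (96, 96)
    roi_strategy: Literal["grid", "random_nonoverlap"] = "grid"
    levels: int = 32
    distance: int = 1
    angles: list[int] = [0, 45, 90, 135]
    directions: list[int] = [0, 45, 90, 135]
    aggregation: Literal["per_roi", "slice_mean"] = "per_roi"


class ChemometricsSection(_Section):
    classifier: str = "decision_tree"
    max_subset_size: int = 5
    label: str = "day"
    classes: Optional[list] = None  # e.g. [1, 16]; None = all classes
    k_folds: int = 5
    n_trees: int = 300
    learning_rate: float = 0.1
    max_depth: int = 2


class FTIRSection(_Section):
    sg_window: int = 9
    sg_poly: int = 3
    prominence_threshold: float = 0.0
    center_window: float = 2.0
    sigma_bounds: tuple[float, float] = (2.0, 20.0)
    atr_reference: float = 3284.77


class StatsSection(_Section):
    alpha: float = 0.05
    test: Literal["tukey", "mann_whitney"] = "tukey"


class RunConfig(_Section):
    """Full, replayable description of one pipeline run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    imaging: ImagingSection = Field(default_factory=ImagingSection)
    chemometrics: ChemometricsSection = Field(default_factory=ChemometricsSection)
    ftir: FTIRSection = Field(default_factory=FTIRSection)
    stats: StatsSection = Field(default_factory=StatsSection)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def demo_config(out_dir: str = "runs/demo", seed: int = 0) -> RunConfig:
    """A light, purely synthetic end-to-end demonstration configuration."""
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        synthetic=SyntheticSection(
            days=[1, 8, 16], slices_per_day=4, image_size=(128, 128)
        ),
        imaging=ImagingSection(n_rois=4, roi_size=(48, 48)),
        chemometrics=ChemometricsSection(
            max_subset_size=2, classes=[1, 16], n_trees=100
        ),
    )
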