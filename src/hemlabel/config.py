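"""Pipeline configuration models.

Every stage reads its parameters from a pydantic model; unknown keys are
rejected so a typo in a YAML file fails loudly instead of silently falling
back to a default. ``PipelineConfig.from_yaml`` loads the whole tree.
"""
from __future__ import annotations

from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class NormalizationConfig(_Strict):
    """Stain color normalization of H&E slides to a template."""

    method: Literal["vahadane", "macenko", "reinhard"] = "vahadane"
    #: OD cutoff below which a pixel is treated as background during fitting.
    beta: float = 0.15
    #: Sparsity weight of the Vahadane dictionary fit.
    sparsity: float = 0.1
    #: Template slide_id, or None for automatic median-of-means selection.
    template: Optional[str] = None
    #: Pixel subsample cap for stain-matrix fitting (keeps fits fast).
    max_fit_pixels: int = 10000
    #: Concentration percentile matched between source and template.
    scale_percentile: float = 99.0


class RegistrationConfig(_Strict):
    """Affine + B-spline mutual-information registration of IHC onto H&E."""

    downscale: int = Field(default=5, ge=1)
    histogram_bins: int = Field(default=50, ge=2)
    learning_rate: float = 1.0
    iterations: int = 200
    shrink_factors: List[int] = [8, 4, 2, 1]
    smoothing_sigmas: List[float] = [3.0, 2.0, 1.0, 0.0]
    use_bspline: bool = True
    #: B-spline control-point spacing in pixels at fitting resolution.
    bspline_spacing_px: float = 64.0
    #: Number of B-spline refinement levels (grid halves each level).
    bspline_levels: int = 2
    bspline_iterations: int = 100
    #: Fraction of pixels sampled per B-spline metric evaluation.
    bspline_sampling_fraction: float = 0.25
    seed: int = 0


class LabelingConfig(_Strict):
    """Tile-level label transfer parameters."""

    tile_px: int = Field(default=224, ge=1)
    downscale: int = Field(default=5, ge=1)
    #: A tile is cancer when more than this fraction of its pixels is
    #: DAB-positive (the 2% rule).
    cancer_fraction_threshold: float = 0.02
    #: Mean-DAB-OD band inside which a tile is labeled uncertain. With
    #: chromogen deposits near OD 1 a tile's mean DAB OD approximates its
    #: positive-area fraction, so the default band spans "clearly above
    #: faint background staining" to "majority positive": tiles in between
    #: are ambiguous mixtures and excluded from training and testing.
    dab_uncertain_low: float = 0.05
    dab_uncertain_high: float = 0.45
    #: Minimum tissue fraction for a tile to count as "containing tissue".
    tissue_presence_min: float = 0.05
    #: Apply the slide-status training filter in build_dataset.
    train_filter: bool = True
    tissue_method: Literal["otsu", "grabcut"] = "otsu"
    #: Fraction of tile area inside a pathologist annotation to call cancer.
    annotation_cover_threshold: float = 0.5

    @property
    def label_tile_px(self) -> int:
        """Tile size on the downscaled registered IHC image (45 for 224/5)."""
        return round(self.tile_px / self.downscale)

    @model_validator(mode="after")
    def _band_ordered(self) -> "LabelingConfig":
        if not 0.0 <= self.dab_uncertain_low <= self.dab_uncertain_high:
            raise ValueError("require 0 <= dab_uncertain_low <= dab_uncertain_high")
        return self


class ClassifierConfig(_Strict):
    """Transfer-learning tile classifier: frozen backbone + dense head."""

    backbone: Literal[
        "tiny", "vgg16", "vgg19", "resnet50", "inceptionv3", "xception"
    ] = "tiny"
    head_width: int = 256
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 64
    #: Augment training tiles with the 8 rotation/flip (dihedral) variants.
    augment: bool = True
    validation_fraction: float = 0.1
    seed: int = 0


class EvaluationConfig(_Strict):
    """Scoring and purity estimation."""

    #: Probability cutoff binarizing tile predictions for purity.
    threshold: float = 0.5
    #: Weight purity by p_cancer instead of the binarized call.
    probabilistic_purity: bool = False
    balancing_seed: int = 0


class PipelineConfig(_Strict):
    """Top-level configuration shared by every stage."""

    seed: int = 0
    verbosity: int = 1
    normalization: NormalizationConfig = NormalizationConfig()
    registration: RegistrationConfig = RegistrationConfig()
    labeling: LabelingConfig = LabelingConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    evaluation: EvaluationConfig = EvaluationConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
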