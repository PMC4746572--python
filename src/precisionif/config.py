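"""Validated run configuration.

All thresholds of the tissue-scoring pipeline live here.  Unknown keys are
rejected so a typo in a config file fails loudly instead of silently falling
back to a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "QuantConfig",
    "FilterConfig",
    "ScoringConfig",
    "HeterogeneityConfig",
    "RunConfig",
    "load_config",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class QuantConfig(_StrictModel):
    """Per-tile ROI determination and measurement."""

    #: minimum ROI size (pixels) for a tile measurement to count as valid
    min_roi_pixels: int = Field(default=50, ge=1)
    #: auto-thresholds below this intensity are treated as noise -> empty mask
    noise_floor: float = Field(default=0.12, ge=0.0, le=1.0)
    #: minimum CK-foreground fraction of the tile for a non-empty ROI
    min_foreground_fraction: float = Field(default=0.01, ge=0.0, le=1.0)
    #: dilation radius (pixels) applied to the nuclear mask before exclusion
    dilation_radius: int = Field(default=1, ge=0)


class FilterConfig(_StrictModel):
    """Case-wise tile filtering."""

    #: minimum number of valid tiles for a case to be scorable
    min_tiles: int = Field(default=20, ge=3)
    #: fallback percentile of ck_mean used when the distribution is unimodal
    fallback_percentile: float = Field(default=10.0, ge=0.0, le=100.0)
    #: Otsu effectiveness (between-class/total variance) required to call the
    #: per-tile CK distribution bimodal; a unimodal Gaussian tops out near
    #: 0.64 and a uniform near 0.75, so the cutoff sits above both
    bimodality_cutoff: float = Field(default=0.8, ge=0.0, le=1.0)
    #: fraction of the brightest surviving tiles removed as artifact guard
    upper_fraction: float = Field(default=0.05, ge=0.0, lt=1.0)


class ScoringConfig(_StrictModel):
    """Ratio histogram, Gaussian fit and QC."""

    min_tiles: int = Field(default=20, ge=3)
    #: adjusted-R^2 cutoff below which a case is excluded
    r2_min: float = Field(default=0.5, le=1.0)
    #: hard cap on histogram bin count (Freedman-Diaconis can explode for
    #: near-degenerate spreads); generous because histograms share the
    #: batch-wide axis while bin width follows the case's own spread
    max_bins: int = Field(default=4096, ge=8)
    #: bin count when the Freedman-Diaconis rule degenerates
    fallback_bins: int = Field(default=50, ge=8)
    #: minimum occupied bins for a Gaussian fit to be attempted
    min_occupied_bins: int = Field(default=3, ge=3)


class HeterogeneityConfig(_StrictModel):
    """Two-population (subclone) detection on the ratio distribution."""

    min_tiles: int = Field(default=30, ge=10)
    #: BIC advantage the 2-component mixture must have over 1 component
    bic_margin: float = Field(default=10.0, ge=0.0)
    #: required separation of component means, in units of pooled sigma
    separation: float = Field(default=2.0, gt=0.0)
    n_init: int = Field(default=3, ge=1)
    max_iter: int = Field(default=200, ge=10)


class RunConfig(_StrictModel):
    """Top-level configuration for the tissue-scoring pipeline."""

    quant: QuantConfig = QuantConfig()
    filter: FilterConfig = FilterConfig()
    scoring: ScoringConfig = ScoringConfig()
    heterogeneity: HeterogeneityConfig = HeterogeneityConfig()
    seed: int = Field(default=0, ge=0)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (nested key-value) config file into a validated RunConfig."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
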