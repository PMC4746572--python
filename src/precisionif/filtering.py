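"""Case-wise tile filtering.

Two filters run per case, in order:

1. a *lower* CK filter removing tiles with little or no epithelium — their
   tile-averaged CK falls below a case-specific threshold; and
2. an *upper* filter removing the 5% brightest remaining CK tiles, guarding
   against saturating artifacts such as small fluorophore agglomerates.

The lower threshold exploits the bimodal stroma/epithelium structure of the
per-tile CK distribution: Otsu's criterion when the distribution is bimodal
enough, a percentile fallback otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .config import FilterConfig
from .errors import UnscorableCaseError
from .quantify import TileMeasurement

__all__ = ["FilterReport", "lower_ck_threshold", "apply_filters"]


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping of one case's tile filtering.

    ``n_input`` counts valid measurements; invalid tiles (empty/tiny ROI) are
    counted separately in ``n_invalid`` and never reach the filters, so
    ``n_retained == n_input - n_below_lower - n_removed_upper`` holds exactly,
    with ``n_removed_upper == floor(upper_fraction * (n_input - n_below_lower))``.
    """

    n_input: int
    n_below_lower: int
    n_removed_upper: int
    n_retained: int
    lower_threshold: float
    upper_threshold: float  # +inf when no tile was removed by the upper filter
    n_invalid: int = 0


def _otsu_effectiveness(values: np.ndarray, threshold: float) -> float:
    """Between-class variance at ``threshold`` divided by total variance."""
    total_var = values.var()
    if total_var == 0:
        return 0.0
    low = values < threshold
    w0 = low.mean()
    w1 = 1.0 - w0
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = values[low].mean()
    mu1 = values[~low].mean()
    return float(w0 * w1 * (mu0 - mu1) ** 2 / total_var)


def lower_ck_threshold(
    measurements: Sequence[TileMeasurement], config: FilterConfig | None = None
) -> float:
    """Case-specific lower CK threshold from the per-tile ck_mean distribution.

    Otsu on the ck_mean values when their histogram is bimodal (Otsu
    effectiveness above ``config.bimodality_cutoff``), else the
    ``config.fallback_percentile`` of the distribution.  The bimodality
    decision is taken on the distribution with its brightest
    ``upper_fraction`` trimmed off: those tiles are artifact suspects that
    the upper filter removes anyway, and a handful of saturating tiles would
    otherwise mimic an upper mode and drag the threshold into the epithelial
    bulk.
    """
    config = config or FilterConfig()
    values = np.array([m.ck_mean for m in measurements if m.valid], dtype=float)
    if values.size < config.min_tiles:
        raise UnscorableCaseError(
            "excluded_few_tiles",
            f"{values.size} valid tiles < min_tiles={config.min_tiles}",
        )
    if np.ptp(values) == 0:
        return float(values[0])
    trimmed = values[values <= np.percentile(values, 100.0 * (1.0 - config.upper_fraction))]
    if np.ptp(trimmed) > 0:
        candidate = float(threshold_otsu(trimmed, nbins=min(256, trimmed.size)))
        bimodal = _otsu_effectiveness(trimmed, candidate) >= config.bimodality_cutoff
        # a stroma/epithelium split never strands the majority of tiles below
        # the threshold; when it would, the "lower mode" is the epithelial
        # bulk itself (e.g. a near-delta CK distribution plus a bright tail)
        majority_kept = (values < candidate).mean() <= 0.5
        if bimodal and majority_kept:
            return candidate
    return float(np.percentile(values, config.fallback_percentile))


def apply_filters(
    measurements: Sequence[TileMeasurement], config: FilterConfig | None = None
) -> tuple[list[TileMeasurement], FilterReport]:
    """Drop invalid tiles, then the lower-CK tiles, then the brightest 5%.

    The upper filter removes exactly ``floor(upper_fraction * n_survivors)``
    tiles with the highest ck_mean; ties are broken deterministically by
    tile_id lexicographic order.  Retained tiles keep their input order.
    """
    config = config or FilterConfig()
    valid = [m for m in measurements if m.valid]
    n_invalid = len(measurements) - len(valid)
    lower = lower_ck_threshold(valid, config)  # raises when too few valid tiles
    survivors = [m for m in valid if m.ck_mean >= lower]
    if len(survivors) < config.min_tiles:
        raise UnscorableCaseError(
            "excluded_few_tiles",
            f"{len(survivors)} tiles above the lower CK threshold "
            f"< min_tiles={config.min_tiles}",
        )
    n_remove = math.floor(config.upper_fraction * len(survivors))
    if n_remove > 0:
        brightest_first = sorted(survivors, key=lambda m: (-m.ck_mean, m.tile_id))
        removed = brightest_first[:n_remove]
        upper = min(m.ck_mean for m in removed)
        removed_ids = {id(m) for m in removed}
        retained = [m for m in survivors if id(m) not in removed_ids]
    else:
        upper = float("inf")
        retained = list(survivors)
    report = FilterReport(
        n_input=len(valid),
        n_below_lower=len(valid) - len(survivors),
        n_removed_upper=n_remove,
        n_retained=len(retained),
        lower_threshold=lower,
        upper_threshold=upper,
        n_invalid=n_invalid,
    )
    return retained, report
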