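"""Cohort-level analysis: FISH classification, score correlations,
scatter-plot export, and heterogeneity flagging.

Scores of the non-control cases are correlated against the cell-averaged
gene copy number N_FISH (or the HER2/CEP17 ratio) with a Pearson coefficient
and a power-law fit y ~ x^alpha (ordinary least squares in log-log space).
Intra-tumoral heterogeneity — two tumor subpopulations expressing the marker
at different levels — shows up as a bimodal ratio distribution and is
flagged with a 1- vs 2-component Gaussian-mixture comparison under BIC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .config import HeterogeneityConfig
from .quantify import TileMeasurement
from .scoring import QCStatus, ScoreSet

__all__ = [
    "FishClass",
    "CohortRecord",
    "CorrelationResult",
    "HeterogeneityResult",
    "classify_fish",
    "correlate_scores",
    "scatter_export",
    "flag_heterogeneity",
]

logger = logging.getLogger(__name__)

SCORE_NAMES = ("M", "Sigma", "MTP")


class FishClass(str, Enum):
    NEGATIVE = "Negative"
    EQUIVOCAL = "Equivocal"
    POSITIVE = "Positive"


def classify_fish(n_fish: float) -> FishClass:
    """Copy-number classification: <4 Negative, 4-<6 Equivocal, >=6 Positive."""
    if not (isinstance(n_fish, (int, float)) and math.isfinite(n_fish) and n_fish > 0):
        raise ValueError(f"n_fish must be a positive finite number, got {n_fish!r}")
    if n_fish < 4.0:
        return FishClass.NEGATIVE
    if n_fish < 6.0:
        return FishClass.EQUIVOCAL
    return FishClass.POSITIVE


@dataclass(frozen=True)
class CohortRecord:
    """Per-case clinical metadata."""

    case_id: str
    batch_id: str
    role: str  # {"case", "pos_control", "neg_control"}
    n_fish: float  # mean HER2 gene copy number per cell
    her2_cep17: float = float("nan")
    ihc_score: str = ""  # ordinal {0, 1+, 2+, 3+}

    def __post_init__(self) -> None:
        if self.role not in ("case", "pos_control", "neg_control"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def fish_class(self) -> FishClass:
        return classify_fish(self.n_fish)


@dataclass(frozen=True)
class CorrelationResult:
    score_name: str
    rho: float  # Pearson coefficient
    alpha: float  # power-law exponent of y ~ x^alpha
    n_cases: int
    n_excluded_log: int = 0  # non-positive values excluded from the log-log fit


def correlate_scores(
    scores: Sequence[ScoreSet],
    records: Sequence[CohortRecord],
    x_variable: str = "n_fish",
) -> list[CorrelationResult]:
    """Pearson rho and power-law exponent per score vs a FISH readout.

    ``scores[i]`` must correspond to ``records[i]``.  Controls and cases that
    failed QC are excluded; cases with non-positive score or x drop out of
    the log-log fit only (with a logged count).  Invariant to case ordering.
    """
    if x_variable not in ("n_fish", "her2_cep17"):
        raise ValueError(f"unknown x_variable {x_variable!r}")
    if len(scores) != len(records):
        raise ValueError("scores and records must be paired one-to-one")
    usable = [
        (getattr(rec, x_variable), sc)
        for sc, rec in zip(scores, records)
        if rec.role == "case" and sc.qc_status == QCStatus.PASS
        and math.isfinite(getattr(rec, x_variable))
    ]
    if len(usable) < 3:
        raise ValueError(f"need >=3 usable cases, got {len(usable)}")
    x = np.array([u[0] for u in usable], dtype=float)
    results = []
    for name, getter in zip(
        SCORE_NAMES,
        (lambda s: s.m_score, lambda s: s.sigma_score, lambda s: s.mtp_score),
    ):
        y = np.array([getter(u[1]) for u in usable], dtype=float)
        rho = float(stats.pearsonr(x, y).statistic)
        pos = (x > 0) & (y > 0)
        n_excluded = int((~pos).sum())
        if n_excluded:
            logger.warning(
                "correlate_scores[%s]: %d cases with non-positive values "
                "excluded from the power-law fit", name, n_excluded)
        if pos.sum() >= 3:
            alpha = float(stats.linregress(np.log(x[pos]), np.log(y[pos])).slope)
        else:
            alpha = float("nan")
        results.append(CorrelationResult(
            score_name=name, rho=rho, alpha=alpha,
            n_cases=len(usable), n_excluded_log=n_excluded,
        ))
    return results


def scatter_export(
    measurements: Mapping[str, Sequence[TileMeasurement]],
    retained_ids: Mapping[str, set],
    roles: Mapping[str, str],
) -> pd.DataFrame:
    """Long-format per-tile table for scatter plotting.

    One row per tile of every case: (case_id, tile_row, tile_col, ck_mean,
    her2_mean, retained_flag, role).  ``retained_ids`` maps a case to the set
    of tile_ids that survived filtering.
    """
    rows = []
    for case_id, tiles in measurements.items():
        keep = retained_ids.get(case_id, set())
        role = roles.get(case_id, "case")
        for m in tiles:
            rows.append({
                "case_id": case_id,
                "tile_row": m.tile_id[0],
                "tile_col": m.tile_id[1],
                "ck_mean": m.ck_mean,
                "her2_mean": m.her2_mean,
                "retained_flag": m.tile_id in keep,
                "role": role,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HeterogeneityResult:
    flag: bool
    means: tuple[float, ...]
    weights: tuple[float, ...]
    bic_one: float
    bic_two: float


def flag_heterogeneity(
    ratios: Sequence[float], config: HeterogeneityConfig | None = None
) -> HeterogeneityResult:
    """Detect a two-population ratio distribution.

    Fits 1- and 2-component Gaussian mixtures; the case is heterogeneous when
    the 2-component model wins by ``config.bic_margin`` BIC units AND the
    component means are separated by more than ``config.separation`` pooled
    standard deviations.  Fit failures default to flag=False.
    """
    config = config or HeterogeneityConfig()
    arr = np.asarray(ratios, dtype=float).reshape(-1, 1)
    if arr.shape[0] < config.min_tiles:
        return HeterogeneityResult(False, (), (), float("nan"), float("nan"))
    try:
        gmms = [
            GaussianMixture(
                n_components=k, n_init=config.n_init, max_iter=config.max_iter,
                random_state=0,
            ).fit(arr)
            for k in (1, 2)
        ]
        bic1, bic2 = (float(g.bic(arr)) for g in gmms)
        g2 = gmms[1]
        means = tuple(sorted(float(m) for m in g2.means_.ravel()))
        weights = tuple(float(w) for w in g2.weights_.ravel())
        pooled_var = float((g2.weights_.ravel() * g2.covariances_.ravel()).sum())
        pooled_sigma = math.sqrt(max(pooled_var, 0.0))
        separated = (
            pooled_sigma > 0
            and abs(means[1] - means[0]) > config.separation * pooled_sigma
        )
        flag = (bic1 - bic2 > config.bic_margin) and separated
        return HeterogeneityResult(flag, means, weights, bic1, bic2)
    except Exception:  # fit failure is a soft negative, not an error
        logger.warning("flag_heterogeneity: mixture fit failed", exc_info=True)
        return HeterogeneityResult(False, (), (), float("nan"), float("nan"))
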