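"""Batch-wise scoring pipeline tying quantification, filtering and scoring.

``score_cohort`` consumes per-case tile measurements plus cohort metadata and
produces one :class:`CaseResult` per case: filter report, ratio histogram
Gaussian fit, QC status, batch-normalized scores and a heterogeneity flag.
Scores are normalized by the batch's positive control; a batch whose positive
control fails QC is unscorable as a whole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortRecord, HeterogeneityResult, flag_heterogeneity
from .config import RunConfig
from .errors import PipelineError, UnscorableCaseError
from .filtering import FilterReport, apply_filters
from .quantify import TileMeasurement
from .scoring import (
    GaussianFit,
    QCStatus,
    ScoreSet,
    build_histogram,
    fit_gaussian,
    qc_case,
    ratio_per_tile,
    score_case,
)

__all__ = ["CaseResult", "score_cohort", "results_to_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CaseResult:
    case_id: str
    batch_id: str
    role: str
    qc_status: QCStatus
    n_tiles_retained: int = 0
    filter_report: FilterReport | None = None
    fit: GaussianFit | None = None
    scores: ScoreSet | None = None
    heterogeneity: HeterogeneityResult | None = None
    ratios: np.ndarray | None = None


def _prepare_case(
    case_id: str,
    measurements: Sequence[TileMeasurement],
    config: RunConfig,
):
    """Filter a case and compute its ratios; None marks an unscorable case."""
    try:
        retained, report = apply_filters(measurements, config.filter)
    except UnscorableCaseError as exc:
        logger.warning("case %s unscorable at filtering: %s", case_id, exc)
        return None, None, None
    ratios = ratio_per_tile(retained)
    return retained, report, ratios


def score_cohort(
    measurements: Mapping[str, Sequence[TileMeasurement]],
    records: Sequence[CohortRecord],
    config: RunConfig | None = None,
) -> list[CaseResult]:
    """Score every case of a cohort, batch by batch."""
    config = config or RunConfig()
    by_id = {r.case_id: r for r in records}
    unknown = set(measurements) - set(by_id)
    if unknown:
        raise PipelineError(f"measurements for cases absent from the cohort table: {sorted(unknown)}")

    batches: dict[str, list[CohortRecord]] = {}
    for record in records:
        if record.case_id not in measurements:
            raise PipelineError(f"no measurements for case {record.case_id}")
        batches.setdefault(record.batch_id, []).append(record)

    results: list[CaseResult] = []
    for batch_id, batch_records in batches.items():
        roles = [r.role for r in batch_records]
        if roles.count("pos_control") != 1 or roles.count("neg_control") != 1:
            raise PipelineError(
                f"{batch_id} must contain exactly one positive and one "
                f"negative control (got roles {sorted(roles)})"
            )
        prepared = {
            r.case_id: _prepare_case(r.case_id, measurements[r.case_id], config)
            for r in batch_records
        }
        scorable_ratios = [p[2] for p in prepared.values() if p[2] is not None]
        batch_max = max((float(r.max()) for r in scorable_ratios), default=0.0)

        fits: dict[str, GaussianFit | None] = {}
        statuses: dict[str, QCStatus] = {}
        for r in batch_records:
            _, _, ratios = prepared[r.case_id]
            if ratios is None:
                fits[r.case_id] = None
                statuses[r.case_id] = QCStatus.EXCLUDED_FEW_TILES
                continue
            try:
                hist = build_histogram(ratios, config.scoring, upper=batch_max)
                fit = fit_gaussian(hist, config.scoring)
            except UnscorableCaseError:
                fits[r.case_id] = None
                statuses[r.case_id] = QCStatus.EXCLUDED_FEW_TILES
                continue
            fits[r.case_id] = fit
            statuses[r.case_id] = qc_case(fit, config.scoring)

        pos_id = next(r.case_id for r in batch_records if r.role == "pos_control")
        pos_fit = fits[pos_id]
        pos_ok = pos_fit is not None and statuses[pos_id] == QCStatus.PASS
        if not pos_ok:
            logger.error("%s: positive-control fit failed QC; batch unscorable", batch_id)

        for r in batch_records:
            retained, report, ratios = prepared[r.case_id]
            fit = fits[r.case_id]
            status = statuses[r.case_id]
            scores = None
            het = None
            if fit is not None and status == QCStatus.PASS and not pos_ok:
                status = QCStatus.EXCLUDED_CONTROL_FAILED
            if fit is not None and status == QCStatus.PASS:
                scores = score_case(fit, pos_fit, batch_id=batch_id, qc_status=status)
            if ratios is not None:
                het = flag_heterogeneity(ratios, config.heterogeneity)
            results.append(
                CaseResult(
                    case_id=r.case_id,
                    batch_id=batch_id,
                    role=r.role,
                    qc_status=status,
                    n_tiles_retained=len(retained) if retained is not None else 0,
                    filter_report=report,
                    fit=fit,
                    scores=scores,
                    heterogeneity=het,
                    ratios=ratios,
                )
            )
    return results


def results_to_frame(results: Sequence[CaseResult]) -> pd.DataFrame:
    """Per-case summary table (one row per case)."""
    rows = []
    for res in results:
        rows.append(
            {
                "case_id": res.case_id,
                "batch_id": res.batch_id,
                "role": res.role,
                "n_tiles_retained": res.n_tiles_retained,
                "mu": res.fit.mu if res.fit else float("nan"),
                "sigma": res.fit.sigma if res.fit else float("nan"),
                "adj_r2": res.fit.adj_r2 if res.fit else float("nan"),
                "m_score": res.scores.m_score if res.scores else float("nan"),
                "sigma_score": res.scores.sigma_score if res.scores else float("nan"),
                "mtp_score": res.scores.mtp_score if res.scores else float("nan"),
                "qc_status": res.qc_status.value,
                "heterogeneity_flag": bool(res.heterogeneity.flag) if res.heterogeneity else False,
            }
        )
    return pd.DataFrame(rows)
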