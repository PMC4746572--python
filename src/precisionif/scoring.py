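"""HER2/CK ratio histogram, Gaussian fit, and the M-, Sigma- and MTP-scores.

The filtered tiles of a case yield one HER2/CK ratio each.  Their frequency
histogram (normalized by tile count) is fitted with a Gaussian
``a * exp(-(x - mu)^2 / (2 sigma^2))``.  The fitted mean, normalized by the
mean of the batch's IHC-3+ positive control, is the M-score; the fitted
standard deviation, normalized the same way, is the Sigma-score; their
product is the MTP-score.  Because both channels share the case's staining
quality, the ratio — and hence every score — is invariant to a common
intensity rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .config import ScoringConfig
from .errors import PrecisionIFError, UnscorableCaseError
from .quantify import TileMeasurement

__all__ = [
    "QCStatus",
    "RatioHistogram",
    "GaussianFit",
    "ScoreSet",
    "ratio_per_tile",
    "build_histogram",
    "fit_gaussian",
    "qc_case",
    "score_case",
]


class QCStatus(str, Enum):
    PASS = "pass"
    EXCLUDED_LOW_R2 = "excluded_low_r2"
    EXCLUDED_FEW_TILES = "excluded_few_tiles"
    EXCLUDED_NO_CONVERGENCE = "excluded_no_convergence"
    EXCLUDED_CONTROL_FAILED = "excluded_control_failed"


@dataclass(frozen=True)
class RatioHistogram:
    """Frequency histogram of per-tile HER2/CK ratios (sums to 1)."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_tiles: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class GaussianFit:
    mu: float
    sigma: float
    amplitude: float
    adj_r2: float
    converged: bool


@dataclass(frozen=True)
class ScoreSet:
    m_score: float
    sigma_score: float
    mtp_score: float
    batch_id: str = ""
    qc_status: QCStatus = QCStatus.PASS


def ratio_per_tile(retained: Sequence[TileMeasurement]) -> np.ndarray:
    """Element-wise her2_mean / ck_mean over the retained tiles, order kept."""
    ck = np.array([m.ck_mean for m in retained], dtype=float)
    her2 = np.array([m.her2_mean for m in retained], dtype=float)
    if np.any(ck <= 0) or not np.all(np.isfinite(ck)):
        raise PrecisionIFError(
            "retained tile with ck_mean <= 0: filter contract violated"
        )
    return her2 / ck


def build_histogram(
    ratios: Sequence[float],
    config: ScoringConfig | None = None,
    upper: float | None = None,
) -> RatioHistogram:
    """Ratio histogram over [0, upper], frequencies normalized by tile count.

    ``upper`` defaults to the maximum ratio of this case; the pipeline passes
    the batch-wide maximum so histograms of a batch share a common axis.  The
    bin width follows the Freedman-Diaconis rule with a fallback bin count
    when the rule degenerates, and a hard cap so near-degenerate spreads do
    not explode the bin count.
    """
    config = config or ScoringConfig()
    arr = np.asarray(ratios, dtype=float)
    if arr.size < config.min_tiles:
        raise UnscorableCaseError(
            "excluded_few_tiles", f"{arr.size} ratios < min_tiles={config.min_tiles}"
        )
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("ratios must be finite and non-negative")
    hi = float(arr.max()) if upper is None else float(upper)
    if hi < arr.max():
        raise ValueError("upper bound below the maximum ratio")
    if hi <= 0:
        raise UnscorableCaseError("excluded_few_tiles", "all ratios are zero")
    iqr = float(np.subtract(*np.percentile(arr, [75, 25])))
    width = 2.0 * iqr / arr.size ** (1.0 / 3.0)
    if width > 0:
        n_bins = int(np.clip(math.ceil(hi / width), 8, config.max_bins))
    else:
        n_bins = config.fallback_bins
    edges = np.linspace(0.0, hi, n_bins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return RatioHistogram(
        bin_edges=edges,
        frequencies=counts / arr.size,
        n_tiles=int(arr.size),
    )


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(hist: RatioHistogram, config: ScoringConfig | None = None) -> GaussianFit:
    """Least-squares Gaussian fit to (bin centers, frequencies).

    Initialized from the histogram's weighted moments.  Reports adjusted R^2
    (3 fitted parameters); non-convergence yields ``converged=False`` rather
    than an exception.
    """
    config = config or ScoringConfig()
    x = hist.bin_centers
    y = hist.frequencies
    occupied = int(np.count_nonzero(y))
    if occupied < config.min_occupied_bins:
        raise UnscorableCaseError(
            "excluded_few_tiles",
            f"{occupied} occupied bins < {config.min_occupied_bins}",
        )
    total = y.sum()
    mu0 = float((x * y).sum() / total)
    var0 = float(((x - mu0) ** 2 * y).sum() / total)
    sigma0 = max(math.sqrt(var0), float(x[1] - x[0]) / 4.0)
    a0 = float(y.max())
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            y,
            p0=[a0, mu0, sigma0],
            bounds=([0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return GaussianFit(
            mu=float("nan"), sigma=float("nan"), amplitude=float("nan"),
            adj_r2=float("nan"), converged=False,
        )
    a, mu, sigma = (float(v) for v in popt)
    resid = y - _gauss(x, a, mu, sigma)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n = y.size
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 4) if n > 4 else r2
    return GaussianFit(mu=mu, sigma=abs(sigma), amplitude=a, adj_r2=adj_r2, converged=True)


def qc_case(fit: GaussianFit, config: ScoringConfig | None = None) -> QCStatus:
    """QC verdict for a fitted case (low adjusted R^2 or no convergence)."""
    config = config or ScoringConfig()
    if not fit.converged:
        return QCStatus.EXCLUDED_NO_CONVERGENCE
    if not math.isfinite(fit.adj_r2) or fit.adj_r2 < config.r2_min:
        return QCStatus.EXCLUDED_LOW_R2
    return QCStatus.PASS


def score_case(
    fit: GaussianFit,
    pos_control_fit: GaussianFit,
    batch_id: str = "",
    qc_status: QCStatus = QCStatus.PASS,
) -> ScoreSet:
    """M = mu/mu_pos, Sigma = sigma/sigma_pos, MTP = M * Sigma."""
    if not (fit.converged and pos_control_fit.converged):
        raise PrecisionIFError("score_case requires converged fits")
    if not (pos_control_fit.mu > 0 and pos_control_fit.sigma > 0):
        raise PrecisionIFError("positive-control fit has non-positive mu or sigma")
    m = fit.mu / pos_control_fit.mu
    s = fit.sigma / pos_control_fit.sigma
    return ScoreSet(
        m_score=m, sigma_score=s, mtp_score=m * s,
        batch_id=batch_id, qc_status=qc_status,
    )
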