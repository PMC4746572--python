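"""Shared fixtures: seeded synthetic cohort runs and independent oracles."""

from __future__ import annotations

import functools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import precisionif as pf  # noqa: E402

COHORT_SEED = 11
POWER_LAW_EXPONENT = 1.2


def run_cohort(spec: pf.SyntheticCohortSpec, model: pf.ImagingModel):
    """Generate, measure and score a synthetic cohort end to end."""
    cohort = pf.generate_cohort(spec)
    records = [rec for _, rec in cohort]
    measurements = {
        rec.case_id: pf.measure_case(pf.generate_case(ph, model), pf.QuantConfig())
        for ph, rec in cohort
    }
    results = pf.score_cohort(measurements, records)
    return results, records, measurements


def pair_scores(results, records):
    """Align ScoreSets with CohortRecords for correlate_scores."""
    by_id = {r.case_id: r for r in records}
    nan = float("nan")
    scores = [
        res.scores
        or pf.ScoreSet(nan, nan, nan, batch_id=res.batch_id, qc_status=res.qc_status)
        for res in results
    ]
    return scores, [by_id[res.case_id] for res in results]


def otsu_between_class_variance(image: np.ndarray, threshold: float,
                                nbins: int = 256) -> float:
    """Quantized between-class variance of the split induced by ``threshold``."""
    arr = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(arr, bins=nbins, range=(arr.min(), arr.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    low = centers <= threshold
    w0 = counts[low].sum()
    w1 = counts[~low].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (counts[low] * centers[low]).sum() / w0
    mu1 = (counts[~low] * centers[~low]).sum() / w1
    return float(w0 * w1 * (mu0 - mu1) ** 2)


def otsu_bruteforce(image: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive between-class-variance search over histogram bin centers.

    Independent re-derivation of the Otsu criterion used to cross-check
    auto_threshold.
    """
    arr = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(arr, bins=nbins, range=(arr.min(), arr.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = counts.sum()
    best_var, best_t = -1.0, float(centers[0])
    for i in range(1, nbins):
        w0 = counts[:i].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:i] * centers[:i]).sum() / w0
        mu1 = (counts[i:] * centers[i:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, float(centers[i - 1])
    return best_t


@pytest.fixture(scope="session")
def default_cohort_run():
    """25-case / 5-batch cohort at generator defaults (noise, artifacts on)."""
    spec = pf.SyntheticCohortSpec(seed=COHORT_SEED)
    return run_cohort(spec, pf.ImagingModel())


@pytest.fixture(scope="session")
def noise_free_power_law_run():
    """Noise-free cohort with a power-law expression map (exponent recovery)."""
    spec = pf.SyntheticCohortSpec(
        seed=COHORT_SEED,
        expression_map=functools.partial(
            pf.power_law_expression_map, exponent=POWER_LAW_EXPONENT, scale=0.025
        ),
        staining_cv=0.0,
        artifact_rate=0.0,
    )
    model = pf.ImagingModel(
        noise_sd=0.0, background_dapi=0.0, background_ck=0.0, background_her2=0.0
    )
    return run_cohort(spec, model)
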