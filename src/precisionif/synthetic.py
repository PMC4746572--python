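"""Seeded synthetic data with the statistical structure the analysis assumes.

Three generators are provided:

* **tiles** — three-channel (DAPI/CK/HER2) mosaic tiles of a virtual tissue
  slide: CK-positive epithelial discs on a stromal background, DAPI-positive
  nuclei inside the epithelium with suppressed CK/HER2, membrane-level HER2
  whose tile mean is drawn around a ground-truth expression level, optional
  two-subclone heterogeneity (each tile belongs wholly to one subclone), and
  rare saturating bright CK artifacts emulating fluorophore agglomerates;
* **cohorts** — batched case tables with one positive (IHC 3+) and one
  negative (IHC 0) control per batch, ground-truth copy-number-like values
  spanning a configured range, and a monotone map from copy number to
  expression level;
* **spotting series** — antigen dilution series with bound-antibody signal
  derived from the Langmuir occupancy model, for linearity experiments.

Everything is driven by explicit integer seeds; identical (parameters, seed)
pairs produce bit-identical output, and per-tile RNG streams are independent
of generation order.

The tile-to-tile dispersion of the HER2 level grows with the expression
level (default coefficient of variation ``0.05 + 0.25 * level``), emulating
the wider scatter of overexpressing tumors.  A case-level staining-quality
factor multiplies CK and HER2 (and DAPI) equally, so the HER2/CK ratio — and
therefore all downstream scores — cancels it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from skimage.draw import disk as draw_disk

from .cohort import CohortRecord
from .errors import PipelineError
from .kinetics import KineticParams, SpottingSeries, saturation_model
from .quantify import TileImage

__all__ = [
    "ImagingModel",
    "CasePhenotype",
    "TileTruth",
    "SyntheticCohortSpec",
    "default_expression_cv",
    "saturating_expression_map",
    "power_law_expression_map",
    "generate_tile",
    "generate_tile_with_truth",
    "generate_case",
    "generate_case_with_truth",
    "generate_cohort",
    "generate_spotting_series",
]


@dataclass(frozen=True)
class ImagingModel:
    """Optical/staining parameters of the virtual slide (intensities in [0,1])."""

    tile_shape: tuple[int, int] = (128, 128)
    background_dapi: float = 0.05
    background_ck: float = 0.05
    background_her2: float = 0.05
    noise_sd: float = 0.01  # additive per-pixel Gaussian noise SD
    ck_level: float = 0.5  # epithelial CK intensity above background
    dapi_level: float = 0.8  # nuclear DAPI intensity above background
    nucleus_radius: int = 4  # px
    nucleus_count: float = 25.0  # mean nuclei per 128x128 epithelial tile
    # (Poisson; scaled by tile area so nuclear density is size-invariant)
    nuclear_suppression: float = 0.2  # CK/HER2 attenuation inside nuclei
    epithelium_radius_frac: float = 0.42  # of min(tile dims)
    artifact_radius: int = 10  # px, saturating CK blob

    def __post_init__(self) -> None:
        if min(self.tile_shape) < 16:
            raise ValueError("tile_shape must be at least 16x16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_expression_cv(expression_level: float) -> float:
    """Tile-to-tile CV of the HER2 level; strictly increasing in the level."""
    return 0.05 + 0.25 * expression_level


@dataclass(frozen=True)
class CasePhenotype:
    """Ground truth for one virtual case."""

    expression_level: float  # mean HER2 membrane intensity scale, >= 0
    epithelial_fraction: float = 0.7  # fraction of tiles that carry epithelium
    n_tiles: int = 100
    expression_cv: float | None = None  # None -> default_expression_cv(level)
    subclone: tuple[float, float] | None = None  # (expression_level, fraction)
    artifact_rate: float = 0.0
    staining_factor: float = 1.0  # multiplies all channels of the case
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.expression_level >= 0 and math.isfinite(self.expression_level)):
            raise ValueError("expression_level must be finite and >= 0")
        if not 0.0 <= self.epithelial_fraction <= 1.0:
            raise ValueError("epithelial_fraction must lie in [0, 1]")
        if self.n_tiles <= 0:
            raise ValueError("n_tiles must be positive")
        if self.expression_cv is not None and self.expression_cv < 0:
            raise ValueError("expression_cv must be >= 0")
        if self.subclone is not None:
            level, frac = self.subclone
            if level < 0 or not 0.0 <= frac <= 1.0:
                raise ValueError("subclone must be (level >= 0, fraction in [0, 1])")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if not (self.staining_factor > 0):
            raise ValueError("staining_factor must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def cv_for(self, level: float) -> float:
        return self.expression_cv if self.expression_cv is not None else default_expression_cv(level)

    @property
    def grid_cols(self) -> int:
        return int(math.ceil(math.sqrt(self.n_tiles)))


@dataclass(frozen=True)
class TileTruth:
    """Ground-truth masks and draws behind one generated tile."""

    epithelium: np.ndarray  # bool
    nuclei: np.ndarray  # bool
    is_epithelial: bool
    her2_level: float  # drawn tile-level HER2 intensity above background
    subclone_index: int  # 0 = main clone, 1 = subclone
    has_artifact: bool


def _tile_rng(seed: int, tile_index: int) -> np.random.Generator:
    # independent per-tile streams: identical (seed, index) -> identical tile
    return np.random.default_rng([int(seed), int(tile_index)])


def generate_tile_with_truth(
    phenotype: CasePhenotype,
    tile_index: int,
    model: ImagingModel | None = None,
) -> tuple[TileImage, TileTruth]:
    """Generate one tile plus its ground truth (masks, drawn HER2 level)."""
    model = model or ImagingModel()
    if not 0 <= tile_index < phenotype.n_tiles:
        raise ValueError(f"tile_index {tile_index} out of range [0, {phenotype.n_tiles})")
    rng = _tile_rng(phenotype.seed, tile_index)
    h, w = model.tile_shape
    dapi = np.full((h, w), model.background_dapi)
    ck = np.full((h, w), model.background_ck)
    her2 = np.full((h, w), model.background_her2)
    epithelium = np.zeros((h, w), dtype=bool)
    nuclei = np.zeros((h, w), dtype=bool)

    is_epithelial = rng.random() < phenotype.epithelial_fraction
    level = phenotype.expression_level
    subclone_index = 0
    if phenotype.subclone is not None:
        sub_level, sub_frac = phenotype.subclone
        if rng.random() < sub_frac:  # tiles belong wholly to one subclone
            level, subclone_index = sub_level, 1
    cv = phenotype.cv_for(level)
    her2_level = max(0.0, rng.normal(level, cv * level)) if level > 0 else 0.0

    if is_epithelial:
        cy = h / 2.0 * (1.0 + rng.uniform(-0.25, 0.25))
        cx = w / 2.0 * (1.0 + rng.uniform(-0.25, 0.25))
        radius = model.epithelium_radius_frac * min(h, w) * rng.uniform(0.9, 1.1)
        rr, cc = draw_disk((cy, cx), radius, shape=(h, w))
        epithelium[rr, cc] = True
        ck[epithelium] = model.background_ck + model.ck_level
        her2[epithelium] = model.background_her2 + her2_level
        n_nuc = rng.poisson(model.nucleus_count * (h * w) / 128.0**2)
        for _ in range(n_nuc):
            rho = radius * math.sqrt(rng.random()) * 0.95
            angle = rng.uniform(0.0, 2.0 * math.pi)
            ny = cy + rho * math.sin(angle)
            nx = cx + rho * math.cos(angle)
            nr, nc = draw_disk((ny, nx), model.nucleus_radius, shape=(h, w))
            nuclei[nr, nc] = True
        nuclei &= epithelium
        dapi[nuclei] = model.background_dapi + model.dapi_level
        ck[nuclei] = model.background_ck + model.ck_level * model.nuclear_suppression
        her2[nuclei] = model.background_her2 + her2_level * model.nuclear_suppression
    else:
        # sparse stromal (fibroblast) nuclei; no CK, no membranous HER2
        n_nuc = rng.poisson(max(1.0, model.nucleus_count * (h * w) / 128.0**2 / 4.0))
        for _ in range(n_nuc):
            ny, nx = rng.uniform(0, h), rng.uniform(0, w)
            nr, nc = draw_disk((ny, nx), model.nucleus_radius, shape=(h, w))
            nuclei[nr, nc] = True
        dapi[nuclei] = model.background_dapi + model.dapi_level

    for img in (dapi, ck, her2):
        img *= phenotype.staining_factor

    has_artifact = rng.random() < phenotype.artifact_rate
    if has_artifact:  # saturating fluorophore agglomerate in the CK channel
        ay, ax = rng.uniform(0, h), rng.uniform(0, w)
        ar, ac = draw_disk((ay, ax), model.artifact_radius, shape=(h, w))
        ck[ar, ac] = 1.0

    if model.noise_sd > 0:
        for img in (dapi, ck, her2):
            img += rng.normal(0.0, model.noise_sd, size=(h, w))
    for img in (dapi, ck, her2):
        np.clip(img, 0.0, 1.0, out=img)

    tile_id = divmod(tile_index, phenotype.grid_cols)
    tile = TileImage(dapi=dapi, ck=ck, her2=her2, tile_id=tile_id)
    truth = TileTruth(
        epithelium=epithelium, nuclei=nuclei, is_epithelial=is_epithelial,
        her2_level=her2_level, subclone_index=subclone_index,
        has_artifact=has_artifact,
    )
    return tile, truth


def generate_tile(
    phenotype: CasePhenotype, tile_index: int, model: ImagingModel | None = None
) -> TileImage:
    return generate_tile_with_truth(phenotype, tile_index, model)[0]


def generate_case_with_truth(
    phenotype: CasePhenotype, model: ImagingModel | None = None
) -> tuple[list[TileImage], list[TileTruth]]:
    pairs = [
        generate_tile_with_truth(phenotype, i, model) for i in range(phenotype.n_tiles)
    ]
    return [p[0] for p in pairs], [p[1] for p in pairs]


def generate_case(
    phenotype: CasePhenotype, model: ImagingModel | None = None
) -> list[TileImage]:
    return generate_case_with_truth(phenotype, model)[0]


# --- cohort generation -------------------------------------------------------

def saturating_expression_map(
    n_fish: float, e_max: float = 0.9, n_floor: float = 1.5, k: float = 8.0
) -> float:
    """Default monotone copy-number -> expression-level map (saturating).

    Zero at/below the diploid-like floor, saturating towards ``e_max``.  A
    config choice standing in for an unknown biology, not a claim about it.
    """
    x = max(n_fish - n_floor, 0.0)
    return e_max * x / (k + x)


def power_law_expression_map(
    n_fish: float, exponent: float = 1.0, scale: float = 0.03
) -> float:
    """Power-law copy-number -> expression-level map, for exponent-recovery runs."""
    return scale * n_fish**exponent


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Layout and noise parameters of a synthetic cohort.

    ``n_cases`` counts every slide in the study including the two controls
    carried by each batch, mirroring a 25-slide / 5-batch design with one
    positive (IHC 3+) and one negative (IHC 0) control per batch.
    """

    n_cases: int = 25
    batch_size: int = 5
    nfish_range: tuple[float, float] = (1.9, 15.0)
    expression_map: Callable[[float], float] = saturating_expression_map
    tiles_per_case: int = 100
    epithelial_fraction: float = 0.7
    expression_cv: float | None = None  # None -> default CV map
    artifact_rate: float = 0.03
    staining_cv: float = 0.1  # case-level staining-quality spread
    pos_control_nfish: float = 12.0
    neg_control_nfish: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 3:
            raise PipelineError(
                "batch_size must be >= 3: each batch holds one positive and "
                "one negative control plus at least one case"
            )
        if self.n_cases < self.batch_size:
            raise PipelineError("n_cases must be >= batch_size")
        if not (0 < self.nfish_range[0] < self.nfish_range[1]):
            raise ValueError("nfish_range must be an increasing positive pair")
        if self.staining_cv < 0:
            raise ValueError("staining_cv must be >= 0")

    @property
    def n_batches(self) -> int:
        return int(math.ceil(self.n_cases / self.batch_size))


def _batch_sizes(spec: SyntheticCohortSpec) -> list[int]:
    sizes = []
    remaining = spec.n_cases
    for b in range(spec.n_batches):
        size = min(spec.batch_size, remaining)
        remaining -= size
        sizes.append(size)
    if any(s < 3 for s in sizes):
        raise PipelineError(
            "cohort layout leaves a batch with fewer than 3 slides; every "
            "batch needs both controls plus at least one case"
        )
    return sizes


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> list[tuple[CasePhenotype, CohortRecord]]:
    """Assign batches, control roles, and ground-truth copy-number values.

    Non-control ground-truth values span ``nfish_range`` evenly and are
    distributed across batches in a seeded random order.  Every batch gets
    exactly one positive and one negative control.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _batch_sizes(spec)
    n_plain = spec.n_cases - 2 * len(sizes)
    lo, hi = spec.nfish_range
    nfish_values = np.linspace(lo, hi, n_plain) if n_plain > 1 else np.array([0.5 * (lo + hi)])
    nfish_values = nfish_values[: n_plain]
    order = rng.permutation(n_plain)
    case_seeds = rng.integers(0, 2**31 - 1, size=spec.n_cases)

    out: list[tuple[CasePhenotype, CohortRecord]] = []
    cursor = 0
    idx = 0
    for b, size in enumerate(sizes):
        batch_id = f"batch{b + 1}"
        slots: list[tuple[str, float]] = [
            ("pos_control", spec.pos_control_nfish),
            ("neg_control", spec.neg_control_nfish),
        ]
        for _ in range(size - 2):
            slots.append(("case", float(nfish_values[order[cursor]])))
            cursor += 1
        for role, nfish in slots:
            case_id = f"case{idx + 1:02d}"
            expression = float(spec.expression_map(nfish))
            staining = 1.0
            if spec.staining_cv > 0:
                staining = float(np.clip(rng.normal(1.0, spec.staining_cv), 0.7, 1.3))
            phenotype = CasePhenotype(
                expression_level=expression,
                epithelial_fraction=spec.epithelial_fraction,
                n_tiles=spec.tiles_per_case,
                expression_cv=spec.expression_cv,
                artifact_rate=spec.artifact_rate,
                staining_factor=staining,
                seed=int(case_seeds[idx]),
            )
            record = CohortRecord(
                case_id=case_id,
                batch_id=batch_id,
                role=role,
                n_fish=nfish,
                her2_cep17=nfish / float(rng.normal(2.0, 0.15)),
                ihc_score=_ihc_from_nfish(nfish),
            )
            out.append((phenotype, record))
            idx += 1
    return out


def _ihc_from_nfish(n_fish: float) -> str:
    # coarse ordinal stand-in used only as cohort metadata
    if n_fish < 2.0:
        return "0"
    if n_fish < 4.0:
        return "1+"
    if n_fish < 6.0:
        return "2+"
    return "3+"


# --- spotting series ---------------------------------------------------------

def generate_spotting_series(
    params: KineticParams,
    ag_levels: Sequence[float],
    t_incubation: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    k_sat: float = math.inf,
) -> SpottingSeries:
    """Simulated antigen dilution series with Langmuir-bound antibody signal.

    The antibody signal is ``occupancy(params, t) * ag_signal`` (optionally
    saturated via ``k_sat``), perturbed by multiplicative Gaussian noise of
    coefficient of variation ``noise_cv`` and clipped at zero.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    clean = saturation_model(ag_levels, params, t_incubation, k_sat=k_sat)
    ab = clean.ab_signal
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        ab = np.clip(ab * (1.0 + noise_cv * rng.standard_normal(ab.shape)), 0.0, None)
    return replace(clean, ab_signal=ab, metadata={**clean.metadata, "noise_cv": noise_cv})
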