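"""Downstream biodiversity accounting on binarized distribution maps.

From per-species binary maps: range change through time (with complete-loss
detection and a five-level change classification), presence-absence matrices
(PAM), species richness (SR) and its temporal difference ΔSR, potential
species hotspots (PSH, cells above 0.6 x the per-country present-day maximum
SR), hotspot extent ratios, and per-cell temporal Sørensen dissimilarity
β_SØR = (b+c)/(2a+b+c) comparing a cell's composition between two periods.

Sign convention: ΔSR = SR_future − SR_present, so positive values are
richness gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble_projection import EnsemblePrediction
from .synthetic_world import WorldMask

# (label, closed-on-the-loss-side bin edges over delta); complete loss is the
# exact delta == -1 case.
DEFAULT_CATEGORY_EDGES = (-0.5, 0.0, 0.5)
CATEGORY_LABELS = ("complete_loss", "severe_loss", "moderate_loss", "stable_gain", "strong_gain")


@dataclass
class RangeChangeRecord:
    species_id: str
    scenario: str
    horizon: str
    n_present: int
    n_future: int
    delta: float
    complete_loss: bool
    category: str


@dataclass
class PAM:
    """Presence-absence matrix: species x grid cells (full-grid columns)."""

    scenario: str
    horizon: str
    matrix: np.ndarray  # bool, shape (n_species, n_cells)
    species_ids: list[str]

    def range_sizes(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


@dataclass
class RichnessMaps:
    sr: np.ndarray  # int, grid shape
    sr_standardized: np.ndarray  # [0,1] per country
    max_sr: dict[int, int]  # per country
    delta_sr: np.ndarray | None = None


@dataclass
class HotspotResult:
    threshold_factor: float
    cutoffs: dict[int, float]  # per-country absolute SR cutoff (present-day)
    psh_present: np.ndarray  # bool grid
    psh_future: np.ndarray | None = None
    extent_ratio: float = 1.0
    extent_ratio_by_country: dict[int, float] = field(default_factory=dict)
    median_bsor: float = float("nan")


def range_change(
    present: EnsemblePrediction, future: EnsemblePrediction,
    category_edges: tuple[float, ...] = DEFAULT_CATEGORY_EDGES,
) -> RangeChangeRecord:
    """Proportional range change between the present and a future projection."""
    n_present = present.range_size
    if n_present == 0:
        raise ValueError(f"{present.species_id}: empty present-day range")
    n_future = future.range_size
    delta = (n_future - n_present) / n_present
    return RangeChangeRecord(
        species_id=present.species_id,
        scenario=future.scenario_id,
        horizon=future.horizon,
        n_present=n_present,
        n_future=n_future,
        delta=delta,
        complete_loss=n_future == 0,
        category=classify_change(delta, category_edges),
    )


def classify_change(
    delta: float, edges: tuple[float, ...] = DEFAULT_CATEGORY_EDGES
) -> str:
    """Five-level range-change category; bins closed on the loss side.

    Defaults: complete loss (= -1), severe loss (-1, -0.5], moderate loss
    (-0.5, 0), stable/gain [0, 0.5], strong gain (> 0.5).
    """
    lo, zero, hi = edges
    if delta <= -1.0:
        return "complete_loss"
    if delta <= lo:
        return "severe_loss"
    if delta < zero:
        return "moderate_loss"
    if delta <= hi:
        return "stable_gain"
    return "strong_gain"


def build_pam(predictions: list[EnsemblePrediction], n_cells: int) -> PAM:
    """Stack per-species binary maps into a PAM for one scenario/horizon.

    Cells outside a species' projected M are absences in its row.
    """
    if predictions:
        scen = {(p.scenario_id, p.horizon) for p in predictions}
        if len(scen) > 1:
            raise ValueError(f"mixed scenario/horizon in PAM input: {sorted(scen)}")
        scenario, horizon = next(iter(scen))
    else:
        scenario, horizon = "empty", "empty"
    matrix = np.zeros((len(predictions), n_cells), dtype=bool)
    for i, p in enumerate(predictions):
        matrix[i, p.cells[p.binary]] = True
    return PAM(
        scenario=scenario,
        horizon=horizon,
        matrix=matrix,
        species_ids=[p.species_id for p in predictions],
    )


def richness(pam: PAM, mask: WorldMask) -> RichnessMaps:
    """Species richness per cell, with per-country 0-1 standardization."""
    sr = pam.matrix.sum(axis=0).astype(np.int64).reshape(mask.grid.shape)
    std = np.zeros(mask.grid.shape, dtype=float)
    max_sr: dict[int, int] = {}
    for c in range(1, mask.country_count + 1):
        in_c = mask.country_id == c
        m = int(sr[in_c].max()) if in_c.any() else 0
        max_sr[c] = m
        if m > 0:
            std[in_c] = sr[in_c] / m
    return RichnessMaps(sr=sr, sr_standardized=std, max_sr=max_sr)


def delta_richness(sr_present: np.ndarray, sr_future: np.ndarray) -> np.ndarray:
    """ΔSR = future − present (positive = gain)."""
    return sr_future.astype(np.int64) - sr_present.astype(np.int64)


def hotspots(
    richness_present: RichnessMaps,
    mask: WorldMask,
    factor: float = 0.6,
    sr_future: np.ndarray | None = None,
) -> HotspotResult:
    """Potential species hotspots: cells with SR strictly above factor x maxSR.

    maxSR is the per-country present-day maximum; the resulting absolute
    cutoff is frozen and applied unchanged to future SR maps, so future
    extents are measured against the present-day definition of a hotspot.
    """
    cutoffs: dict[int, float] = {}
    psh_present = np.zeros(mask.grid.shape, dtype=bool)
    for c, m in richness_present.max_sr.items():
        if m <= 0:
            continue
        cutoff = factor * m
        cutoffs[c] = cutoff
        in_c = mask.country_id == c
        psh_present |= in_c & (richness_present.sr > cutoff)
    result = HotspotResult(
        threshold_factor=factor, cutoffs=cutoffs, psh_present=psh_present
    )
    if sr_future is not None:
        psh_future = np.zeros(mask.grid.shape, dtype=bool)
        for c, cutoff in cutoffs.items():
            in_c = mask.country_id == c
            psh_future |= in_c & (sr_future > cutoff)
        result.psh_future = psh_future
        n_p = int(psh_present.sum())
        result.extent_ratio = float(psh_future.sum()) / n_p if n_p else float("nan")
        for c, cutoff in cutoffs.items():
            in_c = mask.country_id == c
            np_c = int((psh_present & in_c).sum())
            result.extent_ratio_by_country[c] = (
                float((psh_future & in_c).sum()) / np_c if np_c else float("nan")
            )
    return result


def temporal_sorensen(
    pam_present: PAM, pam_future: PAM, cells: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-cell temporal Sørensen dissimilarity between two periods.

    With a = shared species, b = present-only, c = future-only at a cell,
    β_SØR = (b+c)/(2a+b+c); cells empty in both periods are no-data (NaN).
    Returns the per-cell values over ``cells`` and their median.
    """
    cells = np.asarray(cells)
    if cells.size == 0:
        raise ValueError("cells must be non-empty")
    if pam_present.species_ids != pam_future.species_ids:
        raise ValueError("PAMs must index the same species in the same order")
    p = pam_present.matrix[:, cells]
    f = pam_future.matrix[:, cells]
    a = (p & f).sum(axis=0).astype(float)
    b = (p & ~f).sum(axis=0).astype(float)
    c = (~p & f).sum(axis=0).astype(float)
    denom = 2 * a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        bsor = np.where(denom > 0, (b + c) / denom, np.nan)
    valid = ~np.isnan(bsor)
    median = float(np.median(bsor[valid])) if valid.any() else float("nan")
    return bsor, median
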