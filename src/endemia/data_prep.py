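"""Occurrence filtering, endemicity rules, and collinearity-based predictor
pre-selection.

Occurrence records are snapped to grid cells and deduplicated; species are
retained only with at least 25 unique cells (configurable) and capped at a
random subset of 500. Endemicity requires all records to fall inside one
country dilated by a small buffer (default 0.08333 degrees, one 5-arc-minute
cell). Predictor layers are thinned with the standard Pearson-0.8 /
variance-inflation-factor procedure: while any kept pair correlates at or
above the threshold, the member of the worst-offending pair with the higher
VIF is dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grids import GridSpec
from .synthetic_world import ClimateStack, OccurrenceSet, WorldMask, subseed


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    TOO_FEW_RECORDS = "too_few_records"
    NOT_ENDEMIC = "not_endemic"


@dataclass
class SpeciesRecordSet:
    """Deduplicated, filtered occurrence cells for one species."""

    species_id: str
    unique_cells: np.ndarray  # sorted flat cell indices
    n_raw: int
    retained: bool
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        if self.retained != (self.exclusion_reason == ExclusionReason.NONE):
            raise ValueError("retained must mirror exclusion_reason == none")


@dataclass
class PredictorSelection:
    candidate_layers: list[str]
    kept_layers: list[str]
    correlation_matrix: np.ndarray  # over kept layers, final iteration
    vif_values: dict[str, float]


def dedupe_and_filter(
    occ: OccurrenceSet, grid: GridSpec, min_records: int = 25
) -> SpeciesRecordSet:
    """Snap records to cells, deduplicate, and apply the minimum-record rule.

    Records outside the grid raise, listing the offending coordinates.
    """
    offenders = [(lon, lat) for lon, lat in occ.records if not grid.contains(lon, lat)]
    if offenders:
        raise ValueError(f"records outside grid extent: {offenders[:10]}")
    cells = sorted({grid.ravel(*grid.lonlat_to_cell(lon, lat)) for lon, lat in occ.records})
    cells = np.array(cells, dtype=np.int64)
    retained = cells.size >= min_records
    return SpeciesRecordSet(
        species_id=occ.species_id,
        unique_cells=cells,
        n_raw=len(occ.records),
        retained=retained,
        exclusion_reason=ExclusionReason.NONE if retained else ExclusionReason.TOO_FEW_RECORDS,
    )


def cap_records(s: SpeciesRecordSet, max_n: int = 500, seed: int = 0) -> SpeciesRecordSet:
    """Cap a retained species at a uniform random subset of ``max_n`` cells."""
    if not s.retained:
        raise ValueError(f"{s.species_id} is not retained; nothing to cap")
    if s.unique_cells.size <= max_n:
        return s
    rng = np.random.default_rng(subseed(seed, "cap", s.species_id))
    keep = rng.choice(s.unique_cells.size, size=max_n, replace=False)
    return replace(s, unique_cells=np.sort(s.unique_cells[keep]))


def dilate_cells(mask2d: np.ndarray, radius_cells: int) -> np.ndarray:
    """Chebyshev (square-structuring-element) dilation by ``radius_cells``."""
    if radius_cells <= 0:
        return mask2d.astype(bool)
    size = 2 * radius_cells + 1
    return ndimage.maximum_filter(mask2d.astype(np.uint8), size=size).astype(bool)


def endemicity_check(
    s: SpeciesRecordSet, mask: WorldMask, buffer_deg: float = 0.08333
) -> bool:
    """True iff all cells fall within one country dilated by the buffer.

    The buffer is converted to whole cells by ceiling (conservative
    inclusion); with the default 0.08333 degrees and 5-arc-minute cells this
    is a one-cell dilation.
    """
    radius = mask.grid.degrees_to_cells(buffer_deg)
    rows, cols = mask.grid.unravel(s.unique_cells)
    candidates = np.unique(mask.country_id[rows, cols])
    candidates = candidates[candidates > 0]
    for country in candidates:
        dilated = dilate_cells(mask.country_id == country, radius)
        if dilated[rows, cols].all():
            return True
    return False


def mark_not_endemic(s: SpeciesRecordSet) -> SpeciesRecordSet:
    return replace(s, retained=False, exclusion_reason=ExclusionReason.NOT_ENDEMIC)


def _vif(x: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column regressed on the others (OLS)."""
    n, k = x.shape
    if k < 2:
        return np.ones(k)
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    vifs = np.empty(k)
    for j in range(k):
        y = z[:, j]
        others = np.delete(z, j, axis=1)
        a = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        resid = y - a @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)  # y is centered and scaled
        r2 = max(0.0, min(1.0 - ss_res / ss_tot, 1.0 - 1e-12))
        vifs[j] = 1.0 / (1.0 - r2)
    return vifs


def select_predictors(
    stack: ClimateStack,
    sample_cells: np.ndarray,
    r_threshold: float = 0.8,
    layer_names: list[str] | None = None,
) -> PredictorSelection:
    """Thin collinear layers by the Pearson-threshold / VIF procedure.

    While any kept pair has |r| >= ``r_threshold`` over the sampled cells, the
    pair with the largest |r| is located and its member with the higher VIF
    (computed among the currently kept layers) is dropped; VIF ties are broken
    by dropping the later layer in input order. The returned correlation
    matrix and VIFs describe the final kept set.
    """
    sample_cells = np.asarray(sample_cells)
    if sample_cells.size < 3:
        raise ValueError("need at least 3 sample cells")
    candidates = list(layer_names) if layer_names is not None else stack.layer_names
    x = stack.matrix(sample_cells, candidates)
    sds = x.std(axis=0)
    for name, sd in zip(candidates, sds):
        if sd <= 0:
            raise ValueError(f"layer {name} is constant over the sample cells")

    kept = list(range(len(candidates)))
    while len(kept) > 1:
        corr = np.corrcoef(x[:, kept], rowvar=False)
        absr = np.abs(corr)
        np.fill_diagonal(absr, 0.0)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] < r_threshold:
            break
        vifs = _vif(x[:, kept])
        # drop the higher-VIF member of the worst pair; ties -> later layer
        if vifs[i] > vifs[j]:
            drop_local = i
        elif vifs[j] > vifs[i]:
            drop_local = j
        else:
            drop_local = max(i, j)
        kept.pop(drop_local)

    corr = np.corrcoef(x[:, kept], rowvar=False) if len(kept) > 1 else np.ones((1, 1))
    vifs = _vif(x[:, kept])
    kept_names = [candidates[i] for i in kept]
    return PredictorSelection(
        candidate_layers=candidates,
        kept_layers=kept_names,
        correlation_matrix=np.atleast_2d(corr),
        vif_values={n: float(v) for n, v in zip(kept_names, vifs)},
    )
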