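"""AUC-weighted consensus ensembles, scenario projection, TSS binarization,
and cross-algorithm agreement.

Replicate fits from all algorithms are pooled into a single ensemble: members
must clear AUC > 0.7 on their held-out test split, and the consensus
suitability is their AUC-weighted mean. The ensemble is evaluated by scoring
every member's held-out records with the consensus itself, pooled into one
TSS/ROC evaluation, whose maximizing threshold binarizes the map. Future
projections reuse the present-day weights and threshold unchanged — the
threshold cannot be re-fit without future truth — and are confined to the
projected calibration region. Cross-algorithm agreement is summarized by the
per-cell coefficient of variation of algorithm-level consensus maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .niche_models import (
    AlgorithmFit,
    CalibrationRegion,
    EvaluationResult,
    TrainingSet,
    evaluate,
)
from .synthetic_world import ClimateStack


class UnmodelableSpeciesError(ValueError):
    """No ensemble member cleared the evaluation gate; species is excluded."""


def _binarization_threshold(pres: np.ndarray, absn: np.ndarray) -> float:
    """Binarization cutoff: the highest TSS-maximizing grid threshold.

    Pseudo-absences are drawn inside the calibration area and so
    under-sample the near-suitable climates just beyond the range edge; when
    held-out scores separate cleanly every threshold across the separation
    gap maximizes TSS, and a low-side maximizer (the evaluation convention)
    sweeps those uncalibrated near-suitable cells into the binary range. The
    highest maximizer is equally TSS-optimal and the most specific choice;
    with overlapping scores the plateau collapses and the choice is
    immaterial.
    """
    from .niche_models import TSS_THRESHOLD_GRID

    sens = (pres[None, :] >= TSS_THRESHOLD_GRID[:, None]).mean(axis=1)
    spec = (absn[None, :] < TSS_THRESHOLD_GRID[:, None]).mean(axis=1)
    tss = sens + spec - 1.0
    maximizers = np.flatnonzero(tss >= tss.max() - 1e-12)
    return float(TSS_THRESHOLD_GRID[maximizers[-1]])


@dataclass
class EnsembleMember:
    fit: AlgorithmFit
    evaluation: EvaluationResult
    test: TrainingSet  # held-out split the member was evaluated on


@dataclass
class EnsembleModel:
    """Reusable ensemble state: passing members, weights, and the frozen
    TSS threshold, shared by the present-day map and all projections."""

    species_id: str
    members: list[EnsembleMember]
    weights: np.ndarray
    tss_threshold: float
    evaluation: EvaluationResult
    region: CalibrationRegion

    @property
    def member_count(self) -> int:
        return len(self.members)


@dataclass
class EnsemblePrediction:
    """Consensus suitability and binary map over projected M for one
    scenario/horizon; cells outside projected M carry no prediction."""

    species_id: str
    scenario_id: str
    horizon: str
    cells: np.ndarray
    suitability: np.ndarray
    binary: np.ndarray
    member_count: int
    ensemble_eval: EvaluationResult
    model: EnsembleModel | None = field(default=None, repr=False)

    @property
    def range_size(self) -> int:
        return int(self.binary.sum())


def _consensus(
    members: list[EnsembleMember], weights: np.ndarray, stack: ClimateStack, cells: np.ndarray
) -> np.ndarray:
    num = np.zeros(cells.size)
    for m, w in zip(members, weights):
        num += w * m.fit.predict_cells(stack, cells)
    return num / weights.sum()


def build_ensemble(
    members: list[EnsembleMember],
    stack: ClimateStack,
    region: CalibrationRegion,
    auc_min: float = 0.7,
) -> EnsemblePrediction:
    """Assemble the present-day ensemble from replicate fits.

    Members with held-out AUC strictly above ``auc_min`` contribute with
    weight equal to their AUC. The pooled held-out records, scored by the
    consensus, give the ensemble evaluation and its TSS threshold.
    """
    passing = [m for m in members if m.evaluation.auc > auc_min]
    if not passing:
        raise UnmodelableSpeciesError(
            f"{region.species_id}: no member exceeded AUC {auc_min}"
        )
    weights = np.array([m.evaluation.auc for m in passing])
    cells = region.projected_m_cells
    cell_pos = {c: i for i, c in enumerate(cells)}
    suit = _consensus(passing, weights, stack, cells)

    pooled_p, pooled_a = [], []
    for m in passing:
        pooled_p.append(suit[[cell_pos[c] for c in m.test.presence_cells]])
        pooled_a.append(suit[[cell_pos[c] for c in m.test.absence_cells]])
    pooled_p = np.concatenate(pooled_p)
    pooled_a = np.concatenate(pooled_a)
    ens_eval = evaluate(pooled_p, pooled_a)

    model = EnsembleModel(
        species_id=region.species_id,
        members=passing,
        weights=weights,
        tss_threshold=_binarization_threshold(pooled_p, pooled_a),
        evaluation=ens_eval,
        region=region,
    )
    return EnsemblePrediction(
        species_id=region.species_id,
        scenario_id=stack.scenario_id,
        horizon=stack.horizon,
        cells=cells,
        suitability=suit,
        binary=suit >= model.tss_threshold,
        member_count=len(passing),
        ensemble_eval=ens_eval,
        model=model,
    )


def project(model: EnsembleModel, target_stack: ClimateStack) -> EnsemblePrediction:
    """Project the ensemble onto another climate stack.

    Weights and the TSS threshold are the present-day ones; predictions are
    confined to the projected M (full dispersal within it). Projecting onto
    the calibration stack reproduces the present-day prediction exactly.
    """
    missing = [
        layer
        for m in model.members
        for layer in m.fit.kept_layers
        if layer not in target_stack.layers
    ]
    if missing:
        raise ValueError(f"target stack is missing layers: {sorted(set(missing))}")
    cells = model.region.projected_m_cells
    suit = _consensus(model.members, model.weights, target_stack, cells)
    return EnsemblePrediction(
        species_id=model.species_id,
        scenario_id=target_stack.scenario_id,
        horizon=target_stack.horizon,
        cells=cells,
        suitability=suit,
        binary=suit >= model.tss_threshold,
        member_count=model.member_count,
        ensemble_eval=model.evaluation,
        model=model,
    )


def algorithm_consensus_maps(
    model: EnsembleModel, stack: ClimateStack
) -> dict[str, np.ndarray]:
    """Per-algorithm AUC-weighted consensus over projected M (for CV)."""
    cells = model.region.projected_m_cells
    maps: dict[str, np.ndarray] = {}
    for algo in sorted({m.fit.algorithm_id for m in model.members}):
        sel = [m for m in model.members if m.fit.algorithm_id == algo]
        w = np.array([m.evaluation.auc for m in sel])
        maps[algo] = _consensus(sel, w, stack, cells)
    return maps


def cv_across_algorithms(
    maps: list[np.ndarray], eps: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Per-cell coefficient of variation across algorithm-level maps.

    CV = sample standard deviation / mean; cells with mean < ``eps`` are
    no-data (NaN). Returns the CV map and its mean over valid cells.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 algorithm-level maps for a CV")
    arr = np.vstack(maps)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean < eps, np.nan, sd / mean)
    valid = ~np.isnan(cv)
    summary = float(np.nanmean(cv)) if valid.any() else float("nan")
    return cv, summary
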