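"""Climate characterization of scenarios and of richness-gain/loss areas.

Two descriptive summaries: (i) the per-cell change of selected bioclimatic
variables between a baseline and a future stack (scenario delta profile), and
(ii) the present-day climate of the cells with the largest richness gains
(ΔSR above its third quartile) versus the largest losses (below the first
quartile). Following the variable sets used for each purpose, scenario deltas
default to annual mean temperature, annual precipitation, max temperature of
the warmest month and precipitation of the driest month; gain/loss profiles
default to annual mean temperature, temperature seasonality, annual
precipitation and precipitation seasonality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_world import ClimateStack

SCENARIO_DELTA_VARIABLES = ("bio01", "bio12", "bio05", "bio14")
GAIN_LOSS_VARIABLES = ("bio01", "bio04", "bio12", "bio15")


@dataclass
class ClimateProfile:
    """Per-variable summary (mean and quartiles) over one region's cells."""

    region_label: str
    table: pd.DataFrame  # columns: variable, mean, q1, median, q3, n_cells


def _summaries(values_by_var: dict[str, np.ndarray], label: str) -> ClimateProfile:
    rows = []
    for var, v in values_by_var.items():
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        rows.append(
            {
                "region_label": label,
                "variable": var,
                "mean": float(v.mean()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "n_cells": int(v.size),
            }
        )
    return ClimateProfile(region_label=label, table=pd.DataFrame(rows))


def scenario_delta_profile(
    baseline: ClimateStack,
    future: ClimateStack,
    variables: tuple[str, ...] = SCENARIO_DELTA_VARIABLES,
    land: np.ndarray | None = None,
) -> ClimateProfile:
    """Summarize future − baseline per-cell differences over land cells."""
    sel = np.ones(baseline.grid.shape, dtype=bool) if land is None else land
    label = f"scenario_delta:{future.scenario_id}:{future.horizon}"
    values = {
        var: (future.layers[var] - baseline.layers[var])[sel] for var in variables
    }
    return _summaries(values, label)


def gain_loss_profiles(
    delta_sr: np.ndarray,
    stack: ClimateStack,
    valid: np.ndarray,
    variables: tuple[str, ...] = GAIN_LOSS_VARIABLES,
) -> tuple[ClimateProfile, ClimateProfile]:
    """Climate of the strongest richness-gain vs richness-loss cells.

    Quartiles of the ΔSR distribution are taken over ``valid`` cells (the
    cells where richness is defined, zeros included); the gain set is ΔSR
    strictly above Q3, the loss set strictly below Q1 — always disjoint since
    Q1 <= Q3.
    """
    vals = delta_sr[valid]
    if vals.size < 8:
        raise ValueError(f"need >= 8 valid ΔSR cells, got {vals.size}")
    q1, q3 = np.percentile(vals, [25, 75])
    gain = valid & (delta_sr > q3)
    loss = valid & (delta_sr < q1)
    if not gain.any() or not loss.any():
        raise ValueError(
            "degenerate ΔSR distribution (no cells beyond Q1/Q3, "
            f"Q1 = Q3 = {q1:g}); use a larger or more variable richness field"
        )
    gain_p = _summaries({v: stack.layers[v][gain] for v in variables}, "gain_Q4")
    loss_p = _summaries({v: stack.layers[v][loss] for v in variables}, "loss_Q1")
    return gain_p, loss_p
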