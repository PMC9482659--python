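import numpy as np
import pytest

import endemia as e
from endemia.data_prep import dedupe_and_filter
from endemia.niche_models import (
    ALGORITHMS,
    TSS_THRESHOLD_GRID,
    TrainingSet,
    auc_score,
    build_m,
    build_projected_m,
    draw_pseudo_absences,
    evaluate,
    fit_algorithm,
    split_replicates,
    variable_contributions,
)

from conftest import make_stack
from test_data_prep import occ_from_cells


def brute_force_auc(pres, absn):
    wins = sum(1.0 if p > a else 0.5 if p == a else 0.0 for p in pres for a in absn)
    return wins / (len(pres) * len(absn))


def brute_force_max_tss(pres, absn):
    best = (-2.0, None)
    for t in TSS_THRESHOLD_GRID:
        sens = np.mean([p >= t for p in pres])
        spec = np.mean([a < t for a in absn])
        tss = sens + spec - 1
        if tss > best[0] + 1e-12:
            best = (tss, t)
    return best


@pytest.fixture()
def record_set(grid16, world16):
    cells = [(r, c) for r in range(4, 9) for c in range(4, 9)]
    occ_cells = [
        (r, c) for (r, c) in cells if world16.country_id[r, c] == world16.country_id[4, 4]
    ]
    return dedupe_and_filter(
        occ_from_cells(grid16, occ_cells), grid16, min_records=5
    )


class TestCalibrationRegion:
    def test_m_subset_of_occupied_ecoregions_and_superset_of_occurrences(
        self, record_set, world16
    ):
        cr = build_m(record_set, world16, buffer_deg=1.0)
        rows, cols = world16.grid.unravel(record_set.unique_cells)
        occupied = set(world16.ecoregion_id[rows, cols])
        mrows, mcols = world16.grid.unravel(cr.m_cells)
        assert set(world16.ecoregion_id[mrows, mcols]) <= occupied
        assert np.isin(record_set.unique_cells, cr.m_cells).all()

    def test_huge_buffer_gives_union_of_occupied_ecoregions(self, record_set, world16):
        cr = build_m(record_set, world16, buffer_deg=100.0)
        rows, cols = world16.grid.unravel(record_set.unique_cells)
        occupied = np.unique(world16.ecoregion_id[rows, cols])
        expected = np.flatnonzero(np.isin(world16.ecoregion_id, occupied).ravel())
        assert np.array_equal(cr.m_cells, expected)

    def test_buffer_limits_m_within_occupied_ecoregion(self, record_set, world16):
        # with a small buffer, occupied-ecoregion cells beyond the buffer are
        # excluded: every M cell is within Chebyshev radius of an occurrence
        cr = build_m(record_set, world16, buffer_deg=0.5)  # radius 1 cell
        rows, cols = world16.grid.unravel(cr.m_cells)
        orows, ocols = world16.grid.unravel(record_set.unique_cells)
        for r, c in zip(rows, cols):
            assert np.min(np.maximum(np.abs(orows - r), np.abs(ocols - c))) <= 1

    def test_projected_m_is_chebyshev_dilation(self, record_set, world16):
        cr = build_m(record_set, world16, buffer_deg=1.0)
        cr = build_projected_m(cr, world16, buffer_deg=1.0)  # radius 2 cells
        assert np.isin(cr.m_cells, cr.projected_m_cells).all()
        mrows, mcols = world16.grid.unravel(cr.m_cells)
        prows, pcols = world16.grid.unravel(cr.projected_m_cells)
        for r, c in zip(prows, pcols):
            assert np.min(np.maximum(np.abs(mrows - r), np.abs(mcols - c))) <= 2

    def test_zero_buffer_projected_m_equals_m(self, record_set, world16):
        cr = build_m(record_set, world16, buffer_deg=1.0)
        cr = build_projected_m(cr, world16, buffer_deg=0.0)
        assert np.array_equal(cr.projected_m_cells, cr.m_cells)

    def test_fallback_to_country_when_m_too_small(self, grid16, world16):
        # occurrences covering a whole tiny ecoregion leave M == presences
        country = np.ones(grid16.shape, dtype=np.int64)
        eco = np.ones(grid16.shape, dtype=np.int64)
        eco[0:3, 0:3] = 2
        mask = e.WorldMask(grid16, country, eco, 1)
        cells = [(r, c) for r in range(3) for c in range(3)]
        s = dedupe_and_filter(occ_from_cells(grid16, cells), grid16, min_records=5)
        cr = build_m(s, mask, buffer_deg=0.0)
        assert cr.fallback_used
        assert np.array_equal(cr.m_cells, mask.country_cells(1))


class TestTrainingData:
    def test_pool_limited_absences(self, record_set, world16):
        cr = build_m(record_set, world16, buffer_deg=1.0)
        ts = draw_pseudo_absences(cr, record_set.unique_cells, n=10000, seed=0)
        pool = np.setdiff1d(cr.m_cells, record_set.unique_cells)
        assert ts.n_absence == pool.size
        assert not np.isin(ts.absence_cells, ts.presence_cells).any()

    def test_prevalence_weights_balance(self):
        cr = e.CalibrationRegion("sp", np.arange(100), np.arange(100))
        ts = draw_pseudo_absences(cr, np.arange(20), n=80, seed=0)
        assert ts.n_presence == 20 and ts.n_absence == 80
        assert ts.presence_weights.sum() == pytest.approx(ts.absence_weights.sum())
        # each presence weighs 4x each absence
        assert ts.presence_weights[0] / ts.absence_weights[0] == pytest.approx(4.0)

    def test_empty_pool_rejected(self):
        cr = e.CalibrationRegion("sp", np.arange(10), np.arange(10))
        with pytest.raises(ValueError, match="empty pseudo-absence pool"):
            draw_pseudo_absences(cr, np.arange(10), seed=0)

    def test_split_fraction_guard(self):
        ts = TrainingSet(np.arange(10), np.arange(10, 40), np.ones(10), np.full(30, 1 / 3))
        for bad in (0.0, 1.0, 1.3):
            with pytest.raises(ValueError, match="fraction"):
                split_replicates(ts, fraction=bad)

    def test_splits_are_stratified_and_distinct(self):
        ts = TrainingSet(np.arange(20), np.arange(100, 200), np.ones(20), np.full(100, 0.2))
        splits = split_replicates(ts, fraction=0.7, n_reps=10, seed=5)
        assert len(splits) == 10
        signatures = set()
        for train, test in splits:
            assert abs(train.n_presence - 14) <= 1
            assert abs(train.n_absence - 70) <= 1
            assert np.array_equal(
                np.sort(np.concatenate([train.presence_cells, test.presence_cells])),
                ts.presence_cells,
            )
            signatures.add(tuple(train.presence_cells))
        assert len(signatures) > 1


class TestFitAlgorithm:
    @pytest.fixture()
    def separable(self, grid16):
        # one informative layer: left half cold (presence), right half hot
        x = np.tile(np.linspace(-2, 2, grid16.n_cols), (grid16.n_rows, 1))
        noise = np.random.default_rng(0).normal(size=grid16.shape)
        stack = make_stack(grid16, {"temp": x, "junk": noise})
        pres = np.flatnonzero((x < -0.5).ravel())[:40]
        absn = np.flatnonzero((x > 0.5).ravel())[:60]
        ts = TrainingSet(pres, absn, np.ones(pres.size), np.full(absn.size, pres.size / absn.size))
        return stack, ts

    def test_envelope_percentile_box(self, grid16):
        vals = np.linspace(0.0, 10.0, grid16.n_cells).reshape(grid16.shape)
        stack = make_stack(grid16, {"v": vals})
        pres = np.flatnonzero((vals.ravel() >= 4.0) & (vals.ravel() <= 6.0))
        absn = np.flatnonzero(vals.ravel() < 2.0)
        ts = TrainingSet(pres, absn, np.ones(pres.size), np.full(absn.size, pres.size / absn.size))
        fit = fit_algorithm(ts, stack, ["v"], "envelope", seed=0)
        lo, hi = np.percentile(vals.ravel()[pres], [2.5, 97.5])
        scores = fit.predict_cells(stack, np.arange(grid16.n_cells))
        inside = (vals.ravel() >= lo) & (vals.ravel() <= hi)
        assert np.array_equal(scores, inside.astype(float))

    def test_envelope_monotone_in_window(self, separable):
        stack, ts = separable
        cells = np.arange(stack.grid.n_cells)
        narrow = fit_algorithm(ts, stack, ["temp"], "envelope", 0, envelope_window=(10, 90))
        wide = fit_algorithm(ts, stack, ["temp"], "envelope", 0, envelope_window=(2.5, 97.5))
        assert (wide.predict_cells(stack, cells) >= narrow.predict_cells(stack, cells)).all()

    def test_logistic_separable_auc_one(self, separable):
        stack, ts = separable
        splits = split_replicates(ts, 0.7, 1, seed=0)
        train, test = splits[0]
        fit = fit_algorithm(train, stack, ["temp", "junk"], "logistic", seed=0)
        ev = evaluate(
            fit.predict_cells(stack, test.presence_cells),
            fit.predict_cells(stack, test.absence_cells),
        )
        assert ev.auc == 1.0

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_predictions_bounded_and_deterministic(self, separable, algo):
        stack, ts = separable
        cells = np.arange(stack.grid.n_cells)
        fit = fit_algorithm(ts, stack, ["temp", "junk"], algo, seed=7)
        scores = fit.predict_cells(stack, cells)
        assert scores.shape == cells.shape
        assert (scores >= 0).all() and (scores <= 1).all()
        fit2 = fit_algorithm(ts, stack, ["temp", "junk"], algo, seed=7)
        assert np.array_equal(scores, fit2.predict_cells(stack, cells))

    def test_degenerate_training_rejected(self, separable):
        stack, ts = separable
        bad = TrainingSet(ts.presence_cells[:1], ts.absence_cells, np.ones(1), ts.absence_weights)
        with pytest.raises(ValueError, match="degenerate"):
            fit_algorithm(bad, stack, ["temp"], "logistic", seed=0)

    def test_unknown_algorithm_rejected(self, separable):
        stack, ts = separable
        with pytest.raises(ValueError, match="unknown algorithm"):
            fit_algorithm(ts, stack, ["temp"], "kriging", seed=0)


class TestEvaluate:
    def test_perfect_separation(self):
        ev = evaluate([0.9, 0.8], [0.1, 0.2])
        assert ev.auc == 1.0 and ev.tss == 1.0
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0

    def test_pairwise_concordance_example(self):
        ev = evaluate([0.9, 0.4], [0.6, 0.1])
        assert ev.auc == pytest.approx(0.75)

    def test_max_tss_reported_at_lowest_tying_threshold(self):
        ev = evaluate([0.9, 0.7, 0.3], [0.6, 0.4, 0.2])
        assert ev.tss == pytest.approx(2 / 3)
        assert ev.tss_threshold == pytest.approx(0.61)
        assert ev.tss == pytest.approx(ev.sensitivity + ev.specificity - 1)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            evaluate([], [0.5])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        pres = np.round(rng.random(rng.integers(1, 30)), 3)
        absn = np.round(rng.random(rng.integers(1, 30)), 3)
        ev = evaluate(pres, absn)
        assert ev.auc == pytest.approx(brute_force_auc(list(pres), list(absn)))
        tss, thr = brute_force_max_tss(list(pres), list(absn))
        assert ev.tss == pytest.approx(tss)
        assert ev.tss_threshold == pytest.approx(thr)
        assert auc_score(pres, absn) == ev.auc


class TestVariableContributions:
    def test_informative_layer_ranks_first_and_unused_is_null(self):
        grid = e.GridSpec(16, 16, 0.5)
        x = np.tile(np.linspace(-2, 2, grid.n_cols), (grid.n_rows, 1))
        junk = np.random.default_rng(3).normal(size=grid.shape)
        stack = make_stack(grid, {"temp": x, "junk": junk})
        pres = np.flatnonzero((x < -0.5).ravel())[:40]
        absn = np.flatnonzero((x > 0.5).ravel())[:60]
        ts = TrainingSet(pres, absn, np.ones(pres.size), np.full(absn.size, pres.size / absn.size))
        fit = fit_algorithm(ts, stack, ["temp", "junk"], "logistic", seed=0)
        contribs = variable_contributions(fit, ts, stack, seed=0)
        assert contribs[0][0] == "temp"
        assert contribs[0][1] > 0.2
        named = dict(contribs)
        assert abs(named["junk"]) < 0.05
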