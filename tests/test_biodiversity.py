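import numpy as np
import pytest

import endemia as e
from endemia.biodiversity_metrics import (
    build_pam,
    classify_change,
    delta_richness,
    hotspots,
    range_change,
    richness,
    temporal_sorensen,
)
from endemia.ensemble_projection import EnsemblePrediction
from endemia.niche_models import EvaluationResult


def make_prediction(cells, binary, species_id="sp0", scenario="baseline", horizon="T0"):
    cells = np.asarray(cells)
    binary = np.asarray(binary, dtype=bool)
    ev = EvaluationResult(1.0, 1.0, 0.5, 1.0, 1.0)
    return EnsemblePrediction(
        species_id=species_id, scenario_id=scenario, horizon=horizon,
        cells=cells, suitability=binary.astype(float), binary=binary,
        member_count=1, ensemble_eval=ev,
    )


def one_country_mask(grid):
    ids = np.ones(grid.shape, dtype=np.int64)
    return e.WorldMask(grid, ids, ids.copy(), 1)


class TestRangeChange:
    def test_gain(self):
        pres = make_prediction(np.arange(100), np.arange(100) < 50)
        fut = make_prediction(np.arange(100), np.arange(100) < 60, scenario="control", horizon="T1")
        rec = range_change(pres, fut)
        assert rec.delta == pytest.approx(0.2)
        assert rec.n_present == 50 and rec.n_future == 60
        assert not rec.complete_loss and rec.category == "stable_gain"

    def test_complete_loss(self):
        pres = make_prediction(np.arange(120), np.arange(120) < 100)
        fut = make_prediction(np.arange(120), np.zeros(120), scenario="melting", horizon="T3")
        rec = range_change(pres, fut)
        assert rec.delta == -1.0 and rec.complete_loss
        assert rec.category == "complete_loss"

    def test_identity_is_zero(self):
        pres = make_prediction(np.arange(40), np.arange(40) < 10)
        rec = range_change(pres, pres)
        assert rec.delta == 0.0 and not rec.complete_loss

    def test_empty_present_range_rejected(self):
        empty = make_prediction(np.arange(10), np.zeros(10))
        with pytest.raises(ValueError, match="empty present-day range"):
            range_change(empty, empty)


class TestClassifyChange:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (-1.0, "complete_loss"),
            (-0.7, "severe_loss"),
            (-0.5, "severe_loss"),  # closed on the loss side
            (-0.49, "moderate_loss"),
            (-0.01, "moderate_loss"),
            (0.0, "stable_gain"),
            (0.2, "stable_gain"),
            (0.5, "stable_gain"),
            (0.51, "strong_gain"),
        ],
    )
    def test_default_bins(self, delta, expected):
        assert classify_change(delta) == expected


class TestPAMAndRichness:
    @pytest.fixture()
    def grid8(self):
        return e.GridSpec(8, 8, 1.0)

    def test_row_sums_equal_range_sizes_and_column_sums_equal_sr(self, grid8):
        rng = np.random.default_rng(0)
        preds = []
        for i in range(5):
            cells = np.sort(rng.choice(grid8.n_cells, size=30, replace=False))
            preds.append(make_prediction(cells, rng.random(30) < 0.5, species_id=f"sp{i}"))
        pam = build_pam(preds, grid8.n_cells)
        for i, p in enumerate(preds):
            assert pam.matrix[i].sum() == p.range_size
        mask = one_country_mask(grid8)
        rich = richness(pam, mask)
        assert np.array_equal(rich.sr.ravel(), pam.matrix.sum(axis=0))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation_identity(self, grid8, seed):
        # sum over cells of SR == sum over species of range size, exactly
        rng = np.random.default_rng(seed)
        preds = [
            make_prediction(np.arange(grid8.n_cells), rng.random(grid8.n_cells) < 0.3,
                            species_id=f"sp{i}")
            for i in range(7)
        ]
        pam = build_pam(preds, grid8.n_cells)
        rich = richness(pam, one_country_mask(grid8))
        assert rich.sr.sum() == sum(p.range_size for p in preds)

    def test_empty_species_set(self, grid8):
        pam = build_pam([], grid8.n_cells)
        assert pam.matrix.shape == (0, grid8.n_cells)
        rich = richness(pam, one_country_mask(grid8))
        assert rich.sr.sum() == 0
        assert rich.max_sr[1] == 0
        assert np.all(rich.sr_standardized == 0.0)

    def test_mixed_scenarios_rejected(self, grid8):
        a = make_prediction(np.arange(5), np.ones(5), scenario="control", horizon="T1")
        b = make_prediction(np.arange(5), np.ones(5), scenario="melting", horizon="T1")
        with pytest.raises(ValueError, match="mixed scenario"):
            build_pam([a, b], grid8.n_cells)

    def test_standardized_sr_tops_at_one_per_country(self, grid8):
        preds = [
            make_prediction(np.arange(10), np.ones(10), species_id=f"sp{i}") for i in range(3)
        ]
        pam = build_pam(preds, grid8.n_cells)
        rich = richness(pam, one_country_mask(grid8))
        assert rich.sr.max() == 3
        assert rich.sr_standardized.max() == 1.0

    def test_delta_richness_sign_convention(self):
        sr_p = np.array([[5, 0], [1, 2]])
        sr_f = np.array([[3, 0], [4, 2]])
        d = delta_richness(sr_p, sr_f)
        assert d[0, 0] == -2  # loss
        assert d[1, 0] == 3   # gain
        assert d[1, 1] == 0


class TestHotspots:
    @pytest.fixture()
    def richness_fixture(self):
        grid = e.GridSpec(8, 8, 1.0)
        mask = one_country_mask(grid)
        sr = np.zeros(grid.shape, dtype=np.int64)
        sr.ravel()[:4] = [10, 7, 6, 5]
        preds = []  # build a PAM-free RichnessMaps via richness() equivalent
        rich = e.RichnessMaps(sr=sr, sr_standardized=sr / 10, max_sr={1: 10})
        return grid, mask, rich

    def test_strict_threshold_boundary(self, richness_fixture):
        grid, mask, rich = richness_fixture
        hs = hotspots(rich, mask, factor=0.6)
        # maxSR=10 -> cutoff 6: cells with SR {10, 7} qualify; 6 is excluded
        assert hs.psh_present.sum() == 2
        assert set(np.flatnonzero(hs.psh_present.ravel())) == {0, 1}

    def test_monotone_in_factor(self, richness_fixture):
        grid, mask, rich = richness_fixture
        sets = {
            f: set(np.flatnonzero(hotspots(rich, mask, f).psh_present.ravel()))
            for f in (0.2, 0.6, 0.9)
        }
        assert sets[0.9] <= sets[0.6] <= sets[0.2]

    def test_extent_ratio_uses_frozen_present_cutoff(self, richness_fixture):
        grid, mask, rich = richness_fixture
        sr_future = np.zeros(grid.shape, dtype=np.int64)
        sr_future.ravel()[0] = 9  # only one cell above the present cutoff of 6
        hs = hotspots(rich, mask, factor=0.6, sr_future=sr_future)
        assert hs.extent_ratio == pytest.approx(0.5)
        # future maxSR (9) is NOT used to re-derive the cutoff
        assert hs.cutoffs[1] == pytest.approx(6.0)

    def test_present_vs_itself_is_one(self, richness_fixture):
        grid, mask, rich = richness_fixture
        hs = hotspots(rich, mask, factor=0.6, sr_future=rich.sr)
        assert hs.extent_ratio == 1.0


class TestTemporalSorensen:
    def _pams(self, present_rows, future_rows):
        n_cells = len(present_rows[0])
        p = e.PAM("baseline", "T0", np.array(present_rows, dtype=bool),
                  [f"sp{i}" for i in range(len(present_rows))])
        f = e.PAM("melting", "T1", np.array(future_rows, dtype=bool),
                  [f"sp{i}" for i in range(len(future_rows))])
        return p, f, np.arange(n_cells)

    def test_identical_composition_is_zero(self):
        rows = [[1, 0, 1], [0, 1, 1]]
        p, f, cells = self._pams(rows, rows)
        bsor, med = temporal_sorensen(p, f, cells)
        assert np.allclose(bsor[~np.isnan(bsor)], 0.0)
        assert med == 0.0

    def test_disjoint_nonempty_sets_are_one(self):
        p, f, cells = self._pams([[1], [0]], [[0], [1]])
        bsor, med = temporal_sorensen(p, f, cells)
        assert bsor[0] == 1.0 and med == 1.0

    def test_shared_and_unique_example(self):
        # a=2 shared, b=1 present-only, c=1 future-only -> 2/6
        p, f, cells = self._pams(
            [[1], [1], [1], [0]],
            [[1], [1], [0], [1]],
        )
        bsor, med = temporal_sorensen(p, f, cells)
        assert bsor[0] == pytest.approx(1 / 3)

    def test_empty_in_both_periods_is_nodata(self):
        p, f, cells = self._pams([[1, 0]], [[1, 0]])
        bsor, med = temporal_sorensen(p, f, cells)
        assert np.isnan(bsor[1]) and bsor[0] == 0.0
        assert med == 0.0  # median over valid cells only

    @pytest.mark.parametrize("seed", [0, 1])
    def test_symmetric_in_gain_and_loss_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 40)) < 0.4
        b = rng.random((6, 40)) < 0.4
        sp = [f"sp{i}" for i in range(6)]
        pam_a = e.PAM("baseline", "T0", a, sp)
        pam_b = e.PAM("control", "T1", b, sp)
        f_ab, _ = temporal_sorensen(pam_a, pam_b, np.arange(40))
        pam_a2 = e.PAM("baseline", "T0", b, sp)
        pam_b2 = e.PAM("control", "T1", a, sp)
        f_ba, _ = temporal_sorensen(pam_a2, pam_b2, np.arange(40))
        valid = ~np.isnan(f_ab)
        assert np.array_equal(valid, ~np.isnan(f_ba))
        assert np.allclose(f_ab[valid], f_ba[valid])
        assert (f_ab[valid] >= 0).all() and (f_ab[valid] <= 1).all()

    def test_mismatched_species_rejected(self):
        p = e.PAM("baseline", "T0", np.ones((1, 3), dtype=bool), ["a"])
        f = e.PAM("control", "T1", np.ones((1, 3), dtype=bool), ["b"])
        with pytest.raises(ValueError, match="same species"):
            temporal_sorensen(p, f, np.arange(3))

    def test_empty_cells_rejected(self):
        p = e.PAM("baseline", "T0", np.ones((1, 3), dtype=bool), ["a"])
        with pytest.raises(ValueError, match="non-empty"):
            temporal_sorensen(p, p, np.array([], dtype=int))
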