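import numpy as np
import pandas as pd
import pytest

from shrubmap.detection import (
    FeatureStack,
    build_masks,
    fit_and_predict,
    merge_strata,
    select_variables,
)
from shrubmap.lidar_metrics import StructuralStack
from shrubmap.raster import GridMismatchError, RasterGrid
from shrubmap.synthetic_scene import LANDCOVER_CODES, PlotRecord


def _grid(data):
    data = np.asarray(data, dtype=float)
    return RasterGrid(data, (0.0, data.shape[0]), 1.0)


def _structural(cover_below):
    g = _grid(cover_below)
    return StructuralStack(*[g.like(np.asarray(cover_below, float))
                             for _ in range(8)],
                           cover_below_2p5=g.like(np.asarray(cover_below, float)),
                           penetration=g.like(np.ones_like(np.asarray(cover_below, float))),
                           canopy_cover_above_2p5=g.like(np.zeros_like(np.asarray(cover_below, float))))


class TestBuildMasks:
    def test_low_understory_and_impervious_classes_masked(self):
        cover_below = [[0.05, 0.5], [0.5, 0.5]]
        lc = _grid([[LANDCOVER_CODES["grass"], LANDCOVER_CODES["water"]],
                    [LANDCOVER_CODES["paved"], LANDCOVER_CODES["grass"]]])
        mask = build_masks(_structural(cover_below), lc)
        assert mask.data.tolist() == [[False, False], [False, True]]

    def test_unknown_landcover_code_rejected(self):
        lc = _grid([[99, 1], [1, 1]])
        with pytest.raises(ValueError, match="99"):
            build_masks(_structural([[0.5] * 2] * 2), lc)


class TestSelectVariables:
    def _table(self, rng, n=120):
        signal = rng.normal(0, 1, n)
        label = (signal > 0).astype(int)
        return pd.DataFrame({
            "signal": signal + rng.normal(0, 0.15, n),
            "other": rng.normal(0, 1, n),
            "label": label,
        }), label

    def test_duplicate_variable_resolved_by_importance(self):
        rng = np.random.default_rng(0)
        table, _ = self._table(rng)
        table["signal_copy"] = table["signal"]  # |r| = 1 with "signal"
        kept = select_variables(table, n_trees=200, seed=0)
        assert sum(v in kept for v in ("signal", "signal_copy")) == 1

    def test_orthogonal_informative_variables_all_survive(self):
        rng = np.random.default_rng(1)
        n = 150
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        label = ((a + b) > 0).astype(int)
        table = pd.DataFrame({"a": a, "b": b, "label": label})
        assert set(select_variables(table, n_trees=300, seed=0)) == {"a", "b"}

    def test_noise_variable_never_outranks_signal(self):
        rng = np.random.default_rng(2)
        table, _ = self._table(rng)
        table["noise"] = rng.normal(0, 1, len(table))

        ranks = []
        for seed in range(8):
            kept = select_variables(table, n_trees=200, seed=seed)
            ranks.append("signal" in kept)
        assert all(ranks)  # the informative variable always survives

    def test_reaches_fixed_point_within_variable_count(self):
        rng = np.random.default_rng(3)
        table, _ = self._table(rng)
        calls = []

        def importance(X, y, names):
            calls.append(list(names))
            # positive importances, ordered by column index
            return np.arange(len(names), 0, -1, dtype=float)

        kept = select_variables(table, importance_fn=importance)
        assert len(calls) <= table.shape[1]
        assert kept  # fixed point reached

    def test_fewer_than_two_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_variables(pd.DataFrame({"x": [1.0, 2.0], "label": [0, 1]}))


def _separable_stack(nrow=40, ncol=40, seed=0, stratum="open"):
    rng = np.random.default_rng(seed)
    truth = np.zeros((nrow, ncol), bool)
    truth[5:18, 5:18] = True  # one species patch
    feat = truth.astype(float) + rng.normal(0, 0.05, (nrow, ncol))
    other = rng.normal(0, 1, (nrow, ncol))
    g = RasterGrid(feat, (0.0, nrow), 1.0)
    stack = FeatureStack({"feat": g, "other": g.like(other)}, stratum, "blackberry")
    plots = []
    for i in range(24):
        r, c = 6 + (i % 4) * 3, 6 + (i // 6) * 3
        plots.append(PlotRecord(c + 0.5, nrow - r - 0.5, c + 0.5, nrow - r - 0.5,
                                "blackberry", True,
                                "train" if i % 2 == 0 else "validate", stratum))
    for i in range(30):
        r, c = 22 + (i % 5) * 3, 2 + (i // 5) * 4
        plots.append(PlotRecord(c + 0.5, nrow - r - 0.5, c + 0.5, nrow - r - 0.5,
                                "none", False,
                                "train" if i % 2 == 0 else "validate", stratum))
    return stack, plots, truth


class TestFitAndPredict:
    def test_separable_scene_recovers_patch(self):
        stack, plots, truth = _separable_stack()
        mask = stack.grid.like(np.ones(stack.grid.shape, bool), nodata=0)
        smap, model = fit_and_predict(stack, plots, mask,
                                      np.ones(stack.grid.shape, bool),
                                      n_trees=300, seed=0, select=False)
        assert model.ensemble.oob_score_ > 0.95
        pred = smap.presence.data > 0
        assert pred[truth].mean() > 0.9
        assert pred[~truth].mean() < 0.05

    def test_uncertainty_is_one_minus_pmax(self):
        stack, plots, _ = _separable_stack(seed=1)
        mask = stack.grid.like(np.ones(stack.grid.shape, bool), nodata=0)
        smap, _ = fit_and_predict(stack, plots, mask,
                                  np.ones(stack.grid.shape, bool),
                                  n_trees=200, seed=0, select=False)
        p = smap.p_presence.data
        u = smap.uncertainty.data
        ok = np.isfinite(p)
        assert np.allclose(u[ok], 1.0 - np.fmax(p[ok], 1 - p[ok]))
        assert np.nanmax(u) <= 0.5 + 1e-12

    def test_masked_pixels_are_nodata_everywhere(self):
        stack, plots, _ = _separable_stack(seed=2)
        mask_data = np.ones(stack.grid.shape, bool)
        mask_data[:, :10] = False
        mask = stack.grid.like(mask_data, nodata=0)
        smap, _ = fit_and_predict(stack, plots, mask,
                                  np.ones(stack.grid.shape, bool),
                                  n_trees=100, seed=0, select=False)
        assert np.isnan(smap.presence.data[:, :10]).all()
        assert np.isnan(smap.uncertainty.data[:, :10]).all()

    def test_single_class_training_rejected(self):
        stack, plots, _ = _separable_stack(seed=3)
        only_presence = [p for p in plots if p.presence]
        mask = stack.grid.like(np.ones(stack.grid.shape, bool), nodata=0)
        with pytest.raises(ValueError, match="single-class"):
            fit_and_predict(stack, only_presence, mask,
                            np.ones(stack.grid.shape, bool), n_trees=50)


class TestMergeStrata:
    def _maps(self):
        g = RasterGrid(np.zeros((4, 4)), (0.0, 4.0), 1.0)

        def smap(value, stratum):
            from shrubmap.detection import SpeciesMap

            arr = np.full((4, 4), value, dtype=float)
            return SpeciesMap(g.like(arr), g.like(arr), g.like(arr * 0.1),
                              "blackberry", stratum)

        return smap(1.0, "open"), smap(0.0, "closed"), g

    def test_cover_break_routes_pixels(self):
        open_m, closed_m, g = self._maps()
        cover = g.like(np.array([[0.1] * 4, [0.5] * 4, [0.1] * 4, [0.19] * 4]))
        merged = merge_strata(open_m, closed_m, cover)
        assert merged.presence.data[0, 0] == 1.0   # open model
        assert merged.presence.data[1, 0] == 0.0   # closed model
        assert merged.presence.data[3, 0] == 1.0   # 0.19 < 0.20 -> open

    def test_partition_conserves_presence_area(self):
        open_m, closed_m, g = self._maps()
        cover = g.like(np.where(np.arange(16).reshape(4, 4) % 2 == 0, 0.1, 0.6))
        merged = merge_strata(open_m, closed_m, cover)
        open_px = np.nansum(open_m.presence.data[cover.data < 0.2])
        closed_px = np.nansum(closed_m.presence.data[cover.data >= 0.2])
        assert np.nansum(merged.presence.data) == open_px + closed_px

    def test_grid_mismatch_rejected(self):
        open_m, closed_m, _ = self._maps()
        cover = RasterGrid(np.zeros((5, 5)), (0.0, 5.0), 1.0)
        with pytest.raises(GridMismatchError):
            merge_strata(open_m, closed_m, cover)

    def test_closed_stack_rejects_spectral_layers(self):
        g = RasterGrid(np.zeros((3, 3)), (0.0, 3.0), 1.0)
        with pytest.raises(ValueError, match="rule_"):
            FeatureStack({"rule_ivy_all": g, "slope": g}, "closed", "ivy")
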