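import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishloc import localization_metrics as lm


def grid_coords(n):
    side = int(np.ceil(np.sqrt(n)))
    return np.argwhere(np.ones((side, side), bool))[:n]


class TestNormalizeGlobal:
    def test_single_image(self):
        out = lm.normalize_global([np.array([[0.0, 50.0, 100.0]])])
        assert np.allclose(out[0], [[0.0, 0.5, 1.0]])

    def test_shared_range_preserves_order(self):
        a = np.array([[10.0, 20.0]])
        b = np.array([[30.0, 40.0]])
        na, nb = lm.normalize_global([a, b])
        assert na.max() < nb.min()

    def test_global_max_in_one_image_only(self):
        a = np.array([[0.0, 100.0]])
        b = np.array([[0.0, 60.0]])
        _, nb = lm.normalize_global([a, b])
        assert nb.max() < 1.0

    def test_degenerate_range(self):
        with pytest.raises(ValueError):
            lm.normalize_global([np.full((3, 3), 5.0)])


class TestNormalizeCellular:
    def test_basic(self):
        out, flagged = lm.normalize_cellular({1: np.array([10.0, 20.0, 30.0])})
        assert np.allclose(out[1], [0.0, 0.5, 1.0])
        assert not flagged

    def test_each_cell_attains_extremes(self):
        out, _ = lm.normalize_cellular(
            {1: np.array([1.0, 2.0]), 2: np.array([100.0, 900.0])}
        )
        for heat in out.values():
            assert heat.min() == 0.0 and heat.max() == 1.0

    def test_rank_order_preserved(self):
        vals = np.array([5.0, 1.0, 3.0, 2.0])
        out, _ = lm.normalize_cellular({1: vals})
        assert (np.argsort(out[1]) == np.argsort(vals)).all()

    def test_constant_cell_flagged(self):
        out, flagged = lm.normalize_cellular({7: np.full(5, 3.0)})
        assert flagged == {7}
        assert (out[7] == 0.5).all()


class TestSelectTopFraction:
    def test_300_pixels_selects_30(self):
        rng = np.random.default_rng(0)
        sel = lm.select_top_fraction(rng.random(300), grid_coords(300), 0.1)
        assert sel.n_selected == 30

    def test_ten_distinct_selects_max(self):
        vals = np.arange(10.0)
        coords = grid_coords(10)
        sel = lm.select_top_fraction(vals, coords, 0.1)
        assert sel.n_selected == 1
        assert tuple(sel.selected[0]) == tuple(coords[9])

    def test_all_equal_tie_break_raster(self):
        coords = grid_coords(20)
        sel = lm.select_top_fraction(np.ones(20), coords, 0.1)
        assert sel.n_selected == 2
        assert np.array_equal(sel.selected, coords[:2])

    def test_selected_subset_of_cell(self):
        rng = np.random.default_rng(1)
        coords = grid_coords(57)
        sel = lm.select_top_fraction(rng.random(57), coords, 0.25)
        cell = {tuple(c) for c in coords}
        assert {tuple(c) for c in sel.selected} <= cell

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(2, 400), ft=st.floats(0.01, 0.99))
    def test_selection_size_invariant(self, n, ft):
        rng = np.random.default_rng(n)
        sel = lm.select_top_fraction(rng.random(n), grid_coords(n), ft)
        assert sel.n_selected == max(1, int(np.floor(ft * n + 0.5)))

    def test_invalid_ft(self):
        with pytest.raises(ValueError):
            lm.select_top_fraction(np.ones(5), grid_coords(5), 1.0)


class TestObservedOverlap:
    def make_sel(self, coords):
        coords = np.asarray(coords)
        return lm.ThresholdSelection(f_t=0.1, selected=coords, n_cell_pixels=100)

    def test_identical(self):
        s = self.make_sel([[0, 0], [0, 1], [1, 0]])
        assert lm.observed_overlap(s, s) == 1.0

    def test_disjoint(self):
        a = self.make_sel([[0, 0], [0, 1]])
        b = self.make_sel([[5, 5], [6, 6]])
        assert lm.observed_overlap(a, b) == 0.0

    def test_partial(self):
        sig = self.make_sel([[0, 0], [0, 1], [0, 2]])
        ref = self.make_sel([[0, 2], [0, 3], [0, 4]])
        assert lm.observed_overlap(sig, ref) == pytest.approx(1 / 3)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_intersection(self, seed):
        rng = np.random.default_rng(seed)
        coords = grid_coords(80)
        sig = self.make_sel(coords[rng.choice(80, 12, replace=False)])
        ref = self.make_sel(coords[rng.choice(80, 9, replace=False)])
        count = 0
        for p in sig.selected:
            for q in ref.selected:
                if p[0] == q[0] and p[1] == q[1]:
                    count += 1
        assert lm.observed_overlap(sig, ref) == pytest.approx(count / 9)


class TestTos:
    def test_equality_branch(self):
        assert lm.tos(0.1, 0.1) == 0.0

    def test_minimum(self):
        assert lm.tos(0.0, 0.1) == -1.0

    def test_maximum(self):
        assert lm.tos(1.0, 0.1) == pytest.approx(1.0)

    def test_lower_branch(self):
        assert lm.tos(0.05, 0.1) == pytest.approx(-0.5)

    def test_expected_out_of_range(self):
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                lm.tos(0.5, bad)

    @settings(max_examples=60, deadline=None)
    @given(
        expected=st.floats(0.01, 0.99),
        obs=st.lists(st.integers(0, 1000), min_size=2, max_size=10),
    )
    def test_strictly_increasing_in_observed(self, expected, obs):
        obs = [o / 1000 for o in sorted(set(obs))]
        scores = [lm.tos(o, expected) for o in obs]
        assert all(a < b for a, b in zip(scores, scores[1:]))
        assert all(-1 <= s <= 1 for s in scores)

    def test_continuous_at_expected(self):
        e = 0.3
        eps = 1e-9
        assert abs(lm.tos(e - eps, e)) < 1e-7
        assert abs(lm.tos(e + eps, e)) < 1e-7

    def test_expected_equals_ft(self):
        assert lm.expected_overlap(0.1) == 0.1


class TestMembraneLayers:
    def test_ten_by_ten_square(self):
        layers = lm.membrane_layers(grid_coords(100))
        assert len(layers.discarded_edge) == 36
        assert len(layers.membrane) == 28
        assert len(layers.interior) == 36

    def test_thin_roi_excluded(self):
        coords = np.argwhere(np.ones((3, 20), bool))
        with pytest.raises(lm.CellTooThinError):
            lm.membrane_layers(coords)

    @settings(max_examples=30, deadline=None)
    @given(h=st.integers(5, 15), w=st.integers(5, 15))
    def test_partition_property(self, h, w):
        coords = np.argwhere(np.ones((h, w), bool))
        layers = lm.membrane_layers(coords)
        parts = [layers.discarded_edge, layers.membrane, layers.interior]
        total = sum(len(p) for p in parts)
        assert total == h * w
        union = set()
        for p in parts:
            s = {tuple(x) for x in p}
            assert not (union & s)
            union |= s


class TestMembraneTos:
    def setup_method(self):
        self.coords = grid_coords(144)  # 12x12 square
        self.layers = lm.membrane_layers(self.coords)

    def values_high_on(self, px_set):
        high = {tuple(p) for p in px_set}
        return np.array(
            [1000.0 if tuple(c) in high else 1.0 for c in self.coords]
        )

    def test_membrane_signal_gives_plus_one(self):
        vals = self.values_high_on(self.layers.membrane)
        assert lm.membrane_tos(vals, self.coords).tos == pytest.approx(1.0)

    def test_interior_signal_gives_minus_one(self):
        deep = lm.membrane_layers(self.layers.interior).interior
        vals = self.values_high_on(deep)
        assert lm.membrane_tos(vals, self.coords).tos == pytest.approx(-1.0)

    def test_whole_cell_variant(self):
        vals = self.values_high_on(self.layers.membrane)
        res = lm.membrane_tos(vals, self.coords, rank_over="whole")
        assert res.expected == pytest.approx(len(self.layers.membrane) / 144)
        assert res.tos > 0

    def test_uniform_split_near_even(self, geometry_320):
        rng = np.random.default_rng(7)
        pos = neg = 0
        for cell in geometry_320.cells:
            score = lm.membrane_tos(
                rng.random(len(cell.cell_px)), cell.cell_px
            ).tos
            pos += score > 0
            neg += score < 0
        n = len(geometry_320.cells)
        assert abs(pos / n - neg / n) < 0.15
        assert 0.35 < pos / n < 0.65


class TestSignalToBackground:
    def make(self, in_cell, bg):
        img = np.full((20, 20), float(bg))
        cm = np.zeros((20, 20), np.int32)
        cm[5:10, 5:10] = 1
        img[cm == 1] = in_cell
        return img, cm

    def test_boundary_kept(self):
        img, cm = self.make(130, 100)
        rec = lm.signal_to_background(img, cm, cutoff=1.3)[0]
        assert rec.sb_ratio == pytest.approx(1.3)
        assert rec.included

    def test_no_signal_excluded(self):
        img, cm = self.make(100, 100)
        rec = lm.signal_to_background(img, cm, cutoff=1.2)[0]
        assert rec.sb_ratio == pytest.approx(1.0)
        assert not rec.included

    def test_no_background_errors(self):
        img = np.ones((4, 4))
        cm = np.ones((4, 4), np.int32)
        with pytest.raises(ValueError):
            lm.signal_to_background(img, cm)


class TestAxialProfile:
    def test_monotone_signal(self):
        coords = np.argwhere(np.ones((5, 40), bool))
        vals = coords[:, 1].astype(float)
        prof = lm.axial_profile(vals, coords, n_bins=8)
        assert (np.diff(prof) > 0).all()

    def test_bin_count(self):
        coords = np.argwhere(np.ones((5, 30), bool))
        prof = lm.axial_profile(np.ones(150), coords, n_bins=6)
        assert prof.shape == (6,)
        assert np.allclose(prof, 1.0)
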