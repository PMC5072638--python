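"""Difference maps, negative selection, indices, and their invariants."""

import numpy as np
import pytest

from macusym import (
    CellState,
    Eye,
    Layer,
    Mode,
    ThicknessGrid,
    analyze_subject,
    compute_indices,
    default_cutoff,
    interhemispheric_difference,
    interocular_difference,
)
from macusym.grids import DiseaseLaterality, Group, SubjectRecord

from conftest import random_grid
from oracles import brute_indices, brute_interhemispheric, brute_interocular


def _grid(values, layer=Layer.GCIPL, eye=Eye.OD):
    return ThicknessGrid(values=np.asarray(values, dtype=float), layer=layer, laterality=eye)


class TestInterocular:
    def test_self_mirror_comparison_is_all_zero(self, make_grid):
        target = make_grid()
        contra = ThicknessGrid(values=target.values[:, ::-1].copy(),
                               layer=target.layer, laterality=Eye.OS)
        amap = interocular_difference(target, contra)
        assert np.all(amap.diffs == 0)
        assert compute_indices(amap).n_negative == 0

    def test_worked_2x2_example(self):
        target = _grid([[10, 20], [30, 40]])
        contra = _grid([[25, 12], [40, 35]], eye=Eye.OS)
        amap = interocular_difference(target, contra)
        # mirrored fellow columns: diff(r,c) = target(r,c) - contra(r, 1-c)
        expected = {(0, 0): -2.0, (0, 1): -5.0, (1, 0): -5.0}
        retained = {(r, c): amap.diffs[r, c]
                    for r, c in zip(*np.where(amap.states == CellState.RETAINED))}
        assert retained == expected
        assert amap.states[1, 1] == CellState.EXCLUDED_NONNEG
        assert amap.diffs[1, 1] == 0.0
        idx = compute_indices(amap)
        assert idx.avg_negative_diff_um == -4.0
        assert idx.n_negative == 3

    def test_translation_invariance(self, make_grid):
        target = make_grid()
        contra = make_grid(laterality=Eye.OS)
        base = interocular_difference(target, contra)
        shifted = interocular_difference(
            _grid(target.values + 7.5), _grid(contra.values + 7.5, eye=Eye.OS)
        )
        np.testing.assert_allclose(shifted.diffs, base.diffs, atol=1e-9)

    def test_swap_antisymmetry(self, make_grid):
        a = make_grid()
        b = make_grid(laterality=Eye.OS)
        ab = interocular_difference(a, b)
        ba = interocular_difference(b, a)
        nc = a.shape[1]
        np.testing.assert_allclose(ab.diffs, -ba.diffs[:, ::-1], atol=0)
        assert nc == ba.diffs.shape[1]

    def test_shape_layer_laterality_errors(self, make_grid):
        with pytest.raises(ValueError, match="shape"):
            interocular_difference(make_grid(), make_grid(shape=(5, 5), laterality=Eye.OS))
        with pytest.raises(ValueError, match="layer"):
            interocular_difference(make_grid(layer=Layer.RNFL),
                                   make_grid(layer=Layer.GCIPL, laterality=Eye.OS))
        with pytest.raises(ValueError, match="laterality"):
            interocular_difference(make_grid(), make_grid())

    def test_missing_in_either_eye_propagates(self):
        target = _grid([[np.nan, 20], [30, 40]])
        contra = _grid([[25, 12], [np.nan, 35]], eye=Eye.OS)
        amap = interocular_difference(target, contra)
        # target (0,0) missing; contra (1,0) missing maps to target (1,1)
        assert amap.states[0, 0] == CellState.MISSING
        assert amap.states[1, 1] == CellState.MISSING
        assert compute_indices(amap).n_missing == 2


class TestInterhemispheric:
    def test_worked_3x3_example(self):
        amap = interhemispheric_difference(_grid([[10, 11, 12], [99, 99, 99], [13, 9, 14]]))
        retained = {(r, c): amap.diffs[r, c]
                    for r, c in zip(*np.where(amap.states == CellState.RETAINED))}
        assert retained == {(0, 0): -3.0, (0, 2): -2.0, (2, 1): -2.0}
        for rc in [(0, 1), (2, 0), (2, 2)]:
            assert amap.states[rc] == CellState.EXCLUDED_NONNEG
        assert np.all(amap.states[1, :] == CellState.EXCLUDED_CENTERLINE)
        idx = compute_indices(amap)
        assert idx.avg_negative_diff_um == pytest.approx(-7.0 / 3.0)

    def test_vertically_symmetric_grid_retains_nothing(self):
        vals = np.array([[1.0, 2.0], [5.0, 6.0], [1.0, 2.0]])
        amap = interhemispheric_difference(_grid(vals))
        assert compute_indices(amap).n_negative == 0

    def test_antisymmetry_before_selection(self, make_grid):
        g = make_grid(shape=(31, 31))
        amap = interhemispheric_difference(g)
        np.testing.assert_allclose(amap.diffs[:15], -amap.diffs[16:][::-1], atol=0)

    def test_even_rows_rejected(self, make_grid):
        with pytest.raises(ValueError, match="odd"):
            interhemispheric_difference(make_grid(shape=(30, 31)))

    def test_translation_invariance(self, make_grid):
        g = make_grid(shape=(9, 9))
        base = interhemispheric_difference(g)
        shifted = interhemispheric_difference(_grid(g.values + 12.25))
        np.testing.assert_allclose(shifted.diffs, base.diffs, atol=1e-9)


class TestIndices:
    def test_avg_arithmetic(self):
        amap = interhemispheric_difference(_grid([[10, 15, 15], [0, 0, 0], [12, 20, 20]]))
        idx = compute_indices(amap)
        assert idx.avg_negative_diff_um == pytest.approx((-2 - 5 - 5) / 3)
        assert idx.n_negative == 3

    def test_strict_cutoff_threshold(self):
        # retained diffs {-25, -20, -5} at GCIPL cutoff 20: only -25 is black
        target = _grid([[10, 10, 10]])
        contra = _grid([[15, 30, 35]], eye=Eye.OS)  # mirrored -> [35, 30, 15]
        amap = interocular_difference(target, contra)
        np.testing.assert_array_equal(amap.diffs, [[-25.0, -20.0, -5.0]])
        assert compute_indices(amap).n_black == 1
        assert compute_indices(amap, cutoff_inclusive=True).n_black == 2

    def test_empty_retained_set_flagged(self):
        amap = interocular_difference(_grid([[50, 50]]), _grid([[40, 40]], eye=Eye.OS))
        idx = compute_indices(amap)
        assert idx.no_negative_cells
        assert idx.avg_negative_diff_um == 0.0
        assert idx.n_black == 0

    def test_n_black_monotone_in_cutoff_and_equals_n_negative_at_zero(self, make_grid):
        from dataclasses import replace

        target, contra = make_grid(), make_grid(laterality=Eye.OS)
        amap = interocular_difference(target, contra)
        counts = [compute_indices(replace(amap, cutoff_um=c)).n_black
                  for c in [1e-12, 5, 10, 20, 40, 80]]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == compute_indices(amap).n_negative

    def test_default_cutoffs(self):
        assert default_cutoff(Layer.GCIPL) == 20.0
        for layer in (Layer.RNFL, Layer.GCC, Layer.TOTAL_RETINA):
            assert default_cutoff(layer) == 40.0
        with pytest.raises(ValueError):
            default_cutoff("CHOROID")


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", [Mode.INTEROCULAR, Mode.INTERHEMISPHERIC])
    def test_matches_double_loop(self, rng, mode):
        for _ in range(25):
            shape = (int(rng.choice([3, 7, 15, 31])),) * 2
            target = random_grid(rng, shape=shape, missing_frac=0.05)
            if mode is Mode.INTEROCULAR:
                contra = random_grid(rng, shape=shape, laterality=Eye.OS, missing_frac=0.05)
                amap = interocular_difference(target, contra)
                diffs, state = brute_interocular(target.values, contra.values)
            else:
                amap = interhemispheric_difference(target)
                diffs, state = brute_interhemispheric(target.values)
            avg, n_neg, n_black = brute_indices(diffs, state, amap.cutoff_um)
            idx = compute_indices(amap)
            assert idx.n_negative == n_neg
            assert idx.n_black == n_black
            assert idx.avg_negative_diff_um == pytest.approx(avg, abs=1e-12)
            np.testing.assert_array_equal(amap.retained_mask, state == "neg")

    def test_pair_exclusivity(self, rng):
        g = random_grid(rng, shape=(31, 31))
        amap = interhemispheric_difference(g)
        top, bottom = amap.retained_mask[:15], amap.retained_mask[16:][::-1]
        both = top & bottom
        assert not both.any()
        neither = ~top & ~bottom
        zero_pairs = amap.diffs[:15] == 0
        np.testing.assert_array_equal(neither, zero_pairs)


class TestAnalyzeSubject:
    def _record(self, grids_fn, group=Group.NORMAL,
                laterality=DiseaseLaterality.NONE):
        grids = {(eye, layer): grids_fn(eye, layer) for eye in Eye for layer in Layer}
        return SubjectRecord(subject_id="X", group=group, target_eye=Eye.OD,
                             disease_laterality=laterality, grids=grids)

    def test_symmetric_record_all_null(self, rng):
        half = rng.uniform(50, 100, size=(15, 31))
        center = rng.uniform(50, 100, size=(1, 31))
        vsym = np.vstack([half, center, half[::-1]])

        def make(eye, layer):
            vals = vsym if eye is Eye.OD else vsym[:, ::-1]
            return ThicknessGrid(values=vals.copy(), layer=layer, laterality=eye)

        out = analyze_subject(self._record(make))
        assert len(out) == 8
        assert all(idx.n_negative == 0 for idx in out.values())

    def test_cardinality_and_key_coverage(self, rng):
        def make(eye, layer):
            return random_grid(rng, layer=layer, laterality=eye)

        out = analyze_subject(self._record(make))
        assert set(out) == {(layer, mode) for layer in Layer for mode in Mode}
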