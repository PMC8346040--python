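import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrecontact import (
    FibreComponent,
    FibreSelection,
    MaskStack,
    contact_with_cell,
    enrich_across_planes,
    enrichment_chain,
    filter_size,
    label_components,
    selection_to_masks,
    subtract_cell,
)

from _oracles import flood_components, touches_cell


def comp(slice_index, pixels, label=1):
    return FibreComponent(slice_index, label, frozenset(pixels))


def selection(*components):
    return FibreSelection.of(components)


class TestSubtractCell:
    def test_self_subtraction_empties(self, rng):
        m = MaskStack(rng.random((3, 8, 8)) < 0.3)
        assert not subtract_cell(m, m).slices.any()

    def test_disjoint_masks_pass_through(self):
        collagen = np.zeros((2, 5, 5), dtype=bool)
        collagen[0, 1, 1] = True
        cell = np.zeros((2, 5, 5), dtype=bool)
        cell[0, 3, 3] = True
        out = subtract_cell(MaskStack(collagen), MaskStack(cell))
        assert np.array_equal(out.slices, collagen)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            subtract_cell(
                MaskStack(np.ones((2, 4, 4), dtype=bool)),
                MaskStack(np.ones((2, 5, 5), dtype=bool)),
            )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**16))
    def test_boolean_identities(self, seed):
        rng = np.random.default_rng(seed)
        collagen = rng.random((2, 16, 16)) < 0.4
        cell = rng.random((2, 16, 16)) < 0.4
        out = subtract_cell(MaskStack(collagen), MaskStack(cell)).slices
        assert not (out & cell).any()
        assert np.array_equal(out | (collagen & cell), collagen)


class TestLabelComponents:
    def test_diagonal_run_is_one_component(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = True
        comps = label_components(mask, 0)
        assert len(comps) == 1
        assert comps[0].pixels == {(0, 0), (1, 1), (2, 2)}

    def test_full_gap_separates(self):
        mask = np.zeros((1, 5), dtype=bool)
        mask[0, 0] = mask[0, 2] = True
        comps = label_components(mask, 3)
        assert [c.pixels for c in comps] == [frozenset({(0, 0)}), frozenset({(0, 2)})]
        assert [c.slice_index for c in comps] == [3, 3]

    def test_labels_follow_raster_scan_order(self):
        mask = np.zeros((4, 6), dtype=bool)
        mask[3, 0] = True          # first pixel in raster order is (0, 4)
        mask[0, 4] = mask[1, 4] = True
        comps = label_components(mask, 0)
        by_label = {c.label: c.pixels for c in comps}
        assert by_label[1] == {(0, 4), (1, 4)}
        assert by_label[2] == {(3, 0)}

    def test_empty_mask_gives_empty_list(self):
        assert label_components(np.zeros((3, 3), dtype=bool), 0) == []

    def test_partition_matches_flood_fill_oracle(self, rng):
        for _ in range(30):
            mask = rng.random((32, 32)) < 0.3
            ours = {c.pixels for c in label_components(mask, 0)}
            oracle = set(flood_components(mask))
            assert ours == oracle


class TestFilterSize:
    def test_strict_boundary_at_default_bound(self):
        comps = [
            comp(0, {(0, x) for x in range(6)}, label=1),   # 6 pixels
            comp(0, {(1, x) for x in range(5)}, label=2),   # 5 pixels
            comp(0, {(2, x) for x in range(3)}, label=3),   # 3 pixels
        ]
        kept = filter_size(comps, 5)
        assert {c.label for c in kept} == {1}

    def test_zero_bound_keeps_everything(self):
        comps = [comp(0, {(0, 0)}, label=1), comp(1, {(1, 1)}, label=1)]
        assert len(filter_size(comps, 0)) == 2

    def test_matches_direct_predicate(self, rng):
        comps = []
        for i in range(40):
            n = int(rng.integers(1, 12))
            pixels = {(int(rng.integers(0, 20)), int(rng.integers(0, 20)))
                      for _ in range(n)}
            comps.append(comp(i % 4, pixels, label=i))
        kept = filter_size(comps, 5)
        assert kept.members == frozenset(c for c in comps if len(c.pixels) > 5)


class TestContactWithCell:
    def _cell(self, n_slices=3, shape=(8, 8), pixels=()):
        cell = np.zeros((n_slices, *shape), dtype=bool)
        for z, y, x in pixels:
            cell[z, y, x] = True
        return MaskStack(cell)

    def test_diagonal_adjacency_is_contact(self):
        cell = self._cell(pixels=[(0, 3, 3)])
        sel = selection(comp(0, {(2, 2)}))
        assert len(contact_with_cell(sel, cell)) == 1

    def test_chebyshev_distance_two_is_not_contact(self):
        cell = self._cell(pixels=[(0, 4, 4)])
        sel = selection(comp(0, {(2, 2)}))
        assert len(contact_with_cell(sel, cell)) == 0

    def test_contact_is_same_slice_only(self):
        # Adjacent to the cell in-plane, but one slice away: dropped here,
        # recoverable only through the enrichment step.
        cell = self._cell(pixels=[(1, 3, 3)])
        sel = selection(comp(0, {(2, 2), (3, 2)}))
        assert len(contact_with_cell(sel, cell)) == 0

    def test_missing_cell_slice_is_an_error(self):
        cell = self._cell(n_slices=2)
        sel = selection(comp(5, {(1, 1)}))
        with pytest.raises(IndexError):
            contact_with_cell(sel, cell)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            cell = rng.random((4, 16, 16)) < 0.15
            comps = []
            for i in range(12):
                z = int(rng.integers(0, 4))
                pixels = frozenset(
                    (int(rng.integers(0, 16)), int(rng.integers(0, 16)))
                    for _ in range(int(rng.integers(1, 6)))
                )
                comps.append(FibreComponent(z, i, pixels))
            sel = FibreSelection.of(comps)
            ours = contact_with_cell(sel, MaskStack(cell)).members
            oracle = frozenset(
                c for c in comps if touches_cell(c.pixels, cell[c.slice_index])
            )
            assert ours == oracle


class TestEnrichment:
    def test_chain_recruits_through_planes_without_contact(self):
        # A touches the cell in slice 0 only; B and C are picked up through
        # successive same-position overlaps in slices 1 and 2.
        a = comp(0, {(1, 1), (1, 2)}, label=1)
        b = comp(1, {(1, 2), (5, 5)}, label=1)
        c = comp(2, {(5, 5), (7, 7)}, label=1)
        universe = selection(a, b, c)
        chain = enrichment_chain(selection(a), universe)
        assert [s.keys() for s in chain] == [
            frozenset({(0, 1)}),
            frozenset({(0, 1), (1, 1)}),
            frozenset({(0, 1), (1, 1), (2, 1)}),
        ]

    def test_no_overlap_means_no_recruitment(self):
        a = comp(0, {(1, 1)}, label=1)
        b = comp(1, {(5, 5)}, label=1)
        result = enrich_across_planes(selection(a), selection(a, b))
        assert result.keys() == frozenset({(0, 1)})

    def test_same_slice_overlap_does_not_recruit(self):
        # Identical pixels but the same slice index: the recursion pairs
        # slice i only with i-1 and i+1.
        a = comp(0, {(1, 1)}, label=1)
        b = comp(0, {(1, 1), (1, 2)}, label=2)
        result = enrich_across_planes(selection(a), selection(a, b))
        assert result.keys() == frozenset({(0, 1)})

    def test_empty_seed_stays_empty(self):
        universe = selection(comp(0, {(1, 1)}))
        assert len(enrich_across_planes(FibreSelection.of([]), universe)) == 0

    def test_seed_equal_universe_is_fixed_point(self):
        universe = selection(
            comp(0, {(1, 1)}, label=1), comp(1, {(1, 1)}, label=1)
        )
        assert enrich_across_planes(universe, universe).members == universe.members

    def test_idempotence(self):
        a = comp(0, {(1, 1)}, label=1)
        b = comp(1, {(1, 1)}, label=1)
        universe = selection(a, b)
        fixed = enrich_across_planes(selection(a), universe)
        again = enrich_across_planes(fixed, universe)
        assert again.members == fixed.members

    def test_seed_must_be_subset_of_universe(self):
        a = comp(0, {(1, 1)}, label=1)
        with pytest.raises(ValueError):
            enrich_across_planes(selection(a), FibreSelection.of([]))


class TestSelectionToMasks:
    def test_empty_selection_renders_empty_stack(self):
        out = selection_to_masks(FibreSelection.of([]), (4, 4), 3)
        assert out.slices.shape == (3, 4, 4) and not out.slices.any()

    def test_single_component_renders_its_pixels(self):
        sel = selection(comp(1, {(0, 0), (1, 1), (2, 2)}))
        out = selection_to_masks(sel, (4, 4), 3)
        assert out.slices[1].sum() == 3 and out.slices[[0, 2]].sum() == 0

    def test_out_of_bounds_component_rejected(self):
        sel = selection(comp(0, {(9, 9)}))
        with pytest.raises(IndexError):
            selection_to_masks(sel, (4, 4), 1)

    def test_round_trip_through_labelling(self, small_instance):
        collagen, _ = small_instance
        comps = [
            c
            for i in range(collagen.n_slices)
            for c in label_components(collagen.slices[i], i)
        ]
        rebuilt = selection_to_masks(
            FibreSelection.of(comps), collagen.frame_shape, collagen.n_slices
        )
        assert np.array_equal(rebuilt.slices, collagen.slices)
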