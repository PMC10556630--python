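"""CG task generators: glyphs, example-count arithmetic, exclusion splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from counterstream import cg_tasks
from counterstream.cg_tasks import (
    CELL_H,
    CELL_W,
    N_GLYPH_CLASSES,
    classify_glyph,
    encode_chargrid,
    encode_persons,
    make_chargrid_dataset,
    make_persons_dataset,
    render_chargrid_image,
    synth_glyph,
    validate_split,
)


class TestGlyphs:
    def test_distinct_seeds_distinct_bitmaps_same_class(self):
        g1 = synth_glyph(3, seed=1)
        g2 = synth_glyph(3, seed=2)
        assert not np.array_equal(g1, g2)
        assert classify_glyph(g1) == classify_glyph(g2) == 3
        # variation across seeds: nearly all instances are distinct bitmaps
        instances = [synth_glyph(3, seed=s).tobytes() for s in range(10)]
        assert len(set(instances)) >= 8

    def test_zero_amplitude_is_base_template(self):
        from counterstream.cg_tasks import _template_cell

        np.testing.assert_array_equal(synth_glyph(5, seed=9, amplitude=0.0), _template_cell(5))

    def test_template_correlation_self_classification(self):
        rng = np.random.default_rng(0)
        ok = 0
        n = 1000
        for _ in range(n):
            c = int(rng.integers(N_GLYPH_CLASSES))
            ok += classify_glyph(synth_glyph(c, int(rng.integers(1 << 30)))) == c
        assert ok / n >= 0.99

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError):
            synth_glyph(N_GLYPH_CLASSES, seed=0)


class TestChargrid:
    def test_example_count_arithmetic(self, tiny_chargrid_split):
        s = tiny_chargrid_split
        assert len(s.train) == 40 * 5

    def test_no_excluded_pair_in_training_queries(self, tiny_chargrid_split):
        report = validate_split(tiny_chargrid_split)
        assert report["ok"], report["violations"]

    def test_every_cg_example_instantiates_excluded_pair(self, tiny_chargrid_split):
        assert all(ex.contains_excluded for ex in tiny_chargrid_split.test_cg)
        assert not any(ex.contains_excluded for ex in tiny_chargrid_split.test_nc)

    def test_boundary_rule_no_neighbor_queries_at_row_ends(self, tiny_chargrid_split):
        for subset in (tiny_chargrid_split.train, tiny_chargrid_split.test_nc, tiny_chargrid_split.test_cg):
            for ex in subset:
                arr = tiny_chargrid_split.images[ex.image_ref]
                pos = arr.index(ex.i_arg)
                if ex.i_task == "right-of":
                    assert pos < len(arr) - 1
                else:
                    assert pos > 0

    def test_bad_excluded_sequence_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            make_chargrid_dataset(5, n_classes=4, excluded_sequence=[0, 1, 2, 2], seed=0)

    def test_planted_excluded_pair_detected_by_validator(self, tiny_chargrid_split):
        import copy

        s = copy.deepcopy(tiny_chargrid_split)
        bad = s.test_cg[0]
        bad.contains_excluded = False
        s.train.append(bad)
        report = validate_split(s)
        assert not report["ok"]
        assert any(v[0] == "train" for v in report["violations"])

    def test_rendered_image_shape_and_masks(self, tiny_chargrid_split):
        X, y, masks, occ = encode_chargrid(tiny_chargrid_split, tiny_chargrid_split.train[:10])
        img, instr = X[0]
        m = tiny_chargrid_split.params["chars_per_image"]
        assert img.shape == (1, CELL_H, CELL_W * m)
        # target mask marks exactly one glyph cell
        assert masks[0].sum() == CELL_H * CELL_W
        # occurrence marks the chars present
        assert occ[0].sum() == m

    def test_extra_excluded_pairs_enlarge_exclusion_and_stay_sound(self):
        """The exclusion-fraction stress knob grows the excluded set while all
        split invariants keep holding."""
        base = make_chargrid_dataset(n_images=10, n_classes=6, chars_per_image=6,
                                     examples_per_image=3, seed=4, n_test_nc=8, n_test_cg=8)
        bigger = make_chargrid_dataset(n_images=10, n_classes=6, chars_per_image=6,
                                       examples_per_image=3, seed=4, n_test_nc=8, n_test_cg=8,
                                       extra_excluded_pairs=6)
        assert len(bigger.exclusion.pairs) == len(base.exclusion.pairs) + 6
        assert validate_split(bigger)["ok"]

    @given(st.integers(0, 10_000))
    @settings(max_examples=10, deadline=None)
    def test_exclusion_soundness_property(self, seed):
        split = make_chargrid_dataset(n_images=6, n_classes=5, chars_per_image=5,
                                      examples_per_image=3, seed=seed,
                                      n_test_nc=6, n_test_cg=6)
        assert validate_split(split)["ok"]


class TestPersons:
    def test_example_count_arithmetic(self, tiny_persons_split):
        # two persons x five property types per image
        assert len(tiny_persons_split.train) == 40 * 2 * 5

    def test_split_invariants(self, tiny_persons_split):
        report = validate_split(tiny_persons_split)
        assert report["ok"], report["violations"]
        assert all(ex.contains_excluded for ex in tiny_persons_split.test_cg)

    def test_no_training_image_contains_excluded_cooccurrence(self, tiny_persons_split):
        excl = tiny_persons_split.exclusion.pairs
        for ex in tiny_persons_split.train:
            spec = tiny_persons_split.images[ex.image_ref]
            for slot in (0, 1):
                for t, v in spec.properties[slot].items():
                    assert (spec.identities[slot], t, v) not in excl

    def test_empty_exclusion_warns_and_empty_cg(self):
        with pytest.warns(UserWarning, match="empty exclusion"):
            split = make_persons_dataset(n_images=5, n_person_identities=4,
                                         excluded_pairs=[], seed=0, n_test_nc=5, n_test_cg=5)
        assert split.test_cg == []

    def test_exhausting_exclusions_rejected(self):
        bad = [(0, "hat", 0), (0, "hat", 1)]  # hat has cardinality 2
        with pytest.raises(ValueError, match="exhaust"):
            make_persons_dataset(n_images=5, n_person_identities=4,
                                 excluded_pairs=bad, seed=0)

    def test_encoding_masks_select_queried_person(self, tiny_persons_split):
        X, y, masks, occ = encode_persons(tiny_persons_split, tiny_persons_split.train[:10])
        for (img, instr), m, ex in zip(X, masks, tiny_persons_split.train[:10]):
            spec = tiny_persons_split.images[ex.image_ref]
            slot = 0 if spec.identities[0] == ex.i_arg else 1
            w = img.shape[2] // 2
            assert m[:, slot * w:(slot + 1) * w].all()
            assert not m[:, (1 - slot) * w:(2 - slot) * w].any()


class TestPaperScaleCounts:
    """Example-count arithmetic at the published dataset sizes (indices only,
    images rendered lazily so nothing is drawn here)."""

    def test_chargrid24_sufficient(self):
        split = make_chargrid_dataset(n_images=10_000, n_classes=24, chars_per_image=24,
                                      examples_per_image=16, seed=0, n_test_nc=20, n_test_cg=20)
        assert len(split.train) == 160_000

    def test_chargrid6_sufficient(self):
        split = make_chargrid_dataset(n_images=2_500, n_classes=6, chars_per_image=6,
                                      examples_per_image=5, seed=0, n_test_nc=20, n_test_cg=20)
        assert len(split.train) == 12_500

    def test_persons_sufficient(self):
        split = make_persons_dataset(n_images=1_600, n_person_identities=8,
                                     excluded_pairs=6, seed=0, n_test_nc=20, n_test_cg=20)
        assert len(split.train) == 16_000
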