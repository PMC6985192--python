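import numpy as np
import pytest

from lucmap import (
    AmazonClass,
    CerradoClass,
    ClassMap,
    LUC_RULES,
    ReferenceLayers,
    TrajectoryStack,
    apply_basemap_rules,
    apply_luc_rules,
    apply_masks,
    run_postprocessing,
    to_alphabet,
)

V = None  # set in fixture


@pytest.fixture(autouse=True)
def _vocab(vocab):
    global V
    V = vocab


def codes(*labels):
    return [V.code(label) for label in labels]


def single_pixel_stack(*labels):
    arr = np.array(codes(*labels), dtype=np.uint8).reshape(-1, 1, 1)
    return TrajectoryStack(tuple(range(2001, 2001 + len(labels))), arr)


def stack_labels(stack):
    return [V.label(int(c)) for c in stack.codes[:, 0, 0]]


class TestApplyMasks:
    def test_empty_masks_identity(self):
        grid = np.array([[1, 3], [4, 5]], dtype=np.uint8)
        empty = np.zeros((2, 2), dtype=bool)
        out = apply_masks(ClassMap(2001, grid), empty, empty, empty)
        np.testing.assert_array_equal(out.grid, grid)

    def test_water_beats_sugarcane(self):
        grid = np.ones((1, 1), dtype=np.uint8)
        flagged = np.ones((1, 1), dtype=bool)
        empty = np.zeros((1, 1), dtype=bool)
        out = apply_masks(ClassMap(2001, grid), flagged, empty, flagged)
        assert out.grid[0, 0] == V.code("water")

    def test_forest_under_urban_mask(self):
        grid = np.full((1, 1), V.code("forest"), dtype=np.uint8)
        flagged = np.ones((1, 1), dtype=bool)
        empty = np.zeros((1, 1), dtype=bool)
        out = apply_masks(ClassMap(2001, grid), empty, flagged, empty)
        assert out.grid[0, 0] == V.code("urban")

    def test_misaligned_rejected(self):
        grid = np.ones((2, 2), dtype=np.uint8)
        with pytest.raises(ValueError, match="misaligned"):
            apply_masks(
                ClassMap(2001, grid),
                np.zeros((3, 3), bool),
                np.zeros((2, 2), bool),
                np.zeros((2, 2), bool),
            )


class TestBasemapRules:
    def _refs(self, amazon, cerrado):
        return ReferenceLayers(
            np.full((1, 1), amazon, dtype=np.uint8),
            np.full((1, 1), cerrado, dtype=np.uint8),
        )

    @pytest.mark.parametrize(
        "amazon,cerrado,map_label,expected",
        [
            # the five fusion rules, first match wins
            (AmazonClass.FOREST, CerradoClass.ABSENT, "pasture", "forest"),
            (AmazonClass.NON_FOREST, CerradoClass.ABSENT, "forest", "cerrado"),
            (AmazonClass.DEFORESTATION, CerradoClass.ABSENT, "forest",
             "secondary-vegetation"),
            (AmazonClass.ABSENT, CerradoClass.NON_ANTHROPIZED, "forest",
             "cerrado"),
            (AmazonClass.ABSENT, CerradoClass.ANTHROPIZED, "forest",
             "secondary-vegetation"),
            # no rule fires
            (AmazonClass.ABSENT, CerradoClass.ABSENT, "forest", "forest"),
            (AmazonClass.NON_FOREST, CerradoClass.ABSENT, "pasture", "pasture"),
        ],
    )
    def test_fusion_rules(self, amazon, cerrado, map_label, expected):
        base = ClassMap(2001, np.full((1, 1), V.code(map_label), dtype=np.uint8))
        out = apply_basemap_rules(base, self._refs(amazon, cerrado))
        assert V.label(int(out.grid[0, 0])) == expected

    def test_overlapping_reference_layers_rejected(self):
        with pytest.raises(ValueError, match="both reference layers"):
            ReferenceLayers(
                np.full((1, 1), AmazonClass.FOREST, dtype=np.uint8),
                np.full((1, 1), CerradoClass.ANTHROPIZED, dtype=np.uint8),
            )


class TestAlphabet:
    @pytest.mark.parametrize(
        "label,letter",
        [
            ("forest", "F"),
            ("cerrado", "C"),
            ("pasture", "P"),
            ("soy-corn", "S"),
            ("soy-millet", "S"),
            ("soy-fallow", "S"),
            ("fallow-cotton", "O"),  # no soybean cycle
            ("water", "O"),
            ("secondary-vegetation", "O"),
        ],
    )
    def test_letters(self, label, letter):
        assert to_alphabet(V.code(label)) == letter

    def test_unknown_code_raises(self):
        with pytest.raises(Exception):
            to_alphabet(200)


# Each printed trajectory rule, instantiated as an exact trajectory.
WORKED_EXAMPLES = [
    (["cerrado", "forest"], ["cerrado", "cerrado"]),
    (["cerrado", "cerrado", "pasture", "cerrado"],
     ["cerrado", "cerrado", "cerrado", "cerrado"]),
    (["cerrado", "cerrado", "soy-corn", "cerrado"],
     ["cerrado", "cerrado", "cerrado", "cerrado"]),
    (["pasture", "pasture", "cerrado", "cerrado", "pasture"],
     ["pasture", "pasture", "pasture", "pasture", "pasture"]),
    (["forest", "cerrado", "forest", "forest"],
     ["forest", "forest", "forest", "forest"]),
    (["forest", "forest", "cerrado", "forest"],
     ["forest", "forest", "forest", "forest"]),
    (["forest", "cerrado", "forest"], ["forest", "forest", "forest"]),
    (["forest", "cerrado"], ["forest", "forest"]),
    (["forest", "forest", "pasture", "forest"],
     ["forest", "forest", "pasture", "secondary-vegetation"]),
    (["pasture", "pasture", "forest", "pasture"],
     ["pasture", "pasture", "secondary-vegetation", "pasture"]),
]


class TestLucRules:
    @pytest.mark.parametrize("before,after", WORKED_EXAMPLES)
    def test_printed_rules_rewrite_exactly(self, before, after):
        out, _ = apply_luc_rules(single_pixel_stack(*before))
        assert stack_labels(out) == after

    @pytest.mark.parametrize("before,after", WORKED_EXAMPLES)
    def test_second_pass_is_noop(self, before, after):
        once, _ = apply_luc_rules(single_pixel_stack(*before))
        twice, report = apply_luc_rules(once)
        assert stack_labels(twice) == stack_labels(once)

    def test_all_forest_unchanged(self):
        out, report = apply_luc_rules(
            single_pixel_stack(*["forest"] * 6)
        )
        assert stack_labels(out) == ["forest"] * 6
        assert all(v == 0 for v in report.values())

    def test_only_sv_rules_create_secondary_vegetation(self):
        sv = V.code("secondary-vegetation")
        for i, (before, after) in enumerate(WORKED_EXAMPLES):
            out, report = apply_luc_rules(single_pixel_stack(*before))
            has_sv = sv in out.codes
            assert has_sv == (i >= 8)  # rules 9 and 10 only

    def test_unstarred_positions_never_modified(self):
        for before, after in WORKED_EXAMPLES:
            out, _ = apply_luc_rules(single_pixel_stack(*before))
            result = stack_labels(out)
            # positions that kept their letter class are untouched codes
            for b, r in zip(before, result):
                if r == b:
                    continue
                assert r in {"forest", "cerrado", "pasture",
                             "secondary-vegetation"}

    def test_short_trajectory_skips_long_rules(self):
        # 2-year stack: only the 2-long rules can fire
        out, _ = apply_luc_rules(single_pixel_stack("pasture", "pasture"))
        assert stack_labels(out) == ["pasture", "pasture"]

    def test_sliding_window_matches_mid_sequence(self):
        out, _ = apply_luc_rules(
            single_pixel_stack("pasture", "forest", "forest", "pasture",
                               "forest")
        )
        # window at years 2-5 matches the regrowth rule F,F,P,F
        assert stack_labels(out)[-1] == "secondary-vegetation"

    def test_frozen_pixels_untouched(self):
        arr = np.array(codes("cerrado", "forest"), dtype=np.uint8)
        grid = np.tile(arr.reshape(2, 1, 1), (1, 1, 2))
        stack = TrajectoryStack((2001, 2002), grid)
        frozen = np.array([[False, True]])
        out, _ = apply_luc_rules(stack, frozen=frozen)
        assert V.label(int(out.codes[1, 0, 0])) == "cerrado"  # rewritten
        assert V.label(int(out.codes[1, 0, 1])) == "forest"  # frozen

    def test_report_counts_pixels_per_rule(self):
        arr = np.array(codes("cerrado", "forest"), dtype=np.uint8)
        grid = np.tile(arr.reshape(2, 1, 1), (1, 3, 4))
        stack = TrajectoryStack((2001, 2002), grid)
        _, report = apply_luc_rules(stack)
        assert report[1] == 12
        assert sum(report.values()) == 12


class TestRunPostprocessing:
    def _inputs(self, n_years=1, h=2, w=2):
        maps = [
            ClassMap(2001 + i, np.full((h, w), V.code("forest"), dtype=np.uint8))
            for i in range(n_years)
        ]
        masks = {
            name: np.zeros((h, w), dtype=bool)
            for name in ("water", "urban", "sugarcane")
        }
        refs = ReferenceLayers(
            np.zeros((h, w), dtype=np.uint8), np.zeros((h, w), dtype=np.uint8)
        )
        return maps, masks, refs

    def test_single_year_only_basemap_and_masks(self):
        maps, masks, refs = self._inputs(1)
        refs.amazon[:] = AmazonClass.DEFORESTATION
        masks["water"][0, 0] = True
        final, report = run_postprocessing(maps, masks, refs)
        assert len(final) == 1
        assert final[0].grid[0, 0] == V.code("water")
        assert final[0].grid[1, 1] == V.code("secondary-vegetation")
        assert all(v == 0 for v in report.values())

    def test_no_matching_trajectories_identity_plus_masks(self):
        maps, masks, refs = self._inputs(3)
        final, report = run_postprocessing(maps, masks, refs)
        for before, after in zip(maps, final):
            np.testing.assert_array_equal(before.grid, after.grid)
        assert all(v == 0 for v in report.values())

    def test_year_gap_rejected(self):
        maps, masks, refs = self._inputs(2)
        maps[1] = ClassMap(2005, maps[1].grid)
        with pytest.raises(ValueError, match="gap"):
            run_postprocessing(maps, masks, refs)

    def test_regrowth_trajectory_becomes_secondary_vegetation(self):
        maps, masks, refs = self._inputs(4)
        maps[2] = ClassMap(2003, np.full((2, 2), V.code("pasture"), np.uint8))
        final, report = run_postprocessing(maps, masks, refs)
        assert final[3].grid[0, 0] == V.code("secondary-vegetation")
        assert report[9] == 4

    def test_masked_pixels_frozen_and_overwritten(self):
        maps, masks, refs = self._inputs(4)
        maps[2] = ClassMap(2003, np.full((2, 2), V.code("pasture"), np.uint8))
        masks["urban"][0, 1] = True
        final, report = run_postprocessing(maps, masks, refs)
        assert report[9] == 3  # frozen pixel not rewritten
        assert final[3].grid[0, 1] == V.code("urban")
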