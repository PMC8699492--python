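import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semmorph import (
    ValidationError,
    alignment_angle,
    analyze_neuron,
    area_perimeter_circularity,
    circularity_from_area_perimeter,
    classify_alignment,
    count_differentiated,
    extract_neurites,
    identify_soma,
    label_instances,
    neurite_stats,
    radial_and_straightness,
)
from semmorph.neurons import EPSILON_RASTER, NeuriteTrace, NeuronMorphometry
from semmorph.segmentation import BinaryMask
from semmorph.synthetic import gen_neuron

from conftest import disc_mask, single_cell


def _trace(path):
    """Minimal NeuriteTrace stub for stats arithmetic tests."""
    return path


class TestIdentifySoma:
    def test_disc_diameter_recovered(self):
        cell = single_cell(disc_mask(radius=20))
        _, diam, _ = identify_soma(cell, 1.0)
        assert diam == pytest.approx(40.0, abs=2.0)

    def test_rectangle_inscribed_disc_is_short_side(self):
        pix = np.zeros((30, 70), dtype=bool)
        pix[5:25, 5:65] = True  # 20 x 60 rectangle
        cell = single_cell(BinaryMask(pix, 1.0))
        with pytest.warns(UserWarning, match="equal inscribed-disc"):
            _, diam, _ = identify_soma(cell, 1.0)
        assert diam == pytest.approx(20.0, abs=2.0)

    def test_generated_soma_radius(self, three_arm_neuron):
        _, mask, truth = three_arm_neuron
        cell = label_instances(mask)[0]
        _, diam, _ = identify_soma(cell)
        assert diam == pytest.approx(12.0, abs=2 * 0.2)  # ±2 px at 0.2 µm/px


class TestExtractNeurites:
    def test_three_arm_star_recovery(self, three_arm_neuron):
        _, mask, truth = three_arm_neuron
        cell = label_instances(mask)[0]
        _, _, soma_mask = identify_soma(cell)
        traces = extract_neurites(cell, soma_mask)
        assert len(traces) == 3
        true_arms = sorted(
            (r["length_um"], r["chord_angle_deg"])
            for r in truth.records
            if r["kind"] == "neurite"
        )
        got = sorted((t.length_um, t.chord_angle_deg) for t in traces)
        for (tl, ta), (gl, ga) in zip(true_arms, got):
            assert gl == pytest.approx(tl, rel=0.05)
            assert ga == pytest.approx(ta, abs=1.0)

    def test_bare_disc_has_no_neurites(self):
        _, mask, _ = gen_neuron(soma_radius_um=6.0, arms=[])
        cell = label_instances(mask)[0]
        _, _, soma_mask = identify_soma(cell)
        assert extract_neurites(cell, soma_mask) == []

    def test_short_arm_filtered_by_min_length(self):
        _, mask, _ = gen_neuron(arms=[(12.0, 30.0, 0.0)])
        cell = label_instances(mask)[0]
        _, _, soma_mask = identify_soma(cell)
        assert extract_neurites(cell, soma_mask, min_neurite_um=15.0) == []
        assert len(extract_neurites(cell, soma_mask, min_neurite_um=5.0)) == 1

    def test_straight_arm_straightness_near_zero(self, three_arm_neuron):
        _, mask, _ = three_arm_neuron
        cell = label_instances(mask)[0]
        n = analyze_neuron(cell)
        for t in n.neurites:
            assert t.straightness_um <= 0.02 * t.length_um

    def test_tortuous_arm_has_positive_straightness(self):
        _, mask, truth = gen_neuron(arms=[(40.0, 20.0, 2.0)])
        cell = label_instances(mask)[0]
        n = analyze_neuron(cell)
        assert n.neurite_count == 1
        t = n.neurites[0]
        assert t.straightness_um > 0.5
        assert t.tortuosity > 1.01
        rec = [r for r in truth.records if r["kind"] == "neurite"][0]
        assert t.length_um == pytest.approx(rec["length_um"], rel=0.05)


class TestNeuriteStats:
    def test_arithmetic_of_definitions(self):
        traces = [
            NeuriteTrace(i, np.zeros((2, 2)), L, L, 0.0, 0.0, "parallel", 1.0)
            for i, L in enumerate((10.0, 20.0, 30.0))
        ]
        count, avg, mx = neurite_stats(traces)
        assert (count, avg, mx) == (3, 20.0, 30.0)

    def test_single_trace_avg_equals_max(self):
        t = NeuriteTrace(0, np.zeros((2, 2)), 17.0, 17.0, 0.0, 0.0, "parallel", 1.0)
        assert neurite_stats([t]) == (1, 17.0, 17.0)

    def test_empty_is_undefined_not_zero(self):
        count, avg, mx = neurite_stats([])
        assert count == 0 and avg is None and mx is None


class TestRadialAndStraightness:
    def test_straight_two_point_trace(self):
        path = np.array([[0, 0], [3, 4]])
        radial, straight = radial_and_straightness(path, 1.0)
        assert radial == pytest.approx(5.0)
        assert straight == pytest.approx(0.0, abs=1e-9)

    def test_quarter_circle_arc_analytic(self):
        # arc of radius r: length pi*r/2, chord r*sqrt(2),
        # straightness (pi/2 - sqrt(2))*r ~ 0.1566*r
        r = 100.0
        theta = np.linspace(0, math.pi / 2, 400)
        path = np.stack([r * np.sin(theta), r * (1 - np.cos(theta))], axis=1)
        radial, straight = radial_and_straightness(path, 1.0)
        assert radial == pytest.approx(r * math.sqrt(2), rel=0.01)
        assert straight == pytest.approx((math.pi / 2 - math.sqrt(2)) * r, rel=0.05)

    @given(st.integers(0, 1000))
    @settings(max_examples=50, derandomize=True)
    def test_triangle_inequality_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        steps = rng.integers(-1, 2, size=(30, 2))
        path = np.cumsum(np.vstack([[0, 0], steps]), axis=0)
        if (path[-1] == path[0]).all():
            path = np.vstack([path, path[-1] + [1, 0]])
        radial, straight = radial_and_straightness(path, 1.0)
        assert straight >= 0.0


class TestAlignment:
    def test_chord_along_axis(self):
        assert alignment_angle(np.array([[0, 0], [0, 10]])) == pytest.approx(0.0)

    def test_fold_obtuse_to_acute(self):
        # chord at 100° from x-axis folds to 80°
        theta = math.radians(100)
        path = np.array([[0.0, 0.0], [10 * math.sin(theta), 10 * math.cos(theta)]])
        assert alignment_angle(path) == pytest.approx(80.0, abs=1e-9)

    def test_generated_arm_at_37_degrees(self):
        _, mask, _ = gen_neuron(arms=[(30.0, 37.0, 0.0)])
        cell = label_instances(mask)[0]
        n = analyze_neuron(cell)
        assert n.neurites[0].chord_angle_deg == pytest.approx(37.0, abs=1.0)

    def test_reference_axis_shift(self):
        path = np.array([[0.0, 0.0], [0.0, 10.0]])
        assert alignment_angle(path, reference_axis_deg=30.0) == pytest.approx(30.0)

    def test_zero_chord_rejected(self):
        with pytest.raises(ValidationError):
            alignment_angle(np.array([[1, 1], [1, 1]]))

    @pytest.mark.parametrize(
        "angle, cls",
        [
            (10.0, "parallel"),
            (14.999, "parallel"),
            (15.0, "intermediate"),
            (45.0, "intermediate"),
            (75.0, "intermediate"),
            (75.001, "perpendicular"),
            (80.0, "perpendicular"),
            (0.0, "parallel"),
            (90.0, "perpendicular"),
        ],
    )
    def test_classification_boundaries_strict(self, angle, cls):
        assert classify_alignment(angle) == cls

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_alignment(91.0)

    @given(st.floats(0.0, 90.0))
    @settings(max_examples=200, derandomize=True)
    def test_partition_exhaustive_and_exclusive(self, angle):
        assert classify_alignment(angle) in {"parallel", "intermediate", "perpendicular"}


class TestCircularity:
    def test_ideal_disc_is_exactly_one(self):
        for r in (0.5, 1.0, 37.2):
            assert circularity_from_area_perimeter(
                math.pi * r * r, 2 * math.pi * r
            ) == pytest.approx(1.0, abs=1e-15)

    def test_ideal_square_closed_form(self):
        a = 3.0
        assert circularity_from_area_perimeter(a * a, 4 * a) == pytest.approx(math.pi / 4)

    def test_rasterized_disc_calibrates_to_one(self):
        cell = single_cell(disc_mask(radius=200))
        _, _, c = area_perimeter_circularity(cell, 1.0)
        assert 0.95 <= c <= 1.05

    def test_chain_estimator_underestimates_disc(self):
        # the sqrt(2)-weighted contour overestimates smooth perimeters ~5%,
        # pushing disc circularity to ~0.9 — why it is not the default
        cell = single_cell(disc_mask(radius=200))
        _, _, c = area_perimeter_circularity(cell, 1.0, perimeter_method="chain")
        assert 0.85 <= c <= 0.95

    def test_isoperimetric_bound_on_fixtures(self, rod_field, three_arm_neuron):
        for mask in (rod_field[1], three_arm_neuron[1]):
            for cell in label_instances(mask):
                _, _, c = area_perimeter_circularity(cell)
                assert 0 < c <= 1 + EPSILON_RASTER

    def test_rotation_invariance_within_raster_tolerance(self):
        pix = np.zeros((60, 60), dtype=bool)
        pix[20:40, 10:50] = True
        c0 = area_perimeter_circularity(single_cell(BinaryMask(pix, 1.0)))[2]
        c90 = area_perimeter_circularity(single_cell(BinaryMask(pix.T, 1.0)))[2]
        assert c90 == pytest.approx(c0, abs=EPSILON_RASTER)

    def test_scale_invariance(self):
        cell = single_cell(disc_mask(radius=50))
        c1 = area_perimeter_circularity(cell, 1.0)[2]
        c2 = area_perimeter_circularity(cell, 2.5)[2]
        assert c2 == pytest.approx(c1, rel=1e-12)


class TestDifferentiation:
    def _neuron(self, soma_diam, max_len):
        traces = []
        if max_len is not None:
            traces = [NeuriteTrace(0, np.zeros((2, 2)), max_len, max_len, 0.0, 0.0, "parallel", 1.0)]
        return NeuronMorphometry(
            cell_id=0, soma_center=(0, 0), soma_diameter_um=soma_diam, neurites=traces
        )

    def test_neurite_reaching_soma_diameter_counts(self):
        assert count_differentiated([self._neuron(20.0, 25.0)]) == 1
        assert count_differentiated([self._neuron(20.0, 20.0)]) == 1

    def test_short_or_absent_neurites_do_not_count(self):
        assert count_differentiated([self._neuron(20.0, 10.0)]) == 0
        assert count_differentiated([self._neuron(20.0, None)]) == 0

    def test_generated_field_count(self):
        # 10 neurons: 6 constructed with max arm >= soma diameter (12 µm)
        canvas = np.zeros((1000, 1000), dtype=bool)
        long_arm, short_arm = 14.0, 6.0
        for k in range(10):
            arm_len = long_arm if k < 6 else short_arm
            gen_neuron(
                soma_radius_um=6.0,
                arms=[(arm_len, 36.0 * k, 0.0)],
                pixel_size_um=0.2,
                center_px=(130 + 220 * (k // 4), 120 + 230 * (k % 4)),
                _canvas=canvas,
            )
        cells = label_instances(BinaryMask(canvas, 0.2))
        assert len(cells) == 10
        analysed = [analyze_neuron(c) for c in cells]
        assert count_differentiated(analysed) == 6
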