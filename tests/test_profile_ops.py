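import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import layerquant as lq
from layerquant.errors import EditError, NoExpressionError


def make_profile(values, total_length=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    total = total_length if total_length is not None else float(n)
    positions = (np.arange(n) + 0.5) * total / n
    return lq.ExpressionProfile(
        positions=positions,
        mean_r=values.copy(), mean_g=values.copy(), mean_b=values.copy(),
        mean_grey=values.copy(), total_length=total,
    )


class TestInvertImage:
    def test_extremes_and_arbitrary_pixel(self):
        pix = np.zeros((1, 2, 3), dtype=float)
        pix[0, 0] = [255, 255, 255]
        pix[0, 1] = [10, 20, 30]
        inv = lq.invert_image(lq.RGBImage(pixels=pix))
        assert np.array_equal(inv.pixels[0, 0], [0, 0, 0])
        assert np.array_equal(inv.pixels[0, 1], [245, 235, 225])

    def test_double_inversion_is_identity(self, bump_phantom):
        image, _ = bump_phantom
        twice = lq.invert_image(lq.invert_image(image))
        assert np.array_equal(twice.pixels, image.pixels)


class TestRepairInterval:
    def test_constant_replacement(self, flat_profile):
        out = lq.repair_interval(flat_profile, (5, 9), method="constant", constant_value=0.3)
        assert np.allclose(out.mean_grey[5:9], 0.3)
        assert np.allclose(out.mean_grey[:5], flat_profile.mean_grey[:5])

    def test_linear_interpolation_between_flanks(self):
        values = np.array([0.0, 0.0, 0.0, 9.9, 9.9, 9.9, 9.9, 10.0, 10.0, 10.0])
        values[2], values[7] = 0.0, 10.0
        profile = make_profile(values)
        out = lq.repair_interval(profile, (3, 7), method="linear")
        # flanks at positions 2.5 (value 0) and 7.5 (value 10): four interior
        # points equally spaced -> 2, 4, 6, 8
        assert np.allclose(out.mean_grey[3:7], [2.0, 4.0, 6.0, 8.0])

    def test_pchip_preserves_monotone_context(self):
        values = np.concatenate([np.linspace(0, 1, 6), [5.0, -3.0, 2.0], np.linspace(2, 3, 6)])
        profile = make_profile(values)
        out = lq.repair_interval(profile, (6, 9), method="pchip")
        region = out.mean_grey[4:11]
        assert np.all(np.diff(region) >= -1e-12)

    def test_interval_touching_ends_rejected(self, flat_profile):
        with pytest.raises(EditError):
            lq.repair_interval(flat_profile, (0, 3), method="linear")
        with pytest.raises(EditError):
            lq.repair_interval(flat_profile, (17, 20), method="cubic_spline")

    def test_constant_without_value_rejected(self, flat_profile):
        with pytest.raises(EditError):
            lq.repair_interval(flat_profile, (5, 8), method="constant")


class TestMovingAverage:
    def test_span_one_is_identity(self, flat_profile):
        out = lq.moving_average(flat_profile, 1)
        assert np.array_equal(out.mean_grey, flat_profile.mean_grey)

    def test_constant_profile_unchanged(self):
        profile = make_profile(np.full(12, 0.4))
        out = lq.moving_average(profile, 5)
        assert np.allclose(out.mean_grey, 0.4)

    def test_circular_window_arithmetic(self):
        profile = make_profile([1.0, 2.0, 3.0, 4.0, 5.0])
        out = lq.moving_average(profile, 3)
        assert np.allclose(out.mean_grey, [8 / 3, 2.0, 3.0, 4.0, 10 / 3])

    def test_even_span_rejected(self, flat_profile):
        with pytest.raises(EditError):
            lq.moving_average(flat_profile, 4)

    @given(
        values=arrays(float, st.integers(5, 40),
                      elements=st.floats(0, 1, allow_nan=False, width=32)),
        span=st.sampled_from([1, 3, 5, 7]),
    )
    def test_circular_mean_preserved(self, values, span):
        profile = make_profile(values)
        out = lq.moving_average(profile, min(span, len(values) | 1))
        assert out.mean_grey.mean() == pytest.approx(values.mean(), abs=1e-12)


class TestSubtractBaseline:
    def test_clamped_subtraction_examples(self):
        out = lq.subtract_baseline(make_profile([0.05, 0.10, 0.05, 0.2]), 0.05)
        assert np.allclose(out.mean_grey, [0.0, 0.05, 0.0, 0.15])
        out2 = lq.subtract_baseline(make_profile([0.03, 0.10, 0.1, 0.1]), 0.05)
        assert np.allclose(out2.mean_grey, [0.0, 0.05, 0.05, 0.05])

    def test_zero_baseline_is_identity(self, flat_profile):
        out = lq.subtract_baseline(flat_profile, 0.0)
        assert np.array_equal(out.mean_grey, flat_profile.mean_grey)


class TestZeroRegions:
    def test_empty_list_is_identity(self, flat_profile):
        out = lq.zero_regions(flat_profile, [])
        assert np.array_equal(out.mean_grey, flat_profile.mean_grey)

    def test_full_range_zeroes_everything(self, flat_profile):
        out = lq.zero_regions(flat_profile, [(0, len(flat_profile))])
        assert np.all(out.mean_grey == 0)

    def test_idempotence_with_overlaps(self, flat_profile):
        ivs = [(2, 8), (5, 12)]
        once = lq.zero_regions(flat_profile, ivs)
        twice = lq.zero_regions(once, ivs)
        assert np.array_equal(once.mean_grey, twice.mean_grey)
        assert np.all(once.mean_grey[2:12] == 0)
        assert np.array_equal(once.mean_grey[12:], flat_profile.mean_grey[12:])


class TestSymmetrize:
    def test_mirror_symmetric_profile_is_fixed_point(self):
        n = 24
        pos_frac = (np.arange(n) + 0.5) / n
        values = np.cos(2 * np.pi * pos_frac) + 2.0  # even about the anchor
        profile = make_profile(values, total_length=240.0)
        out = lq.symmetrize(profile)
        assert np.abs(out.mean_grey - values).max() < 1e-12

    def test_mirror_pairs_average(self):
        # values 1 and 3 at mirrored positions +/- d from the anchor
        values = np.zeros(8)
        values[0], values[7] = 1.0, 3.0  # positions 0.5 and 7.5 on loop of 8
        profile = make_profile(values)
        out = lq.symmetrize(profile)
        assert out.mean_grey[0] == pytest.approx(2.0)
        assert out.mean_grey[7] == pytest.approx(2.0)

    def test_idempotence(self, flat_profile):
        once = lq.symmetrize(flat_profile)
        twice = lq.symmetrize(once)
        assert np.abs(once.mean_grey - twice.mean_grey).max() < 1e-12

    def test_editing_preserves_positions(self, flat_profile):
        for op in (
            lambda p: lq.symmetrize(p),
            lambda p: lq.moving_average(p, 3),
            lambda p: lq.subtract_baseline(p, 0.1),
            lambda p: lq.zero_regions(p, [(1, 4)]),
            lambda p: lq.repair_interval(p, (8, 11), method="linear"),
        ):
            out = op(flat_profile)
            assert np.array_equal(out.positions, flat_profile.positions)
            assert out.total_length == flat_profile.total_length


class TestStandardize:
    def test_max_is_100_and_endpoints_agree(self, ring_geometry, bump_phantom):
        image, _ = bump_phantom
        dec = lq.decompose_cell_layer(ring_geometry, 2 * np.pi * 100 / 100)
        profile = lq.measure_segments(image, dec)
        std = lq.standardize(profile)
        assert std.values.max() == pytest.approx(100.0)
        assert std.values[0] == pytest.approx(std.values[-1])
        assert len(std) == 101
        assert std.grid[0] == -50 and std.grid[-1] == 50

    def test_landmark_mapping(self):
        # spike exactly at the endoderm arc-center must land on grid 0;
        # the aboral anchor value must appear at both -50 and +50
        n, L = 100, 400.0
        b1, b2 = 120.0, 280.0
        positions = (np.arange(n) + 0.5) * L / n
        values = np.zeros(n)
        center_idx = int(np.argmin(np.abs(positions - 0.5 * (b1 + b2))))
        values[center_idx] = 1.0
        profile = lq.ExpressionProfile(
            positions=positions, mean_r=values, mean_g=values, mean_b=values,
            mean_grey=values, total_length=L, boundary_positions=(b1, b2),
        )
        std = lq.standardize(profile)
        assert std.grid[np.argmax(std.values)] == pytest.approx(0.0, abs=1.0)
        # -50 and +50 are the same physical aboral point
        assert std.values[0] == pytest.approx(std.values[-1])

    def test_boundary_pin_positions(self):
        # spikes at the two boundary arc positions land at -pin and +pin
        n, L = 200, 400.0
        b1, b2 = 100.0, 300.0
        positions = (np.arange(n) + 0.5) * L / n
        for b, pin_sign in ((b1, -1), (b2, +1)):
            values = np.zeros(n)
            values[int(np.argmin(np.abs(positions - b)))] = 1.0
            profile = lq.ExpressionProfile(
                positions=positions, mean_r=values, mean_g=values, mean_b=values,
                mean_grey=values, total_length=L, boundary_positions=(b1, b2),
            )
            std = lq.standardize(profile, pin=25.0)
            assert std.grid[np.argmax(std.values)] == pytest.approx(25.0 * pin_sign, abs=1.0)

    def test_constant_positive_profile_maps_to_all_100(self):
        profile = make_profile(np.full(30, 0.2))
        std = lq.standardize(profile, boundary_positions=(8.0, 22.0))
        assert np.allclose(std.values, 100.0)

    def test_blastula_mapping_without_boundaries(self):
        profile = make_profile(np.linspace(0.1, 0.5, 40))
        std = lq.standardize(profile)  # no boundary positions anywhere
        assert std.values.max() == pytest.approx(100.0)
        assert std.values[0] == pytest.approx(std.values[-1])

    def test_all_zero_profile_raises_unless_allowed(self):
        profile = make_profile(np.zeros(10))
        with pytest.raises(NoExpressionError):
            lq.standardize(profile)
        std = lq.standardize(profile, allow_zero=True)
        assert np.all(std.values == 0)


class TestEditChain:
    def test_artefact_chain_recovers_painted_profile(self, ring_geometry):
        # phantom with annotation glyphs, lighting gradient and noise; the
        # full editor chain must still recover the painted expression
        annotations = [
            {"shape": "rect", "row": 118, "col": 30, "w": 14, "h": 8, "value": 0.1},
            {"shape": "disc", "row": 40, "col": 128, "r": 5, "value": 0.15},
        ]
        image, truth = lq.render_profile_image(
            ring_geometry, lq.gaussian_bump(0.25, 0.06), 256, 256,
            background_level=0.95, lighting_gradient=0.06,
            annotations=annotations, noise_sd=0.01, seed=17,
        )
        dec = lq.decompose_cell_layer(ring_geometry, 2 * np.pi * 100 / 100)
        profile = lq.measure_segments(image, dec)
        # locate artefact segments from the annotation positions
        dirty = []
        for ann in annotations:
            p = np.array([ann["col"], ann["row"]], dtype=float)
            centers = np.stack([[s.center.x, s.center.y] for s in dec.segments])
            k = int(np.argmin(np.linalg.norm(centers - p, axis=1)))
            dirty.append((max(k - 3, 4), min(k + 4, len(dec) - 4)))
        edited = profile
        for iv in dirty:
            edited = lq.repair_interval(edited, iv, method="pchip")
        edited = lq.moving_average(edited, 5)
        edited = lq.subtract_baseline(edited, float(np.percentile(edited.mean_grey, 10)))
        edited = lq.symmetrize(edited)
        g = truth.truth_at(edited.positions)
        g_sym = 0.5 * (g + truth.truth_at(edited.total_length - edited.positions))
        r = np.corrcoef(edited.mean_grey, g_sym)[0, 1]
        assert r >= 0.95

    def test_edit_script_round_trip(self, tmp_path, flat_profile):
        import yaml

        script = {
            "ops": [
                {"op": "repair", "interval": [8, 11], "method": "linear"},
                {"op": "moving_average", "span": 3},
                {"op": "subtract_baseline", "baseline": 0.05},
                {"op": "zero", "intervals": [[0, 2]]},
                {"op": "symmetrize"},
                {"op": "standardize", "boundary_positions": [60.0, 140.0]},
            ]
        }
        path = tmp_path / "edits.yaml"
        path.write_text(yaml.safe_dump(script))
        from layerquant.io import load_edit_script

        out = lq.apply_edit_script(flat_profile, load_edit_script(path))
        assert isinstance(out, lq.StandardProfile)
        assert out.values.max() == pytest.approx(100.0)
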