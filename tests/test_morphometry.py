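"""Segmentation, tracking, shape features, gating and colocalization."""

import math

import numpy as np
import pandas as pd
import pytest
from skimage import draw

from cytomech.morphometry import (
    GateConfig,
    LabeledMask,
    circularity,
    gate_single_cells,
    normalized_intensity,
    nuclear_similarity,
    radius_and_volume,
    segment_cells,
    shape_metrics,
    track_cells,
)
from cytomech.synthetic import make_channel_pair, make_shape_masks, render_frame_sequence


def disk_mask(r_px, pad=10):
    size = 2 * (r_px + pad)
    m = np.zeros((size, size), bool)
    rr, cc = draw.disk((size // 2, size // 2), r_px)
    m[rr, cc] = True
    return m


def render_field(radii_um, seed=0, **kw):
    stack, truth = render_frame_sequence(np.atleast_2d(radii_um), seed=seed, **kw)
    return stack, truth


class TestSegmentation:
    def test_single_disk_area(self):
        stack, _ = render_field([4.0])  # 20 px radius at 0.2 μm/px
        lm = segment_cells(stack[0])
        assert lm.n_objects == 1
        area = (lm.labels == 1).sum()
        assert area == pytest.approx(math.pi * 20**2, rel=0.02)

    def test_blank_frame_empty_mask(self, rng):
        frame = rng.normal(100.0, 5.0, (256, 256))
        lm = segment_cells(frame)
        assert lm.n_objects == 0

    def test_two_disks_centroids(self):
        stack, truth = render_field([4.0, 6.0])
        lm = segment_cells(stack[0])
        assert lm.n_objects == 2
        metrics = shape_metrics(lm)
        found = np.sort(metrics[["centroid_y_um", "centroid_x_um"]].to_numpy() / 0.2, axis=0)
        expected = np.sort(truth[["centroid_y_px", "centroid_x_px"]].to_numpy(), axis=0)
        np.testing.assert_allclose(found, expected, atol=1.0)

    @pytest.mark.parametrize("r_px", [10, 20, 40, 60])
    def test_radius_bias_below_half_pixel(self, r_px):
        stack, _ = render_field([r_px * 0.2], seed=3)
        lm = segment_cells(stack[0])
        df = radius_and_volume(lm)
        assert abs(df.radius_um.iloc[0] / 0.2 - r_px) < 0.5


class TestRadiusVolume:
    def test_exact_disk_formulas(self):
        lm = LabeledMask(disk_mask(20).astype(int), pixel_size=0.2)
        df = radius_and_volume(lm)
        a = df.radius_um.iloc[0]
        assert a == pytest.approx(4.0, abs=0.05)
        assert df.volume_m3.iloc[0] == pytest.approx(4 / 3 * math.pi * (a * 1e-6) ** 3, rel=1e-9)

    def test_population_mean_recovery(self, rng):
        radii = np.clip(rng.normal(9.1, 1.3, 200), 1.0, None)
        stack, _ = render_field(radii, seed=11)
        lm = segment_cells(stack[0])
        df = radius_and_volume(lm)
        assert len(df) == 200
        assert df.radius_um.mean() == pytest.approx(radii.mean(), abs=0.2)


class TestCircularity:
    def test_disk_is_maximal(self):
        assert circularity(disk_mask(20)) >= 0.98

    def test_square_analytic_value(self):
        m = np.zeros((100, 100), bool)
        m[10:90, 10:90] = True
        assert circularity(m) == pytest.approx(math.pi / 4, rel=0.03)

    def test_protrusions_lower_circularity(self):
        masks_smooth, _ = make_shape_masks(1, amplitude=0.0, seed=0)
        masks_star, _ = make_shape_masks(1, amplitude=0.3, lobes=5, seed=0)
        assert circularity(masks_star[0]) < circularity(masks_smooth[0]) - 0.1

    def test_rotation_and_translation_invariance(self):
        m = np.zeros((120, 120), bool)
        m[30:70, 40:90] = True  # rectangle
        c0 = circularity(m)
        assert circularity(np.rot90(m)) == pytest.approx(c0, rel=1e-6)
        assert circularity(np.roll(m, 13, axis=1)) == pytest.approx(c0, rel=1e-6)

    def test_scale_invariance(self):
        assert circularity(disk_mask(20)) == pytest.approx(
            circularity(disk_mask(60)), abs=0.01
        )

    def test_tiny_object_rejected(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        with pytest.raises(ValueError):
            circularity(m)


class TestTracking:
    def masks_from_stack(self, stack):
        return [segment_cells(f, frame_index=i) for i, f in enumerate(stack)]

    def test_static_disks_full_tracks(self):
        stack, _ = render_field(np.tile([4.0, 6.0], (10, 1)))
        tracks = track_cells(self.masks_from_stack(stack))
        lengths = tracks.groupby("track_id").size()
        assert sorted(lengths) == [10, 10]

    def test_shrinking_disk_single_track(self):
        radii = np.linspace(6.0, 4.5, 8).reshape(-1, 1)
        stack, _ = render_field(radii)
        tracks = track_cells(self.masks_from_stack(stack))
        assert tracks.track_id.nunique() == 1
        assert len(tracks) == 8

    def test_disappearing_object_terminates_track(self):
        stack, _ = render_field(np.tile([5.0], (6, 1)))
        stack[4:] = stack[4:] * 0 + stack[0].min()  # object vanishes at frame 4
        tracks = track_cells(self.masks_from_stack(stack))
        assert tracks.frame.max() == 3
        assert tracks.groupby("track_id").size().iloc[0] == 4


class TestGating:
    def synthetic_table(self, n_cells=100, n_frag=20, n_doublet=5):
        rows = []
        rng = np.random.default_rng(5)
        for i in range(n_cells):
            rows.append({"label": i, "area_um2": rng.uniform(200, 400),
                         "aspect_ratio": rng.uniform(1.0, 1.3), "kind": "cell"})
        for i in range(n_frag):
            rows.append({"label": 1000 + i, "area_um2": rng.uniform(1, 40),
                         "aspect_ratio": rng.uniform(1.0, 3.0), "kind": "fragment"})
        for i in range(n_doublet):
            rows.append({"label": 2000 + i, "area_um2": rng.uniform(800, 1200),
                         "aspect_ratio": rng.uniform(1.2, 1.8), "kind": "doublet"})
        return pd.DataFrame(rows)

    def test_gates_recover_planted_single_cells(self):
        table = self.synthetic_table()
        kept, removed = gate_single_cells(table)
        assert len(kept) == 100
        assert set(kept.kind) == {"cell"}
        assert removed["fragment"] == 20 and removed["cluster"] == 5

    def test_gating_is_idempotent(self):
        table = self.synthetic_table()
        once, _ = gate_single_cells(table)
        twice, removed = gate_single_cells(once)
        assert twice.equals(once)
        assert sum(removed.values()) == 0

    def test_bad_gate_config_rejected(self):
        with pytest.raises(ValueError):
            GateConfig(min_area=500, max_area=100)


class TestIntensity:
    def test_control_self_normalization(self, rng):
        img = rng.uniform(50, 150, (64, 64))
        labels = np.zeros((64, 64), int)
        labels[10:30, 10:30] = 1
        labels[40:60, 40:60] = 2
        lm = LabeledMask(labels)
        raw = normalized_intensity(img, lm)
        ctrl = raw.intensity_per_um2.mean()
        norm = normalized_intensity(img, lm, control_mean=ctrl)
        assert norm.control_normalized.mean() == pytest.approx(1.0, rel=1e-9)

    def test_size_invariance_on_uniform_image(self):
        img = np.full((64, 64), 7.0)
        labels = np.zeros((64, 64), int)
        labels[5:15, 5:15] = 1      # small
        labels[30:60, 30:60] = 2    # large
        df = normalized_intensity(img, LabeledMask(labels))
        assert df.intensity_per_um2.iloc[0] == pytest.approx(df.intensity_per_um2.iloc[1], rel=1e-9)

    def test_dimmer_population_scales(self, rng):
        img = rng.uniform(50, 150, (64, 64))
        labels = np.zeros((64, 64), int)
        labels[10:40, 10:40] = 1
        lm = LabeledMask(labels)
        base = normalized_intensity(img, lm).intensity_per_um2.iloc[0]
        dim = normalized_intensity(img * 0.8, lm, control_mean=base)
        assert dim.control_normalized.iloc[0] == pytest.approx(0.8, rel=1e-9)

    def test_zero_control_rejected(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        labels = np.ones((16, 16), int)
        with pytest.raises(ValueError):
            normalized_intensity(img, LabeledMask(labels), control_mean=0.0)


class TestSimilarity:
    def test_identical_channels_maximal(self, rng):
        a = rng.uniform(0, 255, (64, 64))
        mask = np.ones((64, 64), bool)
        score, valid = nuclear_similarity(a, a, mask)
        assert valid
        assert score > 15  # clipped ρ → very large positive score

    def test_independent_channels_near_zero(self):
        a, b, mask = make_channel_pair(0.0, shape=(64, 64), seed=2)
        score, valid = nuclear_similarity(a, b, mask)
        assert valid
        assert abs(score) < 0.1

    def test_inverted_channel_negative(self, rng):
        a = rng.uniform(0, 255, (64, 64))
        score, valid = nuclear_similarity(a, -a, np.ones((64, 64), bool))
        assert valid
        assert score < -15

    def test_symmetry(self):
        a, b, mask = make_channel_pair(0.5, shape=(64, 64), seed=3)
        s_ab, _ = nuclear_similarity(a, b, mask)
        s_ba, _ = nuclear_similarity(b, a, mask)
        assert s_ab == pytest.approx(s_ba, rel=1e-12)

    def test_constant_channel_flagged(self):
        a = np.full((32, 32), 5.0)
        b = np.arange(32 * 32, dtype=float).reshape(32, 32)
        score, valid = nuclear_similarity(a, b, np.ones((32, 32), bool))
        assert not valid
        assert math.isnan(score)
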