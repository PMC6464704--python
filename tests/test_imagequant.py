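"""Fixed-threshold particle analysis and percent-area quantification."""

import numpy as np
import pytest

from synaptodev import (
    AL_PRESET,
    LYSOSOME_PRESET,
    ChannelImage,
    LineROI,
    SomaSimParams,
    ThresholdSpec,
    find_particles,
    gen_soma_image,
    line_scan,
    percent_area_column,
    quantify_soma,
    threshold_mask,
)
from synaptodev.exceptions import ConfigError, DegenerateInputError
from synaptodev.imagequant import particle_perimeter


def brute_force_components(mask: np.ndarray) -> list[frozenset]:
    """Independent 8-connected labeling by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                stack, comp = [(sy, sx)], set()
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                comps.append(frozenset(comp))
    return comps


class TestThresholdMask:
    def test_all_below_cutoff_gives_empty_mask(self):
        img = ChannelImage(np.full((10, 10), 3.0), channel="al")
        spec = ThresholdSpec(cutoffs={"al": 10.0})
        assert threshold_mask(img, spec).sum() == 0

    def test_zero_cutoff_gives_full_mask(self):
        img = ChannelImage(np.random.default_rng(0).random((10, 10)), channel="al")
        assert threshold_mask(img, ThresholdSpec(cutoffs={"al": 0.0})).all()

    def test_mask_sum_equals_brute_force_count(self):
        rng = np.random.default_rng(1)
        px = rng.random((32, 32)) * 100
        cutoff = 60.0
        mask = threshold_mask(ChannelImage(px, channel="al"), ThresholdSpec({"al": cutoff}))
        assert mask.sum() == sum(1 for v in px.ravel() if v >= cutoff)

    def test_missing_channel_cutoff_is_config_error(self):
        img = ChannelImage(np.zeros((5, 5)), channel="al")
        with pytest.raises(ConfigError):
            threshold_mask(img, ThresholdSpec(cutoffs={"soma": 1.0}))


class TestFindParticles:
    def test_empty_mask(self):
        assert find_particles(np.zeros((10, 10), bool)) == []

    def test_labels_match_brute_force_flood_fill(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            mask = rng.random((64, 64)) < 0.3
            found = {frozenset(map(tuple, p.coords)) for p in find_particles(mask)}
            # drop circularity/size filtering: defaults keep everything
            assert found == set(brute_force_components(mask))

    def test_al_preset_size_rule(self):
        """More than eight adjacent pixels: an 8-px component is rejected, a
        9-px one (compact, circularity passing) retained."""
        nine = np.zeros((20, 20), bool)
        nine[2:5, 2:5] = True
        eight = nine.copy()
        eight[2, 2] = False
        assert len(find_particles(nine, **AL_PRESET)) == 1
        assert len(find_particles(eight, **AL_PRESET)) == 0

    def test_disc_is_circular_thin_line_is_not(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disc = (xx - 20) ** 2 + (yy - 20) ** 2 <= 100  # r = 10
        [p] = find_particles(disc)
        assert 0.85 <= p.circularity <= 1.0
        line = np.zeros((40, 40), bool)
        line[5, 5:35] = True  # 30-px 1-px-wide line
        [q] = find_particles(line)
        assert q.circularity < 0.4
        assert find_particles(line, **AL_PRESET) == []

    def test_circularity_converges_for_finer_discs(self):
        circs = []
        for r in (5, 10, 20, 40):
            yy, xx = np.mgrid[0 : 2 * r + 10, 0 : 2 * r + 10]
            disc = (xx - r - 5) ** 2 + (yy - r - 5) ** 2 <= r * r
            circs.append(find_particles(disc)[0].circularity)
        assert circs == sorted(circs)
        assert circs[-1] > 0.95

    def test_brute_force_perimeter_bounds(self):
        # boundary length of a 10x10 square block must sit near 4*10
        sq = np.zeros((20, 20), bool)
        sq[5:15, 5:15] = True
        assert particle_perimeter(sq) == pytest.approx(40.0, rel=0.15)


class TestQuantifySoma:
    SPEC = ThresholdSpec(cutoffs={"soma": 50.0, "nucleus": 100.0, "al": 100.0, "lysosome": 150.0})

    def test_no_al_particles(self):
        channels, _ = gen_soma_image(SomaSimParams(n_al=0, n_lysosomes=3, seed=0))
        q = quantify_soma(channels, self.SPEC)
        assert q.pct_al_area == 0.0
        assert q.n_al == 0
        assert not q.al_positive

    def test_recovers_truth_within_half_point(self):
        p = SomaSimParams(n_al=6, al_radius_range=(4.0, 7.0), al_irregularity=0.25, seed=21)
        channels, truth = gen_soma_image(p)
        q = quantify_soma(channels, self.SPEC)
        assert q.n_al == len(truth.latent["al_particles"])
        assert q.pct_al_area == pytest.approx(truth.latent["true_pct_al_area"], abs=0.5)
        assert q.al_positive

    def test_nucleus_covering_soma_is_degenerate(self):
        size = 64
        full = np.full((size, size), 200.0)
        channels = {"soma": full, "nucleus": full}
        with pytest.raises(DegenerateInputError):
            quantify_soma(channels, self.SPEC)


class TestPercentAreaColumn:
    SPEC = ThresholdSpec(cutoffs={"al": 100.0})

    def test_blank_images_are_zero(self):
        imgs = [ChannelImage(np.zeros((50, 50)), "al") for _ in range(3)]
        q = percent_area_column(imgs, self.SPEC)
        assert q.mean_pct == 0.0

    def test_constructed_five_percent(self):
        px = np.zeros((100, 100))
        px[:5, :] = 200.0  # 500 of 10000 pixels
        q = percent_area_column([ChannelImage(px, "al")], self.SPEC)
        assert q.mean_pct == pytest.approx(5.0)

    def test_mean_across_images(self):
        a = np.zeros((100, 100)); a[:2, :] = 200.0  # 2%
        b = np.zeros((100, 100)); b[:4, :] = 200.0  # 4%
        q = percent_area_column([ChannelImage(a, "al"), ChannelImage(b, "al")], self.SPEC)
        assert q.mean_pct == pytest.approx(3.0)

    def test_raising_cutoff_never_increases_area(self):
        rng = np.random.default_rng(3)
        imgs = [ChannelImage(rng.random((64, 64)) * 255, "al") for _ in range(4)]
        pcts = [
            percent_area_column(imgs, ThresholdSpec({"al": c})).mean_pct
            for c in (50.0, 100.0, 150.0, 200.0)
        ]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_layer_rois(self):
        px = np.zeros((100, 100))
        px[:50, :] = 200.0  # top half
        q = percent_area_column(
            [ChannelImage(px, "al")],
            self.SPEC,
            layer_rois={"upper": (0, 0, 50, 100), "lower": (50, 0, 100, 100)},
        )
        assert q.per_layer_pct["upper"] == pytest.approx(100.0)
        assert q.per_layer_pct["lower"] == pytest.approx(0.0)

    def test_overlapping_layer_rois_warn(self):
        px = np.zeros((100, 100))
        with pytest.warns(UserWarning, match="overlap"):
            percent_area_column(
                [ChannelImage(px, "al")],
                self.SPEC,
                layer_rois={"a": (0, 0, 60, 100), "b": (40, 0, 100, 100)},
            )


class TestLineScan:
    def test_uniform_channel_constant_profile(self):
        channels = {"al": np.full((30, 30), 9.0), "lysosome": np.full((30, 30), 4.0)}
        roi = LineROI([(2.0, 10.0), (27.0, 10.0)], width_px=1)
        df = line_scan(channels, roi)
        assert (df["al"] == 9.0).all()
        assert (df["lysosome"] == 4.0).all()
        assert len(df["al"]) == len(df["lysosome"])

    def test_gradient_profile_matches_direct_indexing(self):
        px = np.tile(np.arange(40.0), (20, 1))
        roi = LineROI([(0.0, 10.0), (39.0, 10.0)], width_px=1)
        df = line_scan({"grad": px}, roi)
        np.testing.assert_allclose(df["grad"].to_numpy(), np.arange(40.0))
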