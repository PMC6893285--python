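import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from optonotch import spotcall, synthgen
from optonotch.stack import CalibratedStack
from optonotch.spotcall import SpotCallConfig

from conftest import truth_spot_table


# ---------------------------------------------------------------------------
# brute-force oracle for the zero-crossing segmentation
# ---------------------------------------------------------------------------

def _laplacian_brute(img: np.ndarray) -> np.ndarray:
    """Pixel-wise 5-point Laplacian with symmetric (reflect) boundaries."""
    h, w = img.shape
    out = np.empty_like(img, dtype=float)

    def at(i, j):
        i = -i - 1 if i < 0 else (2 * h - i - 1 if i >= h else i)
        j = -j - 1 if j < 0 else (2 * w - j - 1 if j >= w else j)
        return img[i, j]

    for i in range(h):
        for j in range(w):
            out[i, j] = (
                at(i - 1, j) + at(i + 1, j) + at(i, j - 1) + at(i, j + 1)
                - 4.0 * at(i, j)
            )
    return out


def _label_brute(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Flood-fill connected-component labelling."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                labels[i, j] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and labels[yy, xx] == 0:
                            labels[yy, xx] = nxt
                            stack.append((yy, xx))
    return labels


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel components in first-occurrence order for comparison."""
    out = np.zeros_like(labels)
    mapping = {}
    flat = labels.ravel()
    oflat = out.ravel()
    for i, v in enumerate(flat):
        if v:
            if v not in mapping:
                mapping[v] = len(mapping) + 1
            oflat[i] = mapping[v]
    return out


@pytest.mark.parametrize("connectivity", [4, 8])
def test_zero_crossing_segmentation_matches_brute_force(connectivity):
    """The production segmentation equals a pixel-wise sign-change evaluation."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        h, w = rng.integers(16, 65, 2)
        # smooth random field: a few Gaussian bumps of either sign
        yy, xx = np.mgrid[0:h, 0:w]
        img = np.zeros((h, w))
        for _ in range(rng.integers(2, 6)):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            s = rng.uniform(2, 6)
            img += rng.uniform(-100, 100) * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)
            )
        got = spotcall.segment_zero_crossings(img, connectivity)
        expected = _label_brute(_laplacian_brute(img) < 0, connectivity)
        np.testing.assert_array_equal(_canonical(got), _canonical(expected))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _flat_stack(value, shape=(128, 128)):
    return CalibratedStack(np.full((1, 1) + shape, float(value)), pixel_size_um=0.13)


def test_all_zero_frame_yields_empty_spotset():
    spots = spotcall.detect_spots(_flat_stack(0.0), SpotCallConfig())
    assert spots.n_spots == 0
    assert spots.counts_per_frame().tolist() == [0]


def test_single_gaussian_spot_detected_at_ground_truth():
    """One noise-free spot: one detection, centroid within 0.5 px."""
    yy, xx = np.mgrid[0:128, 0:128]
    x0, y0 = 61.0, 70.0
    img = 100.0 + 1000.0 * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * 9.0))
    stack = CalibratedStack(img, pixel_size_um=0.13)
    spots = spotcall.detect_spots(stack, SpotCallConfig(min_intensity=1000))
    assert spots.n_spots == 1
    row = spots.table.iloc[0]
    assert abs(row.x_px - x0) < 0.5
    assert abs(row.y_px - y0) < 0.5


def test_grid_of_separated_spots_all_recovered():
    """25 well-separated noise-free spots, one-to-one within 1 px."""
    yy, xx = np.mgrid[0:144, 0:144]
    img = np.full((144, 144), 50.0)
    centers = [(24.0 + 24 * i, 24.0 + 24 * j) for i in range(5) for j in range(5)]
    for cx, cy in centers:
        img += 800.0 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 9.0))
    stack = CalibratedStack(img, pixel_size_um=0.13)
    spots = spotcall.detect_spots(stack, SpotCallConfig(min_intensity=1000))
    assert spots.n_spots == 25
    truth = pd.DataFrame(
        [{"frame": 0, "x_px": cx, "y_px": cy} for cx, cy in centers]
    )
    m = spotcall.match_spots(spots.table, truth, tol_px=1.0)
    assert m["true_positives"] == 25


def test_detection_performance_on_noisy_movie(small_spot_movie):
    """Precision and recall >= 0.95 at SNR 5 and >= 6 sigma separation."""
    params, _, _ = small_spot_movie
    import dataclasses
    p = dataclasses.replace(params, noise_model="gaussian", noise_scale=100.0, seed=21)
    stack, truth = synthgen.gen_spot_movie(p)
    spots = spotcall.detect_spots(stack, SpotCallConfig(min_intensity=12000))
    m = spotcall.match_spots(spots.table, truth_spot_table(truth), tol_px=3.0)
    assert m["precision"] >= 0.95
    assert m["recall"] >= 0.95


def test_frame_smaller_than_filter_window_errors_with_stage_name():
    small = CalibratedStack(np.ones((1, 1, 64, 64)), pixel_size_um=0.13)
    with pytest.raises(ValueError, match="background mean"):
        spotcall.detect_spots(small, SpotCallConfig())
    tiny = CalibratedStack(np.ones((1, 1, 20, 20)), pixel_size_um=0.13)
    with pytest.raises(ValueError, match="background mean"):
        spotcall.detect_spots(tiny, SpotCallConfig(background_mean_px=100))
    with pytest.raises(ValueError, match="median flattening"):
        spotcall.detect_spots(tiny, SpotCallConfig(background_mean_px=10))


def test_raising_min_intensity_never_increases_spot_count(small_spot_movie):
    _, stack, _ = small_spot_movie
    one = stack.with_data(stack.data[-1:])
    counts = []
    for thr in (0.0, 1000.0, 5000.0, 20000.0, 1e6):
        spots = spotcall.detect_spots(one, SpotCallConfig(min_intensity=thr))
        counts.append(spots.n_spots)
    assert counts == sorted(counts, reverse=True)


@settings(deadline=None, max_examples=10, derandomize=True)
@given(scale=st.floats(min_value=0.1, max_value=50.0))
def test_intensity_linearity_under_image_scaling(scale):
    yy, xx = np.mgrid[0:112, 0:112]
    img = 10.0 + 500.0 * np.exp(-((xx - 50.0) ** 2 + (yy - 60.0) ** 2) / 18.0)
    cfg = SpotCallConfig(min_intensity=0, min_area_px=8, max_area_px=400)
    base = spotcall.detect_spots(CalibratedStack(img, pixel_size_um=0.1), cfg)
    scaled = spotcall.detect_spots(CalibratedStack(img * scale, pixel_size_um=0.1), cfg)
    assert base.n_spots == scaled.n_spots
    np.testing.assert_allclose(
        scaled.table.integrated_intensity.to_numpy(),
        base.table.integrated_intensity.to_numpy() * scale,
        rtol=1e-9,
    )


# ---------------------------------------------------------------------------
# intensity extraction
# ---------------------------------------------------------------------------

class TestExtractSpotIntensity:
    def test_uniform_region_gives_value_times_area(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[2:6, 3:8] = 1
        img = np.full((20, 20), 7.0)
        out = spotcall.extract_spot_intensity(mask, img)
        assert out[1] == pytest.approx(7.0 * 20)

    def test_disjoint_regions_are_independent(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[1:4, 1:4] = 1
        mask[10:14, 10:14] = 2
        img = np.ones((20, 20))
        img[10:14, 10:14] = 100.0
        out = spotcall.extract_spot_intensity(mask, img)
        assert out[1] == pytest.approx(9.0)
        assert out[2] == pytest.approx(1600.0)

    def test_gaussian_spot_full_support_matches_analytic_integral(self):
        sigma, amp = 3.0, 250.0
        yy, xx = np.mgrid[0:101, 0:101]
        img = amp * np.exp(-((xx - 50) ** 2 + (yy - 50) ** 2) / (2 * sigma**2))
        mask = np.ones_like(img, dtype=int)
        out = spotcall.extract_spot_intensity(mask, img)
        assert out[1] == pytest.approx(2 * math.pi * sigma**2 * amp, rel=0.02)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            spotcall.extract_spot_intensity(np.zeros((4, 4), int), np.zeros((5, 5)))


# ---------------------------------------------------------------------------
# FISH spot calling with nucleus assignment
# ---------------------------------------------------------------------------

def _fish_scene():
    """One frame with two nuclei; nucleus 1 has two foci, a stray spot sits
    between nuclei, nucleus 2 is empty."""
    yy, xx = np.mgrid[0:128, 0:128]
    img = np.full((128, 128), 20.0)
    for cx, cy in [(30.0, 40.0), (45.0, 52.0), (64.0, 100.0)]:
        img += 900.0 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 9.0))
    nuclei = np.zeros((128, 128), dtype=int)
    nuclei[(xx - 38) ** 2 + (yy - 46) ** 2 <= 20**2] = 1
    nuclei[(xx - 100) ** 2 + (yy - 30) ** 2 <= 18**2] = 2
    return CalibratedStack(img, pixel_size_um=0.1), nuclei


def test_fish_spots_assigned_to_nuclei_including_double_foci():
    stack, nuclei = _fish_scene()
    spots = spotcall.call_fish_spots(stack, nuclei, SpotCallConfig(min_intensity=1000))
    t = spots.table
    assert len(t) == 3
    in_n1 = t[t.nucleus_id == 1]
    assert len(in_n1) == 2          # both foci of the same nucleus reported
    assert (t.nucleus_id == 2).sum() == 0
    stray = t[t.unassigned]
    assert len(stray) == 1


def test_fish_mask_misalignment_rejected():
    stack, nuclei = _fish_scene()
    with pytest.raises(ValueError, match="nuclei mask"):
        spotcall.call_fish_spots(stack, nuclei[:64, :64])
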