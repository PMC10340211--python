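"""Feature operations against independent brute-force scalar oracles."""

import numpy as np
import pytest

from pdrscreen.features import (BoxPlotLimits, ThresholdBand, calibrate_layer2,
                                gradient_features, layer1_filter, layer2_filter,
                                region_energy, region_entropy,
                                region_homogeneity, skewness, tukey_fences)
from pdrscreen.regions import CandidateRegion


# ---------------------------------------------------------------------------
# brute-force oracles (scalar loops, independent of the implementation)
# ---------------------------------------------------------------------------

def entropy_oracle(w, m):
    counts = {}
    for v in np.asarray(w, float).ravel():
        k = min(int(v * m // 256), m - 1)
        counts[k] = counts.get(k, 0) + 1
    n = sum(counts.values())
    return -sum((c / n) * np.log2(c / n) for c in counts.values())


def energy_oracle(w):
    return sum(float(v) ** 2 for v in np.asarray(w, float).ravel())


def homogeneity_oracle(w, m, offsets):
    w = np.asarray(w, float)
    q = np.minimum((w * m // 256).astype(int), m - 1)
    vals = []
    for dr, dc in offsets:
        tot, s = 0, 0.0
        for i in range(q.shape[0]):
            for j in range(q.shape[1]):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < q.shape[0] and 0 <= j2 < q.shape[1]:
                    s += 1.0 / (1.0 + abs(int(q[i, j]) - int(q[i2, j2])))
                    tot += 1
        if tot:
            vals.append(s / tot)
    return float(np.mean(vals))


def sobel_oracle(w):
    """Pixelwise 3x3 Sobel with reflect padding, explicit loops."""
    w = np.asarray(w, float)
    kx = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
    ky = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]
    p = np.pad(w, 1, mode="symmetric")
    h, win = w.shape
    gx = np.zeros_like(w)
    gy = np.zeros_like(w)
    for i in range(h):
        for j in range(win):
            sx = sy = 0.0
            for a in range(3):
                for b in range(3):
                    # scipy.ndimage.convolve flips the kernel
                    sx += kx[2 - a][2 - b] * p[i + a, j + b]
                    sy += ky[2 - a][2 - b] * p[i + a, j + b]
            gx[i, j], gy[i, j] = sx, sy
    mag = np.sqrt(gx**2 + gy**2)
    sel = mag > 0
    theta = np.arctan2(gy[sel], gx[sel])
    s = float(np.std(theta, ddof=1)) if sel.sum() >= 2 else 0.0
    return float(mag.mean()), s


def skew_oracle(w):
    v = np.asarray(w, float).ravel()
    m = v.mean()
    s = np.sqrt(((v - m) ** 2).sum() / (v.size - 1))
    if s == 0:
        return 0.0
    return ((v - m) ** 3).sum() / ((v.size - 1) * s**3)


def quartile_oracle(values, q):
    """Linear-interpolation quantile on sorted order statistics."""
    v = sorted(float(x) for x in values)
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

def test_entropy_worked_examples():
    assert region_entropy(np.full((4, 4), 7.0), 32) == 0.0
    two_level = np.array([[0.0, 255.0] * 4] * 4)
    assert region_entropy(two_level, 32) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        region_entropy(np.empty((0,)), 32)


def test_entropy_bounded_by_log2_m(rng):
    for _ in range(20):
        w = rng.uniform(0, 255, (8, 8))
        m = int(rng.integers(2, 64))
        h = region_entropy(w, m)
        assert 0.0 <= h <= np.log2(m) + 1e-12


def test_energy_worked_example():
    assert region_energy(np.zeros((3, 3))) == 0.0
    assert region_energy(np.array([[1.0, 2.0], [3.0, 4.0]])) == 30.0


def test_homogeneity_constant_window_is_one():
    assert region_homogeneity(np.full((5, 5), 9.0), 32) == pytest.approx(1.0)


def test_homogeneity_checkerboard_closed_form():
    """Alternating extreme levels: every single-step pair differs by M-1."""
    m = 32
    board = np.indices((6, 6)).sum(axis=0) % 2 * 255.0
    h = region_homogeneity(board, m, offsets=((0, 1), (1, 0)))
    assert h == pytest.approx(1.0 / (1.0 + (m - 1)))


def test_homogeneity_rejects_degenerate_window():
    with pytest.raises(ValueError):
        region_homogeneity(np.array([[5.0]]), 32)


def test_gradient_constant_window_is_zero():
    mmag, s = gradient_features(np.full((5, 5), 3.0))
    assert mmag == 0.0 and s == 0.0


def test_gradient_step_edge_has_concentrated_direction():
    w = np.zeros((9, 9))
    w[:, 5:] = 100.0
    _, s = gradient_features(w)
    assert s < 0.15


def test_skewness_examples():
    assert skewness(np.full((3, 3), 100.0)) == 0.0
    assert skewness(np.arange(1.0, 10.0).reshape(3, 3)) == pytest.approx(0.0)


@pytest.mark.parametrize("trial", range(25))
def test_feature_suite_matches_bruteforce_oracles(rng, trial):
    """Every texture/edge statistic equals an independent scalar loop."""
    w = rng.uniform(0, 255, (8, 8))
    m = 32
    offsets = ((0, 1), (1, 0), (1, 1), (1, -1))
    assert region_entropy(w, m) == pytest.approx(entropy_oracle(w, m), rel=1e-9)
    assert region_energy(w) == pytest.approx(energy_oracle(w), rel=1e-9)
    assert region_homogeneity(w, m, offsets) == pytest.approx(
        homogeneity_oracle(w, m, offsets), rel=1e-9)
    mmag, s = gradient_features(w)
    mmag_o, s_o = sobel_oracle(w)
    assert mmag == pytest.approx(mmag_o, rel=1e-9)
    assert s == pytest.approx(s_o, rel=1e-9, abs=1e-10)
    assert skewness(w) == pytest.approx(skew_oracle(w), rel=1e-9)


# ---------------------------------------------------------------------------
# Tukey fences
# ---------------------------------------------------------------------------

def test_tukey_fences_worked_case():
    lim = tukey_fences([1, 2, 3, 4, 5])
    assert (lim.q1, lim.q3) == (2.0, 4.0)
    assert (lim.lower_adjacent, lim.upper_adjacent) == (-1.0, 7.0)


def test_tukey_fences_zero_iqr():
    lim = tukey_fences([5, 5, 5, 5])
    assert lim.q1 == lim.q3 == lim.upper_adjacent == lim.lower_adjacent == 5.0


def test_tukey_fences_requires_four_values():
    with pytest.raises(ValueError):
        tukey_fences([1.0, 2.0, 3.0])


@pytest.mark.parametrize("trial", range(60))
def test_tukey_fences_match_sort_interpolate_oracle(rng, trial):
    n = int(rng.integers(4, 200))
    v = rng.normal(0, 10, n)
    lim = tukey_fences(v)
    q1 = quartile_oracle(v, 0.25)
    q3 = quartile_oracle(v, 0.75)
    assert lim.q1 == pytest.approx(q1, rel=1e-12, abs=1e-12)
    assert lim.q3 == pytest.approx(q3, rel=1e-12, abs=1e-12)
    assert lim.upper_adjacent == pytest.approx(q3 + 1.5 * (q3 - q1), rel=1e-12)
    assert lim.lower_adjacent == pytest.approx(q1 - 1.5 * (q3 - q1), rel=1e-12)
    assert lim.lower_adjacent <= lim.q1 <= lim.q3 <= lim.upper_adjacent


# ---------------------------------------------------------------------------
# band filters and calibration
# ---------------------------------------------------------------------------

def _region(feats):
    reg = CandidateRegion(label_id=1, rows=np.array([0]), cols=np.array([0]),
                          area=1, centroid=(0.0, 0.0), zone="NVD")
    reg.features = feats
    return reg


def test_layer1_filter_interval_logic(rng):
    bands = {"entropy": ThresholdBand("entropy", 1.0, 3.0),
             "energy": ThresholdBand("energy", 0.0, 10.0),
             "homogeneity": ThresholdBand("homogeneity", 0.2, 0.9)}
    inside = _region({"entropy": 2.0, "energy": 5.0, "homogeneity": 0.5})
    outside = _region({"entropy": 2.0, "energy": 11.0, "homogeneity": 0.5})
    kept = layer1_filter([inside, outside], bands, "NVD")
    assert kept == [inside]
    assert inside.layer1_pass is True and outside.layer1_pass is False


def test_filter_missing_band_is_configuration_error():
    with pytest.raises(KeyError):
        layer1_filter([_region({"entropy": 1.0})], {}, "NVD")


@pytest.mark.parametrize("trial", range(10))
def test_filter_matches_interval_oracle_and_antimonotone(rng, trial):
    names = ("f1", "f4", "f6", "f8", "f10")
    regions = [_region({n: float(rng.normal()) for n in names})
               for _ in range(20)]
    bands = {n: ThresholdBand(n, *sorted(rng.normal(0, 1.5, 2))) for n in names}
    kept = layer2_filter(list(regions), bands, "NVD")
    expected = [r for r in regions
                if all(bands[n].lower <= r.features[n] <= bands[n].upper
                       for n in names)]
    assert kept == expected
    # narrowing any band never adds survivors
    n0 = names[0]
    b = bands[n0]
    mid = (b.lower + b.upper) / 2
    narrower = dict(bands)
    narrower[n0] = ThresholdBand(n0, (b.lower + mid) / 2, (mid + b.upper) / 2)
    kept2 = layer2_filter(list(regions), narrower, "NVD")
    assert set(id(r) for r in kept2) <= set(id(r) for r in kept)


def test_calibrate_layer2_band_from_true_distribution():
    labeled = [({"f1": v}, True) for v in [1.0, 2.0, 3.0, 4.0, 5.0]]
    bands, report = calibrate_layer2(labeled, ("f1",))
    assert bands["f1"].lower == pytest.approx(-1.0)
    assert bands["f1"].upper == pytest.approx(7.0)


def test_calibrate_flags_feature_identical_across_classes():
    labeled = [({"f1": v}, True) for v in [1.0, 2, 3, 4, 5]] + \
              [({"f1": v}, False) for v in [1.0, 2, 3, 4, 5]]
    with pytest.warns(UserWarning, match="non-discriminative"):
        _, report = calibrate_layer2(labeled, ("f1",))
    assert report["f1"]["non_discriminative"] is True


def test_calibrate_separable_classes_excludes_false_values():
    true_vals = [9.0, 10.0, 10.5, 11.0, 9.5]
    false_vals = [95.0, 100.0, 105.0, 110.0]
    labeled = [({"f1": v}, True) for v in true_vals] + \
              [({"f1": v}, False) for v in false_vals]
    bands, report = calibrate_layer2(labeled, ("f1",))
    assert all(not bands["f1"].contains(v) for v in false_vals)
    assert report["f1"]["non_discriminative"] is False


def test_calibrate_requires_enough_true_examples():
    with pytest.raises(ValueError):
        calibrate_layer2([({"f1": 1.0}, True)], ("f1",))
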