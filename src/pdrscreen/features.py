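"""Region features and the double-layered threshold machinery.

Layer 1 reads a fixed window around each candidate region on the inverted
8-bit green plane and tests texture/edge statistics: entropy and GLCM
homogeneity separate disordered neovascular tufts from compact bright
exudates, energy brackets them against normal vessels, and the Sobel
gradient statistics capture the contrast variation of fragile new vessels.
Layer 2 re-reads each survivor through an adaptive window on the original
color planes (features f1-f10) and applies bands calibrated from labeled
examples by box-plot (Tukey-fence) analysis: a band is the interval between
the lower and upper adjacent limits, Q1 - 1.5 IQR and Q3 + 1.5 IQR, of the
true-detection distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab

from .preprocess import FundusImage
from .regions import CandidateRegion, Window, adaptive_window

__all__ = [
    "ThresholdBand",
    "BoxPlotLimits",
    "region_entropy",
    "region_energy",
    "region_homogeneity",
    "gradient_features",
    "skewness",
    "layer1_features",
    "postproc_features",
    "layer1_filter",
    "layer2_filter",
    "tukey_fences",
    "calibrate_layer2",
    "LAYER1_FEATURES",
    "LAYER2_FEATURES",
]

# Feature sets tested per zone at each threshold layer.  On-disc
# neovascularization is judged on texture disorder (entropy/homogeneity),
# peripheral tufts on edge statistics in a smaller window.
LAYER1_FEATURES = {
    "NVD": ("entropy", "energy", "homogeneity"),
    "NVE": ("energy", "grad_mean", "grad_dir_std"),
}
# Selected by box-plot analysis of true/false detections on phantom
# cohorts: near-disc false positives are bright rim artifacts (caught by
# intensity/color means and adaptive-window entropy/gradient), peripheral
# false positives are sparse noise clusters (caught by window energy and
# peak intensity).
LAYER2_FEATURES = {
    "NVD": ("f1", "f4", "f6", "f8", "f10"),
    "NVE": ("f2", "f5", "f8", "f10"),
}


@dataclass(frozen=True)
class ThresholdBand:
    feature_name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(
                f"band for {self.feature_name}: lower {self.lower} > upper "
                f"{self.upper}")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class BoxPlotLimits:
    q1: float
    q3: float
    upper_adjacent: float
    lower_adjacent: float


# ---------------------------------------------------------------------------
# scalar feature operations
# ---------------------------------------------------------------------------

def region_entropy(window_pixels: np.ndarray, m_levels: int = 32) -> float:
    """Shannon entropy (bits) of the window histogram binned to M gray levels.

    H = -sum p_k log2 p_k over occupied bins; 0 <= H <= log2(M).
    """
    w = np.asarray(window_pixels, dtype=np.float64)
    if w.size == 0:
        raise ValueError("empty window")
    levels = _quantize(w, m_levels)
    counts = np.bincount(levels.ravel(), minlength=m_levels)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum())


def region_energy(window_pixels: np.ndarray) -> float:
    """Sum of squared pixel intensities, E = sum g(i,j)^2."""
    w = np.asarray(window_pixels, dtype=np.float64)
    return float((w * w).sum())


def _quantize(w: np.ndarray, m_levels: int) -> np.ndarray:
    """Bin 8-bit intensities into m_levels equal bins over [0, 255]."""
    idx = np.floor(w * (m_levels / 256.0)).astype(np.int64)
    return np.clip(idx, 0, m_levels - 1)


def region_homogeneity(window_pixels: np.ndarray, m_levels: int = 32,
                       offsets: tuple[tuple[int, int], ...] = (
                           (0, 1), (1, 0), (1, 1), (1, -1))) -> float:
    """Gray-level co-occurrence homogeneity, averaged over displacement offsets.

    homogeneity = sum_{i,j} P(i,j) / (1 + |i - j|) with P the normalized
    co-occurrence matrix of quantized gray levels at each offset.  Equals 1
    for a constant window (all mass on the diagonal) and decreases as
    co-occurring levels spread apart; always in (0, 1].
    """
    w = np.asarray(window_pixels, dtype=np.float64)
    if w.ndim != 2 or min(w.shape) < 2:
        raise ValueError("homogeneity needs a window of at least 2x2")
    q = _quantize(w, m_levels)
    vals = []
    for dr, dc in offsets:
        a = q[max(0, -dr):q.shape[0] - max(0, dr),
              max(0, -dc):q.shape[1] - max(0, dc)]
        b = q[max(0, dr):q.shape[0] + min(0, dr),
              max(0, dc):q.shape[1] + min(0, dc)]
        if a.size == 0:
            continue
        diff = np.abs(a - b).ravel()
        vals.append(float(np.mean(1.0 / (1.0 + diff))))
    if not vals:
        raise ValueError("window too small for the requested offsets")
    return float(np.mean(vals))


_SOBEL_X = np.array([[-1, 0, 1],
                     [-2, 0, 2],
                     [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


def gradient_features(window_pixels: np.ndarray) -> tuple[float, float]:
    """Mean Sobel gradient magnitude and the std of the gradient direction.

    G = sqrt(Gx^2 + Gy^2) per pixel; Mmag is its mean over the window.
    theta = atan2(Gy, Gx) on pixels with G > 0, and the direction spread s
    is its sample standard deviation (ddof=1); defined as 0 when fewer than
    two pixels carry gradient.
    """
    w = np.asarray(window_pixels, dtype=np.float64)
    if w.ndim != 2 or min(w.shape) < 3:
        raise ValueError("gradient features need a window of at least 3x3")
    gx = ndimage.convolve(w, _SOBEL_X, mode="reflect")
    gy = ndimage.convolve(w, _SOBEL_Y, mode="reflect")
    mag = np.hypot(gx, gy)
    mmag = float(mag.mean())
    sel = mag > 0
    if sel.sum() < 2:
        return mmag, 0.0
    theta = np.arctan2(gy[sel], gx[sel])
    return mmag, float(np.std(theta, ddof=1))


def skewness(window_pixels: np.ndarray) -> float:
    """Sample skewness sum((g - mean)^3) / ((N-1) s^3); 0 for zero variance."""
    w = np.asarray(window_pixels, dtype=np.float64).ravel()
    if w.size < 2:
        return 0.0
    s = np.std(w, ddof=1)
    if s == 0:
        return 0.0
    return float(((w - w.mean()) ** 3).sum() / ((w.size - 1) * s**3))


# ---------------------------------------------------------------------------
# per-region feature vectors
# ---------------------------------------------------------------------------

def _crop(plane: np.ndarray, win: Window) -> np.ndarray:
    r0, c0, r1, c1 = win
    return plane[r0:r1, c0:c1]


def layer1_features(region: CandidateRegion, green_inv8: np.ndarray,
                    m_levels: int = 32,
                    glcm_offsets: tuple[tuple[int, int], ...] = (
                        (0, 1), (1, 0), (1, 1), (1, -1))) -> dict[str, float]:
    """First-layer statistics on the fixed window of the inverted green plane."""
    if region.window is None:
        raise ValueError("region has no fixed analysis window")
    w = _crop(green_inv8, region.window).astype(np.float64)
    mmag, dstd = gradient_features(w)
    return {
        "entropy": region_entropy(w, m_levels),
        "energy": region_energy(w),
        "homogeneity": region_homogeneity(w, m_levels, glcm_offsets),
        "grad_mean": mmag,
        "grad_dir_std": dstd,
    }


def postproc_features(region: CandidateRegion, color_img: FundusImage,
                      pad_frac: float = 0.2, m_levels: int = 32) -> dict[str, float]:
    """Post-processing features f1-f10 for one candidate region.

    Intensity statistics read the candidate region's own pixels: f1/f2
    mean/max green, f3 green skewness, f8/f9 red/blue means, f10 mean L*
    lightness (sRGB->LAB, D65).  Texture and edge statistics need a 2D
    support and read the adaptive window (region bounding box padded by
    ``pad_frac`` per side): f4 entropy, f5 energy, f6/f7 Sobel gradient
    mean and direction std.
    """
    win = adaptive_window(region, color_img.green.shape, pad_frac)
    g_win = _crop(color_img.green, win).astype(np.float64)
    rr, cc = region.rows, region.cols
    g_px = color_img.green[rr, cc].astype(np.float64)
    lab = rgb2lab(color_img.pixels[rr, cc, :][None, :, :])
    mmag, dstd = gradient_features(g_win) if min(g_win.shape) >= 3 else (0.0, 0.0)
    return {
        "f1": float(g_px.mean()),
        "f2": float(g_px.max()),
        "f3": skewness(g_px),
        "f4": region_entropy(g_win, m_levels),
        "f5": region_energy(g_win),
        "f6": mmag,
        "f7": dstd,
        "f8": float(color_img.red[rr, cc].mean()),
        "f9": float(color_img.blue[rr, cc].mean()),
        "f10": float(lab[0, :, 0].mean()),
    }


# ---------------------------------------------------------------------------
# thresholds and calibration
# ---------------------------------------------------------------------------

def _band_filter(regions: list[CandidateRegion],
                 bands: dict[str, ThresholdBand],
                 required: tuple[str, ...],
                 flag_attr: str) -> list[CandidateRegion]:
    for name in required:
        if name not in bands:
            raise KeyError(f"no threshold band configured for feature {name!r}")
    kept = []
    for reg in regions:
        ok = all(bands[name].contains(reg.features[name]) for name in required)
        setattr(reg, flag_attr, ok)
        if ok:
            kept.append(reg)
    return kept


def layer1_filter(regions: list[CandidateRegion],
                  bands: dict[str, ThresholdBand],
                  zone: str) -> list[CandidateRegion]:
    """Keep regions whose zone feature set lies inside every band."""
    return _band_filter(regions, bands, LAYER1_FEATURES[zone], "layer1_pass")


def layer2_filter(regions: list[CandidateRegion],
                  bands: dict[str, ThresholdBand],
                  zone: str | None = None,
                  features_to_use: tuple[str, ...] | None = None,
                  ) -> list[CandidateRegion]:
    """Second-layer band test on the adaptive-window f-features."""
    required = features_to_use or LAYER2_FEATURES[zone or "NVD"]
    return _band_filter(regions, bands, tuple(required), "layer2_pass")


def tukey_fences(values) -> BoxPlotLimits:
    """Box-plot adjacent limits Q3 + 1.5 IQR and Q1 - 1.5 IQR.

    Quartiles use linear interpolation between order statistics.  Requires
    at least 4 values.
    """
    v = np.asarray(list(values), dtype=np.float64)
    if v.size < 4:
        raise ValueError(f"need at least 4 values for quartiles, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return BoxPlotLimits(q1=float(q1), q3=float(q3),
                         upper_adjacent=float(q3 + 1.5 * iqr),
                         lower_adjacent=float(q1 - 1.5 * iqr))


def _box_overlap(a: BoxPlotLimits, b: BoxPlotLimits) -> float:
    """Fractional overlap of two interquartile boxes, relative to the smaller."""
    lo = max(a.q1, b.q1)
    hi = min(a.q3, b.q3)
    if hi < lo:
        return 0.0
    smaller = min(a.q3 - a.q1, b.q3 - b.q1)
    if smaller <= 0:
        return 1.0          # degenerate box inside the other: full overlap
    return (hi - lo) / smaller


def calibrate_layer2(labeled: list[tuple[dict[str, float], bool]],
                     features_to_use: tuple[str, ...],
                     box_overlap_flag: float = 0.5,
                     ) -> tuple[dict[str, ThresholdBand], dict[str, dict]]:
    """Calibrate bands from labeled feature vectors by box-plot analysis.

    Each band is [lower_adjacent, upper_adjacent] of the true-detection
    distribution of that feature.  The report compares true/false
    interquartile boxes; features overlapping more than
    ``box_overlap_flag`` are flagged non-discriminative.
    """
    true_vecs = [f for f, is_true in labeled if is_true]
    false_vecs = [f for f, is_true in labeled if not is_true]
    if len(true_vecs) < 4:
        raise ValueError(
            f"need >= 4 true-detection examples to calibrate, got {len(true_vecs)}")
    bands: dict[str, ThresholdBand] = {}
    report: dict[str, dict] = {}
    for name in features_to_use:
        tl = tukey_fences([f[name] for f in true_vecs])
        bands[name] = ThresholdBand(name, tl.lower_adjacent, tl.upper_adjacent)
        entry: dict = {"true_limits": tl}
        if len(false_vecs) >= 4:
            fl = tukey_fences([f[name] for f in false_vecs])
            ov = _box_overlap(tl, fl)
            entry.update(false_limits=fl, box_overlap=ov,
                         non_discriminative=ov > box_overlap_flag)
            if entry["non_discriminative"]:
                warnings.warn(
                    f"feature {name!r}: true/false interquartile boxes overlap "
                    f"{ov:.2f} (> {box_overlap_flag}); non-discriminative",
                    stacklevel=2)
        report[name] = entry
    return bands, report


def bands_from_config(cfg_bands: dict[str, dict[str, list[float]]],
                      zone: str) -> dict[str, ThresholdBand]:
    """Materialize ThresholdBand objects from the config mapping for a zone."""
    out = {}
    for name, (lo, hi) in cfg_bands.get(zone, {}).items():
        out[name] = ThresholdBand(name, float(lo), float(hi))
    return out
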