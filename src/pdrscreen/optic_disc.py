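"""Optic disc localization and the NVD/NVE zone masks.

The optic disc (OD) is the brightest roughly circular region of the fundus
and the point where the major vessels converge.  Bright candidate regions
are found on an illumination-flattened green plane (low-pass Fourier
reconstruction subtracted from the original); when several candidates
appear — large exudates are the usual confounders — the one whose
neighborhood carries the most segmented-vessel energy is taken as the disc.

Grading geometry: with disc diameter D, the one-disc-distance radius is
1dd = D + D/2.  The NVD zone is the FOV within 1dd of the OD center
(inclusive at the boundary); the NVE zone is the rest of the FOV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .preprocess import PreprocessedImage
from .vessels import VesselMask

__all__ = [
    "OpticDisc",
    "ODCandidate",
    "one_disc_distance",
    "od_candidate_regions",
    "select_od",
    "build_zone_masks",
]


@dataclass(frozen=True)
class OpticDisc:
    center: tuple[float, float]     # (row, col), working-scale pixels
    diameter_d: float               # px
    one_dd: float                   # = 1.5 * diameter_d
    energy: float = 0.0             # vessel-pixel count in the selection window

    def __post_init__(self) -> None:
        if self.diameter_d <= 0:
            raise ValueError("disc diameter must be > 0")


@dataclass(frozen=True)
class ODCandidate:
    centroid: tuple[float, float]   # (row, col)
    area: int
    brightness: float               # mean flattened brightness in the region
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    diameter: float = 0.0           # refined equivalent-circle diameter (px)


def one_disc_distance(diameter_d: float) -> float:
    """One disc distance: 1dd = D + D/2."""
    return diameter_d + diameter_d / 2.0


def od_candidate_regions(pre: PreprocessedImage,
                         cfg: PipelineConfig | None = None) -> list[ODCandidate]:
    """Bright OD candidates on the (non-inverted) green plane, ranked by brightness.

    Illumination is estimated by keeping only the lowest ``od_lowpass_frac``
    of the frequency radius and subtracted; the brightest
    (1 - od_bright_quantile) in-FOV pixels of the flattened plane are
    thresholded, closed, and labeled.  May return an empty list.
    """
    from .vessels import fov_extend

    cfg = cfg or PipelineConfig()
    # continue the green plane past the rim so the illumination estimate
    # sees no step edge at the field boundary
    green = fov_extend(pre.image.green.astype(np.float64), pre.fov_mask)
    fov = pre.fov_mask
    h, w = green.shape

    ky = np.fft.fftfreq(h)[:, None]
    kx = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(ky, kx)
    lowpass = radius <= cfg.od_lowpass_frac * 0.5   # fraction of Nyquist
    illum = np.fft.ifft2(np.fft.fft2(green) * lowpass).real
    flat = green - illum
    # the illumination estimate overshoots just inside the field rim;
    # exclude a thin rim band so the ring cannot seed candidates
    inner = ndimage.binary_erosion(fov, iterations=8)
    flat[~inner] = 0.0
    fov = inner

    vals = flat[fov]
    if vals.size == 0:
        return []
    thresh = float(np.quantile(vals, cfg.od_bright_quantile))
    bright = (flat > thresh) & (flat > 0) & fov
    if not bright.any():
        return []
    r = cfg.od_close_radius
    yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
    disc = (yy * yy + xx * xx) <= r * r
    bright = ndimage.binary_closing(bright, structure=disc)

    labels, n = ndimage.label(bright, structure=np.ones((3, 3)))
    cands: list[ODCandidate] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        area = rows.size
        if area < cfg.od_min_area:
            continue
        centroid = (float(rows.mean()), float(cols.mean()))
        cands.append(ODCandidate(
            centroid=centroid,
            area=int(area),
            brightness=float(flat[rows, cols].mean()),
            pixels=(rows, cols),
            diameter=_refine_diameter(flat, fov, centroid, (rows, cols), cfg)))
    cands.sort(key=lambda c: c.brightness, reverse=True)
    return cands[:cfg.od_max_candidates]


def _refine_diameter(flat: np.ndarray, fov: np.ndarray,
                     centroid: tuple[float, float],
                     pixels: tuple[np.ndarray, np.ndarray],
                     cfg: PipelineConfig) -> float:
    """Equivalent-circle diameter from region growing around a bright core.

    The top-percentile threshold that finds candidates captures only the
    brightest core of the disc; the full extent is recovered by
    re-thresholding a local window at half the core brightness and taking
    the component containing the core.
    """
    h, w = flat.shape
    half = int(round(1.5 * cfg.od_expected_diameter))
    r = int(round(centroid[0]))
    c = int(round(centroid[1]))
    r0, r1 = max(0, r - half), min(h, r + half + 1)
    c0, c1 = max(0, c - half), min(w, c + half + 1)
    local = flat[r0:r1, c0:c1]
    core_level = float(flat[pixels].mean())
    grown = (local > 0.5 * core_level) & fov[r0:r1, c0:c1]
    # close over crossing vessels, which darken the disc locally
    grown = ndimage.binary_closing(grown, structure=np.ones((5, 5)))
    labels, _ = ndimage.label(grown, structure=np.ones((3, 3)))
    lab = labels[r - r0, c - c0]
    if lab == 0:
        return float(2.0 * np.sqrt(len(pixels[0]) / np.pi))
    area = int((labels == lab).sum())
    return float(2.0 * np.sqrt(area / np.pi))


def select_od(candidates: list[ODCandidate], vessels: VesselMask,
              cfg: PipelineConfig | None = None) -> OpticDisc:
    """Pick the candidate with maximal vessel energy in its analysis window.

    Vessel energy is the count of segmented vessel pixels inside a square
    window of side ``od_window_factor * od_expected_diameter`` centered on
    the candidate centroid: the vasculature converges at the disc, so the
    true disc wins over exudates.  The disc diameter is the equivalent-circle
    diameter of the selected bright region.
    """
    cfg = cfg or PipelineConfig()
    if not candidates:
        raise ValueError("OD not found: no candidate regions (image ungradable)")
    half = int(round(cfg.od_window_factor * cfg.od_expected_diameter / 2))
    vm = vessels.mask
    h, w = vm.shape

    def energy(c: ODCandidate) -> int:
        r0 = max(0, int(round(c.centroid[0])) - half)
        r1 = min(h, int(round(c.centroid[0])) + half + 1)
        c0 = max(0, int(round(c.centroid[1])) - half)
        c1 = min(w, int(round(c.centroid[1])) + half + 1)
        return int(vm[r0:r1, c0:c1].sum())

    # prefer candidates whose refined extent is disc-like: exudates are an
    # order of magnitude smaller than the expected disc diameter
    plausible = [c for c in candidates
                 if 0.4 * cfg.od_expected_diameter <= c.diameter
                 <= 2.0 * cfg.od_expected_diameter]
    pool = plausible if plausible else candidates
    best = max(pool, key=energy)
    d = best.diameter if best.diameter > 0 else 2.0 * np.sqrt(best.area / np.pi)
    return OpticDisc(center=best.centroid, diameter_d=float(d),
                     one_dd=one_disc_distance(float(d)),
                     energy=float(energy(best)))


def build_zone_masks(od: OpticDisc, fov: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """NVD/NVE filter masks: an exact partition of the field of view.

    A pixel exactly at distance 1dd belongs to the NVD zone (inclusive rule).
    """
    fov = fov.astype(bool)
    h, w = fov.shape
    rows = np.arange(h)[:, None] - od.center[0]
    cols = np.arange(w)[None, :] - od.center[1]
    dist = np.hypot(rows, cols)
    nvd = fov & (dist <= od.one_dd)
    nve = fov & ~nvd
    return nvd, nve
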