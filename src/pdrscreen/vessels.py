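"""Binary vessel maps and the dual-path abnormal-vessel candidate map.

Two copies of the preprocessed image are filtered in parallel.  The
*normal* path blurs the image (3x3 Gaussian) before an elongated,
coarse-scale Gabor bank, so only the principal vasculature survives.  The
*detail* path sharpens the image (3x3 unsharp kernel) before an isotropic,
fine-scale bank, recovering thin tortuous neovascular tufts along with the
normal vessels.  Each response map is binarized by multilayered adaptive
thresholding, and the candidate map is the detail mask minus a dilated
normal mask: what remains are abnormal vessels and exudates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gabor import GaborBankParams, ResponseMap, orientation_max
from .preprocess import PreprocessedImage

__all__ = [
    "VesselMask",
    "multilayer_threshold",
    "normal_vessel_path",
    "detail_vessel_path",
    "candidate_map",
]

# unsharp kernel: center 9, neighbors -1; sums to 1
_SHARPEN = np.array([[-1, -1, -1],
                     [-1, 9, -1],
                     [-1, -1, -1]], dtype=np.float64)


@dataclass(frozen=True)
class VesselMask:
    mask: np.ndarray            # bool
    source: str                 # normal_path | detail_path | candidate

    def __post_init__(self) -> None:
        if self.source not in ("normal_path", "detail_path", "candidate"):
            raise ValueError(f"unknown mask source {self.source!r}")


def fov_extend(img: np.ndarray, fov: np.ndarray) -> np.ndarray:
    """Replace outside-FOV pixels by their nearest in-FOV value.

    Without this the intensity step at the field-of-view rim is the
    strongest ridge in the image and floods the top response quantiles.
    """
    fov = fov.astype(bool)
    if fov.all():
        return np.asarray(img, dtype=np.float64)
    _, (ir, ic) = ndimage.distance_transform_edt(~fov, return_indices=True)
    return np.asarray(img, dtype=np.float64)[ir, ic]


def _erode_fov(fov: np.ndarray, rim: int) -> np.ndarray:
    """Shrink the FOV by ``rim`` pixels to keep residual rim response out."""
    if rim <= 0:
        return fov.astype(bool)
    return ndimage.binary_erosion(fov.astype(bool), iterations=rim)


def _normalize(resp: np.ndarray, fov: np.ndarray) -> np.ndarray:
    """Scale a response map to [0,1] over the field of view."""
    out = np.zeros_like(resp)
    vals = resp[fov]
    if vals.size == 0:
        raise ValueError("empty field-of-view mask")
    peak = vals.max()
    if peak > 0:
        out[fov] = resp[fov] / peak
    return out


def multilayer_threshold(resp: ResponseMap | np.ndarray, fov: np.ndarray,
                         levels: int = 3, local_window: int = 25,
                         offset: float = 0.03,
                         top_frac: float = 0.02) -> VesselMask:
    """Multilayered + adaptive binarization of a vessel-enhancement map.

    Layer l (l = 1..levels) keeps pixels above the global (1 - l*top_frac)
    quantile of the in-FOV response *and* above their local mean by
    l*offset; the mask is the union of the layers.  Deeper layers reach
    dimmer vessels but demand progressively more local contrast, which keeps
    smooth background out of the mask.  Deterministic for fixed inputs.
    """
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    r = resp.m_psi if isinstance(resp, ResponseMap) else np.asarray(resp, float)
    fov = fov.astype(bool)
    if not fov.any():
        raise ValueError("empty field-of-view mask")
    vals = r[fov]
    local_mean = ndimage.uniform_filter(r, size=local_window)
    mask = np.zeros(r.shape, dtype=bool)
    for layer in range(1, levels + 1):
        q = float(np.quantile(vals, max(0.0, 1.0 - layer * top_frac)))
        mask |= (r >= q) & (r > local_mean + layer * offset)
    mask &= fov
    return VesselMask(mask=mask, source="normal_path")


_FOV_RIM = 6    # rim band (px) excluded from thresholding


def _threshold_path(enhanced: np.ndarray, fov: np.ndarray,
                    params: GaborBankParams, source: str,
                    levels: int, local_window: int, offset: float,
                    top_frac: float) -> VesselMask:
    resp = orientation_max(enhanced, params)
    inner = _erode_fov(fov, _FOV_RIM)
    if not inner.any():
        inner = fov.astype(bool)
    norm = _normalize(resp.m_psi, inner)
    vm = multilayer_threshold(norm, inner, levels=levels,
                              local_window=local_window, offset=offset,
                              top_frac=top_frac)
    return VesselMask(mask=vm.mask, source=source)


def normal_vessel_path(pre: PreprocessedImage, params_normal: GaborBankParams,
                       levels: int = 3, local_window: int = 25,
                       offset: float = 0.03, top_frac: float = 0.02) -> VesselMask:
    """Principal-vasculature mask: 3x3 Gaussian blur, coarse elongated Gabor."""
    filled = fov_extend(pre.green_inv, pre.fov_mask)
    # sigma 1.0 truncated at one sigma gives a 3x3 support
    blurred = ndimage.gaussian_filter(filled, sigma=1.0, truncate=1.0)
    return _threshold_path(blurred, pre.fov_mask, params_normal, "normal_path",
                           levels, local_window, offset, top_frac)


def detail_vessel_path(pre: PreprocessedImage, params_detail: GaborBankParams,
                       levels: int = 3, local_window: int = 25,
                       offset: float = 0.03, top_frac: float = 0.02) -> VesselMask:
    """Fine-detail mask: 3x3 unsharp sharpening, fine isotropic Gabor."""
    filled = fov_extend(pre.green_inv, pre.fov_mask)
    sharp = ndimage.convolve(filled, _SHARPEN, mode="reflect")
    return _threshold_path(sharp, pre.fov_mask, params_detail, "detail_path",
                           levels, local_window, offset, top_frac)


def _disc(r: int) -> np.ndarray:
    yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= r * r


def clean_normal_mask(normal: VesselMask, min_component: int = 200,
                      close_radius: int = 2,
                      min_extent: float = 100.0) -> VesselMask:
    """Morphological cleanup of the principal-vessel mask before subtraction.

    The principal vasculature forms large connected runs spanning a good
    fraction of the field, so components are kept only when both big
    enough (area >= ``min_component``) and extended enough (bounding
    diagonal >= ``min_extent``).  Small blobs are speckle; *compact* big
    blobs are dense fine structure (e.g. a neovascular cluster) that the
    coarse path caught and that must not be subtracted from the candidate
    map.  Remaining gaps along vessels are bridged by a closing so the
    guard dilation covers the tree contiguously.
    """
    mask = normal.mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n:
        keep = np.zeros(n + 1, dtype=bool)
        for lab in range(1, n + 1):
            rows, cols = np.nonzero(labels == lab)
            if rows.size < min_component:
                continue
            extent = np.hypot(int(rows.max()) - int(rows.min()),
                              int(cols.max()) - int(cols.min()))
            keep[lab] = extent >= min_extent
        mask = keep[labels]
    if close_radius > 0:
        mask = ndimage.binary_closing(mask, structure=_disc(close_radius))
    return VesselMask(mask=mask, source="normal_path")


def cluster_gate(candidate: VesselMask | np.ndarray, radius: int = 12,
                 min_count: int = 65, merge_radius: int = 3) -> np.ndarray:
    """Keep candidate pixels that sit inside dense pixel clusters.

    A neovascular tuft is a dense cluster of strokes, so each of its pixels
    has many candidate neighbors within ``radius``; scattered noise and
    thin subtraction halos do not.  Surviving cores are merged by a small
    closing so that one tuft labels as one region.
    """
    mask = candidate.mask if isinstance(candidate, VesselMask) else candidate
    density = ndimage.convolve(mask.astype(np.float64),
                               _disc(radius).astype(np.float64),
                               mode="constant")
    gated = mask & (density >= min_count)
    if merge_radius > 0:
        gated = ndimage.binary_closing(gated, structure=_disc(merge_radius))
    return gated


def candidate_map(detail: VesselMask, normal: VesselMask,
                  guard_radius: int = 3) -> VesselMask:
    """Subtract the (dilated) normal-vessel mask from the detail mask.

    The guard dilation removes the 1-px halos that raw binary subtraction
    leaves along wide vessels; what survives are abnormal-vessel and
    exudate pixels.
    """
    if detail.mask.shape != normal.mask.shape:
        raise ValueError("detail and normal masks have different dimensions")
    if guard_radius > 0:
        guard = ndimage.binary_dilation(normal.mask, structure=_disc(guard_radius))
    else:
        guard = normal.mask
    return VesselMask(mask=detail.mask & ~guard, source="candidate")
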