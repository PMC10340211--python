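"""Candidate regions: connected components, moments, analysis windows.

A candidate region is an 8-connected component of the abnormal-vessel
candidate map.  Its area is the 0th moment A = sum of the indicator over
the component, and its centroid is the first moment
(x_bar, y_bar) = (sum x L / A, sum y L / A); small components below
``min_area`` are speckle and dropped.  Each region is assigned to the NVD
or NVE zone by which zone mask contains its centroid, and carries two
analysis windows: a fixed-size window for the first threshold layer
(larger for NVD, where neovascular bunches sprawl) and an adaptive window
(bounding box padded by 20% per side) for the second layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .vessels import VesselMask

__all__ = ["CandidateRegion", "label_candidates", "fixed_window", "adaptive_window"]

Window = tuple[int, int, int, int]   # (row0, col0, row1, col1), half-open


@dataclass
class CandidateRegion:
    label_id: int
    rows: np.ndarray                    # pixel coordinates (row)
    cols: np.ndarray                    # pixel coordinates (col)
    area: int
    centroid: tuple[float, float]       # (row, col)
    zone: str                           # "NVD" | "NVE"
    elongation: float = 1.0             # principal-axis ratio (>= 1)
    window: Window | None = None        # fixed layer-1 window
    features: dict[str, float] = field(default_factory=dict)
    layer1_pass: bool | None = None
    layer2_pass: bool | None = None

    def distance_to(self, point: tuple[float, float],
                    mode: str = "centroid") -> float:
        """Euclidean distance from a point to the region (centroid or nearest px)."""
        if mode == "centroid":
            return float(np.hypot(self.centroid[0] - point[0],
                                  self.centroid[1] - point[1]))
        if mode == "nearest":
            d = np.hypot(self.rows - point[0], self.cols - point[1])
            return float(d.min())
        raise ValueError(f"unknown distance mode {mode!r}")


def _clip_window(center: tuple[float, float], size: int,
                 shape: tuple[int, int]) -> Window:
    half = size // 2
    r = int(round(center[0]))
    c = int(round(center[1]))
    r0 = max(0, r - half)
    c0 = max(0, c - half)
    r1 = min(shape[0], r + half + 1)
    c1 = min(shape[1], c + half + 1)
    return (r0, c0, r1, c1)


def fixed_window(region: CandidateRegion, size: int,
                 shape: tuple[int, int]) -> Window:
    """Fixed-size square window centered on the region centroid, clipped."""
    return _clip_window(region.centroid, size, shape)


def adaptive_window(region: CandidateRegion, shape: tuple[int, int],
                    pad_frac: float = 0.2) -> Window:
    """Bounding box of the region padded by ``pad_frac`` per side, clipped."""
    r0, r1 = int(region.rows.min()), int(region.rows.max()) + 1
    c0, c1 = int(region.cols.min()), int(region.cols.max()) + 1
    pr = max(1, int(round((r1 - r0) * pad_frac)))
    pc = max(1, int(round((c1 - c0) * pad_frac)))
    return (max(0, r0 - pr), max(0, c0 - pc),
            min(shape[0], r1 + pr), min(shape[1], c1 + pc))


def _elongation(rows: np.ndarray, cols: np.ndarray) -> float:
    """Principal-axis length ratio from second central moments (>= 1).

    Near 1 for compact blobs (neovascular tufts); large for thin strips
    (residue of under-subtracted vessel segments).
    """
    if rows.size < 3:
        return 1.0
    cov = np.cov(np.stack([rows.astype(float), cols.astype(float)]))
    ev = np.linalg.eigvalsh(cov)
    return float(np.sqrt(max(ev[1], 1e-9) / max(ev[0], 1e-9)))


def label_candidates(candidate: VesselMask | np.ndarray,
                     zone_masks: tuple[np.ndarray, np.ndarray],
                     min_area: int = 30,
                     window_sizes: dict[str, int] | None = None,
                     max_elongation: float | None = None,
                     ) -> list[CandidateRegion]:
    """Extract 8-connected candidate regions with moments and zones.

    Object classification by moments: components below ``min_area`` (0th
    moment) are speckle; components more elongated than ``max_elongation``
    (second-moment axis ratio) are vessel-shaped residue rather than tuft
    candidates.  ``zone_masks`` is (nvd_mask, nve_mask); regions whose
    rounded centroid falls in neither mask (outside the FOV) default to the
    zone containing the majority of their pixels.
    """
    mask = candidate.mask if isinstance(candidate, VesselMask) else candidate
    mask = mask.astype(bool)
    nvd_mask, nve_mask = zone_masks
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    regions: list[CandidateRegion] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        area = int(rows.size)
        if area < min_area:
            continue
        elong = _elongation(rows, cols)
        if max_elongation is not None and elong > max_elongation:
            continue
        centroid = (float(rows.mean()), float(cols.mean()))
        ri, ci = int(round(centroid[0])), int(round(centroid[1]))
        ri = min(max(ri, 0), mask.shape[0] - 1)
        ci = min(max(ci, 0), mask.shape[1] - 1)
        if nvd_mask[ri, ci]:
            zone = "NVD"
        elif nve_mask[ri, ci]:
            zone = "NVE"
        else:
            zone = "NVD" if nvd_mask[rows, cols].sum() >= nve_mask[rows, cols].sum() \
                else "NVE"
        region = CandidateRegion(label_id=len(regions) + 1, rows=rows, cols=cols,
                                 area=area, centroid=centroid, zone=zone,
                                 elongation=elong)
        if window_sizes is not None:
            region.window = fixed_window(region, window_sizes[zone], mask.shape)
        regions.append(region)
    return regions
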