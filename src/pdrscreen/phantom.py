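"""Seeded synthetic fundus phantoms with per-pixel ground truth.

A phantom emulates the features the screening pipeline actually exploits:
a dark red-brown retinal field with radial illumination falloff inside a
circular field of view, noisy near-black camera background outside it, a
bright yellowish optic disc, a branching tree of wide smooth vessels that
are dark in the green plane, optional bright exudate blobs, and optional
neovascular tufts — dense clusters of short tortuous 1-2 px strokes at
60% of the main-vessel contrast — planted at controlled distances from
the disc.  It does not attempt photorealism (no hemorrhages, drusen, or
camera optics), so passing tests demonstrate recovery of planted
structure, not clinical performance.

Every phantom is a pure function of its spec: the same spec yields a
byte-identical image and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .optic_disc import OpticDisc, one_disc_distance
from .preprocess import FundusImage

__all__ = ["NVLesion", "PhantomSpec", "PhantomTruth", "generate_phantom",
           "generate_cohort"]


@dataclass(frozen=True)
class NVLesion:
    """A neovascular tuft: ``distance`` is in units of one disc distance."""

    distance: float
    radius: float = 22.0
    n_strokes: int = 28
    stroke_width: float = 1.2

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("lesion distance must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    size: tuple[int, int] = (480, 720)          # (height, width)
    od_center: tuple[float, float] | None = None  # default: nasal-side placement
    od_diameter: float = 64.0
    n_main_vessels: int = 6
    vessel_width_range: tuple[float, float] = (4.0, 6.5)
    nv_lesions: tuple[NVLesion, ...] = ()
    n_exudates: int = 0
    noise_sigma: float = 2.5
    illumination_gradient: float = 0.25


@dataclass(frozen=True)
class PhantomTruth:
    vessel_mask: np.ndarray
    nv_mask: np.ndarray
    exudate_mask: np.ndarray
    fov_mask: np.ndarray
    od: OpticDisc
    expected_grades: frozenset[int]
    nv_centers: tuple[tuple[float, float], ...] = ()


def _stamp_disk(mask: np.ndarray, center: tuple[float, float], radius: float) -> None:
    h, w = mask.shape
    r0 = max(0, int(np.floor(center[0] - radius)))
    r1 = min(h, int(np.ceil(center[0] + radius)) + 1)
    c0 = max(0, int(np.floor(center[1] - radius)))
    c1 = min(w, int(np.ceil(center[1] + radius)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    sel = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius * radius
    mask[r0:r1, c0:c1][sel] = True


def _walk(mask: np.ndarray, rng: np.random.Generator,
          start: tuple[float, float], angle: float, length: float,
          width: float, fov_center: tuple[float, float], fov_radius: float,
          jitter_deg: float = 10.0, curvature: float = 0.0,
          level: int = 0, max_level: int = 2,
          branch_width_decay: float = 0.7) -> None:
    """Stamp a random-walk vessel stroke with recursive branching."""
    pos = np.array(start, dtype=float)
    step = 1.5
    n_steps = max(1, int(length / step))
    branch_at = set()
    if level < max_level and n_steps > 8:
        n_branches = int(rng.integers(1, 3))
        branch_at = {int(v) for v in
                     rng.integers(n_steps // 3, n_steps, size=n_branches)}
    for i in range(n_steps):
        angle += np.deg2rad(rng.normal(0.0, jitter_deg)) + curvature
        pos = pos + step * np.array([np.sin(angle), np.cos(angle)])
        if np.hypot(pos[0] - fov_center[0], pos[1] - fov_center[1]) > fov_radius - 4:
            return
        _stamp_disk(mask, (pos[0], pos[1]), max(width / 2.0, 0.6))
        if i in branch_at:
            sign = 1 if rng.random() < 0.5 else -1
            _walk(mask, rng, (pos[0], pos[1]),
                  angle + sign * np.deg2rad(rng.uniform(25, 45)),
                  length * 0.55, width * branch_width_decay,
                  fov_center, fov_radius, jitter_deg, curvature,
                  level + 1, max_level, branch_width_decay)
        width *= 0.998   # gentle taper along the trunk


def generate_phantom(spec: PhantomSpec) -> tuple[FundusImage, PhantomTruth]:
    """Render a phantom fundus image and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    fov_center = (h / 2.0, w / 2.0)
    fov_radius = 0.48 * min(h, w * 2 / 3)      # circle roughly filling the height
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dist_center = np.hypot(yy - fov_center[0], xx - fov_center[1])
    fov = dist_center <= fov_radius

    od_center = spec.od_center
    if od_center is None:
        od_center = (fov_center[0], fov_center[1] - 0.55 * fov_radius)
    od_r = spec.od_diameter / 2.0
    one_dd = one_disc_distance(spec.od_diameter)

    # --- background field with radial falloff and low-frequency mottling ---
    falloff = 1.0 - spec.illumination_gradient * (dist_center / fov_radius) ** 2
    mottle = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=25) * 18
    red = 120.0 * falloff + mottle
    green = 70.0 * falloff + mottle * 0.7
    blue = 30.0 * falloff + mottle * 0.3

    # --- main vessel tree from the disc rim -------------------------------
    vessel_mask = np.zeros((h, w), dtype=bool)
    base_angles = np.linspace(0, 2 * np.pi, spec.n_main_vessels, endpoint=False)
    for base in base_angles:
        ang = base + rng.normal(0.0, 0.25)
        start = (od_center[0] + od_r * np.sin(ang),
                 od_center[1] + od_r * np.cos(ang))
        width = rng.uniform(*spec.vessel_width_range)
        curvature = rng.normal(0.0, 0.004)
        _walk(vessel_mask, rng, start, ang,
              length=rng.uniform(0.8, 1.4) * fov_radius, width=width,
              fov_center=fov_center, fov_radius=fov_radius,
              jitter_deg=3.0, curvature=curvature)
    vessel_depth = np.clip(
        ndimage.gaussian_filter(vessel_mask.astype(np.float64), 0.8), 0, 1)
    red -= 30.0 * vessel_depth
    green -= 48.0 * vessel_depth
    blue -= 12.0 * vessel_depth

    # --- optic disc (alpha-blended so crossing vessels stay visible) -------
    od_profile = np.clip((od_r - np.hypot(yy - od_center[0], xx - od_center[1]))
                         / 2.5, 0, 1)           # soft 2.5-px rim
    alpha = 0.8 * od_profile
    red = red * (1 - alpha) + 235.0 * alpha
    green = green * (1 - alpha) + 190.0 * alpha
    blue = blue * (1 - alpha) + 110.0 * alpha

    # --- neovascular tufts: tortuous fine strokes at 60% vessel contrast ---
    nv_mask = np.zeros((h, w), dtype=bool)
    nv_centers = []
    for lesion in spec.nv_lesions:
        d_px = lesion.distance * one_dd
        placed = False
        for _ in range(60):
            ang = rng.uniform(0, 2 * np.pi)
            center = (od_center[0] + d_px * np.sin(ang),
                      od_center[1] + d_px * np.cos(ang))
            if (np.hypot(center[0] - fov_center[0], center[1] - fov_center[1])
                    + lesion.radius < fov_radius - 8):
                placed = True
                break
        if not placed:
            raise ValueError(
                f"nv lesion at {lesion.distance:.2f} x 1dd cannot be placed "
                "inside the field of view")
        nv_centers.append(center)
        for _ in range(lesion.n_strokes):
            r = lesion.radius * np.sqrt(rng.random()) * 0.85
            a = rng.uniform(0, 2 * np.pi)
            start = (center[0] + r * np.sin(a), center[1] + r * np.cos(a))
            _walk(nv_mask, rng, start, rng.uniform(0, 2 * np.pi),
                  length=rng.uniform(0.5, 1.0) * lesion.radius,
                  width=lesion.stroke_width, fov_center=fov_center,
                  fov_radius=fov_radius, jitter_deg=30.0, max_level=0)
    nv_depth = np.clip(
        ndimage.gaussian_filter(nv_mask.astype(np.float64), 0.6), 0, 1)
    red -= 18.0 * nv_depth
    green -= 29.0 * nv_depth        # 60% of the main-vessel green contrast
    blue -= 8.0 * nv_depth

    # --- exudates: small sharp bright blobs away from the disc -------------
    exudate_mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_exudates):
        for _ in range(60):
            er = rng.uniform(3.0, 7.0)
            c = (rng.uniform(fov_center[0] - fov_radius, fov_center[0] + fov_radius),
                 rng.uniform(fov_center[1] - fov_radius, fov_center[1] + fov_radius))
            far_in_fov = (np.hypot(c[0] - fov_center[0], c[1] - fov_center[1])
                          + er < fov_radius - 10)
            off_disc = np.hypot(c[0] - od_center[0], c[1] - od_center[1]) > od_r + 15
            if far_in_fov and off_disc:
                break
        else:
            continue
        _stamp_disk(exudate_mask, c, er)
    ex_depth = np.clip(
        ndimage.gaussian_filter(exudate_mask.astype(np.float64), 0.7), 0, 1)
    red = red * (1 - ex_depth) + 245.0 * ex_depth
    green = green * (1 - ex_depth) + 215.0 * ex_depth
    blue = blue * (1 - ex_depth) + 90.0 * ex_depth

    # --- camera background: near-black with border noise and specks --------
    bg_noise = rng.normal(0.0, 3.0, (h, w))
    red[~fov] = 9.0 + bg_noise[~fov]
    green[~fov] = 7.0 + bg_noise[~fov]
    blue[~fov] = 6.0 + bg_noise[~fov]
    n_specks = int(rng.integers(3, 9))
    for _ in range(n_specks):
        ang = rng.uniform(0, 2 * np.pi)
        rr = rng.uniform(fov_radius + 8, fov_radius * 1.15)
        c = (fov_center[0] + rr * np.sin(ang), fov_center[1] + rr * np.cos(ang))
        if 0 <= c[0] < h and 0 <= c[1] < w:
            speck = np.zeros((h, w), dtype=bool)
            _stamp_disk(speck, c, rng.uniform(0.8, 1.6))
            speck &= ~fov
            green[speck] += rng.uniform(25, 60)
            red[speck] += rng.uniform(25, 60)

    # --- sensor noise, quantization ----------------------------------------
    noise = rng.normal(0.0, spec.noise_sigma, (h, w, 3))
    rgb = np.stack([red, green, blue], axis=-1) + noise
    pixels = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    grades: set[int] = set()
    for lesion in spec.nv_lesions:
        grades.add(2 if lesion.distance <= 1.0 else 1)
    if not grades:
        grades = {0}
    truth = PhantomTruth(
        vessel_mask=vessel_mask & fov, nv_mask=nv_mask & fov,
        exudate_mask=exudate_mask & fov, fov_mask=fov,
        od=OpticDisc(center=od_center, diameter_d=spec.od_diameter,
                     one_dd=one_dd),
        expected_grades=frozenset(grades),
        nv_centers=tuple(nv_centers))
    return FundusImage(pixels=pixels, source_path=f"<phantom seed={spec.seed}>"), truth


def _allocate(n: int, mix: tuple[float, float, float, float]) -> list[str]:
    """Deterministic proportional label allocation (largest-remainder rule)."""
    if not np.isclose(sum(mix), 1.0):
        raise ValueError(f"mix must sum to 1, got {sum(mix)}")
    labels = ("healthy", "NVD", "NVE", "both")
    exact = [n * m for m in mix]
    counts = [int(np.floor(e)) for e in exact]
    rem = n - sum(counts)
    order = sorted(range(4), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    out: list[str] = []
    for lab, c in zip(labels, counts):
        out.extend([lab] * c)
    return out


def generate_cohort(n: int, seed: int,
                    mix: tuple[float, float, float, float] = (0.4, 0.3, 0.3, 0.0),
                    ) -> list[tuple[FundusImage, PhantomTruth]]:
    """Generate ``n`` phantoms with class labels drawn per ``mix``.

    ``mix`` gives the fractions of healthy / NVD / NVE / both-grade
    phantoms.  Each phantom's RNG stream derives from (seed, index), so
    cohorts are reproducible and embarrassingly parallel.  Per-phantom
    specs are jittered: OD position/diameter, vessel count and widths,
    lesion geometry, exudate count.
    """
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    labels = _allocate(n, mix)
    out = []
    for i, label in enumerate(labels):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        h, w = 480, 720
        fov_radius = 0.48 * h
        side = -1 if rng.random() < 0.5 else 1
        od_center = (h / 2 + rng.uniform(-25, 25),
                     w / 2 + side * rng.uniform(0.45, 0.62) * fov_radius)
        lesions: list[NVLesion] = []
        if label in ("NVD", "both"):
            lesions.append(NVLesion(
                distance=rng.uniform(0.3, 0.8),
                radius=rng.uniform(18, 26),
                n_strokes=int(rng.integers(22, 34)),
                stroke_width=rng.uniform(1.0, 1.5)))
        if label in ("NVE", "both"):
            lesions.append(NVLesion(
                distance=rng.uniform(1.4, 2.1),
                radius=rng.uniform(18, 26),
                n_strokes=int(rng.integers(22, 34)),
                stroke_width=rng.uniform(1.0, 1.5)))
        spec = PhantomSpec(
            seed=int(rng.integers(2**31)),
            od_center=od_center,
            od_diameter=rng.uniform(56, 72),
            n_main_vessels=int(rng.integers(5, 8)),
            nv_lesions=tuple(lesions),
            n_exudates=int(rng.integers(0, 3)),
        )
        out.append(generate_phantom(spec))
    return out
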