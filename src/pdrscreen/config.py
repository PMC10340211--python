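"""Pipeline configuration: every tunable constant in one serializable place.

All geometric constants (window sizes, radii, areas) are expressed in pixels
at the working scale (default 720 px wide).  The Gabor dilation values are
stored at their reference scale and rescaled to the working width at run
time, so the same config grades images of different resolutions coherently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = ["GaborPathConfig", "PipelineConfig", "load_config", "default_bands"]


@dataclass(frozen=True)
class GaborPathConfig:
    """Gabor wavelet parameters for one filter-bank path (normal or detail).

    ``dilation`` is the wavelet scale *a* at ``reference_width``; ``elongation``
    is the anisotropy ε ≥ 1 of the Gaussian envelope (1 = isotropic);
    ``k0_mag`` is the carrier-frequency magnitude |k0| in radians/pixel, with
    the carrier vector taken as (0, |k0|) before rotation.
    """

    dilation: float
    elongation: float
    k0_mag: float

    def __post_init__(self) -> None:
        if self.elongation < 1:
            raise ValueError(f"elongation must be >= 1, got {self.elongation}")
        if self.k0_mag <= 0:
            raise ValueError(f"|k0| must be > 0, got {self.k0_mag}")
        if self.dilation <= 0:
            raise ValueError(f"dilation must be > 0, got {self.dilation}")


def _theta_grid(step: float = 10.0, stop: float = 180.0) -> tuple[float, ...]:
    n = int(round(stop / step))
    return tuple(i * step for i in range(n))


@dataclass(frozen=True)
class PipelineConfig:
    # -- geometry / preprocessing -------------------------------------------
    working_width: int = 720
    reference_width: int = 1440      # scale at which gabor dilations are quoted
    mask_window: int = 15            # local mean/variance window for FOV mask
    mask_mean_frac: float = 0.5      # keep pixels whose local mean > frac * global
    mask_var_frac: float = 0.5
    mask_open_radius: int = 3

    # -- gabor filter banks (normal = principal vessels, detail = fine) ------
    # Normal-path parameters follow the published fundus-screening values at
    # reference scale; the detail-path dilations are re-tuned on phantoms
    # (fine scales below ~1.5 px effective are sensor-noise limited).
    nvd_normal: GaborPathConfig = field(
        default_factory=lambda: GaborPathConfig(11.0, 5.0, 2.5))
    nvd_detail: GaborPathConfig = field(
        default_factory=lambda: GaborPathConfig(4.0, 1.0, 2.5))
    nve_normal: GaborPathConfig = field(
        default_factory=lambda: GaborPathConfig(7.0, 10.0, 2.5))
    nve_detail: GaborPathConfig = field(
        default_factory=lambda: GaborPathConfig(4.0, 1.0, 2.5))
    theta_step: float = 10.0

    # -- multilayered / adaptive thresholding --------------------------------
    threshold_levels: int = 3
    threshold_window: int = 25
    normal_top_frac: float = 0.05      # layer l keeps the top l*frac quantile
    normal_offset: float = 0.01        # layer l local-mean offset = l*offset
    detail_top_frac: float = 0.04
    detail_offset: float = 0.01
    normal_min_component: int = 200    # drop smaller blobs from the normal mask
    normal_close_radius: int = 2       # bridge gaps along vessels before guarding
    guard_radius: int = 3              # dilation of normal mask before subtraction

    # -- optic disc localization --------------------------------------------
    od_lowpass_frac: float = 0.02      # keep lowest 2% of frequency radius
    od_bright_quantile: float = 0.99
    od_close_radius: int = 4
    od_min_area: int = 80
    od_max_candidates: int = 8
    od_expected_diameter: float = 64.0  # px at working scale
    od_window_factor: float = 1.4       # vessel-energy window side = f * expected D
    od_exclusion_margin: float = 5.0    # rim band beyond D/2 excluded from
                                        # the candidate map (bright-edge artifact)

    # -- candidate regions / features ----------------------------------------
    density_radius: int = 12       # cluster gate: neighborhood radius (px)
    density_count: int = 40        # ... and required candidate-pixel count
    merge_radius: int = 3          # closing that joins one tuft into one region
    min_area: int = 30
    max_elongation: float = 3.5   # axis ratio above which a component is
                                  # vessel-shaped residue, not a tuft
    max_parent_extent: float = 300.0  # detail-mask component span (px) above
                                      # which a region is vessel-network residue
    nvd_window: int = 101              # fixed layer-1 analysis window (NVD)
    nve_window: int = 51               # fixed layer-1 analysis window (NVE)
    adaptive_pad_frac: float = 0.2     # layer-2 window = bbox padded 20%/side
    entropy_bins: int = 32
    glcm_levels: int = 32
    glcm_offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

    # -- double-layered thresholds -------------------------------------------
    # bands: {"NVD"|"NVE": {feature: [lower, upper]}}
    layer1_bands: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    layer2_bands: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    box_overlap_flag: float = 0.5      # IQR-box overlap above which a feature is
                                       # flagged non-discriminative in calibration

    # -- grading / evaluation --------------------------------------------------
    distance_mode: str = "nearest"     # nearest | centroid
    overlap_frac: float = 0.2          # TP overlap threshold (region-level eval)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        """Deterministic hash of the fully resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @property
    def theta_grid(self) -> tuple[float, ...]:
        return _theta_grid(self.theta_step)

    def scaled(self, path: GaborPathConfig) -> GaborPathConfig:
        """Rescale a Gabor path's dilation from reference to working width."""
        factor = self.working_width / self.reference_width
        return replace(path, dilation=path.dilation * factor)


def _from_dict(d: dict[str, Any]) -> PipelineConfig:
    d = dict(d)
    for key in ("nvd_normal", "nvd_detail", "nve_normal", "nve_detail"):
        if key in d and isinstance(d[key], dict):
            d[key] = GaborPathConfig(**d[key])
    if "glcm_offsets" in d:
        d["glcm_offsets"] = tuple(tuple(o) for o in d["glcm_offsets"])
    return PipelineConfig(**d)


def default_bands() -> dict[str, dict[str, dict[str, list[float]]]]:
    """Packaged threshold bands calibrated on the synthetic phantom cohort."""
    text = resources.files("pdrscreen.data").joinpath("default_bands.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a config from YAML, filling unspecified keys with defaults.

    With no path, returns the packaged defaults (including phantom-calibrated
    threshold bands).
    """
    if path is None:
        bands = default_bands()
        return _from_dict(
            {"layer1_bands": bands["layer1"], "layer2_bands": bands["layer2"]})
    data = yaml.safe_load(Path(path).read_text()) or {}
    base = load_config(None).to_dict()
    base.update(data)
    return _from_dict(base)
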