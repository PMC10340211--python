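"""End-to-end orchestration: image in, grade report and artifacts out.

Stage order: preprocess -> dual-path vessel maps (one filter-bank pair per
zone) -> candidate map -> optic disc -> zone masks -> region extraction ->
layer-1 feature thresholds -> layer-2 feature thresholds -> grading.  Every
report embeds the hash of the fully resolved configuration, so identical
input + config reproduce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import PipelineConfig, load_config
from .features import (LAYER1_FEATURES, LAYER2_FEATURES, bands_from_config,
                       layer1_features, layer1_filter, layer2_filter,
                       postproc_features)
from .gabor import GaborBankParams
from .grading import GradeReport, grade_image
from .optic_disc import OpticDisc, build_zone_masks, od_candidate_regions, select_od
from .preprocess import FundusImage, PreprocessedImage, load_image, preprocess
from .regions import CandidateRegion, label_candidates
from .vessels import (VesselMask, candidate_map, clean_normal_mask,
                      cluster_gate, detail_vessel_path, normal_vessel_path)

logger = logging.getLogger("pdrscreen")

__all__ = ["PipelineResult", "run_pipeline", "extract_candidates"]


@dataclass
class PipelineResult:
    report: GradeReport
    pre: PreprocessedImage
    normal_masks: dict[str, VesselMask]     # per zone params ("NVD"/"NVE")
    candidate_masks: dict[str, VesselMask]
    od: OpticDisc | None
    zone_masks: tuple[np.ndarray, np.ndarray] | None
    regions: list[CandidateRegion]          # all labeled regions with flags
    survivors: list[CandidateRegion]        # post-layer-2
    config: PipelineConfig = field(repr=False)

    def to_json_dict(self) -> dict:
        od = None
        if self.od is not None:
            od = {"center": [round(c, 2) for c in self.od.center],
                  "diameter_d": round(self.od.diameter_d, 2),
                  "one_dd": round(self.od.one_dd, 2),
                  "energy": self.od.energy}
        return {
            "status": self.report.status,
            "grades": sorted(self.report.grades),
            "od": od,
            "regions": [
                {"label_id": r.label_id, "zone": r.zone, "area": r.area,
                 "centroid": [round(c, 2) for c in r.centroid],
                 "layer1_pass": r.layer1_pass, "layer2_pass": r.layer2_pass}
                for r in self.regions],
            "config_hash": self.config.config_hash(),
        }

    def region_table(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            row = {"label_id": r.label_id, "zone": r.zone, "area": r.area,
                   "centroid_row": r.centroid[0], "centroid_col": r.centroid[1],
                   "layer1_pass": r.layer1_pass, "layer2_pass": r.layer2_pass}
            row.update(r.features)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_artifacts(self, out_dir: str | Path,
                        save_intermediates: bool = False) -> None:
        from .preprocess import save_image
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, sort_keys=True))
        self.region_table().to_csv(out / "regions.csv", index=False)
        if save_intermediates:
            save_image(self.pre.fov_mask, out / "fov_mask.png")
            save_image(self.pre.green_inv, out / "green_inv.png")
            for zone, vm in self.candidate_masks.items():
                save_image(vm.mask, out / f"candidate_{zone.lower()}.png")


def _bank(cfg: PipelineConfig, path_cfg) -> GaborBankParams:
    return GaborBankParams.from_path_config(cfg.scaled(path_cfg),
                                            thetas=cfg.theta_grid)


def extract_candidates(pre: PreprocessedImage, cfg: PipelineConfig,
                       return_details: bool = False):
    """Dual-path vessel maps and candidate maps for both zone parameter sets.

    Returns ``(normals, candidates)`` or, with ``return_details``,
    ``(normals, candidates, details)`` where each is a per-zone dict of
    VesselMask.
    """
    kw_norm = dict(levels=cfg.threshold_levels, local_window=cfg.threshold_window,
                   offset=cfg.normal_offset, top_frac=cfg.normal_top_frac)
    kw_det = dict(levels=cfg.threshold_levels, local_window=cfg.threshold_window,
                  offset=cfg.detail_offset, top_frac=cfg.detail_top_frac)
    t0 = time.perf_counter()
    normals: dict[str, VesselMask] = {}
    details: dict[str, VesselMask] = {}
    cache: dict[tuple, VesselMask] = {}
    for zone, p_norm, p_det in (("NVD", cfg.nvd_normal, cfg.nvd_detail),
                                ("NVE", cfg.nve_normal, cfg.nve_detail)):
        key_n = ("normal", p_norm)
        if key_n not in cache:
            cache[key_n] = clean_normal_mask(
                normal_vessel_path(pre, _bank(cfg, p_norm), **kw_norm),
                cfg.normal_min_component, cfg.normal_close_radius)
        normals[zone] = cache[key_n]
        key_d = ("detail", p_det)
        if key_d not in cache:
            cache[key_d] = detail_vessel_path(pre, _bank(cfg, p_det), **kw_det)
        details[zone] = cache[key_d]
    # both normal banks enhance the same principal vasculature; their union
    # is the strongest available evidence of what to subtract
    guard_union = VesselMask(mask=normals["NVD"].mask | normals["NVE"].mask,
                             source="normal_path")
    candidates = {zone: candidate_map(details[zone], guard_union,
                                      cfg.guard_radius)
                  for zone in ("NVD", "NVE")}
    logger.info("candidate maps: %.2fs", time.perf_counter() - t0)
    if return_details:
        return normals, candidates, details
    return normals, candidates


def prune_network_regions(regions: list[CandidateRegion],
                          detail_mask: np.ndarray,
                          max_extent: float) -> list[CandidateRegion]:
    """Drop regions that belong to a sprawling detail-mask component.

    A candidate region is looked up in the connected components of the
    detail-path mask (which sees all vasculature).  Components spanning
    more than ``max_extent`` pixels diagonally are thin-vessel networks
    whose junctions and tips survive subtraction; genuine tufts form
    compact components.
    """
    if not regions:
        return regions
    labels, _ = ndimage.label(detail_mask, structure=np.ones((3, 3)))
    kept = []
    for reg in regions:
        if reg.zone == "NVD":
            # on-disc neovascularization grows among the converging
            # vasculature, so network membership is not evidence against it
            kept.append(reg)
            continue
        labs = labels[reg.rows, reg.cols]
        labs = labs[labs > 0]
        if labs.size:
            parent = int(np.bincount(labs).argmax())
            rr, cc = np.nonzero(labels == parent)
            extent = float(np.hypot(int(rr.max()) - int(rr.min()),
                                    int(cc.max()) - int(cc.min())))
            if extent > max_extent:
                continue
        kept.append(reg)
    for i, reg in enumerate(kept):
        reg.label_id = i + 1
    return kept


def run_pipeline(image: str | Path | FundusImage,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full grading pipeline on one fundus image."""
    cfg = config or load_config()
    img = load_image(image) if not isinstance(image, FundusImage) else image

    t0 = time.perf_counter()
    pre = preprocess(img, cfg)
    logger.info("preprocess: %.2fs", time.perf_counter() - t0)

    normals, candidates, details = extract_candidates(pre, cfg,
                                                      return_details=True)

    # optic disc: brightness candidates disambiguated by vessel convergence
    od: OpticDisc | None
    try:
        od_cands = od_candidate_regions(pre, cfg)
        od = select_od(od_cands, normals["NVD"], cfg)
    except ValueError as exc:
        logger.warning("optic disc stage: %s", exc)
        od = None
    if od is None:
        report = grade_image([], None)
        return PipelineResult(report=report, pre=pre, normal_masks=normals,
                              candidate_masks=candidates, od=None,
                              zone_masks=None, regions=[], survivors=[],
                              config=cfg)

    zones = build_zone_masks(od, pre.fov_mask)

    # combine zone-specific candidate maps inside their own zones, then
    # keep only dense pixel clusters (tufts), merged one-per-lesion
    combined = (candidates["NVD"].mask & zones[0]) | \
               (candidates["NVE"].mask & zones[1])
    # the bright disc rim fires the detail filter but is in no vessel
    # guard; exclude the disc surface and its rim from candidates
    h, w = combined.shape
    dist_od = np.hypot(np.arange(h)[:, None] - od.center[0],
                       np.arange(w)[None, :] - od.center[1])
    combined &= dist_od > (0.5 * od.diameter_d + cfg.od_exclusion_margin)
    gated = cluster_gate(combined, cfg.density_radius, cfg.density_count,
                         cfg.merge_radius)
    window_sizes = {"NVD": cfg.nvd_window, "NVE": cfg.nve_window}
    regions = label_candidates(gated, zones, min_area=cfg.min_area,
                               window_sizes=window_sizes,
                               max_elongation=cfg.max_elongation)
    regions = prune_network_regions(
        regions, details["NVD"].mask | details["NVE"].mask,
        cfg.max_parent_extent)

    green_inv8 = np.zeros_like(pre.image.green)
    green_inv8[pre.fov_mask] = 255 - pre.image.green[pre.fov_mask]
    for reg in regions:
        reg.features.update(layer1_features(reg, green_inv8, cfg.entropy_bins,
                                            cfg.glcm_offsets))
    survivors1: list[CandidateRegion] = []
    for zone in ("NVD", "NVE"):
        zone_regs = [r for r in regions if r.zone == zone]
        bands = bands_from_config(cfg.layer1_bands, zone)
        survivors1.extend(layer1_filter(zone_regs, bands, zone))

    for reg in survivors1:
        reg.features.update(postproc_features(reg, pre.image,
                                              cfg.adaptive_pad_frac,
                                              cfg.entropy_bins))
    survivors2: list[CandidateRegion] = []
    for zone in ("NVD", "NVE"):
        zone_regs = [r for r in survivors1 if r.zone == zone]
        bands = bands_from_config(cfg.layer2_bands, zone)
        survivors2.extend(layer2_filter(zone_regs, bands, zone))

    report = grade_image(survivors2, od, distance_mode=cfg.distance_mode)
    logger.info("pipeline total: %.2fs, grades=%s",
                time.perf_counter() - t0, sorted(report.grades))
    return PipelineResult(report=report, pre=pre, normal_masks=normals,
                          candidate_masks=candidates, od=od, zone_masks=zones,
                          regions=regions, survivors=survivors2, config=cfg)
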