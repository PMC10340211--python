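"""Vessel-map binarization and the dual-path candidate subtraction."""

import numpy as np
import pytest
from scipy import ndimage

from pdrscreen.config import PipelineConfig
from pdrscreen.gabor import GaborBankParams
from pdrscreen.phantom import NVLesion, PhantomSpec, generate_phantom
from pdrscreen.preprocess import preprocess
from pdrscreen.vessels import (VesselMask, candidate_map, clean_normal_mask,
                               cluster_gate, detail_vessel_path,
                               multilayer_threshold, normal_vessel_path)


def _bank(cfg, path_cfg):
    return GaborBankParams.from_path_config(cfg.scaled(path_cfg),
                                            thetas=cfg.theta_grid)


def _path_kwargs(cfg, which):
    if which == "normal":
        return dict(levels=cfg.threshold_levels,
                    local_window=cfg.threshold_window,
                    offset=cfg.normal_offset, top_frac=cfg.normal_top_frac)
    return dict(levels=cfg.threshold_levels, local_window=cfg.threshold_window,
                offset=cfg.detail_offset, top_frac=cfg.detail_top_frac)


def test_constant_response_yields_empty_mask():
    fov = np.ones((40, 40), bool)
    vm = multilayer_threshold(np.full((40, 40), 0.5), fov, levels=3,
                              local_window=11, offset=0.03)
    assert not vm.mask.any()


def test_single_bright_ridge_recovered_exactly():
    """Quantile + local-mean oracle on a toy 32x32 field."""
    field = np.zeros((32, 32))
    field[16, 4:28] = 1.0
    fov = np.ones((32, 32), bool)
    vm = multilayer_threshold(field, fov, levels=1, local_window=11,
                              offset=0.03, top_frac=0.02)
    assert np.array_equal(vm.mask, field == 1.0)


def test_increasing_offset_never_adds_pixels(rng):
    field = rng.uniform(0, 1, (48, 48))
    fov = np.ones((48, 48), bool)
    lo = multilayer_threshold(field, fov, offset=0.05).mask
    hi = multilayer_threshold(field, fov, offset=0.10).mask
    assert not (hi & ~lo).any()


def test_threshold_rejects_empty_fov():
    with pytest.raises(ValueError):
        multilayer_threshold(np.ones((8, 8)), np.zeros((8, 8), bool))
    with pytest.raises(ValueError):
        multilayer_threshold(np.ones((8, 8)), np.ones((8, 8), bool), levels=0)


def test_blank_phantom_paths_nearly_empty(plain_cfg):
    """Featureless field: both paths keep at most scattered noise."""
    spec = PhantomSpec(seed=5, n_main_vessels=0, od_diameter=40.0)
    img, _ = generate_phantom(spec)
    pre = preprocess(img, plain_cfg)
    n_fov = pre.fov_mask.sum()
    nrm = normal_vessel_path(pre, _bank(plain_cfg, plain_cfg.nvd_normal),
                             **_path_kwargs(plain_cfg, "normal"))
    assert nrm.mask.sum() < 0.25 * n_fov


def test_normal_path_recovers_wide_tree(plain_cfg):
    """Centerline recall: a predicted vessel pixel within 2 px of the skeleton.

    Uses a phantom whose tree is uniformly wide (5.5-6.5 px) and the union
    of the two normal-path banks, as the pipeline's subtraction guard does.
    """
    from skimage.morphology import skeletonize
    spec = PhantomSpec(seed=8, vessel_width_range=(5.5, 6.5))
    img, truth = generate_phantom(spec)
    pre = preprocess(img, plain_cfg)
    mask = normal_vessel_path(pre, _bank(plain_cfg, plain_cfg.nvd_normal),
                              **_path_kwargs(plain_cfg, "normal")).mask |         normal_vessel_path(pre, _bank(plain_cfg, plain_cfg.nve_normal),
                           **_path_kwargs(plain_cfg, "normal")).mask
    skel = skeletonize(truth.vessel_mask)
    near_pred = ndimage.binary_dilation(mask, iterations=2)
    recall = (skel & near_pred).sum() / skel.sum()
    assert recall >= 0.8


def test_normal_path_suppresses_fine_tuft(plain_cfg):
    spec = PhantomSpec(seed=9, n_main_vessels=0,
                       nv_lesions=(NVLesion(distance=1.6),))
    img, truth = generate_phantom(spec)
    pre = preprocess(img, plain_cfg)
    nrm = clean_normal_mask(
        normal_vessel_path(pre, _bank(plain_cfg, plain_cfg.nvd_normal),
                           **_path_kwargs(plain_cfg, "normal")),
        plain_cfg.normal_min_component, plain_cfg.normal_close_radius)
    recall = (truth.nv_mask & nrm.mask).sum() / truth.nv_mask.sum()
    assert recall <= 0.3


def test_detail_path_recovers_tuft_and_tree(plain_cfg, dual_phantom):
    img, truth = dual_phantom
    pre = preprocess(img, plain_cfg)
    det = detail_vessel_path(pre, _bank(plain_cfg, plain_cfg.nvd_detail),
                             **_path_kwargs(plain_cfg, "detail"))
    tuft_recall = (truth.nv_mask & det.mask).sum() / truth.nv_mask.sum()
    assert tuft_recall >= 0.4
    skel_near = ndimage.binary_dilation(det.mask, iterations=2)
    from skimage.morphology import skeletonize
    skel = skeletonize(truth.vessel_mask)
    assert (skel & skel_near).sum() / skel.sum() >= 0.7


def test_detail_mask_largely_contains_normal_mask(plain_cfg):
    """|detail ∩ normal| / |normal| >= 0.7 on a small seeded cohort."""
    from pdrscreen.phantom import generate_cohort
    ratios = []
    for img, _ in generate_cohort(6, seed=77, mix=(0.5, 0.25, 0.25, 0.0)):
        pre = preprocess(img, plain_cfg)
        nrm = normal_vessel_path(pre, _bank(plain_cfg, plain_cfg.nvd_normal),
                                 **_path_kwargs(plain_cfg, "normal"))
        det = detail_vessel_path(pre, _bank(plain_cfg, plain_cfg.nvd_detail),
                                 **_path_kwargs(plain_cfg, "detail"))
        guard = ndimage.binary_dilation(det.mask, iterations=2)
        ratios.append((guard & nrm.mask).sum() / max(nrm.mask.sum(), 1))
    assert np.mean(ratios) >= 0.7


def test_candidate_map_set_algebra():
    base = np.zeros((40, 40), bool)
    base[10:30, 10:12] = True
    blob = np.zeros_like(base)
    blob[33:36, 33:36] = True
    detail = VesselMask(mask=base | blob, source="detail_path")
    normal = VesselMask(mask=base, source="normal_path")
    # detail == normal -> empty
    assert not candidate_map(normal := VesselMask(base, "normal_path"),
                             normal, guard_radius=2).mask.any()
    cand = candidate_map(detail, normal, guard_radius=2)
    assert cand.mask[33:36, 33:36].all()
    assert not (cand.mask & ndimage.binary_dilation(base, iterations=2)).any()


def test_candidate_map_dimension_mismatch():
    a = VesselMask(np.zeros((10, 10), bool), "detail_path")
    b = VesselMask(np.zeros((12, 10), bool), "normal_path")
    with pytest.raises(ValueError):
        candidate_map(a, b)


def test_candidate_disjoint_from_dilated_normal(plain_cfg, dual_phantom):
    img, _ = dual_phantom
    pre = preprocess(img, plain_cfg)
    nrm = normal_vessel_path(pre, _bank(plain_cfg, plain_cfg.nvd_normal),
                             **_path_kwargs(plain_cfg, "normal"))
    det = detail_vessel_path(pre, _bank(plain_cfg, plain_cfg.nvd_detail),
                             **_path_kwargs(plain_cfg, "detail"))
    cand = candidate_map(det, nrm, guard_radius=3)
    r = 3
    yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
    guard = ndimage.binary_dilation(nrm.mask,
                                    structure=(yy * yy + xx * xx) <= r * r)
    assert not (cand.mask & guard).any()
    assert not (cand.mask & ~det.mask).any()        # candidate ⊆ detail
    assert not (cand.mask & ~pre.fov_mask).any()    # confined to FOV


def test_tuft_separates_from_tree_on_phantom(plain_cfg, dual_phantom):
    """Dual-path subtraction keeps tuft pixels, drops principal vessels."""
    img, truth = dual_phantom
    pre = preprocess(img, plain_cfg)
    nrm_nvd = normal_vessel_path(pre, _bank(plain_cfg, plain_cfg.nvd_normal),
                                 **_path_kwargs(plain_cfg, "normal"))
    nrm_nve = normal_vessel_path(pre, _bank(plain_cfg, plain_cfg.nve_normal),
                                 **_path_kwargs(plain_cfg, "normal"))
    guard = VesselMask(
        clean_normal_mask(nrm_nvd, plain_cfg.normal_min_component,
                          plain_cfg.normal_close_radius).mask |
        clean_normal_mask(nrm_nve, plain_cfg.normal_min_component,
                          plain_cfg.normal_close_radius).mask,
        "normal_path")
    det = detail_vessel_path(pre, _bank(plain_cfg, plain_cfg.nvd_detail),
                             **_path_kwargs(plain_cfg, "detail"))
    cand = candidate_map(det, guard, plain_cfg.guard_radius)
    tuft_recall = (truth.nv_mask & cand.mask).sum() / truth.nv_mask.sum()
    tree_leak = (truth.vessel_mask & cand.mask).sum() / truth.vessel_mask.sum()
    # The default detail threshold favors region-level specificity, so only
    # the brighter third of tuft pixels survives at the pixel level; region
    # detection is certified end-to-end in the pipeline tests.
    assert tuft_recall >= 0.3
    # compact vessel fragments excluded from the guard leak a few percent
    # of tree pixels into the map; region-level moment classification and
    # network pruning remove them before grading
    assert tree_leak <= 0.08


def test_pipeline_masks_are_deterministic(plain_cfg, dual_phantom):
    img, _ = dual_phantom
    pre1 = preprocess(img, plain_cfg)
    pre2 = preprocess(img, plain_cfg)
    m1 = detail_vessel_path(pre1, _bank(plain_cfg, plain_cfg.nvd_detail),
                            **_path_kwargs(plain_cfg, "detail")).mask
    m2 = detail_vessel_path(pre2, _bank(plain_cfg, plain_cfg.nvd_detail),
                            **_path_kwargs(plain_cfg, "detail")).mask
    assert np.array_equal(m1, m2)


def test_cluster_gate_keeps_dense_drops_sparse():
    mask = np.zeros((100, 100), bool)
    mask[40:60, 40:60] = True              # dense block
    mask[10, 10:90:4] = True               # sparse dotted line
    gated = cluster_gate(mask, radius=8, min_count=60, merge_radius=0)
    assert gated[48:52, 48:52].all()
    assert not gated[10].any()
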