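"""End-to-end detection: preprocess -> anatomy -> blob filter ->
candidates -> features -> (optional) SVM false-positive reduction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .anatomy import extract_mediastinum, segment_air, select_lungs
from .candidates import CandidateRegion, extract_candidates, median_fill
from .config import PipelineConfig
from .filters import filter_volume
from .fp_reduction import (
    ClassifierState,
    FROCPoint,
    GroundTruthNode,
    apply_classifier,
    extract_features,
    loo_cross_validation,
)
from .preprocess import preprocess
from .volume import Volume3D, load_volume, save_mask, save_volume

log = logging.getLogger(__name__)

__all__ = ["DetectionResult", "run_detect", "prepare_volume", "run_experiment"]


@dataclass
class DetectionResult:
    preprocessed: Volume3D
    lung_mask: np.ndarray
    mediastinum: np.ndarray
    response: Volume3D
    candidates: list[CandidateRegion]
    features: np.ndarray
    kept: list[CandidateRegion]
    detection_mask: np.ndarray


def _ball(radius_mm: float, spacing) -> np.ndarray:
    r_vox = np.maximum(np.ceil(radius_mm / np.asarray(spacing)).astype(int), 0)
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) * s for r, s in zip(r_vox, spacing)], indexing="ij"
    )
    return grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2 <= radius_mm**2 + 1e-9


def prepare_volume(
    volume: Volume3D, config: PipelineConfig
) -> DetectionResult:
    """Run every stage up to feature extraction (no classifier)."""
    t0 = time.perf_counter()
    pre = preprocess(volume, config.preprocess_params())
    log.info("preprocess: %s -> %s in %.1fs", volume.shape, pre.shape,
             time.perf_counter() - t0)

    air = segment_air(pre, config.t_air)
    lungs = select_lungs(air, config.second_lung_fraction)
    media = extract_mediastinum(lungs)
    log.info("anatomy: air=%d lung=%d mediastinum=%d voxels",
             int(air.sum()), int(lungs.sum()), int(media.sum()))

    if config.mask_dilation > 0 and media.any():
        roi = ndimage.binary_dilation(
            media, structure=_ball(config.mask_dilation, pre.spacing)
        )
    else:
        roi = None

    t0 = time.perf_counter()
    response = filter_volume(
        pre,
        config.filter_mode,
        params=config.radial_params(),
        target=config.target_range(),
        mask=roi,
        hessian_scale=config.hessian_scale,
    )
    log.info("filter (%s): %.1fs", config.filter_mode, time.perf_counter() - t0)

    filled = median_fill(response, config.w_hole)
    cparams = config.candidate_params()
    cands = extract_candidates(filled, cparams.t_blob, cparams.t_small, media)
    log.info("candidates: %d regions", len(cands))

    feats = (
        np.vstack([extract_features(c, pre, lungs, config.D) for c in cands])
        if cands
        else np.empty((0, 9 + 7 * len(config.D)))
    )
    mask = np.zeros(pre.shape, dtype=bool)
    for c in cands:
        mask[c.coords[:, 0], c.coords[:, 1], c.coords[:, 2]] = True
    return DetectionResult(
        preprocessed=pre, lung_mask=lungs, mediastinum=media,
        response=response, candidates=cands, features=feats,
        kept=list(cands), detection_mask=mask,
    )


def _write_candidates_csv(result: DetectionResult, path: Path) -> None:
    rows = [
        {
            "label": c.label,
            "centroid_x_mm": c.centroid_mm[0],
            "centroid_y_mm": c.centroid_mm[1],
            "centroid_z_mm": c.centroid_mm[2],
            "volume_mm3": c.volume_mm3,
            "kept": c in result.kept,
        }
        for c in result.candidates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def run_detect(
    volume: Volume3D | str,
    config: PipelineConfig,
    model: ClassifierState | None = None,
    skip_fp_reduction: bool = False,
    out_dir: str | None = None,
) -> DetectionResult:
    """Full detection on one volume.

    Without a trained model, ``skip_fp_reduction`` must be set and the
    output mask equals the candidate mask.
    """
    input_path = None
    if isinstance(volume, (str, Path)):
        input_path = str(volume)
        volume = load_volume(volume)
    if model is None and not skip_fp_reduction:
        raise ValueError("a trained model is required unless FP reduction is skipped")

    result = prepare_volume(volume, config)
    if model is not None and not skip_fp_reduction:
        mask, kept = apply_classifier(
            model, result.candidates, result.features,
            grid_shape=result.preprocessed.shape,
        )
        result.kept = kept
        result.detection_mask = mask
        log.info("FP reduction: kept %d / %d", len(kept), len(result.candidates))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_mask(result.preprocessed.like(
            result.detection_mask.astype(np.uint8)), out / "detection.nii.gz")
        save_volume(result.response, out / "response.nii.gz")
        _write_candidates_csv(result, out / "candidates.csv")
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "input": input_path,
            "input_hash": _array_hash(volume.values),
            "n_candidates": len(result.candidates),
            "n_kept": len(result.kept),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _array_hash(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()[:16]


def run_experiment(
    volumes: list[Volume3D],
    ground_truth: list[list[GroundTruthNode]] | None,
    config: PipelineConfig,
    w_F_list,
    node_sources=None,
    out_csv: str | None = None,
) -> tuple[list[FROCPoint], pd.DataFrame]:
    """Leave-one-out FROC over a set of volumes with ground truth.

    Ground truth may be given per volume directly, or as
    ``node_sources`` — callables receiving the preprocessed grid and
    returning the node list on that grid (used by phantom objects whose
    nodes are defined analytically).
    """
    if ground_truth is None and node_sources is None:
        raise ValueError("ground truth is required")
    bundles = []
    for i, vol in enumerate(volumes):
        res = prepare_volume(vol, config)
        nodes = (
            node_sources[i](res.preprocessed)
            if node_sources is not None
            else ground_truth[i]
        )
        bundles.append(
            {"candidates": res.candidates, "features": res.features,
             "nodes": nodes, "cancer_mask": None}
        )
    points = loo_cross_validation(
        bundles, config.training_policy(), w_F_list, C=config.svm_C
    )
    df = pd.DataFrame(
        [
            {"w_F": p.w_F, "mean_rate": p.rate_mean, "sd_rate": p.rate_sd,
             "mean_fps": p.fps_mean}
            for p in points
        ]
    )
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return points, df
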