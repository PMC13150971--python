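"""Stage-1 orchestration, image I/O and run manifests.

``run_stage1`` executes the whole edge-prior heuristic on one radiograph:
body blob -> LoG contours -> spine removal -> Canny fusion -> channel set.
Degenerate content (blank films, missing anatomy) produces warnings and
empty planes, never exceptions: batch processing must not halt on one bad
image.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
from PIL import Image

from . import body_blob, canny_channel, fusion, imops, log_channel, spine
from .params import HeuristicParams, default_params

__all__ = ["Stage1Result", "load_image", "save_gray_png", "save_mask_png",
           "run_stage1", "write_channel_bundle"]


@dataclass
class Stage1Result:
    """Everything the heuristic stage produces for one radiograph."""

    channels: fusion.ChannelSet
    body: body_blob.BodyBlobArtifacts
    log: log_channel.LogStageArtifacts
    spine: spine.SpineArtifacts
    canny: canny_channel.CannyArtifacts
    warnings: List[str] = field(default_factory=list)
    timings: dict = field(default_factory=dict)

    @property
    def predicted_mask(self) -> np.ndarray:
        """Working-resolution predicted lung-field mask."""
        return self.canny.predicted_mask


def load_image(path) -> tuple[np.ndarray, int]:
    """Read an 8- or 16-bit grayscale PNG/TIFF as floats in [0, 1].

    Returns ``(image, source_depth)``; color images are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(str(path))
    else:
        with Image.open(path) as im:
            if im.mode in ("RGB", "RGBA", "P"):
                raise IOError(f"{path}: color images are not supported")
            arr = np.array(im)
    if arr.ndim != 2:
        raise IOError(f"{path}: expected a single-plane grayscale image")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0, 8
    if arr.dtype in (np.uint16, np.int32):
        return arr.astype(np.float64) / 65535.0, 16
    arr = arr.astype(np.float64)
    top = arr.max() if arr.max() > 0 else 1.0
    return np.clip(arr / top, 0.0, 1.0), 16


def save_gray_png(img: np.ndarray, path) -> None:
    arr = np.clip(np.asarray(img, np.float64), 0, 1)
    Image.fromarray((arr * 255).astype(np.uint8)).save(path)


def save_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(mask, bool).astype(np.uint8) * 255).save(path)


def run_stage1(image: np.ndarray, params: HeuristicParams | None = None,
               channel_size: int = 256) -> Stage1Result:
    """Run the full heuristic on one grayscale radiograph (floats in [0, 1])."""
    p = params or default_params()
    timings = {}

    t0 = time.perf_counter()
    body = body_blob.run_body_blob(image, p)
    timings["body_blob"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    log_art = log_channel.run_log_stage(
        body.input_img, body.body_mask, body.boundary_band, p)
    timings["log_channel"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    spine_art = spine.run_spine_stage(
        log_art.conditioned, log_art.roi_hull, log_art.refined_edges,
        log_art.eps.epsilon, p)
    timings["spine"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    eps_d = imops.local_std_epsilon(log_art.enhanced).epsilon
    canny_art = canny_channel.run_canny_stage(
        log_art.enhanced, eps_d, spine_art.edges_no_spine,
        spine_art.spine_mask, ribcage=log_art.ribcage_mask, params=p)
    timings["canny_channel"] = time.perf_counter() - t0

    channels = fusion.build_channel_set(
        body.input_img, canny_art.canny1, canny_art.canny2,
        spine_art.edges_no_spine, canny_art.predicted_mask,
        size=channel_size)

    warnings = (body.warnings + log_art.warnings + spine_art.warnings
                + canny_art.warnings)
    return Stage1Result(channels=channels, body=body, log=log_art,
                        spine=spine_art, canny=canny_art,
                        warnings=warnings, timings=timings)


def write_channel_bundle(result: Stage1Result, outdir, stem: str,
                         params: HeuristicParams | None = None,
                         qc: bool = False) -> Path:
    """Write the five channel PNGs plus a JSON manifest for one image."""
    p = params or default_params()
    outdir = Path(outdir) / stem
    outdir.mkdir(parents=True, exist_ok=True)
    ch = result.channels
    save_gray_png(ch.image, outdir / "Io.png")
    for name in fusion.CHANNEL_NAMES:
        save_mask_png(getattr(ch, name) > 0.5, outdir / f"{name}.png")
    if qc:
        qcdir = outdir / "qc"
        qcdir.mkdir(exist_ok=True)
        save_gray_png(result.body.enhanced, qcdir / "body_enhanced.png")
        save_mask_png(result.body.body_mask, qcdir / "body_mask.png")
        save_mask_png(result.log.log_edges, qcdir / "log_edges.png")
        save_mask_png(result.log.ribcage_mask, qcdir / "ribcage_mask.png")
        save_mask_png(result.spine.spine_mask, qcdir / "spine_mask.png")
        save_mask_png(result.canny.minimal_mask, qcdir / "minimal_mask.png")
        save_mask_png(result.canny.predicted_mask, qcdir / "predicted_mask.png")
    params_json = json.dumps(p.to_dict(), sort_keys=True)
    manifest = {
        "stem": stem,
        "params_sha1": hashlib.sha1(params_json.encode()).hexdigest(),
        "params": p.to_dict(),
        "warnings": result.warnings,
        "timings": result.timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
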