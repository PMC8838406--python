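"""End-to-end segmentation: preprocess, filter, threshold, clean up.

Stage order: MSR illumination correction on the input image, green
channel extraction (for color input), maximum-orientation matched-filter
response at each of three scales, convex fusion, three-threshold Otsu
optimized by particle swarm on the in-FOV histogram, rendering of the
four classes at equally spaced gray levels, single-threshold Otsu
re-binarization, and morphological post-processing.

One pipeline seed deterministically derives the per-stage seeds, so one
integer reproduces the whole run.
"""

from __future__ import annotations

import time
from dataclasses import replace
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .errors import StageError, VesselSegError
from .filterbank import KernelSpec, max_response, fuse_scales
from .metrics import report
from .postprocess import build_fov_mask, postprocess
from .preprocessing import extract_green_channel, msr
from .thresholding import (
    apply_thresholds,
    histogram256,
    otsu_pso,
    otsu_single,
    quantize256,
    render_labels,
)


def derive_seed(seed: int, stream: int) -> int:
    """Deterministic per-stage child seed of the single pipeline seed."""
    state = np.random.SeedSequence([int(seed), int(stream)]).generate_state(1)
    return int(state[0] % (2**31))


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except VesselSegError as exc:
        raise StageError(name, exc) from exc


def segment_image(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    fov: np.ndarray | None = None,
    return_intermediates: bool = False,
) -> tuple[np.ndarray, dict]:
    """Segment one fundus-like image into a binary vessel map.

    Returns the binary map and a provenance record (config digest, seed,
    chosen thresholds, per-stage timings).  With
    ``return_intermediates=True`` the provenance also carries the MSR
    output, fused response and multi-level labeling for inspection.
    """
    config = config or PipelineConfig()
    config.validate()
    image = np.asarray(image, dtype=float)
    provenance: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "timings": {},
    }
    clock = time.perf_counter

    t0 = clock()
    enhanced = _stage("msr", msr, image, config.msr)
    if enhanced.ndim == 3:
        enhanced = _stage("green_channel", extract_green_channel, enhanced)
    provenance["timings"]["preprocess"] = clock() - t0

    t0 = clock()
    if fov is None:
        fov = _stage("fov_mask", build_fov_mask, image)
    fov = np.asarray(fov, dtype=bool)
    provenance["timings"]["fov"] = clock() - t0

    t0 = clock()
    responses = tuple(
        _stage(
            f"matched_filter_sigma_{sigma}",
            max_response,
            enhanced,
            replace(config.kernel, sigma=sigma),
        )
        for sigma in config.fusion.sigmas
    )
    fused = _stage("fuse_scales", fuse_scales, responses, config.fusion)
    provenance["timings"]["filterbank"] = clock() - t0

    t0 = clock()
    hist = _stage("histogram", histogram256, fused, fov)
    pso = replace(config.pso, rng_seed=derive_seed(config.seed, 1))
    thresholds = _stage(
        "otsu_pso", otsu_pso, hist, config.n_thresholds, pso
    )
    labels = _stage("apply_thresholds", apply_thresholds, fused, thresholds)
    rendered = render_labels(labels, config.n_thresholds)
    binary_threshold = _stage(
        "otsu_single", otsu_single, histogram256(rendered, fov)
    )
    binary = quantize256(rendered) > binary_threshold
    provenance["timings"]["thresholding"] = clock() - t0
    provenance["thresholds"] = tuple(int(t) for t in thresholds)
    provenance["binarization_threshold"] = int(binary_threshold)

    t0 = clock()
    cleaned = _stage(
        "postprocess", postprocess, binary, source=image,
        config=config.post, fov=fov,
    )
    provenance["timings"]["postprocess"] = clock() - t0

    if return_intermediates:
        provenance["intermediates"] = {
            "enhanced": enhanced,
            "fused_response": fused,
            "labels": labels,
            "raw_binary": binary,
            "fov": fov,
        }
    return cleaned, provenance


def _find_pairs(directory: Path) -> list[tuple[Path, Path, Path | None]]:
    """Discover (image, truth, fov) triples under a dataset directory.

    Two layouts are recognized: the DRIVE-style split into ``images/``,
    ``1st_manual/`` and ``mask/`` subdirectories matched by leading
    digits in the filename, and a flat layout where ``<stem>_truth.*``
    and optional ``<stem>_fov.*`` sit next to ``<stem>.*``.
    """
    exts = {".png", ".tif", ".tiff", ".ppm", ".gif"}
    drive_images = directory / "images"
    if drive_images.is_dir():
        def key(path: Path) -> str:
            digits = "".join(ch for ch in path.stem if ch.isdigit())
            return digits or path.stem

        truths = {
            key(p): p
            for p in sorted((directory / "1st_manual").glob("*"))
            if p.suffix.lower() in exts
        }
        masks = {
            key(p): p
            for p in sorted((directory / "mask").glob("*"))
            if p.suffix.lower() in exts
        }
        pairs = []
        for img in sorted(drive_images.iterdir()):
            if img.suffix.lower() not in exts:
                continue
            truth = truths.get(key(img))
            if truth is not None:
                pairs.append((img, truth, masks.get(key(img))))
        return pairs

    pairs = []
    for img in sorted(directory.iterdir()):
        if img.suffix.lower() not in exts or img.stem.endswith(
            ("_truth", "_fov")
        ):
            continue
        truth = next(
            (
                img.with_name(f"{img.stem}_truth{ext}")
                for ext in exts
                if img.with_name(f"{img.stem}_truth{ext}").exists()
            ),
            None,
        )
        if truth is None:
            continue
        fov = next(
            (
                img.with_name(f"{img.stem}_fov{ext}")
                for ext in exts
                if img.with_name(f"{img.stem}_fov{ext}").exists()
            ),
            None,
        )
        pairs.append((img, truth, fov))
    return pairs


def evaluate_batch(
    directory: str | Path, config: PipelineConfig | None = None
) -> list[dict]:
    """Segment and score every image with ground truth in a directory.

    Returns one row of metrics per image plus a final ``mean`` row with
    the arithmetic column means.  Images without discoverable ground
    truth are skipped with a warning row is not emitted for them.
    """
    import warnings

    from .imageio_utils import read_image, read_mask

    config = config or PipelineConfig()
    directory = Path(directory)
    pairs = _find_pairs(directory)
    rows: list[dict] = []
    for img_path, truth_path, fov_path in pairs:
        try:
            image = read_image(img_path)
            truth = read_mask(truth_path)
            fov = read_mask(fov_path) if fov_path else None
            pred, _ = segment_image(image, config, fov=fov)
            rep = report(pred, truth, fov)
        except VesselSegError as exc:
            warnings.warn(f"skipping {img_path.name}: {exc}", stacklevel=2)
            continue
        rows.append(
            {
                "image": img_path.stem,
                "acc": rep.acc,
                "se": rep.se,
                "sp": rep.sp,
                "ssim": rep.ssim,
                "s_measure": rep.s_measure,
            }
        )
    if rows:
        mean_row = {"image": "mean"}
        for col in ("acc", "se", "sp", "ssim", "s_measure"):
            values = [r[col] for r in rows if r[col] is not None]
            mean_row[col] = float(np.mean(values)) if values else None
        rows.append(mean_row)
    return rows
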