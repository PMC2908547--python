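"""Readers, writers, run configuration and the end-to-end pipeline.

Conventions: all images are normalized to [0, 255] float grayscale on load
regardless of source bit depth; coordinates are 0-based (row, col) with row
increasing downward; masks are written as 8-bit PNGs (0 = background,
255 = worm); skeletons and metrics go to CSV.  A JSON run log records the
configuration hash, seeds and package version so any run can be reproduced
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from numpy.typing import NDArray

from . import __version__
from .appearance import (
    BackgroundModel,
    Frame,
    PatchConfig,
    UserAnnotation,
    WormModel,
    learn_background_model,
    learn_worm_model,
)
from .errors import ContractViolation, MemeError, SkeletonizationError
from .motility import SkeletonTimeSeries, compute_metrics, curvature_field
from .segmentation import SegmentationConfig, segment_sequence
from .skeleton import extract_skeleton, postprocess_skeleton

logger = logging.getLogger("meme")

__all__ = [
    "RunConfig",
    "load_sequence",
    "load_mask",
    "save_mask",
    "save_masks",
    "save_model",
    "load_model",
    "save_skeleton_csv",
    "load_skeleton_csv",
    "save_kymograph_png",
    "run_pipeline",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")


@dataclass
class RunConfig:
    """Schema-validated configuration of a full pipeline run.

    Unknown keys are rejected on load; every tunable of the learning,
    segmentation, skeleton and motility stages is mirrored here.
    """

    frames_dir: str = ""
    annotation_mask: str = ""
    worm_width_px: float = 9.0
    annotation_frame_index: int = 0
    output_dir: str = "meme_output"
    model_file: str = ""
    # appearance learning
    worm_components: int = 3
    background_components: int = 3
    cell_size: int = 32
    patch_slope: float = 0.25
    patch_intercept: float = 0.5
    n_patch_samples: int = 2000
    seed: int = 0
    # segmentation
    tau: float = 1.0
    morph_radius: int | None = None
    keep_largest: bool = True
    # skeleton / motility
    n_skeleton_points: int = 51
    fps: float = 30.0
    pixel_size_mm: float | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ContractViolation(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def patch_config(self) -> PatchConfig:
        return PatchConfig(
            slope=self.patch_slope,
            intercept=self.patch_intercept,
            n_samples=self.n_patch_samples,
            seed=self.seed,
        )

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            tau=self.tau,
            morph_radius=self.morph_radius,
            keep_largest=self.keep_largest,
        )


def _normalize_to_255(img: NDArray, dtype: np.dtype) -> NDArray[np.float64]:
    """Rescale an image to [0, 255] floats by its dtype range."""
    arr = np.asarray(img, dtype=np.float64)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        arr = (arr - info.min) / (info.max - info.min) * 255.0
    else:
        # Float sources: assume [0, 1] if within it, else clip to [0, 255].
        if arr.size and arr.max() <= 1.0 and arr.min() >= 0.0:
            arr = arr * 255.0
    return np.clip(arr, 0.0, 255.0)


def _to_grayscale(arr: NDArray[np.float64]) -> NDArray[np.float64]:
    if arr.ndim == 3:
        warnings.warn("RGB input converted to grayscale by luminance", stacklevel=3)
        rgb = arr[..., :3]
        return rgb @ np.array([0.2126, 0.7152, 0.0722])
    return arr


def load_sequence(path: str | Path) -> list[Frame]:
    """Load an ordered frame sequence from a directory or a multipage TIFF.

    Directory frames are taken in lexicographic filename order; all frames
    must share one shape.
    """
    path = Path(path)
    raws: list[tuple[str, NDArray]] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise MemeError(f"no image files found in {path}")
        for p in files:
            raws.append((p.name, iio.imread(p)))
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        for i, page in enumerate(stack):
            raws.append((f"{path.name}[{i}]", page))
    else:
        raise MemeError(f"unsupported sequence source: {path}")

    frames = []
    shape = None
    for t, (name, raw) in enumerate(raws):
        arr = _to_grayscale(_normalize_to_255(raw, raw.dtype))
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise MemeError(
                f"frame {name} has shape {arr.shape}, expected {shape}"
            )
        frames.append(Frame(pixels=arr, t=t))
    return frames


def load_mask(path: str | Path) -> NDArray[np.bool_]:
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., 0]
    return np.asarray(raw) > 0


def save_mask(mask: NDArray[np.bool_], path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def save_masks(
    masks: list[NDArray[np.bool_]], out_dir: str | Path, stem: str = "frame"
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, mask in enumerate(masks):
        p = out_dir / f"{stem}_mask_{t:05d}.png"
        save_mask(mask, p)
        paths.append(p)
    return paths


def save_model(
    worm: WormModel, background: BackgroundModel, path: str | Path
) -> None:
    """Serialize both appearance models to one portable JSON file."""
    payload = {
        "format": "meme-model",
        "version": __version__,
        "worm": {
            "model": worm.mixture.to_dict(),
            "frame_index": worm.frame_index,
            "mask_area": worm.mask_area,
            "worm_width_px": worm.worm_width_px,
        },
        "background": background.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> tuple[WormModel, BackgroundModel]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "meme-model":
        raise MemeError(f"{path} is not a model file")
    from .appearance import MixtureModel

    worm = WormModel(
        mixture=MixtureModel.from_dict(payload["worm"]["model"]),
        frame_index=payload["worm"]["frame_index"],
        mask_area=payload["worm"]["mask_area"],
        worm_width_px=payload["worm"]["worm_width_px"],
    )
    background = BackgroundModel.from_dict(payload["background"])
    return worm, background


def save_skeleton_csv(
    skeletons: list[NDArray[np.float64]], path: str | Path, fps: float = 30.0
) -> None:
    """Skeleton table: frame, t_index, point_index, row, col, arc_s.

    Coordinates are 0-based pixels, row increasing downward; arc_s is the
    cumulative arc length from the first point.
    """
    rows = []
    for t, pts in enumerate(skeletons):
        pts = np.asarray(pts, float)
        seg = np.hypot(*np.diff(pts, axis=0).T) if len(pts) > 1 else np.array([])
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        for i, (r, c) in enumerate(pts):
            rows.append(
                {
                    "frame": t,
                    "t_index": t,
                    "point_index": i,
                    "row": r,
                    "col": c,
                    "arc_s": arc[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def load_skeleton_csv(path: str | Path) -> list[NDArray[np.float64]]:
    df = pd.read_csv(path)
    return [
        g.sort_values("point_index")[["row", "col"]].to_numpy(float)
        for _, g in df.groupby("frame", sort=True)
    ]


def save_kymograph_png(field_kappa: NDArray[np.float64], path: str | Path) -> None:
    """Render a curvature kymograph (red positive / blue negative)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = np.nanmax(np.abs(field_kappa)) or 1.0
    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(
        field_kappa,
        aspect="auto",
        origin="upper",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        extent=(0, field_kappa.shape[1], 1, 0),
    )
    ax.set_xlabel("frame")
    ax.set_ylabel("s (head = 0)")
    fig.colorbar(im, ax=ax, label="curvature (1/px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Full analysis: learn models, segment, skeletonize, compute metrics.

    Artifacts written under ``config.output_dir``: model.json, per-frame
    mask PNGs, skeleton.csv, curvature.csv, metrics.json/csv, a kymograph
    PNG and run_log.json.  Per-frame skeleton failures are logged and
    skipped, never fatal.  Identical config + seed reproduce identical
    artifacts byte for byte.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if not Path(config.annotation_mask).exists():
        raise MemeError(f"annotation mask not found: {config.annotation_mask}")
    frames = load_sequence(config.frames_dir)
    ann_mask = load_mask(config.annotation_mask)
    annotation = UserAnnotation(
        frame=frames[config.annotation_frame_index],
        worm_mask=ann_mask,
        worm_width_px=config.worm_width_px,
    )

    patch_cfg = config.patch_config()
    worm = learn_worm_model(annotation, config.worm_components, patch_cfg)
    background = learn_background_model(
        annotation, config.background_components, config.cell_size, patch_cfg
    )
    model_path = Path(config.model_file) if config.model_file else out / "model.json"
    save_model(worm, background, model_path)

    seg_cfg = config.segmentation_config()
    masks, frame_logs = segment_sequence(frames, worm, background, seg_cfg)
    save_masks(masks, out / "masks")

    skeletons: list[NDArray[np.float64]] = []
    skeleton_flags = []
    prev_head = None
    for t, mask in enumerate(masks):
        try:
            sk = extract_skeleton(mask, config.worm_width_px, t=t)
            pts = postprocess_skeleton(sk, config.n_skeleton_points)
        except (SkeletonizationError, ContractViolation) as exc:
            logger.warning("frame %d: skeleton failed (%s)", t, exc)
            skeleton_flags.append({"frame": t, "ok": False, "error": str(exc)})
            skeletons.append(
                skeletons[-1]
                if skeletons
                else np.zeros((config.n_skeleton_points, 2))
            )
            continue
        if prev_head is not None:
            if np.sum((pts[-1] - prev_head) ** 2) < np.sum((pts[0] - prev_head) ** 2):
                pts = pts[::-1]
        prev_head = pts[0]
        skeletons.append(pts)
        skeleton_flags.append({"frame": t, "ok": True, "error": ""})
    save_skeleton_csv(skeletons, out / "skeleton.csv", fps=config.fps)

    series = SkeletonTimeSeries(
        points=np.stack(skeletons),
        fps=config.fps,
        pixel_size_mm=config.pixel_size_mm,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        metrics = compute_metrics(series)
        field = curvature_field(series)
    np.savetxt(out / "curvature.csv", field.kappa, delimiter=",", fmt="%.8g")
    save_kymograph_png(field.kappa, out / "kymograph.png")
    metrics_dict = {
        k: (None if isinstance(v, float) and not np.isfinite(v) else v)
        for k, v in metrics.to_dict().items()
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics_dict, fh, indent=2, sort_keys=True)
    pd.DataFrame([metrics.to_dict()]).to_csv(out / "metrics.csv", index=False)

    run_log = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_frames": len(frames),
        "frame_logs": [
            {"t": fl.t, "area": fl.foreground_area, "failed": fl.failed}
            for fl in frame_logs
        ],
        "skeleton_flags": skeleton_flags,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return run_log
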