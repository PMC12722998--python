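"""Readers and writers: frame-sequence videos, manifests, truth side-channels.

Videos are stored as per-video directories of zero-padded grayscale PNG frames
(``frame_000000.png`` ...) — the lossless interchange format for exported
ultrasound stills — plus a dataset-level ``manifest.csv``. Common video
containers readable by imageio also load. Color inputs are converted to
grayscale with the standard Rec. 601 luma weights (ultrasound exports are
nominally gray but containers often store three channels).
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import FrameVideo, VideoTruth

log = logging.getLogger(__name__)

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])
MANIFEST_COLUMNS = ["video_id", "subject_id", "scan_site", "label", "group_tag",
                    "n_frames", "fps", "path"]


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Single-channel 8-bit view of a frame; color collapses via luma."""
    if frame.ndim == 2:
        return frame.astype(np.uint8, copy=False)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        gray = frame[:, :, :3].astype(float) @ LUMA_WEIGHTS
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported frame shape {frame.shape}")


def load_video(path: str | Path, fps: float = 30.0, subject_id: str = "",
               scan_site: str = "BLD", label: str = "negative",
               video_id: str = "", group_tag: str = "") -> FrameVideo:
    """Load a frame-sequence directory (PNG/TIFF, lexicographic order) or a
    video container into a FrameVideo. ``fps`` from the manifest overrides any
    container metadata."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        raw = [iio.imread(f) for f in files]
    else:
        try:
            raw = list(iio.imiter(path))
        except Exception as exc:  # noqa: BLE001 - name the offending file
            raise IOError(f"cannot read video container {path}: {exc}") from exc
        if not raw:
            raise IOError(f"no frames decoded from {path}")
    if any(f.ndim == 3 for f in raw):
        log.warning("%s contains multi-channel frames; converting via luma "
                    "weights", path)
    frames = [to_grayscale(f) for f in raw]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame sizes in {path}: {sorted(shapes)}")
    return FrameVideo(frames=np.stack(frames), fps=fps, subject_id=subject_id,
                      scan_site=scan_site, label=label,
                      video_id=video_id or path.stem, group_tag=group_tag)


def write_video(video: FrameVideo, out_dir: str | Path) -> Path:
    """Write frames as zero-padded grayscale PNGs; returns the directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for t in range(video.n_frames):
        iio.imwrite(out_dir / f"frame_{t:06d}.png", video.frames[t])
    return out_dir


def write_dataset(videos: list[FrameVideo], manifest: pd.DataFrame,
                  out_dir: str | Path,
                  truths: "list[VideoTruth] | None" = None) -> pd.DataFrame:
    """Write all videos plus manifest.csv (and optional truth NPZs) under
    ``out_dir``; returns the manifest with filled-in paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for i, video in enumerate(videos):
        vdir = write_video(video, out_dir / video.video_id)
        manifest.loc[manifest["video_id"] == video.video_id, "path"] = str(vdir)
        if truths is not None:
            np.savez_compressed(out_dir / f"{video.video_id}_truth.npz",
                                cue_mask=truths[i].cue_mask,
                                cue_frames=truths[i].cue_frames,
                                crescent_region=truths[i].crescent_region)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    manifest = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if manifest["video_id"].duplicated().any():
        dupes = manifest.loc[manifest["video_id"].duplicated(), "video_id"]
        raise ValueError(f"duplicate video_id values: {sorted(set(dupes))}")
    bad = set(manifest["label"]) - {"negative", "positive"}
    if bad:
        raise ValueError(f"unknown labels in manifest: {sorted(bad)}")
    if check_paths:
        for p in manifest["path"]:
            if p and not Path(p).exists():
                raise FileNotFoundError(f"manifest path does not exist: {p}")
    return manifest


def load_videos_from_manifest(manifest: pd.DataFrame) -> list[FrameVideo]:
    return [load_video(row.path, fps=row.fps, subject_id=row.subject_id,
                       scan_site=row.scan_site, label=row.label,
                       video_id=row.video_id, group_tag=row.group_tag)
            for row in manifest.itertuples()]
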