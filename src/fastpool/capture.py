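"""Arithmetic of the capture protocol.

Exported FAST-exam sweeps are fixed-length clips (30 s at the native 30 FPS,
hence 900 frames each), so image counts and holdout fractions follow directly
from clip counts. These helpers keep that bookkeeping in one place.
"""

from __future__ import annotations


def frames_per_clip(fps: float = 30.0, duration_s: float = 30.0) -> int:
    """Frames in one exported clip; must come out integral."""
    t = fps * duration_s
    if abs(t - round(t)) > 1e-9 or round(t) < 1:
        raise ValueError(f"fps*duration_s must be a positive integer, got {t}")
    return int(round(t))


def images_in_clips(n_clips: int, fps: float = 30.0,
                    duration_s: float = 30.0) -> int:
    """Total still-image count across ``n_clips`` fixed-length clips."""
    if n_clips < 0:
        raise ValueError("n_clips must be non-negative")
    return n_clips * frames_per_clip(fps, duration_s)


def holdout_video_percent(n_test_videos: int, n_trainval_videos: int) -> float:
    """Percentage of a dataset's videos held out for testing."""
    total = n_test_videos + n_trainval_videos
    if total == 0:
        raise ValueError("empty dataset")
    return 100.0 * n_test_videos / total
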