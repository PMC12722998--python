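"""Pooled frame windows.

A video of T frames is converted into fixed-size windows of n consecutive
frames taken at a fixed stride s; each window becomes one n-channel CNN input
so a single prediction sees up to n sweep angles. Start indices run over every
multiple of s below T (ceil(T/s) windows), so trailing windows that extend
past the last frame are kept and completed by repeating the final frame —
repeat-padding preserves intensity statistics, whereas zero padding would
inject an artificial anechoic signal that mimics free fluid.

Frame indices are 0-based; windows are half-open [start, start + n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import FrameVideo


@dataclass(frozen=True)
class WindowingConfig:
    """Window size / stride / padding policy.

    Training default stride is 15 frames; inference pools one 150-frame window
    per 30 s of video (stride 900 at 30 FPS).
    """

    window_size: int = 150
    stride: int = 15
    padding_policy: str = "repeat_last"

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.stride < 1:
            raise ValueError("window_size and stride must be >= 1")
        if self.padding_policy != "repeat_last":
            raise ValueError(f"unknown padding policy: {self.padding_policy!r}")


@dataclass
class Window:
    """n consecutive (possibly end-padded) frames from one video."""

    frames: np.ndarray  # (n, H, W)
    video_id: str
    start_index: int
    n_padded: int
    label: str


def plan_windows(t_frames: int, window_size: int, stride: int
                 ) -> list[tuple[int, int]]:
    """Window plan for a T-frame video: list of (start_index, n_padded).

    Starts are 0, s, 2s, ... for every multiple of s strictly below T; padding
    for a window is the number of frames it extends past the last frame.
    """
    if t_frames < 1:
        raise ValueError("video must contain at least one frame")
    return [(start, max(0, start + window_size - t_frames))
            for start in range(0, t_frames, stride)]


def make_windows(video: FrameVideo, cfg: WindowingConfig) -> list[Window]:
    """Slice a video into pooled windows, ordered by start index.

    Unpadded slices are views into the video's frame buffer; only padded
    windows allocate. A video shorter than the window size yields a single,
    heavily padded window — not an error.
    """
    t = video.n_frames
    n = cfg.window_size
    windows = []
    for start, n_padded in plan_windows(t, n, cfg.stride):
        if n_padded == 0:
            frames = video.frames[start:start + n]
        else:
            body = video.frames[start:t]
            pad = np.repeat(video.frames[t - 1][None], n_padded, axis=0)
            frames = np.concatenate([body, pad], axis=0)
        windows.append(Window(frames=frames, video_id=video.video_id,
                              start_index=start, n_padded=n_padded,
                              label=video.label))
    return windows


def window_to_tensor_stack(window: Window) -> np.ndarray:
    """Window as a float32 (n, H, W) stack scaled to [0, 1].

    Channels are ordered by temporal index; each grayscale frame contributes
    one channel.
    """
    return np.asarray(window.frames, dtype=np.float32) / 255.0
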