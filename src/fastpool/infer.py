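"""Window scoring and per-video aggregation.

A trained model scores every pooled window of a video with a 2-class softmax;
the video-level confidence is the arithmetic mean of the positive-class
confidences over its windows, and the video is called positive when that mean
reaches the confidence threshold (a tie at the threshold is called positive —
even a suspicion of free fluid is treated as a positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import _prepare_eval_stack
from .nn import TinyCNN, softmax
from .synthetic import FrameVideo
from .windows import Window, WindowingConfig, make_windows


@dataclass
class PredictionRecord:
    video_id: str
    window_scores: list[tuple[float, float]]   # (p_negative, p_positive) pairs
    video_score: float
    threshold: float
    predicted_label: str
    true_label: str | None = None

    @property
    def n_windows(self) -> int:
        return len(self.window_scores)


def score_windows(model: TinyCNN, windows: list[Window],
                  input_size: int = 64, batch_size: int = 32
                  ) -> list[tuple[float, float]]:
    """Softmax confidence pair per window, order preserved, evaluation mode."""
    if windows and windows[0].frames.shape[0] != model.in_channels:
        raise ValueError(
            f"window size {windows[0].frames.shape[0]} does not match model "
            f"in_channels {model.in_channels}")
    pairs: list[tuple[float, float]] = []
    for i in range(0, len(windows), batch_size):
        xb = np.stack([_prepare_eval_stack(w, input_size)
                       for w in windows[i:i + batch_size]])
        p = softmax(model.forward(xb, train=False))
        pairs.extend((float(a), float(b)) for a, b in p)
    return pairs


def aggregate_video(window_scores: list[tuple[float, float]], threshold: float,
                    video_id: str = "", true_label: str | None = None
                    ) -> PredictionRecord:
    """Average window confidences into one video prediction.

    ``video_score`` is the mean positive-class confidence; the predicted label
    is positive iff ``video_score >= threshold``.
    """
    if not window_scores:
        raise ValueError("need at least one window score to aggregate")
    p_pos = np.array([p for _, p in window_scores], dtype=float)
    score = float(p_pos.mean())
    label = "positive" if score >= threshold else "negative"
    return PredictionRecord(video_id=video_id, window_scores=list(window_scores),
                            video_score=score, threshold=threshold,
                            predicted_label=label, true_label=true_label)


def predict_videos(model: TinyCNN, videos: list[FrameVideo],
                   windowing: WindowingConfig, threshold: float = 0.5,
                   input_size: int = 64) -> list[PredictionRecord]:
    """Window, score and aggregate every video; one record per video."""
    records = []
    for video in videos:
        windows = make_windows(video, windowing)
        scores = score_windows(model, windows, input_size=input_size)
        records.append(aggregate_video(scores, threshold,
                                       video_id=video.video_id,
                                       true_label=video.label))
    return records


def records_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    rows = [dict(video_id=r.video_id, n_windows=r.n_windows,
                 video_score=r.video_score, threshold=r.threshold,
                 predicted_label=r.predicted_label,
                 true_label=r.true_label if r.true_label is not None else "")
            for r in records]
    return pd.DataFrame(rows)
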