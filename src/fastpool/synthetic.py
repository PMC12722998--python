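"""Synthetic B-mode ultrasound sweep simulator.

Real FAST-exam data for free-fluid (hemorrhage) classification is restricted,
so this module generates labeled grayscale sweep videos with a controllable
positive-class cue: an anechoic (dark) crescent of fluid hugging a dark
elliptical organ. The cue is rendered only in a contiguous block of frames —
mimicking the fluid pocket entering and leaving the imaging plane as the probe
sweeps — so a single frame is an unreliable witness of the video label while a
multi-frame pooled window is not.

Both classes additionally carry transient anechoic artifacts — short-lived
dark patches mimicking rib shadows, edge dropout or bowel gas — appearing at
random positions for one to a few frames. On a single frame an artifact is
indistinguishable from a fluid pocket; across a pooled window the fluid cue
persists at a fixed location while artifacts flicker, which is exactly the
multi-angle context a sonographer uses and the reason single-frame
classification is noisy here.

The first-order image model is standard for B-mode texture: a piecewise-smooth
echogenicity map multiplied by fully developed multiplicative Rayleigh speckle,
spatially correlated at the point-spread-function scale, quantized to 8 bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

log = logging.getLogger(__name__)

NEGATIVE = "negative"
POSITIVE = "positive"
SCAN_SITES = ("BLD", "RUQ")

#: smooth entry/exit of the fluid pocket: depression ramps between RAMP_FLOOR
#: and 1.0 across the visibility block (half-sine), so edge frames carry a
#: weak cue — the realistic failure mode of single-frame classification.
RAMP_FLOOR = 0.3
_PSF_SIGMA = 0.8  # px; speckle correlation length


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticConfig:
    """All parameters of the simulated sweep.

    Fractional coordinates/radii are relative to image height/width so the
    same geometry scales with resolution.
    """

    image_height: int = 64
    image_width: int = 64
    fps: float = 30.0
    duration_s: float = 30.0
    speckle_scale: float = 1.0
    organ_center: tuple[float, float] = (0.45, 0.5)
    organ_center_jitter: float = 0.08   # per-video probe-placement variation
    organ_radii: tuple[float, float] = (0.18, 0.24)
    organ_drift_amplitude: float = 2.0
    fluid_visibility_fraction: float = 1.0
    fluid_contrast: float = 0.5
    artifact_rate: float = 0.2
    artifact_contrast: float = 0.5
    n_subjects: int = 4
    videos_per_subject: int = 2
    positive_fraction: float = 0.5
    scan_site: str = "BLD"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 32 or self.image_width < 32:
            raise ConfigurationError("image dimensions must be >= 32 px")
        for name in ("fluid_visibility_fraction", "fluid_contrast",
                     "positive_fraction", "artifact_rate", "artifact_contrast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.scan_site not in SCAN_SITES:
            raise ConfigurationError(f"scan_site must be one of {SCAN_SITES}")
        t = self.fps * self.duration_s
        if abs(t - round(t)) > 1e-9 or round(t) < 1:
            raise ConfigurationError(
                f"fps*duration_s must be a positive integer frame count, got {t}"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass
class FrameVideo:
    """An ordered stack of grayscale frames with one binary injury label."""

    frames: np.ndarray  # (T, H, W) uint8
    fps: float
    subject_id: str
    scan_site: str
    label: str
    group_tag: str = ""
    video_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (T, H, W) stack")
        if self.label not in (NEGATIVE, POSITIVE):
            raise ValueError(f"label must be '{NEGATIVE}' or '{POSITIVE}'")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class VideoTruth:
    """Generator side-channel: per-frame cue masks and the clean background.

    Never consumed by the classifier path; exists so oracle tests can count
    cue frames and locate the crescent region exactly.
    """

    cue_mask: np.ndarray        # (T, H, W) bool, True where the crescent is rendered
    crescent_region: np.ndarray  # (H, W) bool, the nominal (undrifted) crescent footprint
    background: np.ndarray      # (H, W) float echogenicity map at drift phase 0
    cue_frames: np.ndarray      # (T,) bool


def _echogenicity_map(cfg: SyntheticConfig, center: tuple[float, float],
                      drift_row: float, drift_col: float,
                      with_fluid: bool, fluid_depth: float) -> tuple[np.ndarray, np.ndarray]:
    """Clean (pre-speckle) intensity map and the crescent mask at one drift offset."""
    h, w = cfg.image_height, cfg.image_width
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    # bright tissue with a mild depth gradient (near field brighter)
    base = 170.0 - 40.0 * rows / max(h - 1, 1)
    base = np.broadcast_to(base, (h, w)).copy()

    cr = center[0] * h + drift_row
    cc = center[1] * w + drift_col
    rr = cfg.organ_radii[0] * h
    rc = cfg.organ_radii[1] * w
    d = np.sqrt(((rows - cr) / rr) ** 2 + ((cols - cc) / rc) ** 2)
    organ = d <= 1.0
    base[organ] = 35.0  # hypoechoic organ interior (urine-filled bladder / kidney)

    crescent = (d > 1.05) & (d <= 1.45) & (rows > cr)  # dependent pocket below the organ
    if with_fluid and fluid_depth > 0.0:
        base[crescent] *= 1.0 - cfg.fluid_contrast * fluid_depth
    return base, crescent


def _cue_depth_profile(t_frames: int, fraction: float, rng: np.random.Generator
                       ) -> np.ndarray:
    """Per-frame cue depression in [0, 1]; nonzero on a contiguous block.

    Exactly ``round(fraction * T)`` frames carry the cue. Depth follows a
    half-sine with floor RAMP_FLOOR so the pocket fades in and out.
    """
    depth = np.zeros(t_frames)
    m = int(round(fraction * t_frames))
    if m == 0:
        return depth
    start = int(rng.integers(0, t_frames - m + 1))
    i = np.arange(m)
    ramp = np.sin(np.pi * (i + 0.5) / m)
    depth[start:start + m] = RAMP_FLOOR + (1.0 - RAMP_FLOOR) * ramp
    return depth


def _artifact_events(cfg: SyntheticConfig, t_frames: int,
                     rng: np.random.Generator) -> list[dict]:
    """Transient anechoic artifacts: label-independent dark arcs.

    The per-video artifact burden is drawn from Uniform(0, 2*artifact_rate) —
    some sweeps image cleanly, others are littered with shadows and bowel
    gas — so the *rate* of dark events carries no class information for any
    single video. Each event lasts 1-3 frames and is an elliptical ring
    segment (the same morphology as a fluid crescent) at a position and
    orientation drawn uniformly over the tissue field: on one frame an
    artifact and a fluid pocket look alike in shape, size and darkness, and
    only persistence across consecutive frames tells them apart.
    """
    mean_duration = 2.0
    burden = rng.uniform(0.0, 2.0 * cfg.artifact_rate)
    n_events = int(round(burden * t_frames / mean_duration))
    events = []
    for _ in range(n_events):
        # most transient artifacts at these views are organ-edge phenomena
        # (posterior shadowing, refraction at the curved interface): anchored
        # to the organ's rim at a random angle, in the same annulus band as a
        # fluid pocket. The rest are free-floating arcs.
        anchored = bool(rng.uniform() < 0.6)
        span = rng.uniform(0.4 * np.pi, 0.9 * np.pi)
        if anchored:
            # shadowing is distal to the organ along the beam: the arc lies in
            # the lower half-plane, the same place a fluid pocket appears
            angle0 = rng.uniform(0.0, np.pi - span)
        else:
            angle0 = rng.uniform(0.0, 2.0 * np.pi)
        events.append(dict(
            t0=int(rng.integers(0, t_frames)),
            duration=int(rng.integers(1, 4)),
            anchored=anchored,
            center=(rng.uniform(0.15, 0.9), rng.uniform(0.1, 0.9)),
            radius=rng.uniform(0.12, 0.25),
            width=rng.uniform(0.06, 0.1),
            angle0=angle0,
            span=span,
        ))
    return events


def _artifact_mask(cfg: SyntheticConfig, events: list[dict], t: int,
                   organ_center_px: tuple[float, float]) -> np.ndarray | None:
    h, w = cfg.image_height, cfg.image_width
    active = [e for e in events if e["t0"] <= t < e["t0"] + e["duration"]]
    if not active:
        return None
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    mask = np.zeros((h, w), dtype=bool)
    scale = (h + w) / 2.0
    rr_o = cfg.organ_radii[0] * h
    rc_o = cfg.organ_radii[1] * w
    for e in active:
        if e["anchored"]:
            cr, cc = organ_center_px
            d = np.sqrt(((rows - cr) / rr_o) ** 2 + ((cols - cc) / rc_o) ** 2)
            ring = (d > 1.05) & (d <= 1.45)
        else:
            cr, cc = e["center"][0] * h, e["center"][1] * w
            d = np.sqrt((rows - cr) ** 2 + (cols - cc) ** 2) / scale
            ring = (d >= e["radius"]) & (d <= e["radius"] + e["width"])
        theta = np.mod(np.arctan2(rows - cr, cols - cc) - e["angle0"],
                       2.0 * np.pi)
        mask |= ring & (theta <= e["span"])
    return mask


def simulate_video(cfg: SyntheticConfig, subject_id: str, label: str,
                   rng: np.random.Generator | None = None,
                   return_truth: bool = False):
    """Simulate one labeled sweep video.

    Returns a :class:`FrameVideo`, or ``(FrameVideo, VideoTruth)`` when
    ``return_truth`` is set. Deterministic for a given config/seed (when no
    external ``rng`` is passed, one is derived from ``cfg.seed``).
    """
    if label not in (NEGATIVE, POSITIVE):
        raise ValueError(f"label must be '{NEGATIVE}' or '{POSITIVE}'")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t_frames = cfg.n_frames
    h, w = cfg.image_height, cfg.image_width

    depth = (_cue_depth_profile(t_frames, cfg.fluid_visibility_fraction, rng)
             if label == POSITIVE else np.zeros(t_frames))
    artifacts = _artifact_events(cfg, t_frames, rng)
    # per-video probe placement: organ position varies between captures
    j = cfg.organ_center_jitter
    center = (cfg.organ_center[0] + rng.uniform(-j, j),
              cfg.organ_center[1] + rng.uniform(-j, j))
    # per-video drift phase so sweeps are not identical across captures
    phase = rng.uniform(0.0, 2.0 * np.pi)
    tt = np.arange(t_frames)
    drift_r = cfg.organ_drift_amplitude * np.sin(2.0 * np.pi * tt / max(t_frames, 2) + phase)
    drift_c = cfg.organ_drift_amplitude * np.sin(4.0 * np.pi * tt / max(t_frames, 2) + phase / 2)

    frames = np.empty((t_frames, h, w), dtype=np.uint8)
    cue_mask = np.zeros((t_frames, h, w), dtype=bool)
    rayleigh_mean = np.sqrt(np.pi / 2.0)  # unit-scale Rayleigh mean, for unit-mean speckle
    for t in range(t_frames):
        base, crescent = _echogenicity_map(
            cfg, center, drift_r[t], drift_c[t],
            with_fluid=depth[t] > 0, fluid_depth=depth[t]
        )
        amask = _artifact_mask(cfg, artifacts, t,
                               (center[0] * h + drift_r[t],
                                center[1] * w + drift_c[t]))
        if amask is not None:
            base = base.copy()
            base[amask] *= 1.0 - cfg.artifact_contrast
        speckle = rng.rayleigh(scale=1.0, size=(h, w)) / rayleigh_mean
        speckle = gaussian_filter(speckle, _PSF_SIGMA, mode="nearest")
        img = base * (cfg.speckle_scale * (speckle - 1.0) + 1.0)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        if depth[t] > 0:
            cue_mask[t] = crescent

    video = FrameVideo(frames=frames, fps=cfg.fps, subject_id=subject_id,
                       scan_site=cfg.scan_site, label=label)
    if not return_truth:
        return video
    base0, crescent0 = _echogenicity_map(cfg, center, 0.0, 0.0,
                                         with_fluid=False, fluid_depth=0.0)
    truth = VideoTruth(cue_mask=cue_mask, crescent_region=crescent0,
                       background=base0, cue_frames=depth > 0)
    return video, truth


def _positives_per_subject(n_subjects: int, videos_per_subject: int,
                           positive_fraction: float) -> list[int]:
    """Largest-remainder style rounding that keeps every subject within +/-1
    of the target and the grand total within +/-1 of fraction*total."""
    target = positive_fraction * videos_per_subject
    counts = []
    cum_prev = 0
    for i in range(1, n_subjects + 1):
        cum = int(np.floor(i * target + 0.5))
        counts.append(min(videos_per_subject, max(0, cum - cum_prev)))
        cum_prev = cum
    exact_total = positive_fraction * n_subjects * videos_per_subject
    if abs(sum(counts) - exact_total) > 1e-9 and abs(target - round(target)) > 1e-9:
        log.warning(
            "positive_fraction=%.3g not exactly realizable with %d videos/subject; "
            "using %d positives of %d videos",
            positive_fraction, videos_per_subject, sum(counts),
            n_subjects * videos_per_subject,
        )
    return counts


def simulate_dataset(cfg: SyntheticConfig, return_truth: bool = False,
                     n_groups: int | None = None):
    """Simulate a full labeled dataset.

    Returns ``(videos, manifest)`` — or ``(videos, manifest, truths)`` — where
    the manifest is a DataFrame with one row per video (video_id, subject_id,
    scan_site, label, group_tag, n_frames, fps, path). ``path`` is empty until
    the dataset is written to disk (see :func:`fastpool.io.write_dataset`).
    """
    if cfg.n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")
    rng = np.random.default_rng(cfg.seed)
    if n_groups is None:
        n_groups = min(3, cfg.n_subjects)
    pos_counts = _positives_per_subject(cfg.n_subjects, cfg.videos_per_subject,
                                        cfg.positive_fraction)
    videos: list[FrameVideo] = []
    truths: list[VideoTruth] = []
    rows = []
    for si in range(cfg.n_subjects):
        subject = f"subject{si:03d}"
        group = f"capture{si % n_groups:02d}"
        labels = [POSITIVE] * pos_counts[si]
        labels += [NEGATIVE] * (cfg.videos_per_subject - pos_counts[si])
        for vi, label in enumerate(labels):
            vid_id = f"{subject}_{cfg.scan_site}_{vi:02d}"
            out = simulate_video(cfg, subject, label, rng=rng, return_truth=return_truth)
            video = out[0] if return_truth else out
            if return_truth:
                truths.append(out[1])
            video.group_tag = group
            video.video_id = vid_id
            videos.append(video)
            rows.append(dict(video_id=vid_id, subject_id=subject,
                             scan_site=cfg.scan_site, label=label, group_tag=group,
                             n_frames=video.n_frames, fps=cfg.fps, path=""))
    manifest = pd.DataFrame(rows)
    if return_truth:
        return videos, manifest, truths
    return videos, manifest


def with_overrides(cfg: SyntheticConfig, **kwargs) -> SyntheticConfig:
    """Return a copy of ``cfg`` with the given fields replaced."""
    return replace(cfg, **kwargs)
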