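"""Training-time sampling and image preparation.

The training pipeline for one series and one epoch is

    splice(9 frames, containing the null) -> drop 2 frames (never the null)
    -> 5 sliding windows of 3 adjacent frames -> augment,

with frames standardised by corpus-level mean/variance and resized to the
model resolution.  At validation/inference no splicing, dropping or
oversampling happens: a series of n frames yields its n - 2 windows as is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .series import LabelledSeries, TIScoutSeries

SPLICE_LENGTH = 9
KEPT_FRAMES = 7
WINDOW_WIDTH = 3


@dataclass(frozen=True)
class NormalizationStats:
    """Corpus-level intensity moments used to standardise every frame."""

    mean: float
    std: float

    def __post_init__(self):
        if self.std <= 0:
            raise ValueError("std must be > 0 (degenerate statistics)")

    @classmethod
    def from_series(cls, series_list) -> "NormalizationStats":
        """Global mean/std over all pixels of all series (two-pass, exact)."""
        n, total = 0, 0.0
        for s in series_list:
            total += float(s.frames.sum())
            n += s.frames.size
        if n == 0:
            raise ValueError("no pixels to compute statistics from")
        mean = total / n
        ss = 0.0
        for s in series_list:
            ss += float(((s.frames - mean) ** 2).sum())
        std = float(np.sqrt(ss / n))
        if std == 0:
            raise ValueError("zero variance across the corpus (degenerate statistics)")
        return cls(mean=mean, std=std)


@dataclass(frozen=True)
class Window:
    """Three temporally adjacent frames stacked as channels
    (earliest, middle, latest), supervised by the centre frame's label."""

    channels: np.ndarray        # (3, H, W)
    centre_ti: float
    centre_index: int
    target: float

    def __post_init__(self):
        if self.channels.shape[0] != WINDOW_WIDTH:
            raise ValueError("a window stacks exactly three frames as channels")


def label_series(series: TIScoutSeries, null_index: int) -> LabelledSeries:
    """Attach the soft-label scheme: 0 before the null frame, 0.5 at it,
    1 after it."""
    return LabelledSeries(series=series, null_index=null_index)


def normalize(frames: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Standardise pixels: (x - mean) / std, identically on every frame."""
    return (np.asarray(frames, dtype=np.float32) - stats.mean) / stats.std


def resize(frame: np.ndarray, side: int = 256) -> np.ndarray:
    """Resize a single frame to side x side by bilinear interpolation."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("cannot resize an empty frame")
    if frame.shape == (side, side):
        return frame.astype(np.float32, copy=False)
    out = _sk_resize(frame, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def resize_stack(frames: np.ndarray, side: int) -> np.ndarray:
    if frames.shape[1:] == (side, side):
        return frames.astype(np.float32, copy=False)
    return np.stack([resize(f, side) for f in frames])


def admissible_splice_starts(n_frames: int, null_index: int) -> np.ndarray:
    """Start indices of 9-frame runs that contain the null frame."""
    lo = max(0, null_index - SPLICE_LENGTH + 1)
    hi = min(n_frames - SPLICE_LENGTH, null_index)
    return np.arange(lo, hi + 1)


def splice_start_weights(starts: np.ndarray, null_index: int) -> np.ndarray:
    """Triangular weighting over admissible starts, peaked where the null
    frame lands at the splice centre (oversampling near the optimal TI)."""
    ideal = null_index - SPLICE_LENGTH // 2  # null at centre position 4
    w = SPLICE_LENGTH - np.abs(starts - ideal).astype(float)
    w = np.clip(w, 1.0, None)
    return w / w.sum()


def sample_splice(labelled: LabelledSeries, rng: np.random.Generator,
                  uniform: bool = False) -> LabelledSeries:
    """Draw a 9-frame contiguous splice that contains the null frame.

    The start index follows a triangular distribution over admissible
    starts favouring splices centred on the null (``uniform=True`` disables
    the preference).  A 9-frame series is returned whole; shorter series
    are rejected.
    """
    n = len(labelled.series)
    if n < SPLICE_LENGTH:
        raise ValueError(f"series {labelled.series.series_id!r} has {n} < 9 frames")
    if n == SPLICE_LENGTH:
        return labelled
    starts = admissible_splice_starts(n, labelled.null_index)
    # prefer starts that keep the null off the splice edges, so that after
    # frame dropping it can sit at a window centre (the 0.5 target survives)
    interior = starts[(labelled.null_index - starts > 0)
                      & (labelled.null_index - starts < SPLICE_LENGTH - 1)]
    if interior.size:
        starts = interior
    p = None if uniform else splice_start_weights(starts, labelled.null_index)
    start = int(rng.choice(starts, p=p))
    sub = TIScoutSeries(
        frames=labelled.series.frames[start:start + SPLICE_LENGTH],
        ti_values=labelled.series.ti_values[start:start + SPLICE_LENGTH],
        vendor=labelled.series.vendor,
        series_id=labelled.series.series_id,
    )
    return LabelledSeries(series=sub, null_index=labelled.null_index - start)


def drop_frames(splice: LabelledSeries, rng: np.random.Generator) -> LabelledSeries:
    """Remove two random frames from a 9-frame splice, never the null frame,
    preserving temporal order (emulates coarser temporal resolution)."""
    n = len(splice.series)
    if n != SPLICE_LENGTH:
        raise ValueError(f"drop_frames expects a 9-frame splice, got {n}")
    p = splice.null_index
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)
             if a != p and b != p]
    # prefer removals that leave the null at an interior position of the 7
    # kept frames (positions 1..5), so it remains a window centre
    def _new_pos(pair):
        return p - sum(1 for r in pair if r < p)
    interior = [pair for pair in pairs if 1 <= _new_pos(pair) <= KEPT_FRAMES - 2]
    if interior:
        pairs = interior
    removed = pairs[int(rng.integers(len(pairs)))]
    keep = np.array(sorted(set(range(n)) - set(removed)))
    sub = TIScoutSeries(
        frames=splice.series.frames[keep],
        ti_values=splice.series.ti_values[keep],
        vendor=splice.series.vendor,
        series_id=splice.series.series_id,
    )
    new_null = int(np.searchsorted(keep, splice.null_index))
    return LabelledSeries(series=sub, null_index=new_null)


def extract_windows(labelled: LabelledSeries) -> list[Window]:
    """Slide a width-3, stride-1 window over the frames: n frames give
    n - 2 windows; window k is supervised by frame k + 1 (its centre)."""
    series = labelled.series
    n = len(series)
    if n < WINDOW_WIDTH:
        raise ValueError(f"need at least 3 frames to form a window, got {n}")
    windows = []
    for k in range(n - WINDOW_WIDTH + 1):
        centre = k + 1
        windows.append(Window(
            channels=np.asarray(series.frames[k:k + WINDOW_WIDTH], dtype=np.float32),
            centre_ti=float(series.ti_values[centre]),
            centre_index=centre,
            target=float(labelled.labels[centre]),
        ))
    return windows


@dataclass(frozen=True)
class AugmentPolicy:
    """Stochastic training augmentations, applied identically to the three
    channels of a window (geometry-preserving for the labels).

    Conservative defaults: horizontal/vertical flips, small rotations
    (degrees), multiplicative intensity jitter (fraction).  Everything off
    yields the identity.
    """

    flip_horizontal: float = 0.0   # probability
    flip_vertical: float = 0.0
    max_rotation: float = 0.0      # degrees, uniform in +/- range
    intensity_jitter: float = 0.0  # uniform scale in 1 +/- jitter

    @classmethod
    def training_default(cls) -> "AugmentPolicy":
        return cls(flip_horizontal=0.5, flip_vertical=0.0,
                   max_rotation=10.0, intensity_jitter=0.1)

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls()


def augment(window: Window, policy: AugmentPolicy, rng: np.random.Generator) -> Window:
    """Apply the policy's random transforms to one window."""
    channels = window.channels
    if policy.flip_horizontal and rng.random() < policy.flip_horizontal:
        channels = channels[:, :, ::-1]
    if policy.flip_vertical and rng.random() < policy.flip_vertical:
        channels = channels[:, ::-1, :]
    if policy.max_rotation:
        from scipy.ndimage import rotate as _rotate
        angle = rng.uniform(-policy.max_rotation, policy.max_rotation)
        channels = _rotate(channels, angle, axes=(1, 2), reshape=False,
                           order=1, mode="nearest")
    if policy.intensity_jitter:
        channels = channels * rng.uniform(1 - policy.intensity_jitter,
                                          1 + policy.intensity_jitter)
    return Window(
        channels=np.ascontiguousarray(channels, dtype=np.float32),
        centre_ti=window.centre_ti,
        centre_index=window.centre_index,
        target=window.target,
    )


def training_sample(labelled: LabelledSeries, rng: np.random.Generator,
                    policy: AugmentPolicy | None = None,
                    uniform_splice: bool = False) -> list[Window]:
    """One epoch's training sample for one series: splice -> drop -> 5 windows
    (-> augment).  Always yields exactly five windows, exactly one of which
    carries the 0.5 target."""
    spliced = sample_splice(labelled, rng, uniform=uniform_splice)
    kept = drop_frames(spliced, rng)
    windows = extract_windows(kept)
    if policy is not None:
        windows = [augment(w, policy, rng) for w in windows]
    return windows


def inference_windows(series: TIScoutSeries) -> list[Window]:
    """Validation/test windows: the full series as is, in n - 2 groups of
    three consecutive frames (no splicing, dropping or oversampling).
    Targets are NaN placeholders."""
    n = len(series)
    if n < WINDOW_WIDTH:
        raise ValueError(f"need at least 3 frames for inference, got {n}")
    dummy = LabelledSeries(series=series, null_index=0)
    windows = extract_windows(dummy)
    return [Window(channels=w.channels, centre_ti=w.centre_ti,
                   centre_index=w.centre_index, target=float("nan"))
            for w in windows]
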