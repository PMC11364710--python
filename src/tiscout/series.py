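"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VENDORS = ("ge", "siemens", "philips", "unknown")


@dataclass(frozen=True)
class TIScoutSeries:
    """An ordered TI scout: frame stack, inversion times (ms), provenance.

    Invariants enforced at construction: one TI per frame, strictly
    increasing TIs, a single frame geometry.
    """

    frames: np.ndarray          # (n_frames, H, W) float
    ti_values: np.ndarray       # (n_frames,) ms, strictly increasing
    vendor: str = "unknown"
    series_id: str = ""

    def __post_init__(self):
        frames = np.asarray(self.frames)
        tis = np.asarray(self.ti_values, dtype=float)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) stack")
        if len(frames) != len(tis):
            raise ValueError("one TI value per frame is required")
        if len(frames) < 1:
            raise ValueError("a series needs at least one frame")
        if np.any(np.diff(tis) <= 0):
            raise ValueError("ti_values must be strictly increasing")
        if self.vendor not in VENDORS:
            raise ValueError(f"vendor must be one of {VENDORS}, got {self.vendor!r}")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "ti_values", tis)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class LabelledSeries:
    """A series plus its annotated null frame and derived soft labels.

    Labels are 0 before the null frame, 0.5 at it, 1 after it — the
    transition encoding the model is trained to reproduce.
    """

    series: TIScoutSeries
    null_index: int
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n = len(self.series)
        if not (0 <= self.null_index < n):
            raise ValueError(
                f"null_index {self.null_index} out of range for {n}-frame series"
            )
        labels = np.ones(n, dtype=float)
        labels[: self.null_index] = 0.0
        labels[self.null_index] = 0.5
        object.__setattr__(self, "labels", labels)

    @property
    def null_ti(self) -> float:
        return float(self.series.ti_values[self.null_index])
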