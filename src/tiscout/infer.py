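"""Decoding a predicted optimal TI from window probabilities.

The operative rule: the window whose probability is closest to 0.5 marks
the class transition; the predicted TI is its centre frame's inversion
time.  Exact ties break to the earliest window by default (a ``latest``
option exists, matching the observation that slight overestimation is the
more benign error for LGE imaging).  An alternative transition-point
decoder (first 0.5 crossing of the monotone-smoothed trace) is available
but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelBundle, WindowProbabilities, sequence_probabilities
from .preprocess import inference_windows, normalize, resize_stack
from .series import TIScoutSeries

__all__ = ["TIPrediction", "select_null_window", "predict_ti"]


@dataclass(frozen=True)
class TIPrediction:
    """A decoded prediction: TI (ms), window / frame indices, and the full
    probability trace for audit."""

    predicted_ti: float
    predicted_window_index: int
    predicted_frame_index: int
    probability_trace: WindowProbabilities


def select_null_window(probabilities: WindowProbabilities | np.ndarray,
                       tie_break: str = "earliest") -> int:
    """Index of the window with probability closest to 0.5."""
    values = probabilities.values if isinstance(probabilities, WindowProbabilities) \
        else np.asarray(probabilities, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one window probability")
    dist = np.abs(values - 0.5)
    if tie_break == "earliest":
        return int(np.argmin(dist))
    elif tie_break == "latest":
        return int(values.size - 1 - np.argmin(dist[::-1]))
    raise ValueError(f"unknown tie_break {tie_break!r}")


def select_transition_window(probabilities: WindowProbabilities | np.ndarray) -> int:
    """Alternative decoder: first window whose monotone-smoothed probability
    reaches 0.5 (the 0 -> 1 transition point)."""
    values = probabilities.values if isinstance(probabilities, WindowProbabilities) \
        else np.asarray(probabilities, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one window probability")
    mono = np.maximum.accumulate(values)
    above = np.nonzero(mono >= 0.5)[0]
    return int(above[0]) if above.size else int(values.size - 1)


def predict_ti(bundle: ModelBundle, series: TIScoutSeries,
               tie_break: str = "earliest",
               decoder: str = "closest") -> TIPrediction:
    """Run the full inference path on one series.

    The whole series is windowed as is (n - 2 windows of three consecutive
    frames), standardised with the bundle's stored corpus statistics,
    resized to the model resolution, and passed through the network; the
    closest-to-0.5 window's centre TI is returned.
    """
    if len(series) < 3:
        raise ValueError(f"series {series.series_id!r} has {len(series)} < 3 frames")
    side = bundle.spec.image_size
    frames = resize_stack(series.frames, side)
    frames = normalize(frames, bundle.norm_stats)
    prepared = TIScoutSeries(frames=frames, ti_values=series.ti_values,
                             vendor=series.vendor, series_id=series.series_id)
    windows = inference_windows(prepared)
    bundle.network.eval()
    probs = sequence_probabilities(bundle.network, windows)
    if decoder == "closest":
        k = select_null_window(probs, tie_break=tie_break)
    elif decoder == "transition":
        k = select_transition_window(probs)
    else:
        raise ValueError(f"unknown decoder {decoder!r}")
    return TIPrediction(
        predicted_ti=float(probs.centre_tis[k]),
        predicted_window_index=k,
        predicted_frame_index=k + 1,
        probability_trace=probs,
    )
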