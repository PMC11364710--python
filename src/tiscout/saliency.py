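"""Gradient-based model interpretability.

Spatial saliency: the magnitude of the gradient of the selected window's
pre-logistic score with respect to the input pixels, accumulated over the
(up to three) windows each frame participates in, optionally Gaussian
smoothed.  Temporal saliency: the mean of each frame's spatial map — a
per-frame attention profile that should peak around the predicted null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .infer import select_null_window
from .model import ModelBundle
from .preprocess import inference_windows, normalize, resize_stack
from .series import TIScoutSeries

__all__ = ["SaliencyResult", "spatial_saliency", "temporal_saliency", "compute_saliency"]


@dataclass(frozen=True)
class SaliencyResult:
    """Per-frame non-negative saliency maps and the derived temporal profile."""

    spatial_maps: np.ndarray     # (n_frames, S, S), >= 0
    temporal_profile: np.ndarray  # (n_frames,)
    selected_window: int
    smoothed: bool
    gaussian_sigma: float


def spatial_saliency(bundle: ModelBundle, series: TIScoutSeries,
                     gaussian_sigma: float = 2.0, smooth: bool = True) -> SaliencyResult:
    """Per-frame saliency of the decoded prediction for one series.

    The series goes through the standard inference path; the gradient of the
    selected window's logit is backpropagated to the input pixels, absolute
    gradients are summed over each frame's window memberships, and the maps
    are optionally smoothed with a Gaussian of ``gaussian_sigma`` pixels
    (``sigma = 0`` is the identity).
    """
    if len(series) < 3:
        raise ValueError("saliency needs a series of at least 3 frames")
    side = bundle.spec.image_size
    frames = normalize(resize_stack(series.frames, side), bundle.norm_stats)
    prepared = TIScoutSeries(frames=frames, ti_values=series.ti_values,
                             vendor=series.vendor, series_id=series.series_id)
    windows = inference_windows(prepared)

    network = bundle.network
    network.eval()
    stack = np.stack([w.channels for w in windows])[:, None]    # (T, 1, 3, S, S)
    logits = network.forward_sequence(stack)
    probs = 1.0 / (1.0 + np.exp(-logits[:, 0].astype(np.float64)))
    k_star = select_null_window(probs)

    dlogits = np.zeros_like(logits)
    dlogits[k_star, 0] = 1.0                                    # pre-logistic score
    network.zero_grad()
    dx = network.backward_sequence(dlogits)[:, 0]               # (T, 3, S, S)

    n_frames = len(series)
    maps = np.zeros((n_frames, side, side), dtype=np.float64)
    for k in range(len(windows)):                               # frame k+c sits in window k, channel c
        for c in range(3):
            maps[k + c] += np.abs(dx[k, c])
    if smooth and gaussian_sigma > 0:
        maps = np.stack([gaussian_filter(m, sigma=gaussian_sigma) for m in maps])
        smoothed = True
    else:
        smoothed = False
    return SaliencyResult(
        spatial_maps=maps,
        temporal_profile=temporal_saliency(maps),
        selected_window=k_star,
        smoothed=smoothed,
        gaussian_sigma=float(gaussian_sigma if smoothed else 0.0),
    )


def temporal_saliency(spatial_maps: np.ndarray) -> np.ndarray:
    """Average intensity of each frame's saliency map."""
    maps = np.asarray(spatial_maps)
    if maps.ndim != 3 or len(maps) == 0:
        raise ValueError("expected a non-empty (n_frames, H, W) map stack")
    return maps.mean(axis=(1, 2))


def compute_saliency(bundle: ModelBundle, series: TIScoutSeries,
                     gaussian_sigma: float = 2.0, smooth: bool = True) -> SaliencyResult:
    """Alias for :func:`spatial_saliency` (maps + temporal profile)."""
    return spatial_saliency(bundle, series, gaussian_sigma=gaussian_sigma, smooth=smooth)
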