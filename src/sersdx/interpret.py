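"""CNN peak-contribution profile across Raman shifts.

Attribution is gradient x input on the pre-sigmoid logit: for each test
spectrum, the gradient of the logit with respect to every input channel is
multiplied channel-wise by the input intensity, and the products are
averaged over the dataset.  Positive contributions push the model toward
the malignant class.  The averaged profile is lightly smoothed (SG window
5, order 3) and its local extrema, separated by at least 10 cm^-1, are
ranked by absolute contribution to name diagnostically significant bands.

An occlusion variant (zeroing a sliding window and recording the mean
logit drop) is available for robustness comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .classifiers import CnnModel
from .core import SpectrumDataset
from .errors import ValidationError


@dataclass
class SaliencyProfile:
    shifts: np.ndarray
    contribution: np.ndarray
    top_peaks: list[tuple[float, float]]  # (center cm^-1, signed contribution), |c| descending


def _extract_peaks(shifts: np.ndarray, profile: np.ndarray, min_separation: float) -> list[tuple[float, float]]:
    step = float(np.median(np.diff(shifts)))
    distance = max(1, int(round(min_separation / step)))
    peaks = []
    for sign in (1.0, -1.0):
        idx, _ = find_peaks(sign * profile, distance=distance)
        peaks.extend((float(shifts[i]), float(profile[i])) for i in idx)
    peaks.sort(key=lambda p: abs(p[1]), reverse=True)
    # enforce separation across the merged positive/negative extrema lists
    kept: list[tuple[float, float]] = []
    for center, value in peaks:
        if all(abs(center - c) >= min_separation for c, _ in kept):
            kept.append((center, value))
    return kept


def gradient_times_input(model, dataset: SpectrumDataset) -> np.ndarray:
    """Mean over spectra of d(logit)/d(channel) * channel intensity."""
    grads = model.input_gradients(dataset)
    return (grads * dataset.intensities).mean(axis=0)


def cnn_saliency(
    model: CnnModel,
    dataset: SpectrumDataset,
    smooth_window: int = 5,
    smooth_order: int = 3,
    min_separation: float = 10.0,
) -> SaliencyProfile:
    """Peak-contribution profile of a fitted CNN over a dataset."""
    if not isinstance(model, CnnModel):
        raise ValidationError(
            f"saliency attribution supports only the cnn model, got {getattr(model, 'model_kind', type(model).__name__)!r}"
        )
    if len(dataset) == 0:
        raise ValidationError("saliency needs a nonempty dataset")
    raw = gradient_times_input(model, dataset)
    smoothed = savgol_filter(raw, smooth_window, smooth_order, mode="interp")
    return SaliencyProfile(dataset.shifts.copy(), smoothed,
                           _extract_peaks(dataset.shifts, smoothed, min_separation))


def occlusion_profile(model: CnnModel, dataset: SpectrumDataset, window: int = 11) -> np.ndarray:
    """Mean logit drop when a sliding window of channels is zeroed.

    Positive values mark regions whose presence pushes scores toward
    malignant; coarser but model-agnostic compared to gradient x input.
    """
    if not isinstance(model, CnnModel):
        raise ValidationError("occlusion attribution supports only the cnn model")
    base = model._logits(dataset.intensities)
    n_channels = dataset.intensities.shape[1]
    half = window // 2
    profile = np.zeros(n_channels)
    for c in range(n_channels):
        occluded = dataset.intensities.copy()
        occluded[:, max(0, c - half) : c + half + 1] = 0.0
        profile[c] = float(np.mean(base - model._logits(occluded)))
    return profile
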