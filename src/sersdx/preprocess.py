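"""Spectral preprocessing chain and group-level aggregation.

The chain applied to every spectrum, in order:

1. Savitzky–Golay smoothing (window 5, order 3) — local least-squares
   polynomial fit; exact on polynomials up to the fit order.  Edges are
   handled by fitting the nearest full window and evaluating the fitted
   polynomial at the edge positions (no reflection padding).
2. airPLS baseline removal (adaptive iteratively reweighted penalized
   least squares): the baseline z minimizes

       sum_i w_i (y_i - z_i)^2 + lambda * sum (Delta^d z)^2,

   a weighted Whittaker smoother, with weights re-estimated each pass —
   zeroed on channels above the baseline (peaks) and exponentially
   up-weighted below it — until the negative-residual mass falls under
   ``tol`` of the total signal magnitude.  Defaults: lambda = 150,
   difference order d = 3.
3. Crop to the 300–1800 cm^-1 fingerprint region.
4. Per-spectrum linear min-max normalization to (0, 1).

Cropping precedes normalization so the analyzed window itself spans [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .core import Spectrum, SpectrumDataset, crop_dataset
from .errors import ConfigError, DegenerateInputError, SersdxError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    sg_window: int = 5
    sg_order: int = 3
    airpls_lambda: float = 150.0
    airpls_diff_order: int = 3
    airpls_max_iter: int = 15
    airpls_tol: float = 1e-3
    norm_lo: float = 0.0
    norm_hi: float = 1.0
    crop_lo: float = 300.0
    crop_hi: float = 1800.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_order:
            raise ConfigError(
                f"sg_window must be odd and > sg_order, got window={self.sg_window}, order={self.sg_order}"
            )
        if self.airpls_lambda <= 0:
            raise ConfigError("airpls_lambda must be > 0")
        if self.airpls_diff_order not in (1, 2, 3):
            raise ConfigError("airpls_diff_order must be 1, 2 or 3")
        if self.airpls_max_iter < 1 or self.airpls_tol <= 0:
            raise ConfigError("airpls_max_iter must be >= 1 and airpls_tol > 0")
        if not self.norm_lo < self.norm_hi:
            raise ConfigError("norm_lo must be < norm_hi")
        if not self.crop_lo < self.crop_hi:
            raise ConfigError("crop_lo must be < crop_hi")


# ---------------------------------------------------------------- smoothing


def savitzky_golay(spectrum: Spectrum, window: int = 5, order: int = 3) -> Spectrum:
    """Least-squares polynomial smoothing over a sliding window."""
    if window % 2 != 1 or window <= order:
        raise ConfigError(f"window must be odd and > order, got window={window}, order={order}")
    if len(spectrum) < window:
        raise ConfigError(f"spectrum has {len(spectrum)} channels, fewer than window={window}")
    smoothed = savgol_filter(spectrum.intensities, window, order, mode="interp")
    return spectrum.with_intensities(smoothed)


# ------------------------------------------------------------------ airPLS


def _penalty_bands(n: int, diff_order: int, lam: float) -> np.ndarray:
    """Upper banded form (for ``solveh_banded``) of lambda * D^T D."""
    D = sparse.eye(n, format="csc")
    for _ in range(diff_order):
        D = D[1:] - D[:-1]
    P = (lam * (D.T @ D)).todia()
    ab = np.zeros((diff_order + 1, n))
    for off, data in zip(P.offsets, P.data):
        if off >= 0:
            ab[diff_order - off] = data
    return ab


def _airpls_core(
    y: np.ndarray,
    lam: float,
    diff_order: int,
    max_iter: int,
    tol: float,
    bands: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """airPLS reweighting loop on a raw intensity vector.

    Returns (baseline, converged).  Non-convergence is not an error: the
    baseline at max_iter is returned and the caller may log it.
    """
    n = len(y)
    if bands is None:
        bands = _penalty_bands(n, diff_order, lam)
    w = np.ones(n)
    abs_y = np.abs(y).sum()
    z = np.zeros(n)
    for t in range(1, max_iter + 1):
        ab = bands.copy()
        ab[-1] += w
        z = solveh_banded(ab, w * y, lower=False)
        neg = y < z
        d = y[neg] - z[neg]
        d_norm = np.abs(d).sum()
        if d_norm < tol * abs_y or d_norm == 0.0:
            return z, True
        w[:] = 0.0
        w[neg] = np.exp(t * np.abs(d) / d_norm)
    return z, False


def airpls_baseline(
    spectrum: Spectrum,
    lam: float = 150.0,
    diff_order: int = 3,
    max_iter: int = 15,
    tol: float = 1e-3,
) -> tuple[Spectrum, Spectrum]:
    """Estimate and subtract the baseline; returns (baseline, corrected)."""
    if lam <= 0:
        raise ConfigError("lambda must be > 0")
    z, converged = _airpls_core(spectrum.intensities, lam, diff_order, max_iter, tol)
    if not converged:
        logger.warning("airPLS did not converge within %d iterations on %r", max_iter, spectrum.spectrum_id)
    return spectrum.with_intensities(z), spectrum.with_intensities(spectrum.intensities - z)


# ------------------------------------------------------------- normalization


def normalize_minmax(spectrum: Spectrum, lo: float = 0.0, hi: float = 1.0) -> Spectrum:
    """Affine map sending the spectrum's min to ``lo`` and max to ``hi``."""
    y = spectrum.intensities
    ymin, ymax = y.min(), y.max()
    if ymax == ymin:
        raise DegenerateInputError(f"constant spectrum {spectrum.spectrum_id!r} cannot be min-max normalized")
    return spectrum.with_intensities(lo + (hi - lo) * (y - ymin) / (ymax - ymin))


# ----------------------------------------------------------------- pipeline


def preprocess_dataset(dataset: SpectrumDataset, config: PreprocessConfig | None = None) -> SpectrumDataset:
    """smooth -> baseline-correct -> crop -> normalize, per spectrum.

    The manifest passes through unchanged; failures carry the offending
    spectrum_id.
    """
    config = config or PreprocessConfig()
    Y = savgol_filter(dataset.intensities, config.sg_window, config.sg_order, axis=-1, mode="interp")
    bands = _penalty_bands(Y.shape[1], config.airpls_diff_order, config.airpls_lambda)
    corrected = np.empty_like(Y)
    for i in range(Y.shape[0]):
        z, converged = _airpls_core(
            Y[i], config.airpls_lambda, config.airpls_diff_order,
            config.airpls_max_iter, config.airpls_tol, bands=bands,
        )
        if not converged:
            logger.warning(
                "airPLS did not converge on spectrum %r", dataset.manifest["spectrum_id"].iloc[i]
            )
        corrected[i] = Y[i] - z
    out = crop_dataset(dataset.with_intensities(corrected), config.crop_lo, config.crop_hi)
    ymin = out.intensities.min(axis=1, keepdims=True)
    ymax = out.intensities.max(axis=1, keepdims=True)
    flat = (ymax == ymin).ravel()
    if flat.any():
        sid = out.manifest["spectrum_id"].iloc[int(np.flatnonzero(flat)[0])]
        raise DegenerateInputError(f"constant spectrum {sid!r} cannot be min-max normalized")
    scaled = config.norm_lo + (config.norm_hi - config.norm_lo) * (out.intensities - ymin) / (ymax - ymin)
    return out.with_intensities(scaled)


# -------------------------------------------------------------- aggregation


def sample_means(dataset: SpectrumDataset, class_label: str | None = None) -> tuple[list[str], np.ndarray]:
    """Per-sample mean spectra (the first stage of the two-stage group mean)."""
    m = dataset.manifest
    mask = np.ones(len(m), dtype=bool) if class_label is None else (m["class_label"] == class_label).to_numpy()
    if not mask.any():
        raise ValidationError(f"class {class_label!r} not present in dataset")
    sub = m[mask]
    ids, means = [], []
    for sample_id, grp in sub.groupby("sample_id", sort=True):
        ids.append(str(sample_id))
        means.append(dataset.intensities[grp.index.to_numpy()].mean(axis=0))
    return ids, np.vstack(means)


def group_mean_and_sd(dataset: SpectrumDataset, class_label: str) -> tuple[Spectrum, Spectrum]:
    """Group mean and SD computed across sample means, not pooled spectra.

    Each sample contributes equally regardless of its replicate count; the
    SD (n-1 denominator) therefore reflects between-sample variability.
    """
    ids, means = sample_means(dataset, class_label)
    if len(ids) < 2:
        raise DegenerateInputError(
            f"class {class_label!r} has {len(ids)} sample(s); SD across samples needs >= 2"
        )
    mean = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    return (
        Spectrum(dataset.shifts, mean, f"mean_{class_label}"),
        Spectrum(dataset.shifts, sd, f"sd_{class_label}"),
    )


def difference_spectrum(dataset: SpectrumDataset) -> Spectrum:
    """Malignant group mean minus benign group mean, channel-wise."""
    _, mal = sample_means(dataset, "malignant")
    _, ben = sample_means(dataset, "benign")
    return Spectrum(
        dataset.shifts, mal.mean(axis=0) - ben.mean(axis=0), "difference_malignant_minus_benign"
    )
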