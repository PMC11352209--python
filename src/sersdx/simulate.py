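"""Synthetic SERS cohort generator.

The clinical spectra this pipeline was designed around are not publicly
deposited, so this module generates labelled cohorts with the same
statistical structure: a fixed library of vibrational bands whose mean
amplitudes differ between malignant and benign samples, a constant
preservation-buffer band, a smooth fluorescence-like background, and
hierarchical amplitude noise (patient -> sample -> spectrum).  Because
patient and sample effects are shared across all replicate spectra of a
sample, splitting at the spectrum level leaks sample fingerprints into the
test set — exactly the failure mode patient-level splitting guards against,
and the reason the generator is hierarchical rather than i.i.d.

Generative model for one spectrum of sample *s* of patient *q* with class
indicator ``c`` (malignant = 1)::

    y(x) = sum_k a_k * L_k(x) + buffer(x) + baseline(x) + eps(x),  clipped at 0
    a_k  = base_k + c * effect_scale * delta_k + u_qk + v_sk
    u_qk ~ N(0, sigma_patient^2),  v_sk ~ N(0, sigma_sample^2)   (per band)
    eps(x) ~ N(0, sigma_noise^2)                                  (per channel)

where ``L_k`` is a unit-apex Lorentzian (optionally Gaussian) with
half-width-at-half-maximum ``width_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .core import GridSpec, SpectrumDataset, MANIFEST_COLUMNS
from .errors import ConfigError


@dataclass(frozen=True)
class PeakSpec:
    """One vibrational band of the simulator's peak library.

    ``width`` is the half-width at half-maximum in cm^-1; ``class_delta`` is
    the malignant-minus-benign shift of the mean apex amplitude (a.u.).
    """

    center: float
    width: float
    base_amplitude: float
    class_delta: float = 0.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ConfigError(f"peak at {self.center}: width must be > 0")
        if self.base_amplitude < 0:
            raise ConfigError(f"peak at {self.center}: base_amplitude must be >= 0")
        if self.base_amplitude + self.class_delta < 0:
            raise ConfigError(f"peak at {self.center}: base_amplitude + class_delta must be >= 0")


# Band positions follow the standard SERS assignments for FNA washout
# fluids: 747 (adenine / cytochrome c), 1038 (tau(HCH), collagen /
# phospholipids / phenylalanine), 1163 (C-C / C-N stretch, proteins and
# lipids), 1396 (CH rocking, carbohydrates), 1616 (amide I and lipids).
# The malignant-minus-benign deltas sit on 747, 1038, 1396 and 1616, the
# bands the difference spectrum and the CNN contribution profile single
# out.  1036 is the preservation-buffer band (constant across classes);
# 1459 is the residual-ethanol band of the buffer, also class-neutral.
DEFAULT_PEAKS = [
    PeakSpec(center=747.0, width=10.0, base_amplitude=0.80, class_delta=0.20),
    PeakSpec(center=1038.0, width=9.0, base_amplitude=0.60, class_delta=0.40),
    PeakSpec(center=1163.0, width=10.0, base_amplitude=0.50, class_delta=0.10),
    PeakSpec(center=1396.0, width=11.0, base_amplitude=0.45, class_delta=0.24),
    PeakSpec(center=1616.0, width=12.0, base_amplitude=0.55, class_delta=0.30),
    PeakSpec(center=1459.0, width=12.0, base_amplitude=0.35, class_delta=0.0),
]
DEFAULT_BUFFER_PEAK = PeakSpec(center=1036.0, width=14.0, base_amplitude=0.70, class_delta=0.0)

# Fluorescence-like background: cubic in the normalized coordinate
# u = (x - start)/(stop - start), plus a broad Rayleigh-wing Lorentzian
# centred below the measured range so airPLS has realistic work to do.
# Magnitudes are on the order of the band amplitudes.
DEFAULT_BASELINE_COEFFS = [1.0, -1.2, 0.9, -0.3]
DEFAULT_WING = PeakSpec(center=150.0, width=350.0, base_amplitude=1.5, class_delta=0.0)

DEFAULT_SIGMA_PATIENT = 0.10
DEFAULT_SIGMA_SAMPLE = 0.10
DEFAULT_SIGMA_NOISE = 0.02


@dataclass
class SimulationConfig:
    n_patients: int = 18
    samples_per_class_per_patient: int = 1
    spectra_per_sample: int = 100
    grid: GridSpec = field(default_factory=lambda: GridSpec(300.0, 2000.0, 1.0))
    peaks: list[PeakSpec] = field(default_factory=lambda: list(DEFAULT_PEAKS))
    buffer_peak: PeakSpec = field(default_factory=lambda: DEFAULT_BUFFER_PEAK)
    baseline_coeffs: list[float] = field(default_factory=lambda: list(DEFAULT_BASELINE_COEFFS))
    baseline_wing: PeakSpec = field(default_factory=lambda: DEFAULT_WING)
    sigma_patient: float = DEFAULT_SIGMA_PATIENT
    sigma_sample: float = DEFAULT_SIGMA_SAMPLE
    sigma_noise: float = DEFAULT_SIGMA_NOISE
    effect_scale: float = 1.0
    line_shape: Literal["lorentzian", "gaussian"] = "lorentzian"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "samples_per_class_per_patient", "spectra_per_sample"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("sigma_patient", "sigma_sample", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.effect_scale < 0:
            raise ConfigError("effect_scale must be >= 0")
        if self.buffer_peak.class_delta != 0:
            raise ConfigError("buffer_peak must have class_delta = 0 (constant background)")
        if self.line_shape not in ("lorentzian", "gaussian"):
            raise ConfigError(f"unknown line_shape {self.line_shape!r}")

    # -------------------------------------------------------------- serde

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {"start": self.grid.start, "stop": self.grid.stop, "step": self.grid.step}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = GridSpec(**d["grid"])
        for key in ("peaks",):
            if key in d:
                d[key] = [p if isinstance(p, PeakSpec) else PeakSpec(**p) for p in d[key]]
        for key in ("buffer_peak", "baseline_wing"):
            if key in d and isinstance(d[key], dict):
                d[key] = PeakSpec(**d[key])
        return cls(**d)


def default_config(seed: int = 0) -> SimulationConfig:
    """The study-design defaults: 18 patients, one malignant and one benign
    sample each (36 samples), 100 spectra per sample (1800 per class),
    300-2000 cm^-1 at 1 cm^-1."""
    return SimulationConfig(seed=seed)


# ------------------------------------------------------------------ model


def line_profile(shifts: np.ndarray, center: float, width: float, shape: str = "lorentzian") -> np.ndarray:
    """Unit-apex band profile; ``width`` is the HWHM for both shapes."""
    if shape == "lorentzian":
        return 1.0 / (1.0 + ((shifts - center) / width) ** 2)
    return np.exp(-np.log(2.0) * ((shifts - center) / width) ** 2)


def baseline_template(config: SimulationConfig) -> np.ndarray:
    """Deterministic smooth background shared by every spectrum."""
    x = config.grid.shifts
    u = (x - config.grid.start) / (config.grid.stop - config.grid.start)
    poly = np.polynomial.polynomial.polyval(u, np.asarray(config.baseline_coeffs, dtype=float))
    wing = config.baseline_wing
    return poly + wing.base_amplitude * line_profile(x, wing.center, wing.width, config.line_shape)


def class_template(config: SimulationConfig, malignant: bool) -> np.ndarray:
    """Noise-free expected spectrum of a class (before clipping)."""
    x = config.grid.shifts
    total = baseline_template(config).copy()
    for pk in [*config.peaks, config.buffer_peak]:
        amp = pk.base_amplitude + (config.effect_scale * pk.class_delta if malignant else 0.0)
        total += amp * line_profile(x, pk.center, pk.width, config.line_shape)
    return total


def simulate(config: SimulationConfig) -> SpectrumDataset:
    """Draw a full cohort; bit-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    x = config.grid.shifts
    all_peaks = [*config.peaks, config.buffer_peak]
    profiles = np.stack([line_profile(x, p.center, p.width, config.line_shape) for p in all_peaks])
    base_amps = np.array([p.base_amplitude for p in all_peaks])
    deltas = np.array([p.class_delta for p in all_peaks]) * config.effect_scale
    baseline = baseline_template(config)

    rows, blocks = [], []
    for q in range(config.n_patients):
        patient_id = f"P{q:02d}"
        patient_eff = rng.normal(0.0, config.sigma_patient, size=len(all_peaks))
        for cls_name, cls in (("benign", 0), ("malignant", 1)):
            for s in range(config.samples_per_class_per_patient):
                sample_id = f"{patient_id}_{cls_name[:3]}{s}"
                sample_eff = rng.normal(0.0, config.sigma_sample, size=len(all_peaks))
                amps = base_amps + cls * deltas + patient_eff + sample_eff
                clean = amps @ profiles + baseline
                noise = rng.normal(0.0, config.sigma_noise, size=(config.spectra_per_sample, len(x)))
                blocks.append(np.clip(clean + noise, 0.0, None))
                rows.extend(
                    (f"{sample_id}_s{j:03d}", sample_id, patient_id, cls_name)
                    for j in range(config.spectra_per_sample)
                )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return SpectrumDataset(x, np.vstack(blocks), manifest)
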