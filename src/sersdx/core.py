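"""Domain types and I/O for SERS spectra.

A :class:`Spectrum` is a single Raman/SERS trace on a strictly increasing
wavenumber grid (cm^-1).  A :class:`SpectrumDataset` bundles many spectra
that share one grid with a manifest recording, for each spectrum, which
physical sample and patient it came from and the diagnostic class of that
sample.  The manifest hierarchy (patient -> sample -> spectrum) is what
patient-level splitting relies on, so its consistency is enforced here.

On-disk layout (UTF-8 delimited text, '.' decimal separator):

* spectra matrix — header ``spectrum_id,<shift_1>,...,<shift_p>`` followed
  by one row per spectrum; floats are written with 9 significant digits;
* manifest — columns ``spectrum_id, sample_id, patient_id, class_label``
  with ``class_label`` in ``{benign, malignant}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, ValidationError

CLASS_LABELS = ("benign", "malignant")
#: class encoding used consistently by every model and metric
POSITIVE_CLASS = "malignant"

MIN_CHANNELS = 8
FLOAT_FMT = "%.9g"

MANIFEST_COLUMNS = ["spectrum_id", "sample_id", "patient_id", "class_label"]


@dataclass(frozen=True)
class GridSpec:
    """Uniform wavenumber grid: ``start, start+step, ..., <= stop`` (cm^-1)."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if not (self.start < self.stop):
            raise ValidationError(f"GridSpec requires start < stop, got {self.start} >= {self.stop}")
        if not (self.step > 0):
            raise ValidationError(f"GridSpec requires step > 0, got {self.step}")

    @property
    def shifts(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)

    @property
    def n_channels(self) -> int:
        return len(self.shifts)


@dataclass
class Spectrum:
    """One trace: intensities (a.u.) over strictly increasing shifts (cm^-1)."""

    shifts: np.ndarray
    intensities: np.ndarray
    spectrum_id: str = ""

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("shifts and intensities must be one-dimensional")
        if len(self.shifts) != len(self.intensities):
            raise ValidationError(
                f"length mismatch: {len(self.shifts)} shifts vs {len(self.intensities)} intensities"
            )
        if len(self.shifts) < MIN_CHANNELS:
            raise ValidationError(f"a spectrum needs >= {MIN_CHANNELS} channels, got {len(self.shifts)}")
        if not np.all(np.isfinite(self.shifts)) or not np.all(np.isfinite(self.intensities)):
            raise ValidationError(f"non-finite values in spectrum {self.spectrum_id!r}")
        if not np.all(np.diff(self.shifts) > 0):
            raise ValidationError(f"shifts must be strictly increasing in spectrum {self.spectrum_id!r}")

    def __len__(self) -> int:
        return len(self.shifts)

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.shifts.copy(), np.asarray(intensities, dtype=float), self.spectrum_id)


@dataclass
class SpectrumDataset:
    """Spectra on one shared grid plus the patient/sample/class manifest.

    Rows of ``intensities`` align with rows of ``manifest``.  Invariants
    checked at construction: unique spectrum ids, one patient and one class
    per sample, labels in ``{benign, malignant}``.
    """

    shifts: np.ndarray
    intensities: np.ndarray  # (n_spectra, n_channels)
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.manifest = self.manifest.reset_index(drop=True)
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be a 2-D matrix (spectra x channels)")
        if self.intensities.shape[1] != len(self.shifts):
            raise ValidationError("intensity matrix width does not match the shift grid")
        if list(self.manifest.columns[:4]) != MANIFEST_COLUMNS:
            raise FormatError(f"manifest must have columns {MANIFEST_COLUMNS}")
        if len(self.manifest) != self.intensities.shape[0]:
            raise ValidationError("manifest row count does not match the number of spectra")
        if not np.all(np.diff(self.shifts) > 0):
            raise FormatError("shift grid must be strictly increasing")
        ids = self.manifest["spectrum_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate spectrum_id {dup.iloc[0]!r} in manifest")
        bad = set(self.manifest["class_label"]) - set(CLASS_LABELS)
        if bad:
            raise ValidationError(f"unknown class label(s) {sorted(bad)}; expected one of {CLASS_LABELS}")
        per_sample = self.manifest.groupby("sample_id")[["patient_id", "class_label"]].nunique()
        mixed = per_sample[(per_sample > 1).any(axis=1)]
        if len(mixed):
            raise ValidationError(
                f"sample {mixed.index[0]!r} maps to more than one patient_id or class_label"
            )

    # ------------------------------------------------------------------ views

    def __len__(self) -> int:
        return len(self.manifest)

    @property
    def spectrum_ids(self) -> list[str]:
        return self.manifest["spectrum_id"].tolist()

    @property
    def labels(self) -> np.ndarray:
        """Binary class vector, malignant = 1."""
        return (self.manifest["class_label"] == POSITIVE_CLASS).to_numpy(dtype=int)

    def spectra(self) -> Iterator[Spectrum]:
        for i, sid in enumerate(self.manifest["spectrum_id"]):
            yield Spectrum(self.shifts, self.intensities[i], str(sid))

    def subset(self, mask: np.ndarray) -> "SpectrumDataset":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return SpectrumDataset(self.shifts, self.intensities[idx], self.manifest.iloc[idx])

    def subset_patients(self, patient_ids: Sequence[str]) -> "SpectrumDataset":
        keep = self.manifest["patient_id"].isin(list(patient_ids)).to_numpy()
        return self.subset(keep)

    def with_intensities(self, intensities: np.ndarray, shifts: np.ndarray | None = None) -> "SpectrumDataset":
        return SpectrumDataset(
            self.shifts if shifts is None else shifts, intensities, self.manifest
        )


# ---------------------------------------------------------------------- ops


def resample(spectrum: Spectrum, grid: GridSpec) -> Spectrum:
    """Linearly interpolate a spectrum onto a uniform grid (no extrapolation)."""
    target = grid.shifts
    if target[0] < spectrum.shifts[0] - 1e-9 or target[-1] > spectrum.shifts[-1] + 1e-9:
        raise ValidationError(
            f"grid [{target[0]}, {target[-1]}] extends beyond the data range "
            f"[{spectrum.shifts[0]}, {spectrum.shifts[-1]}]; extrapolation is not supported"
        )
    values = np.interp(target, spectrum.shifts, spectrum.intensities)
    return Spectrum(target, values, spectrum.spectrum_id)


def crop(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep channels with lo <= shift <= hi (closed interval)."""
    if not lo < hi:
        raise ValidationError(f"crop requires lo < hi, got ({lo}, {hi})")
    keep = (spectrum.shifts >= lo) & (spectrum.shifts <= hi)
    if not keep.any():
        raise DegenerateInputError(f"crop({lo}, {hi}) leaves no channels")
    return Spectrum(spectrum.shifts[keep], spectrum.intensities[keep], spectrum.spectrum_id)


def crop_dataset(dataset: SpectrumDataset, lo: float, hi: float) -> SpectrumDataset:
    if not lo < hi:
        raise ValidationError(f"crop requires lo < hi, got ({lo}, {hi})")
    keep = (dataset.shifts >= lo) & (dataset.shifts <= hi)
    if not keep.any():
        raise DegenerateInputError(f"crop({lo}, {hi}) leaves no channels")
    return SpectrumDataset(dataset.shifts[keep], dataset.intensities[:, keep], dataset.manifest)


# ---------------------------------------------------------------------- I/O


def _detect_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_dataset(dataset: SpectrumDataset, spectra_path: str | Path, manifest_path: str | Path) -> None:
    """Write the spectra matrix and manifest as delimited text (9 sig. digits)."""
    spectra_path, manifest_path = Path(spectra_path), Path(manifest_path)
    sep = _detect_sep(spectra_path)
    header = "spectrum_id" + sep + sep.join(FLOAT_FMT % s for s in dataset.shifts)
    with open(spectra_path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for sid, row in zip(dataset.manifest["spectrum_id"], dataset.intensities):
            fh.write(str(sid) + sep + sep.join(FLOAT_FMT % v for v in row) + "\n")
    dataset.manifest[MANIFEST_COLUMNS].to_csv(
        manifest_path, sep=_detect_sep(manifest_path), index=False, encoding="utf-8"
    )


def read_dataset(spectra_path: str | Path, manifest_path: str | Path) -> SpectrumDataset:
    """Read and validate a dataset written by :func:`write_dataset`.

    The manifest row order defines the dataset order; every manifest
    spectrum_id must appear in the matrix and vice versa.
    """
    spectra_path, manifest_path = Path(spectra_path), Path(manifest_path)
    mat = pd.read_csv(spectra_path, sep=_detect_sep(spectra_path), dtype={0: str})
    if mat.columns[0] != "spectrum_id":
        raise FormatError(f"first column of {spectra_path} must be 'spectrum_id', got {mat.columns[0]!r}")
    try:
        shifts = np.array([float(c) for c in mat.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"non-numeric shift in header of {spectra_path}: {exc}") from exc
    if not np.all(np.diff(shifts) > 0):
        raise FormatError(f"shift header of {spectra_path} is not strictly increasing")
    manifest = pd.read_csv(manifest_path, sep=_detect_sep(manifest_path), dtype=str)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise FormatError(f"manifest {manifest_path} is missing column(s) {missing_cols}")
    matrix_ids = mat.iloc[:, 0].astype(str)
    dup = matrix_ids[matrix_ids.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate spectrum_id {dup.iloc[0]!r} in spectra matrix")
    id_to_row = {sid: i for i, sid in enumerate(matrix_ids)}
    rows = []
    for sid in manifest["spectrum_id"]:
        if sid not in id_to_row:
            raise ValidationError(f"manifest spectrum_id {sid!r} absent from the spectra matrix")
        rows.append(id_to_row[sid])
    extra = set(id_to_row) - set(manifest["spectrum_id"])
    if extra:
        raise ValidationError(f"spectrum_id {sorted(extra)[0]!r} in matrix but not in manifest")
    intensities = mat.iloc[:, 1:].to_numpy(dtype=float)[rows]
    return SpectrumDataset(shifts, intensities, manifest[MANIFEST_COLUMNS])
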