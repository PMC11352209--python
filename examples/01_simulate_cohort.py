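"""Generate the default synthetic FNA-washout SERS cohort and inspect it.

The generator emulates the study design: 18 patients, one malignant and
one benign washout sample each, 100 spectra per sample on a 300-2000 cm^-1
grid, with class-dependent band amplitudes, a constant preservation-buffer
band, a smooth background, and hierarchical patient/sample/spectrum noise.
"""

import numpy as np

from sersdx import default_config, simulate

config = default_config(seed=1)
cohort = simulate(config)

print(f"spectra:          {len(cohort)}")
print(f"channels:         {cohort.intensities.shape[1]} "
      f"({cohort.shifts[0]:.0f}-{cohort.shifts[-1]:.0f} cm^-1)")
print(f"samples:          {cohort.manifest['sample_id'].nunique()} "
      f"({(cohort.labels == 1).sum()} malignant / {(cohort.labels == 0).sum()} benign spectra)")
print(f"patients:         {cohort.manifest['patient_id'].nunique()}")
print("bands (center, width, base amplitude, malignant-minus-benign delta):")
for p in config.peaks:
    print(f"  {p.center:7.1f} cm^-1   w={p.width:4.1f}  a={p.base_amplitude:.2f}  delta={p.class_delta:+.2f}")
print(f"  {config.buffer_peak.center:7.1f} cm^-1   (preservation buffer, class-neutral)")

# the raw traces sit on a fluorescence-like background around 1-2 a.u.
print(f"raw intensity range: {cohort.intensities.min():.2f} .. {cohort.intensities.max():.2f} a.u.")
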