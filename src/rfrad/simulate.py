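"""Synthetic RF speckle phantoms with controllable ground truth.

Each phantom A-line is a sparse train of Gaussian-amplitude point
scatterers convolved with a Gaussian-envelope pulse, so the diffuse
echo is circular-Gaussian and its envelope Rayleigh — the fully
developed speckle regime.  Three ground-truth dials drive the three map
estimators:

* ``attenuation`` (dB/(m.MHz), applied at the pulse centre frequency):
  multiplies the summed RF by ``10**(-attenuation * f0 * z / 20)`` with
  ``z = row * c / (2 fs)``, producing the depth energy decay that DEA
  measures;
* ``coherent_amp``: a constant-amplitude sinusoid at the pulse centre
  frequency added inside the lesion before the decay, turning the
  envelope Rician with noncentrality ~ coherent_amp (the NRD target);
* scatterer statistics (density/attenuation) shift the window spectra
  that SSD summarises.

The pulse is normalised so the diffuse RF has unit variance per sample
at zero depth, which makes ``coherent_amp`` directly interpretable as a
coherent-to-diffuse amplitude ratio.

A two-class cohort applies per-class values of selected spec fields
("class deltas") with per-patient seeds, emulating a binary-labelled
patient cohort at desk scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .rf_core import ROIMask, RFFrame, ValidationError, write_rf_frame

__all__ = ["PhantomSpec", "CohortSpec", "simulate_rf", "simulate_cohort", "write_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of one synthetic RF frame.

    The default frame (320 x 24 samples) carries a centred rectangular
    lesion of 200 x 14 samples — tall enough for every map window scheme
    (DEA span 144, SSD span 168, NRD block 37 x 8).
    """

    shape: tuple[int, int] = (320, 24)
    fs: float = 3.2e7
    c: float = 1540.0
    pulse_center: float = 3.5e6  # within the 1-5 MHz curved-probe band
    pulse_bandwidth: float = 0.6  # fractional -6 dB bandwidth
    attenuation: float = 50.0  # dB/(m.MHz), ~0.5 dB/(cm.MHz) soft tissue
    scatterer_density: float = 0.15  # scatterers per fast-time sample
    coherent_amp: float = 0.0  # coherent amplitude inside the lesion
    amplitude_scale: float = 1.0  # overall gain applied to the frame
    lesion_shape: tuple[int, int] = (200, 14)
    seed: int = 0

    def __post_init__(self) -> None:
        H, W = self.shape
        lh, lw = self.lesion_shape
        if H < 200:
            raise ValidationError("frame must have >= 200 rows for all map windows")
        if self.attenuation < 0:
            raise ValidationError("attenuation must be >= 0")
        if not self.scatterer_density > 0:
            raise ValidationError("scatterer density must be positive")
        if self.coherent_amp < 0:
            raise ValidationError("coherent amplitude must be >= 0")
        if lh > H or lw > W:
            raise ValidationError("lesion larger than frame")
        if not (0 < self.pulse_center < self.fs / 2):
            raise ValidationError("pulse centre must lie below Nyquist")

    @property
    def lesion_slices(self) -> tuple[slice, slice]:
        H, W = self.shape
        lh, lw = self.lesion_shape
        r0 = (H - lh) // 2
        c0 = (W - lw) // 2
        return slice(r0, r0 + lh), slice(c0, c0 + lw)


@dataclass(frozen=True)
class CohortSpec:
    """Two-class cohort: per-class overrides of phantom fields."""

    n_per_class: int = 20
    class_deltas: dict = field(
        default_factory=lambda: {
            "attenuation": (50.0, 60.0),
            "coherent_amp": (0.0, 0.8),
        }
    )
    base: PhantomSpec = field(default_factory=PhantomSpec)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 3:
            raise ValidationError("need >= 3 patients per class")
        for name, pair in self.class_deltas.items():
            if not hasattr(self.base, name):
                raise ValidationError(f"unknown phantom field {name!r}")
            if len(pair) != 2:
                raise ValidationError("class delta must provide (class0, class1)")


def _gaussian_pulse(spec: PhantomSpec) -> np.ndarray:
    """Gaussian-envelope carrier, normalised for unit diffuse RF variance."""
    sigma_f = spec.pulse_bandwidth * spec.pulse_center / 2.355  # FWHM -> sigma
    tau = 1.0 / (2.0 * np.pi * sigma_f)
    half = max(int(np.ceil(3 * tau * spec.fs)), 2)
    t = np.arange(-half, half + 1) / spec.fs
    p = np.exp(-(t**2) / (2 * tau**2)) * np.cos(2 * np.pi * spec.pulse_center * t)
    return p / np.sqrt(spec.scatterer_density * np.sum(p**2))


def simulate_rf(spec: PhantomSpec) -> tuple[RFFrame, ROIMask]:
    """Generate one RF frame and its lesion ROI mask, deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    pulse = _gaussian_pulse(spec)
    amp = rng.normal(0.0, 1.0, (H, W))
    hit = rng.random((H, W)) < spec.scatterer_density
    rf = fftconvolve(amp * hit, pulse[:, None], mode="same", axes=0)
    rs, cs = spec.lesion_slices
    if spec.coherent_amp > 0:
        rows = np.arange(rs.start, rs.stop)
        phases = rng.uniform(0, 2 * np.pi, cs.stop - cs.start)
        carrier = np.cos(
            2 * np.pi * spec.pulse_center * rows[:, None] / spec.fs + phases[None, :]
        )
        rf[rs, cs] += spec.coherent_amp * carrier
    if spec.attenuation > 0:
        z = np.arange(H) * spec.c / (2.0 * spec.fs)  # metres of depth
        decay_db = spec.attenuation * (spec.pulse_center / 1e6) * z
        rf *= (10.0 ** (-decay_db / 20.0))[:, None]
    mask = np.zeros((H, W), dtype=bool)
    mask[rs, cs] = True
    frame = RFFrame(rf * spec.amplitude_scale, fs=spec.fs, c=spec.c)
    return frame, ROIMask(mask)


def simulate_cohort(spec: CohortSpec):
    """Generate ``2 * n_per_class`` labelled phantoms with per-patient seeds.

    Returns a list of ``(patient_id, RFFrame, ROIMask, label)``, class 0
    first; patient ``i`` uses seed ``base_seed + i``.
    """
    out = []
    for i in range(2 * spec.n_per_class):
        label = 0 if i < spec.n_per_class else 1
        overrides = {name: pair[label] for name, pair in spec.class_deltas.items()}
        pspec = replace(spec.base, seed=spec.base_seed + i, **overrides)
        frame, roi = simulate_rf(pspec)
        out.append((f"p{i:03d}", frame, roi, label))
    return out


def write_cohort(cohort, out_dir) -> Path:
    """Write each frame+ROI to HDF5 and a ``manifest.csv`` alongside."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "path", "label"])
        for pid, frame, roi, label in cohort:
            path = out_dir / f"{pid}.h5"
            write_rf_frame(frame, path, roi=roi)
            w.writerow([pid, path.name, label])
    return manifest
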