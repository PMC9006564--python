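"""RF frame data model, HDF5 I/O, envelope detection and B-mode reconstruction.

A raw radiofrequency (RF) ultrasound frame is a 2-D array of signed echo
amplitudes: rows are axial fast-time samples, columns are A-lines.  The
frame retains phase and spectral content that is destroyed by display
processing, which is what the downstream attenuation / spectral / envelope
statistics estimators exploit.

Conventions used throughout the package:

* coordinates are 0-based, axial index = row;
* axial windows are half-open ``[start, start + length)``;
* the envelope is the magnitude of the per-column analytic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

__all__ = [
    "RFFrame",
    "ROIMask",
    "BModeImage",
    "FormatError",
    "ValidationError",
    "read_rf_frame",
    "write_rf_frame",
    "envelope",
    "reconstruct_bmode",
    "save_bmode",
    "crop_roi",
]

DEFAULT_FS = 3.2e7  # Hz; 32 MHz sampling of the RF fast-time axis
DEFAULT_C = 1540.0  # m/s; assumed soft-tissue sound speed


class FormatError(ValueError):
    """A file does not conform to the expected on-disk container layout."""


class ValidationError(ValueError):
    """An in-memory object violates its invariants."""


@dataclass
class SectorGeometry:
    """Polar acquisition geometry: probe radius (m) and angular pitch (rad/line)."""

    probe_radius: float
    angular_pitch: float


@dataclass
class RFFrame:
    """One raw RF frame: ``samples[axial, lateral]`` plus sampling metadata."""

    samples: np.ndarray
    fs: float = DEFAULT_FS
    c: float = DEFAULT_C
    geometry: str = "linear"
    sector: SectorGeometry | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] < 2 or self.samples.shape[1] < 1:
            raise ValidationError("RF samples must be 2-D with >= 2 rows and >= 1 column")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("RF samples must be finite")
        if not self.fs > 0:
            raise ValidationError("sampling rate fs must be positive")
        if not self.c > 0:
            raise ValidationError("sound speed c must be positive")
        if self.geometry not in ("linear", "sector"):
            raise ValidationError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "sector" and self.sector is None:
            raise ValidationError("sector geometry requires sector parameters")

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape

    @property
    def axial_pitch_m(self) -> float:
        """Depth covered by one fast-time sample (two-way travel): c / (2 fs)."""
        return self.c / (2.0 * self.fs)


@dataclass
class ROIMask:
    """Boolean lesion mask congruent with an RF frame's sample grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValidationError("ROI mask must contain at least one true element")

    @property
    def origin(self) -> tuple[int, int]:
        """(row, col) of the true region's bounding box, 0-based frame coordinates."""
        rows, cols = np.nonzero(self.mask)
        return int(rows.min()), int(cols.min())

    @property
    def bbox(self) -> tuple[slice, slice]:
        rows, cols = np.nonzero(self.mask)
        return (
            slice(int(rows.min()), int(rows.max()) + 1),
            slice(int(cols.min()), int(cols.max()) + 1),
        )


@dataclass
class BModeImage:
    """Log-compressed, [0, 1]-normalised display image."""

    pixels: np.ndarray
    dynamic_range_db: float
    converted: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not self.dynamic_range_db > 0:
            raise ValidationError("dynamic range must be positive")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValidationError("B-mode pixels must lie in [0, 1]")


# ---------------------------------------------------------------------------
# File I/O.  Container layout: "/rf" float64 dataset (axial x lateral) with
# attrs "fs", "c", "geometry" (+ sector params when present); optional
# "/roi" uint8 dataset of the same shape.
# ---------------------------------------------------------------------------

def write_rf_frame(frame: RFFrame, path, roi: ROIMask | None = None) -> None:
    """Write a frame (and optional ROI) to an HDF5 container.

    Round-trips bit-exactly through :func:`read_rf_frame`.
    """
    if not isinstance(frame, RFFrame):
        frame = RFFrame(frame)
    if roi is not None and roi.mask.shape != frame.shape:
        raise ValidationError("ROI shape does not match frame shape")
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("rf", data=frame.samples, dtype=np.float64)
        ds.attrs["fs"] = frame.fs
        ds.attrs["c"] = frame.c
        ds.attrs["geometry"] = frame.geometry
        if frame.sector is not None:
            ds.attrs["probe_radius"] = frame.sector.probe_radius
            ds.attrs["angular_pitch"] = frame.sector.angular_pitch
        if roi is not None:
            h5.create_dataset("roi", data=roi.mask.astype(np.uint8))


def read_rf_frame(path) -> tuple[RFFrame, ROIMask | None]:
    """Read an RF frame (and the ROI, when stored) from an HDF5 container."""
    with h5py.File(path, "r") as h5:
        if "rf" not in h5:
            raise FormatError(f"{path}: missing '/rf' dataset")
        ds = h5["rf"]
        samples = np.asarray(ds[()], dtype=np.float64)
        attrs = dict(ds.attrs)
        geometry = attrs.get("geometry", "linear")
        if isinstance(geometry, bytes):
            geometry = geometry.decode()
        sector = None
        if geometry == "sector":
            sector = SectorGeometry(
                probe_radius=float(attrs["probe_radius"]),
                angular_pitch=float(attrs["angular_pitch"]),
            )
        frame = RFFrame(
            samples,
            fs=float(attrs.get("fs", DEFAULT_FS)),
            c=float(attrs.get("c", DEFAULT_C)),
            geometry=str(geometry),
            sector=sector,
        )
        roi = None
        if "roi" in h5:
            mask = np.asarray(h5["roi"][()]).astype(bool)
            if mask.shape != frame.shape:
                raise ValidationError(
                    f"{path}: ROI shape {mask.shape} does not match frame {frame.shape}"
                )
            roi = ROIMask(mask)
    return frame, roi


# ---------------------------------------------------------------------------
# Signal processing
# ---------------------------------------------------------------------------

def envelope(frame: RFFrame | np.ndarray) -> np.ndarray:
    """Envelope of the RF: per-column magnitude of the analytic signal.

    Under fully developed speckle the envelope is Rayleigh distributed; a
    coherent scattering component shifts it towards a Rician law, which is
    what the NRD estimator quantifies.
    """
    x = frame.samples if isinstance(frame, RFFrame) else np.asarray(frame, dtype=float)
    return np.abs(hilbert(x, axis=0))


def reconstruct_bmode(
    frame: RFFrame,
    smooth_len: int = 5,
    dynamic_range_db: float = 60.0,
) -> BModeImage:
    """B-mode reconstruction: smooth -> envelope -> log compress -> scan convert.

    The processing chain is: per-A-line moving-average smoothing of odd
    length ``smooth_len``; envelope detection; ``20 log10(env / max(env))``;
    clipping to ``[-dynamic_range_db, 0]``; an affine map onto ``[0, 1]``;
    and, for sector geometry, nearest-neighbour polar-to-Cartesian scan
    conversion (identity for linear arrays).
    """
    if smooth_len < 1 or smooth_len % 2 == 0:
        raise ValidationError("smooth_len must be an odd integer >= 1")
    if not dynamic_range_db > 0:
        raise ValidationError("dynamic range must be positive")
    x = frame.samples
    if smooth_len > 1:
        x = uniform_filter1d(x, size=smooth_len, axis=0, mode="nearest")
    env = np.abs(hilbert(x, axis=0))
    peak = env.max()
    if peak <= 0:
        raise ValidationError("all-zero frame: B-mode normalisation undefined")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    db = np.clip(db, -dynamic_range_db, 0.0)
    pixels = db / dynamic_range_db + 1.0
    converted = False
    if frame.geometry == "sector":
        pixels = _scan_convert(pixels, frame)
        converted = True
    return BModeImage(pixels=pixels, dynamic_range_db=dynamic_range_db, converted=converted)


def _scan_convert(polar: np.ndarray, frame: RFFrame) -> np.ndarray:
    """Nearest-neighbour polar-to-Cartesian resampling of a sector image."""
    n_r, n_theta = polar.shape
    geo = frame.sector
    dr = frame.axial_pitch_m
    r0 = geo.probe_radius
    r_max = r0 + n_r * dr
    theta = (np.arange(n_theta) - (n_theta - 1) / 2.0) * geo.angular_pitch
    half_width = r_max * np.sin(abs(theta).max()) if n_theta > 1 else dr
    nx = max(int(np.ceil(2 * half_width / dr)), 1)
    x = (np.arange(nx) - (nx - 1) / 2.0) * dr
    z = r0 + np.arange(n_r) * dr
    zz, xx = np.meshgrid(z, x, indexing="ij")
    rr = np.hypot(zz, xx)
    tt = np.arctan2(xx, zz)
    ri = np.rint((rr - r0) / dr).astype(int)
    ti = np.rint(tt / geo.angular_pitch + (n_theta - 1) / 2.0).astype(int)
    inside = (ri >= 0) & (ri < n_r) & (ti >= 0) & (ti < n_theta)
    out = np.zeros_like(rr)
    out[inside] = polar[ri[inside], ti[inside]]
    return out


def save_bmode(image: BModeImage, path) -> None:
    """Export a B-mode image: 8-bit grayscale PNG or HDF5 (by extension)."""
    path = str(path)
    if path.endswith(".png"):
        from PIL import Image

        Image.fromarray(np.round(image.pixels * 255).astype(np.uint8), mode="L").save(path)
    elif path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as h5:
            ds = h5.create_dataset("bmode", data=image.pixels)
            ds.attrs["dynamic_range_db"] = image.dynamic_range_db
            ds.attrs["converted"] = image.converted
    else:
        raise ValidationError(f"unsupported B-mode export extension: {path}")


def crop_roi(array: np.ndarray, roi: ROIMask) -> tuple[np.ndarray, np.ndarray]:
    """Bounding-box crop of ``array`` and the congruent cropped mask.

    Values outside the true region but inside the bounding box are kept in
    the crop and flagged ``False`` in the returned mask.
    """
    array = np.asarray(array)
    if array.shape != roi.mask.shape:
        raise ValidationError("array and ROI mask shapes differ")
    rs, cs = roi.bbox
    return array[rs, cs].copy(), roi.mask[rs, cs].copy()
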