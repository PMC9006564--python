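"""Ultrasound feature maps: DEA, SSD and NRD estimators on ROI RF data.

Three local quantitative-ultrasound parameters are estimated with sliding
gated windows along each A-line (DEA, SSD) or with a sliding 2-D block
(NRD), producing one "feature map" per parameter:

DEA (direct energy attenuation, dB/m)
    Ratio of average spectral energies of two gated 64-sample windows
    separated by a 16-sample interval, converted to attenuation per unit
    depth::

        DEA = 10 * log10(E0 / E1) / (D * c / fs / 2)

    where ``D`` is the gated window length (64 samples), ``c`` the sound
    speed (1540 m/s) and ``fs`` the sampling rate (32 MHz); the denominator
    is the depth spanned by one window (1.54 mm at the defaults).

SSD (skewness of spectrum difference, dimensionless)
    Skewness (third standardised moment, population normalisation) of the
    elementwise difference of the magnitude spectra of two 64-sample
    windows separated by a 40-sample interval.

NRD (noncentrality of the Rician distribution, amplitude units)
    Maximum-likelihood noncentrality parameter ``s`` of the Rician density

        p(x) = x / sigma^2 * exp(-(x^2 + s^2) / (2 sigma^2)) * I0(x s / sigma^2)

    fitted to the envelope inside a sliding 37 x 8 block.  ``s`` indexes
    the coherent-to-diffuse scattering balance: fully developed speckle is
    Rayleigh (s = 0), a specular component raises s.

Each estimator only evaluates placements whose full window(s) lie inside
the ROI mask, and assigns the value to a fixed offset inside the window
span (the mid-gap point for DEA/SSD, the block midpoint for NRD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special, stats

from .rf_core import DEFAULT_C, DEFAULT_FS, ValidationError

__all__ = [
    "FeatureMap",
    "WindowScheme1D",
    "WindowScheme2D",
    "DEA_SCHEME",
    "SSD_SCHEME",
    "NRD_SCHEME",
    "block_energy",
    "sample_skewness",
    "fit_rician",
    "compute_dea_map",
    "compute_ssd_map",
    "compute_nrd_map",
]

MAP_KINDS = ("DEA", "SSD", "NRD", "GRAYSCALE")
MAP_UNITS = {"DEA": "dB/m", "SSD": "1", "NRD": "amplitude", "GRAYSCALE": "1"}


@dataclass
class FeatureMap:
    """A 2-D parameter map plus the mask of placements that were computable."""

    values: np.ndarray
    valid: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.kind not in MAP_KINDS:
            raise ValidationError(f"unknown map kind {self.kind!r}")
        if self.values.shape != self.valid.shape:
            raise ValidationError("values and valid mask shapes differ")
        if self.valid.any() and not np.all(np.isfinite(self.values[self.valid])):
            raise ValidationError("feature map contains non-finite valid values")

    @property
    def units(self) -> str:
        return MAP_UNITS[self.kind]


@dataclass(frozen=True)
class WindowScheme1D:
    """Two gated axial windows of ``win_len`` samples separated by ``gap``.

    The estimate is assigned ``assign_offset`` samples below the top
    window's start; the conventional choice is the mid-gap point
    ``(win_len + gap) // 2``.
    """

    win_len: int
    gap: int
    assign_offset: int

    def __post_init__(self) -> None:
        if self.win_len < 2:
            raise ValidationError("window length must be >= 2")
        if self.gap < 0:
            raise ValidationError("window interval must be >= 0")
        if not 0 <= self.assign_offset < self.span:
            raise ValidationError("assignment offset must fall inside the window span")

    @property
    def span(self) -> int:
        """Total axial extent of one placement: two windows plus the gap."""
        return 2 * self.win_len + self.gap

    @property
    def bottom_start(self) -> int:
        return self.win_len + self.gap


@dataclass(frozen=True)
class WindowScheme2D:
    """Axial x lateral block extent for the 2-D (NRD) estimator."""

    rows: int = 37
    cols: int = 8

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 1:
            raise ValidationError("2-D block must have >= 2 rows and >= 1 column")


DEA_SCHEME = WindowScheme1D(win_len=64, gap=16, assign_offset=40)
SSD_SCHEME = WindowScheme1D(win_len=64, gap=40, assign_offset=52)
NRD_SCHEME = WindowScheme2D(rows=37, cols=8)


# ---------------------------------------------------------------------------
# Primitive statistics
# ---------------------------------------------------------------------------

def block_energy(block: np.ndarray) -> float:
    """Average spectral energy of a gated window: mean squared DFT magnitude.

    By Parseval's theorem this equals the sum of squared samples, so the
    quantity is strictly positive unless the block is identically zero.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 1 or block.size < 1:
        raise ValidationError("block must be a non-empty 1-D array")
    return float(np.mean(np.abs(np.fft.fft(block)) ** 2))


def sample_skewness(x: np.ndarray) -> float:
    """Third standardised moment with population (1/n) normalisation.

    Returns NaN when the variance is zero; callers treat that placement
    as invalid.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValidationError("skewness needs at least 2 samples")
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        return float("nan")
    return float(stats.skew(x, bias=True))


# ---------------------------------------------------------------------------
# Rician maximum likelihood
# ---------------------------------------------------------------------------

def _bessel_ratio(z: np.ndarray) -> np.ndarray:
    """I1(z) / I0(z), numerically stable via exponentially scaled Bessels."""
    return special.i1e(z) / special.i0e(z)


def rician_negloglik(params, x: np.ndarray) -> float:
    """Negative log-likelihood of Rician(s, sigma) for positive samples."""
    s, sigma = params
    if sigma <= 0 or s < 0:
        return np.inf
    z = x * s / sigma**2
    # log I0(z) = log(i0e(z)) + z
    log_i0 = np.log(special.i0e(z)) + z
    ll = np.log(x) - 2 * np.log(sigma) - (x**2 + s**2) / (2 * sigma**2) + log_i0
    return float(-np.sum(ll))


def _rician_mle_fixed_point(
    x: np.ndarray,
    max_iter: int = 200,
    rtol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched Rician MLE via a Steffensen-accelerated score fixed point.

    ``x`` has shape (B, n): B independent blocks of n positive samples.
    The stationarity conditions of the likelihood are

        s       = mean( x * I1/I0(x s / sigma^2) )
        sigma^2 = (mean(x^2) - s^2) / 2

    defining the map ``T(s) = mean(x * I1/I0(x s / ((m2 - s^2)/2)))``
    whose fixed point is the MLE.  Plain iteration of ``T`` stalls in the
    Rayleigh basin (s -> 0, contraction factor -> 1), so each step uses
    Steffensen (Aitken delta-squared) extrapolation with a fallback to the
    plain update when the extrapolation leaves ``[0, sqrt(m2))``.  Returns
    ``(s, sigma, converged)`` arrays of shape (B,); a block is converged
    when the map residual ``|T(s) - s|`` drops below ``rtol * sqrt(m2)``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    m1 = x.mean(axis=1)
    m2 = (x**2).mean(axis=1)
    m4 = (x**4).mean(axis=1)
    rms = np.sqrt(m2)
    s_cap = rms * (1.0 - 1e-12)

    def T(s: np.ndarray, xs: np.ndarray, m2s: np.ndarray) -> np.ndarray:
        sigma2 = np.maximum((m2s - s**2) / 2.0, 1e-300)
        z = xs * (s / sigma2)[:, None]
        return np.mean(xs * _bessel_ratio(z), axis=1)

    # Gaussian-limit moment start: s^2 ~ 2 m1^2 - m2, floored for low SNR.
    s = np.sqrt(np.clip(2 * m1**2 - m2, 0.0, None))
    s = np.clip(s, 1e-3 * rms, s_cap)
    converged = np.zeros(s.shape, dtype=bool)
    # Boundary criterion: expanding the score map near 0 gives
    # T(s) - s = s^3/m2 * (1 - m4/(2 m2^2)) + O(s^5), so the likelihood
    # peaks at the s = 0 boundary exactly when m4 >= 2 m2^2 — those
    # blocks need no iteration.
    at_boundary = m4 >= 2 * m2**2
    s[at_boundary] = 0.0
    converged[at_boundary] = True
    active = np.nonzero(~at_boundary)[0]
    for _ in range(max_iter):
        if active.size == 0:
            break
        xs, m2s = x[active], m2[active]
        t1 = np.clip(T(s[active], xs, m2s), 0.0, s_cap[active])
        resid = np.abs(t1 - s[active])
        # converged on residual, or shrunk to numerical zero (flat basin)
        done = (resid <= rtol * rms[active]) | (t1 <= 1e-4 * rms[active])
        t2 = np.clip(T(t1, xs, m2s), 0.0, s_cap[active])
        denom = t2 - 2 * t1 + s[active]
        with np.errstate(divide="ignore", invalid="ignore"):
            s_acc = s[active] - (t1 - s[active]) ** 2 / denom
        bad = ~np.isfinite(s_acc) | (s_acc < 0) | (s_acc >= s_cap[active])
        s_new = np.where(bad | done, t2, s_acc)
        s[active] = s_new
        converged[active[done]] = True
        active = active[~done]
    sigma = np.sqrt(np.maximum((m2 - s**2) / 2.0, 1e-300))
    return s, sigma, converged


def fit_rician(x: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood (s, sigma) of the Rician law for positive samples.

    Raises on non-positive samples or non-convergence.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 8:
        raise ValidationError("Rician fit needs at least 8 samples")
    if np.any(x <= 0):
        raise ValidationError("Rician fit requires strictly positive samples")
    s, sigma, ok = _rician_mle_fixed_point(x[None, :])
    if not ok[0]:
        raise RuntimeError(
            f"Rician MLE did not converge (s={s[0]:.4g}, sigma={sigma[0]:.4g})"
        )
    return float(s[0]), float(sigma[0])


# ---------------------------------------------------------------------------
# Sliding-window map estimators
# ---------------------------------------------------------------------------

def _full_window_valid(valid: np.ndarray, span: int) -> np.ndarray:
    """Per (start row, column): does a ``span``-row window lie fully in the mask?"""
    v = sliding_window_view(valid.astype(np.int64), span, axis=0)
    return v.sum(axis=-1) == span


def compute_dea_map(
    frame_roi: np.ndarray,
    valid: np.ndarray | None = None,
    scheme: WindowScheme1D = DEA_SCHEME,
    c: float = DEFAULT_C,
    fs: float = DEFAULT_FS,
) -> FeatureMap:
    """Direct-energy-attenuation map of an ROI RF patch.

    For each column and axial start ``i`` with both gated windows inside
    the mask, ``E0`` is the average spectral energy of rows
    ``[i, i+D)`` and ``E1`` of rows ``[i+D+gap, i+2D+gap)``;
    ``10*log10(E0/E1) / (D*c/fs/2)`` is assigned to row
    ``i + assign_offset``.  Placements where ``E1`` vanishes are flagged
    invalid rather than raising.
    """
    x = np.asarray(frame_roi, dtype=np.float64)
    if x.ndim != 2:
        raise ValidationError("ROI must be 2-D")
    if valid is None:
        valid = np.ones(x.shape, dtype=bool)
    if x.shape[0] < scheme.span:
        raise ValidationError(
            f"ROI height {x.shape[0]} below one placement span {scheme.span}"
        )
    if not (fs > 0 and c > 0):
        raise ValidationError("fs and c must be positive")
    # Parseval: mean |DFT|^2 over the window == sum of squares of the window.
    sq = np.where(valid, x, 0.0) ** 2
    csum = np.cumsum(sq, axis=0)
    csum = np.vstack([np.zeros((1, x.shape[1])), csum])
    D = scheme.win_len

    def window_sum(start_rows: np.ndarray) -> np.ndarray:
        return csum[start_rows + D] - csum[start_rows]

    n_place = x.shape[0] - scheme.span + 1
    starts = np.arange(n_place)
    e0 = window_sum(starts)
    e1 = window_sum(starts + scheme.bottom_start)
    place_ok = _full_window_valid(valid, scheme.span)
    denom = D * c / fs / 2.0  # depth of one gated window, metres
    values = np.full(x.shape, np.nan)
    ok = place_ok & (e0 > 0) & (e1 > 0)
    n_degenerate = int((place_ok & ~ok).sum())
    if n_degenerate:
        warnings.warn(f"DEA: {n_degenerate} placements with zero window energy skipped")
    with np.errstate(divide="ignore", invalid="ignore"):
        dea = 10.0 * np.log10(e0 / e1) / denom
    out_valid = np.zeros(x.shape, dtype=bool)
    rows = starts + scheme.assign_offset
    values[rows] = np.where(ok, dea, np.nan)
    out_valid[rows] = ok
    values[~out_valid] = np.nan
    return FeatureMap(values=values, valid=out_valid, kind="DEA")


def compute_ssd_map(
    frame_roi: np.ndarray,
    valid: np.ndarray | None = None,
    scheme: WindowScheme1D = SSD_SCHEME,
) -> FeatureMap:
    """Skewness-of-spectrum-difference map of an ROI RF patch.

    Per placement the magnitude spectra of the top and bottom gated
    windows are subtracted elementwise (top minus bottom) and the
    skewness of the difference vector is assigned to the mid-gap row.
    A zero-variance difference (identical blocks) marks the placement
    invalid.
    """
    x = np.asarray(frame_roi, dtype=np.float64)
    if x.ndim != 2:
        raise ValidationError("ROI must be 2-D")
    if valid is None:
        valid = np.ones(x.shape, dtype=bool)
    if x.shape[0] < scheme.span:
        raise ValidationError(
            f"ROI height {x.shape[0]} below one placement span {scheme.span}"
        )
    D = scheme.win_len
    xm = np.where(valid, x, 0.0)
    # (placements, columns, D) views of the top and bottom windows
    win = sliding_window_view(xm, D, axis=0)
    top = win[: x.shape[0] - scheme.span + 1]
    bot = win[scheme.bottom_start : scheme.bottom_start + top.shape[0]]
    diff = np.abs(np.fft.fft(top, axis=-1)) - np.abs(np.fft.fft(bot, axis=-1))
    mean = diff.mean(axis=-1, keepdims=True)
    dev = diff - mean
    m2 = np.mean(dev**2, axis=-1)
    m3 = np.mean(dev**3, axis=-1)
    place_ok = _full_window_valid(valid, scheme.span) & (m2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = m3 / m2**1.5
    values = np.full(x.shape, np.nan)
    out_valid = np.zeros(x.shape, dtype=bool)
    rows = np.arange(top.shape[0]) + scheme.assign_offset
    values[rows] = np.where(place_ok, skew, np.nan)
    out_valid[rows] = place_ok
    return FeatureMap(values=values, valid=out_valid, kind="SSD")


def compute_nrd_map(
    frame_roi: np.ndarray,
    valid: np.ndarray | None = None,
    scheme: WindowScheme2D = NRD_SCHEME,
    input_transform: str = "envelope",
    axial_step: int = 1,
    lateral_step: int = 1,
) -> FeatureMap:
    """Rician-noncentrality (NRD) map of an ROI RF patch.

    The block input is the envelope (default) or the absolute value of
    the RF; a Rician law is fitted by maximum likelihood to each sliding
    ``rows x cols`` block and the noncentrality ``s`` is assigned to the
    block midpoint.  Strides other than one trade resolution for speed.
    """
    x = np.asarray(frame_roi, dtype=np.float64)
    if x.ndim != 2:
        raise ValidationError("ROI must be 2-D")
    if valid is None:
        valid = np.ones(x.shape, dtype=bool)
    H, W = x.shape
    if H < scheme.rows or W < scheme.cols:
        raise ValidationError("ROI smaller than one 2-D block")
    if input_transform == "envelope":
        from .rf_core import envelope as _env

        amp = _env(x)
    elif input_transform == "abs":
        amp = np.abs(x)
    else:
        raise ValidationError(f"unknown input transform {input_transform!r}")
    # Positive-support requirement of the Rician law: exact zeros invalidate
    # a block (they arise only from degenerate, e.g. all-zero, input).
    pos = amp > 0
    blocks = sliding_window_view(amp, (scheme.rows, scheme.cols))
    vblocks = sliding_window_view(valid & pos, (scheme.rows, scheme.cols))
    i_idx = np.arange(0, H - scheme.rows + 1, axial_step)
    j_idx = np.arange(0, W - scheme.cols + 1, lateral_step)
    blocks = blocks[np.ix_(i_idx, j_idx)]
    ok = vblocks[np.ix_(i_idx, j_idx)].all(axis=(2, 3))
    nb = blocks.shape[0] * blocks.shape[1]
    flat = blocks.reshape(nb, -1)
    ok_flat = ok.ravel()
    s = np.full(nb, np.nan)
    ok_idx = np.nonzero(ok_flat)[0]
    if ok_idx.size:
        s_fit, _, conv = _rician_mle_fixed_point(flat[ok_idx])
        if (~conv).any():
            warnings.warn(f"NRD: {int((~conv).sum())} block fits did not converge")
        s[ok_idx[conv]] = s_fit[conv]
        ok_flat = ok_flat.copy()
        ok_flat[ok_idx[~conv]] = False
    values = np.full(x.shape, np.nan)
    out_valid = np.zeros(x.shape, dtype=bool)
    mid_r = i_idx + scheme.rows // 2
    mid_c = j_idx + scheme.cols // 2
    rr, cc = np.meshgrid(mid_r, mid_c, indexing="ij")
    values[rr.ravel(), cc.ravel()] = s
    out_valid[rr.ravel(), cc.ravel()] = ok_flat
    values[~out_valid] = np.nan
    return FeatureMap(values=values, valid=out_valid, kind="NRD")
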