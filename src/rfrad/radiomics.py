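"""Texture and wavelet-texture radiomics on a feature map.

Per map, 69 texture features are computed on the original values and on
each of the 4 single-level 2-D wavelet subbands (LL, LH, HL, HH), for a
total of 69 * 5 = 345 features.  The per-family breakdown on any single
(sub)band is:

====================  =====
histogram (first order)  16
GLCM (Haralick)          13
GLRLM                    22
GLSZM                    13
NGTDM (Amadasun-King)     5
====================  =====

All matrix-based families operate on an equal-width quantisation of the
valid values (``Ng`` gray levels, default 64), restricted to valid-valid
cell pairs / runs / zones / neighbourhoods, so invalid placements at the
ROI border never contribute.  Because equal-width quantisation is
invariant under positive affine rescaling of the input, so is every
feature in those families.

Degenerate (constant) inputs never raise during cohort extraction: the
map is assigned a single gray level and features whose definition becomes
0/0 take a sentinel value of 0 (with a warning).
"""

from __future__ import annotations

import warnings
from collections import OrderedDict

import numpy as np
import pywt
from scipy import ndimage, stats

from .feature_maps import MAP_KINDS, FeatureMap
from .rf_core import ValidationError

__all__ = [
    "QuantizedMap",
    "ConstantMapError",
    "quantize",
    "histogram_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "wavelet_subbands",
    "extract_map_features",
    "extract_patient_features",
    "FAMILY_COUNTS",
    "SUBBANDS",
]

FAMILY_COUNTS = {"histogram": 16, "GLCM": 13, "GLRLM": 22, "GLSZM": 13, "NGTDM": 5}
SUBBANDS = ("orig", "LL", "LH", "HL", "HH")
FEATURES_PER_BAND = sum(FAMILY_COUNTS.values())  # 69
FEATURES_PER_MAP = FEATURES_PER_BAND * len(SUBBANDS)  # 345

#: the four distance-1 co-occurrence / run directions: 0, 45, 90, 135 degrees
#: as (row, col) offsets in image coordinates
DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

COARSENESS_CAP = 1e6  # coarseness -> 1/0 on uniform images; capped sentinel


class ConstantMapError(ValidationError):
    """Raised by :func:`quantize` on constant input.

    Callers extracting whole feature vectors should short-circuit to the
    degenerate single-level quantisation instead of aborting.
    """


class QuantizedMap:
    """Equal-width quantisation of a map's valid values onto ``1..Ng``."""

    def __init__(self, levels, ng, valid, bin_edges):
        self.levels = np.asarray(levels, dtype=np.int64)
        self.ng = int(ng)
        self.valid = np.asarray(valid, dtype=bool)
        self.bin_edges = np.asarray(bin_edges, dtype=np.float64)
        lv = self.levels[self.valid]
        if lv.size and (lv.min() < 1 or lv.max() > self.ng):
            raise ValidationError("quantised levels out of range")


def _as_values_valid(map_, valid=None):
    if isinstance(map_, FeatureMap):
        return map_.values, map_.valid
    values = np.asarray(map_, dtype=np.float64)
    if valid is None:
        valid = np.isfinite(values)
    return values, np.asarray(valid, dtype=bool)


def quantize(map_, ng: int = 64, valid=None) -> QuantizedMap:
    """Equal-width quantisation over ``[min, max]`` of the valid values.

    The top edge maps to level ``Ng``.  Raises :class:`ConstantMapError`
    when fewer than two distinct valid values exist.
    """
    values, valid = _as_values_valid(map_, valid)
    if ng < 2:
        raise ValidationError("Ng must be >= 2")
    v = values[valid]
    if v.size < 2 or v.min() == v.max():
        raise ConstantMapError("constant map cannot be quantised")
    lo, hi = float(v.min()), float(v.max())
    width = (hi - lo) / ng
    levels = np.zeros(values.shape, dtype=np.int64)
    lv = np.floor((values[valid] - lo) / width).astype(np.int64) + 1
    levels[valid] = np.clip(lv, 1, ng)
    edges = lo + width * np.arange(ng + 1)
    return QuantizedMap(levels, ng, valid, edges)


def _degenerate_quantized(values, valid) -> QuantizedMap:
    levels = np.zeros(values.shape, dtype=np.int64)
    levels[valid] = 1
    c = float(values[valid][0]) if valid.any() else 0.0
    return QuantizedMap(levels, 1, valid, np.array([c, c]))


def _sentinel(name: str) -> float:
    warnings.warn(f"degenerate input: feature {name} set to 0")
    return 0.0


# ---------------------------------------------------------------------------
# Histogram (first-order) features
# ---------------------------------------------------------------------------

def histogram_features(map_, valid=None, ng: int = 64) -> OrderedDict:
    """The 16 first-order features of the valid map values.

    Entropy and uniformity are computed on an ``ng``-bin equal-width
    histogram (log base 2); variance and the standardised moments use
    population (1/n) normalisation.
    """
    values, valid = _as_values_valid(map_, valid)
    v = values[valid].astype(np.float64)
    if v.size < 1:
        raise ValidationError("no valid values")
    out = OrderedDict()
    out["mean"] = float(v.mean())
    out["median"] = float(np.median(v))
    out["minimum"] = float(v.min())
    out["maximum"] = float(v.max())
    out["range"] = float(v.max() - v.min())
    m2 = float(np.mean((v - v.mean()) ** 2))
    out["variance"] = m2
    out["std"] = float(np.sqrt(m2))
    if m2 > 0:
        out["skewness"] = float(stats.skew(v, bias=True))
        out["kurtosis"] = float(stats.kurtosis(v, bias=True, fisher=False))
    else:
        out["skewness"] = _sentinel("skewness")
        out["kurtosis"] = _sentinel("kurtosis")
    out["energy"] = float(np.sum(v**2))
    out["rms"] = float(np.sqrt(np.mean(v**2)))
    if v.min() == v.max():
        p = np.array([1.0])
    else:
        counts, _ = np.histogram(v, bins=ng)
        p = counts[counts > 0] / v.size
    out["entropy"] = float(-np.sum(p * np.log2(p)))
    out["uniformity"] = float(np.sum(p**2))
    out["mad"] = float(np.mean(np.abs(v - v.mean())))
    out["p10"] = float(np.percentile(v, 10))
    out["p90"] = float(np.percentile(v, 90))
    return out


# ---------------------------------------------------------------------------
# GLCM (Haralick) features
# ---------------------------------------------------------------------------

def _cooccurrence(q: QuantizedMap, offset) -> np.ndarray:
    """Symmetric distance-1 co-occurrence counts restricted to valid pairs."""
    dr, dc = offset
    lev, val = q.levels, q.valid
    H, W = lev.shape
    r0 = slice(max(0, -dr), min(H, H - dr))
    c0 = slice(max(0, -dc), min(W, W - dc))
    r1 = slice(max(0, dr), min(H, H + dr))
    c1 = slice(max(0, dc), min(W, W + dc))
    a = lev[r0, c0]
    b = lev[r1, c1]
    ok = val[r0, c0] & val[r1, c1]
    mat = np.zeros((q.ng, q.ng), dtype=np.float64)
    np.add.at(mat, (a[ok] - 1, b[ok] - 1), 1.0)
    return mat + mat.T


def _haralick(p: np.ndarray) -> OrderedDict:
    """The 13 Haralick features of one normalised symmetric GLCM."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    var = float(np.sum((i - mu) ** 2 * px))
    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    k_sum = (ii + jj).astype(int)
    k_dif = np.abs(ii - jj).astype(int)
    p_sum = np.zeros(2 * ng + 1)
    np.add.at(p_sum, k_sum.ravel(), p.ravel())
    p_dif = np.zeros(ng)
    np.add.at(p_dif, k_dif.ravel(), p.ravel())
    nz = p[p > 0]

    def ent(x):
        x = x[x > 0]
        return float(-np.sum(x * np.log2(x))) if x.size else 0.0

    out = OrderedDict()
    out["asm"] = float(np.sum(p**2))
    out["contrast"] = float(np.sum((ii - jj) ** 2 * p))
    if var > 0:
        out["correlation"] = float((np.sum(ii * jj * p) - mu * mu) / var)
    else:
        out["correlation"] = _sentinel("glcm correlation")
    out["sum_of_squares"] = var
    out["idm"] = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    ks = np.arange(2 * ng + 1, dtype=np.float64)
    sa = float(np.sum(ks * p_sum))
    out["sum_average"] = sa
    out["sum_variance"] = float(np.sum((ks - sa) ** 2 * p_sum))
    out["sum_entropy"] = ent(p_sum)
    hxy = ent(nz)
    out["entropy"] = hxy
    kd = np.arange(ng, dtype=np.float64)
    da = float(np.sum(kd * p_dif))
    out["difference_variance"] = float(np.sum((kd - da) ** 2 * p_dif))
    out["difference_entropy"] = ent(p_dif)
    # information measures of correlation
    hx = ent(px[px > 0])
    with np.errstate(divide="ignore"):
        log_pp = np.log2(np.outer(px, px))
    joint_ok = (p > 0) & np.isfinite(log_pp)
    hxy1 = float(-np.sum(p[joint_ok] * log_pp[joint_ok]))
    marg_ok = np.isfinite(log_pp)
    hxy2 = float(-np.sum(np.outer(px, px)[marg_ok] * log_pp[marg_ok]))
    if hx > 0:
        out["imc1"] = float((hxy - hxy1) / hx)
    else:
        out["imc1"] = _sentinel("glcm imc1")
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return out


def glcm_features(q: QuantizedMap) -> OrderedDict:
    """13 Haralick features averaged over the 4 distance-1 directions.

    Directions without a single co-occurring valid pair are excluded from
    the average (with a warning).
    """
    per_dir = []
    for off in DIRECTIONS:
        mat = _cooccurrence(q, off)
        tot = mat.sum()
        if tot < 1:
            warnings.warn(f"GLCM: direction {off} has no co-occurring pairs; skipped")
            continue
        per_dir.append(_haralick(mat / tot))
    if not per_dir:
        raise ValidationError("GLCM: no direction has co-occurring pairs")
    out = OrderedDict()
    for name in per_dir[0]:
        out[name] = float(np.mean([d[name] for d in per_dir]))
    return out


# ---------------------------------------------------------------------------
# GLRLM features
# ---------------------------------------------------------------------------

def _run_lengths(q: QuantizedMap, offset):
    """(level, length) of every maximal run of equal valid levels along ``offset``."""
    dr, dc = offset
    lev = np.where(q.valid, q.levels, 0)
    H, W = lev.shape
    if (dr, dc) == (0, 1):
        lines = [lev[r, :] for r in range(H)]
    elif (dr, dc) == (-1, 0):
        lines = [lev[:, c] for c in range(W)]
    else:
        # runs are undirected: (-1,-1) lies along the (1,1) diagonals and
        # (-1,1) along the anti-diagonals (diagonals of the column-flipped map)
        base = lev if (dr, dc) == (-1, -1) else lev[:, ::-1]
        lines = [np.diagonal(base, offset=k) for k in range(-(H - 1), W)]
    # flatten all lines with -1 separators, then one vectorised run scan
    lines = [ln for ln in lines if ln.size]
    if not lines:
        return []
    sep = np.full(1, -1, dtype=np.int64)
    flat = np.concatenate([np.concatenate([ln.astype(np.int64), sep]) for ln in lines])
    change = np.nonzero(np.diff(flat))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [flat.size]])
    levels = flat[starts]
    keep = levels > 0
    return list(zip(levels[keep].tolist(), (ends - starts)[keep].tolist()))


def _glrlm_one_direction(q: QuantizedMap, offset) -> OrderedDict | None:
    runs = _run_lengths(q, offset)
    if not runs:
        return None
    gl = np.array([r[0] for r in runs], dtype=np.float64)
    rl = np.array([r[1] for r in runs], dtype=np.float64)
    nr = float(len(runs))
    npix = float(q.valid.sum())
    # gray-level and run-length marginals
    out = OrderedDict()
    out["sre"] = float(np.sum(1.0 / rl**2) / nr)
    out["lre"] = float(np.sum(rl**2) / nr)
    gsum = np.bincount(gl.astype(int))
    rsum = np.bincount(rl.astype(int))
    out["gln"] = float(np.sum(gsum.astype(float) ** 2) / nr)
    out["rln"] = float(np.sum(rsum.astype(float) ** 2) / nr)
    out["rp"] = nr / npix
    out["lgre"] = float(np.sum(1.0 / gl**2) / nr)
    out["hgre"] = float(np.sum(gl**2) / nr)
    out["srlge"] = float(np.sum(1.0 / (gl**2 * rl**2)) / nr)
    out["srhge"] = float(np.sum(gl**2 / rl**2) / nr)
    out["lrlge"] = float(np.sum(rl**2 / gl**2) / nr)
    out["lrhge"] = float(np.sum(gl**2 * rl**2) / nr)
    return out


GLRLM_BASE = ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge")


def glrlm_features(q: QuantizedMap) -> OrderedDict:
    """22 run-length features: mean and range over the 4 directions of 11 bases."""
    per_dir = []
    for off in DIRECTIONS:
        d = _glrlm_one_direction(q, off)
        if d is None:
            warnings.warn(f"GLRLM: direction {off} has no runs; skipped")
            continue
        per_dir.append(d)
    if not per_dir:
        raise ValidationError("GLRLM: no runs in any direction")
    out = OrderedDict()
    for name in GLRLM_BASE:
        vals = [d[name] for d in per_dir]
        out[f"{name}_mean"] = float(np.mean(vals))
    for name in GLRLM_BASE:
        vals = [d[name] for d in per_dir]
        out[f"{name}_range"] = float(np.max(vals) - np.min(vals))
    return out


# ---------------------------------------------------------------------------
# GLSZM features
# ---------------------------------------------------------------------------

_STRUCT8 = np.ones((3, 3), dtype=bool)


def glszm_features(q: QuantizedMap) -> OrderedDict:
    """13 size-zone features with 8-connected zones of equal gray level."""
    zones = []  # (level, size)
    for g in np.unique(q.levels[q.valid]):
        labels, n = ndimage.label((q.levels == g) & q.valid, structure=_STRUCT8)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            zones.extend((int(g), int(sz)) for sz in sizes)
    gl = np.array([z[0] for z in zones], dtype=np.float64)
    zs = np.array([z[1] for z in zones], dtype=np.float64)
    nz = float(len(zones))
    npix = float(q.valid.sum())
    out = OrderedDict()
    out["sae"] = float(np.sum(1.0 / zs**2) / nz)
    out["lae"] = float(np.sum(zs**2) / nz)
    out["gln"] = float(np.sum(np.bincount(gl.astype(int)).astype(float) ** 2) / nz)
    out["szn"] = float(np.sum(np.bincount(zs.astype(int)).astype(float) ** 2) / nz)
    out["zp"] = nz / npix
    out["lgze"] = float(np.sum(1.0 / gl**2) / nz)
    out["hgze"] = float(np.sum(gl**2) / nz)
    out["salge"] = float(np.sum(1.0 / (gl**2 * zs**2)) / nz)
    out["sahge"] = float(np.sum(gl**2 / zs**2) / nz)
    out["lalge"] = float(np.sum(zs**2 / gl**2) / nz)
    out["lahge"] = float(np.sum(gl**2 * zs**2) / nz)
    out["glv"] = float(np.mean((gl - gl.mean()) ** 2))
    out["zsv"] = float(np.mean((zs - zs.mean()) ** 2))
    return out


# ---------------------------------------------------------------------------
# NGTDM features
# ---------------------------------------------------------------------------

def ngtdm_arrays(q: QuantizedMap) -> tuple[np.ndarray, np.ndarray]:
    """NGTDM occupancy ``n_i`` and gray-tone difference sums ``s_i``.

    ``s_i`` accumulates, over the valid cells of level ``i``, the absolute
    difference between the cell level and the mean of its valid 3x3
    neighbours; cells without a valid neighbour are excluded.  Index 0 of
    both arrays is unused (levels are 1-based).
    """
    lev = np.where(q.valid, q.levels, 0).astype(np.float64)
    val = q.valid.astype(np.float64)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nsum = ndimage.convolve(lev * val, kernel, mode="constant", cval=0.0)
    ncnt = ndimage.convolve(val, kernel, mode="constant", cval=0.0)
    ok = q.valid & (ncnt > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = nsum / ncnt
    diff = np.abs(lev - nbar)
    n_i = np.zeros(q.ng + 1)
    s_i = np.zeros(q.ng + 1)
    lv = q.levels[ok]
    np.add.at(n_i, lv, 1.0)
    np.add.at(s_i, lv, diff[ok])
    return n_i, s_i


def ngtdm_features(q: QuantizedMap) -> OrderedDict:
    """The 5 Amadasun-King neighbourhood gray-tone difference features.

    The neighbourhood is the 3x3 ring around each valid cell; only valid
    neighbours enter the neighbourhood average, and cells with no valid
    neighbour are excluded.  Coarseness is capped at ``1e6`` when every
    ``s_i`` vanishes (uniform image).
    """
    ng = q.ng
    n_i, s_i = ngtdm_arrays(q)
    n_tot = n_i.sum()
    if n_tot == 0:
        raise ValidationError("NGTDM: no cell has a valid neighbour")
    p_i = n_i / n_tot
    present = n_i > 0
    i = np.arange(ng + 1, dtype=np.float64)
    n_g = int(present.sum())
    out = OrderedDict()
    denom = float(np.sum(p_i * s_i))
    out["coarseness"] = float(min(1.0 / denom, COARSENESS_CAP)) if denom > 0 else COARSENESS_CAP
    # contrast
    if n_g > 1:
        pij = np.outer(p_i[present], p_i[present])
        dij = np.subtract.outer(i[present], i[present]) ** 2
        out["contrast"] = float(
            np.sum(pij * dij) / (n_g * (n_g - 1)) * (s_i.sum() / n_tot)
        )
    else:
        out["contrast"] = 0.0
    # busyness
    num = float(np.sum(p_i * s_i))
    den = float(
        np.sum(
            np.abs(
                np.subtract.outer(i[present] * p_i[present], i[present] * p_i[present])
            )
        )
    )
    out["busyness"] = float(num / den) if den > 0 else _sentinel("ngtdm busyness")
    # complexity
    if n_g > 1:
        ip, pp, sp = i[present], p_i[present], s_i[present]
        with np.errstate(divide="ignore", invalid="ignore"):
            comp = (
                np.abs(np.subtract.outer(ip, ip))
                * (np.add.outer(pp * sp, pp * sp))
                / np.add.outer(pp, pp)
            )
        out["complexity"] = float(np.sum(comp) / n_tot)
    else:
        out["complexity"] = 0.0
    # strength
    if denom > 0:
        ip, pp = i[present], p_i[present]
        stren = np.add.outer(pp, pp) * np.subtract.outer(ip, ip) ** 2
        out["strength"] = float(np.sum(stren) / s_i.sum()) if s_i.sum() > 0 else 0.0
    else:
        out["strength"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Wavelet subbands
# ---------------------------------------------------------------------------

def _nearest_fill(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid cells with the value of the nearest valid cell."""
    if valid.all():
        return values
    idx = ndimage.distance_transform_edt(~valid, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def wavelet_subbands(map_, valid=None, wavelet: str = "haar"):
    """Single-level 2-D DWT of the valid bounding-box crop.

    Invalid cells are filled with their nearest valid neighbour before the
    transform.  Returns an ordered mapping ``{"LL": (values, valid), ...}``
    where each subband validity mask marks coefficients whose 2x2 input
    block was fully valid.
    """
    values, valid = _as_values_valid(map_, valid)
    rows = np.nonzero(valid.any(axis=1))[0]
    cols = np.nonzero(valid.any(axis=0))[0]
    if rows.size == 0:
        raise ValidationError("no valid region")
    rs = slice(rows.min(), rows.max() + 1)
    cs = slice(cols.min(), cols.max() + 1)
    crop = values[rs, cs]
    vmask = valid[rs, cs]
    if crop.shape[0] < 2 or crop.shape[1] < 2:
        raise ValidationError("valid region smaller than 2x2")
    filled = _nearest_fill(crop, vmask)
    ll, (lh, hl, hh) = pywt.dwt2(filled, wavelet)
    # a subband coefficient is trusted when its 2x2 (for haar) input
    # support was fully valid; approximate the support by 2x2 blocks after
    # symmetric padding to even shape
    H, W = vmask.shape
    vp = np.pad(vmask, ((0, H % 2), (0, W % 2)), mode="edge")
    block_valid = vp.reshape(vp.shape[0] // 2, 2, vp.shape[1] // 2, 2).all(axis=(1, 3))
    sub_valid = np.zeros(ll.shape, dtype=bool)
    sub_valid[: block_valid.shape[0], : block_valid.shape[1]] = block_valid
    return OrderedDict(
        (name, (band, sub_valid.copy()))
        for name, band in (("LL", ll), ("LH", lh), ("HL", hl), ("HH", hh))
    )


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def _band_features(values, valid, ng: int) -> OrderedDict:
    """All 69 features of one (sub)band, in fixed family order."""
    out = OrderedDict()
    for name, value in histogram_features(values, valid, ng=ng).items():
        out[f"histogram_{name}"] = value
    try:
        q = quantize(values, ng=ng, valid=valid)
    except ConstantMapError:
        q = _degenerate_quantized(values, valid)
    for fam, fn in (
        ("GLCM", glcm_features),
        ("GLRLM", glrlm_features),
        ("GLSZM", glszm_features),
        ("NGTDM", ngtdm_features),
    ):
        for name, value in fn(q).items():
            out[f"{fam}_{name}"] = value
    return out


def extract_map_features(
    map_: FeatureMap,
    ng: int = 64,
    wavelet: str = "haar",
) -> OrderedDict:
    """The 345-feature vector of one map: 69 original + 69 x 4 subbands.

    Feature names are ``{kind}_{subband}_{family}_{feature}`` and the
    order (subband-major, family order histogram/GLCM/GLRLM/GLSZM/NGTDM)
    is deterministic.
    """
    out = OrderedDict()
    for name, value in _band_features(map_.values, map_.valid, ng).items():
        out[f"{map_.kind}_orig_{name}"] = value
    bands = wavelet_subbands(map_.values, map_.valid, wavelet=wavelet)
    for band_name, (bv, bvalid) in bands.items():
        if not bvalid.any():
            # tiny ROI: no fully-valid wavelet support; fall back to all
            # coefficients so the vector stays complete
            bvalid = np.ones(bv.shape, dtype=bool)
        for name, value in _band_features(bv, bvalid, ng).items():
            out[f"{map_.kind}_{band_name}_{name}"] = value
    assert len(out) == FEATURES_PER_MAP, f"expected 345 features, got {len(out)}"
    return out


def extract_patient_features(maps, ng: int = 64, wavelet: str = "haar") -> OrderedDict:
    """Concatenated per-map vectors in fixed map order (345 per map).

    One to three RF maps (DEA, SSD, NRD) or a single grayscale map; map
    kinds must be unique.
    """
    kinds = [m.kind for m in maps]
    if len(set(kinds)) != len(kinds):
        raise ValidationError(f"duplicate map kinds: {kinds}")
    if not 1 <= len(maps) <= 3:
        raise ValidationError("expected 1-3 maps")
    order = {k: i for i, k in enumerate(MAP_KINDS)}
    out = OrderedDict()
    for m in sorted(maps, key=lambda m: order[m.kind]):
        out.update(extract_map_features(m, ng=ng, wavelet=wavelet))
    return out
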