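"""Texture/wavelet radiomics: counts, hand examples, brute-force oracles."""

import warnings
from collections import OrderedDict

import numpy as np
import pytest

from rfrad.feature_maps import FeatureMap
from rfrad.radiomics import (
    DIRECTIONS,
    FAMILY_COUNTS,
    ConstantMapError,
    QuantizedMap,
    _cooccurrence,
    _glrlm_one_direction,
    extract_map_features,
    extract_patient_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    histogram_features,
    ngtdm_features,
    quantize,
    wavelet_subbands,
)
from rfrad.rf_core import ValidationError


def fmap(values, kind="DEA", valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    return FeatureMap(values=values, valid=valid, kind=kind)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_cooccurrence(levels, valid, offset, ng):
    """Loop over all cells; count symmetric valid-valid co-occurrences."""
    H, W = levels.shape
    dr, dc = offset
    mat = np.zeros((ng, ng))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and valid[r, c] and valid[r2, c2]:
                mat[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                mat[levels[r2, c2] - 1, levels[r, c] - 1] += 1
    return mat


def brute_runs(levels, valid, offset):
    """Enumerate maximal runs along ``offset`` by walking each line."""
    H, W = levels.shape
    dr, dc = offset
    starts = []
    for r in range(H):
        for c in range(W):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < H and 0 <= pc < W):
                starts.append((r, c))
    runs = []
    for r0, c0 in starts:
        line = []
        r, c = r0, c0
        while 0 <= r < H and 0 <= c < W:
            line.append(levels[r, c] if valid[r, c] else 0)
            r, c = r + dr, c + dc
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            if line[i] > 0:
                runs.append((line[i], j - i))
            i = j
    return sorted(runs)


def brute_zones(levels, valid):
    """8-connected equal-level zones by flood fill."""
    H, W = levels.shape
    seen = np.zeros((H, W), dtype=bool)
    zones = []
    for r in range(H):
        for c in range(W):
            if seen[r, c] or not valid[r, c]:
                continue
            g = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if (
                            0 <= yy < H
                            and 0 <= xx < W
                            and not seen[yy, xx]
                            and valid[yy, xx]
                            and levels[yy, xx] == g
                        ):
                            seen[yy, xx] = True
                            stack.append((yy, xx))
            zones.append((g, size))
    return sorted(zones)


def random_quantized(rng, shape=(6, 6), ng=4):
    levels = rng.integers(1, ng + 1, shape)
    valid = rng.random(shape) > 0.2
    valid.flat[0] = True  # never empty
    return QuantizedMap(levels, ng, valid, np.arange(ng + 1, dtype=float))


# ---------------------------------------------------------------------------
# Quantisation
# ---------------------------------------------------------------------------

class TestQuantize:
    def test_integer_identity(self):
        v = np.arange(64, dtype=float).reshape(8, 8)
        q = quantize(v, ng=64)
        np.testing.assert_array_equal(q.levels, v.astype(int) + 1)

    def test_affine_invariance(self, rng):
        # integer-valued data and power-of-two scale keep the affine map
        # exact in floating point
        v = rng.integers(0, 1000, (12, 9)).astype(float)
        q1 = quantize(v, ng=16)
        q2 = quantize(4.0 * v + 128.0, ng=16)
        np.testing.assert_array_equal(q1.levels, q2.levels)

    def test_binary_map(self):
        v = np.array([[0.0, 5.0], [5.0, 0.0]])
        q = quantize(v, ng=2)
        np.testing.assert_array_equal(q.levels, [[1, 2], [2, 1]])

    def test_constant_map_raises(self):
        with pytest.raises(ConstantMapError):
            quantize(np.ones((4, 4)), ng=8)


class TestHistogram:
    def test_constant_map(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = histogram_features(np.full((5, 5), 3.0))
        assert h["mean"] == h["median"] == h["minimum"] == h["maximum"] == 3.0
        assert h["range"] == 0.0 and h["variance"] == 0.0
        assert h["uniformity"] == 1.0 and h["entropy"] == 0.0

    def test_hand_arithmetic(self):
        h = histogram_features(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert h["mean"] == 2.5
        assert h["variance"] == 1.25  # population
        assert h["range"] == 3.0

    def test_count(self, random_map):
        assert len(histogram_features(random_map.values)) == 16


class TestGLCM:
    def test_constant_degenerate(self):
        q = QuantizedMap(np.ones((4, 4), int), 1, np.ones((4, 4), bool), [0.0, 1.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = glcm_features(q)
        assert g["asm"] == 1.0 and g["contrast"] == 0.0 and g["entropy"] == 0.0

    def test_two_by_two_horizontal(self):
        q = QuantizedMap(np.array([[1, 2], [1, 2]]), 2, np.ones((2, 2), bool), [0, 0.5, 1])
        mat = _cooccurrence(q, (0, 1))
        p = mat / mat.sum()
        np.testing.assert_allclose(p, [[0, 0.5], [0.5, 0]])
        contrast0 = np.sum(np.subtract.outer([1, 2], [1, 2]) ** 2 * p)
        assert contrast0 == 1.0

    def test_matrix_matches_brute_force(self, rng):
        for _ in range(5):
            q = random_quantized(rng)
            for off in DIRECTIONS:
                np.testing.assert_array_equal(
                    _cooccurrence(q, off), brute_cooccurrence(q.levels, q.valid, off, q.ng)
                )

    def test_count(self, rng):
        assert len(glcm_features(random_quantized(rng))) == 13


class TestGLRLM:
    def test_single_row_run(self):
        q = QuantizedMap(np.array([[1, 1, 1, 1]]), 2, np.ones((1, 4), bool), [0, 0.5, 1])
        d = _glrlm_one_direction(q, (0, 1))
        assert d["sre"] == 1 / 16
        assert d["lre"] == 16
        assert d["rp"] == 1 / 4

    def test_constant_map_column_runs(self):
        n = 5
        q = QuantizedMap(np.ones((n, n), int), 1, np.ones((n, n), bool), [0.0, 1.0])
        runs = brute_runs(q.levels, q.valid, (0, 1))
        assert runs == [(1, n)] * n

    def test_runs_match_brute_force(self, rng):
        from rfrad.radiomics import _run_lengths

        for _ in range(5):
            q = random_quantized(rng)
            for off in DIRECTIONS:
                assert sorted(_run_lengths(q, off)) == brute_runs(q.levels, q.valid, off)

    def test_count(self, rng):
        assert len(glrlm_features(random_quantized(rng))) == 22


class TestGLSZM:
    def test_constant_single_zone(self):
        n = 4
        q = QuantizedMap(np.ones((n, n), int), 1, np.ones((n, n), bool), [0.0, 1.0])
        z = glszm_features(q)
        assert z["zp"] == 1 / n**2
        assert z["lae"] == n**4

    def test_checkerboard_diagonal_connectivity(self):
        # 8-connectivity joins the equal-level diagonals: two zones of size 2
        q = QuantizedMap(np.array([[1, 2], [2, 1]]), 2, np.ones((2, 2), bool), [0, 0.5, 1])
        assert brute_zones(q.levels, q.valid) == [(1, 2), (2, 2)]
        z = glszm_features(q)
        assert z["zp"] == 2 / 4
        assert z["lae"] == 4.0

    def test_zones_match_brute_force(self, rng):
        from scipy import ndimage

        for _ in range(5):
            q = random_quantized(rng)
            zones = []
            for g in np.unique(q.levels[q.valid]):
                labels, n = ndimage.label((q.levels == g) & q.valid, structure=np.ones((3, 3)))
                sizes = np.bincount(labels.ravel())[1:]
                zones.extend((int(g), int(s)) for s in sizes)
            assert sorted(zones) == brute_zones(q.levels, q.valid)

    def test_count(self, rng):
        assert len(glszm_features(random_quantized(rng))) == 13


class TestNGTDM:
    def test_constant_map_cap(self):
        q = QuantizedMap(np.ones((4, 4), int), 1, np.ones((4, 4), bool), [0.0, 1.0])
        g = ngtdm_features(q)
        assert g["coarseness"] == 1e6
        assert g["contrast"] == 0.0

    def test_centre_difference(self):
        from rfrad.radiomics import ngtdm_arrays

        lev = np.full((3, 3), 2, dtype=int)
        lev[1, 1] = 5
        q = QuantizedMap(lev, 5, np.ones((3, 3), bool), np.arange(6, dtype=float))
        _, s_i = ngtdm_arrays(q)
        # s at the centre level equals the centre-to-neighbour-mean gap
        assert s_i[5] == pytest.approx(3.0)
        g = ngtdm_features(q)
        assert np.isfinite(list(g.values())).all()

    def test_count(self, rng):
        assert len(ngtdm_features(random_quantized(rng))) == 5


class TestWavelet:
    def test_constant_haar(self):
        bands = wavelet_subbands(np.full((6, 6), 3.0), np.ones((6, 6), bool))
        assert list(bands) == ["LL", "LH", "HL", "HH"]
        np.testing.assert_allclose(bands["LL"][0], 6.0)
        for name in ("LH", "HL", "HH"):
            np.testing.assert_allclose(bands[name][0], 0.0, atol=1e-12)

    def test_two_by_two_hand_example(self):
        a, b, c, d = 1.0, 2.0, 3.0, 4.0
        bands = wavelet_subbands(np.array([[a, b], [c, d]]), np.ones((2, 2), bool))
        assert bands["LL"][0][0, 0] == pytest.approx((a + b + c + d) / 2)
        assert bands["HH"][0][0, 0] == pytest.approx((a - b - c + d) / 2)

    def test_too_small_region_raises(self):
        with pytest.raises(ValidationError):
            wavelet_subbands(np.ones((1, 5)), np.ones((1, 5), bool))


class TestExtraction:
    def test_counts_are_structural(self, random_map):
        feats = extract_map_features(random_map)
        assert len(feats) == 345
        by_band_family = {}
        for name in feats:
            _, band, family = name.split("_")[:3]
            by_band_family.setdefault(band, {}).setdefault(family, 0)
            by_band_family[band][family] += 1
        assert set(by_band_family) == {"orig", "LL", "LH", "HL", "HH"}
        for band, fams in by_band_family.items():
            assert fams == FAMILY_COUNTS
        n_wavelet = sum(1 for n in feats if n.split("_")[1] != "orig")
        assert n_wavelet == 276

    def test_extraction_deterministic(self, random_map):
        a = extract_map_features(random_map)
        b = extract_map_features(random_map)
        assert list(a) == list(b)
        assert all(a[k] == b[k] for k in a)

    def test_matrix_families_affine_invariant(self, rng):
        v = rng.integers(0, 500, (20, 15)).astype(float)
        m1 = fmap(v)
        m2 = fmap(2.0 * v + 64.0)
        f1 = extract_map_features(m1, ng=16)
        f2 = extract_map_features(m2, ng=16)
        for name in f1:
            fam = name.split("_")[2]
            if fam in ("GLCM", "GLRLM", "GLSZM", "NGTDM") and name.split("_")[1] == "orig":
                assert f1[name] == pytest.approx(f2[name], rel=1e-12), name

    def test_patient_concatenation_lengths(self, rng):
        v = rng.normal(0, 1, (25, 10))
        maps = [fmap(v, k) for k in ("DEA", "SSD", "NRD")]
        assert len(extract_patient_features(maps[:1])) == 345
        assert len(extract_patient_features(maps[:2])) == 690
        assert len(extract_patient_features(maps)) == 1035

    def test_duplicate_kinds_rejected(self, rng):
        v = rng.normal(0, 1, (25, 10))
        with pytest.raises(ValidationError):
            extract_patient_features([fmap(v, "DEA"), fmap(v, "DEA")])

    def test_constant_map_yields_full_vector(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = extract_map_features(fmap(np.full((10, 8), 2.0)))
        assert len(feats) == 345
        assert all(np.isfinite(v) for v in feats.values())
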