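import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lucency as lc
from lucency.volume import boundary_pixels

from conftest import block_volume, random_blob_mask


# ---------------------------------------------------------------------------
# independent geometric oracles (pure python, O(n^2) over boundary pixels)

def _oracle_boundary(mask):
    pts = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            edge = r in (0, h - 1) or c in (0, w - 1)
            nbs = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
            if edge or any(not mask[rr, cc] for rr, cc in nbs):
                pts.append((r, c))
    return pts


def _oracle_span(mask):
    pts = _oracle_boundary(mask)
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = ((pts[i][0] - pts[j][0]) ** 2 + (pts[i][1] - pts[j][1]) ** 2) ** 0.5
            best = max(best, d)
    return best


def _oracle_losa(a, b):
    """Directed boundary distance of the largest hole, by explicit flood fill."""
    h, w = a.shape
    holes = b & ~a
    seen = np.zeros_like(holes)
    components = []
    for r in range(h):
        for c in range(w):
            if holes[r, c] and not seen[r, c]:
                comp, stack = [], [(r, c)]
                while stack:
                    rr, cc = stack.pop()
                    if not (0 <= rr < h and 0 <= cc < w):
                        continue
                    if seen[rr, cc] or not holes[rr, cc]:
                        continue
                    seen[rr, cc] = True
                    comp.append((rr, cc))
                    stack += [(rr - 1, cc), (rr + 1, cc), (rr, cc - 1), (rr, cc + 1)]
                components.append(comp)
    if not components:
        return 0.0
    largest = max(components, key=len)
    comp_mask = np.zeros_like(holes)
    for r, c in largest:
        comp_mask[r, c] = True
    inner = _oracle_boundary(comp_mask)
    wall = _oracle_boundary(b)
    best = 0.0
    for ri, ci in inner:
        nearest = min(((ri - rk) ** 2 + (ci - ck) ** 2) ** 0.5 for rk, ck in wall)
        best = max(best, nearest)
    return best


# ---------------------------------------------------------------------------
# worked examples

class TestCompositionScores:
    def test_single_slice_counts(self):
        vol = block_volume(3, hole=1)
        assert lc.rdc(vol) == pytest.approx(8 / 9)
        assert lc.rlc(vol) == pytest.approx(1 / 9)
        assert lc.at_ratio(vol) == pytest.approx(1 / 8)

    def test_solid_tumor_extremes(self):
        vol = block_volume(5)
        assert lc.rdc(vol) == 1.0
        assert lc.rlc(vol) == 0.0
        assert lc.at_ratio(vol) == 0.0
        assert lc.losa(vol) == 0.0
        assert lc.loca(vol) == 0.0

    def test_multi_slice_mean(self):
        # per-slice solid ratios 1.0 and 0.5 average to 0.75; SlicePairs are
        # built directly so A and B are controlled independently
        b = np.ones((4, 4), dtype=bool)
        a = b.copy()
        a[1:3, 1:3] = False
        a[0, :2] = False
        a[3, 2:] = False
        vol = lc.TumorVolume([lc.SlicePair(b, b), lc.SlicePair(a, b)])
        assert lc.rdc(vol) == pytest.approx(0.75)
        assert lc.rlc(vol) == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "r,l,expected", [(0.8, 0.2, 0.6), (0.5, 0.5, 0.0), (8 / 9, 1 / 9, 7 / 9)]
    )
    def test_doc(self, r, l, expected):
        assert lc.doc(r, l) == pytest.approx(expected)

    def test_all_lucent_slice_rejected(self):
        b = np.zeros((5, 5), dtype=bool)
        b[1:4, 1:4] = True
        a = np.zeros_like(b)
        vol = lc.TumorVolume([lc.SlicePair(a, b)])
        with pytest.raises(ValueError, match="no solid tissue"):
            lc.at_ratio(vol)

    def test_empty_volume_rejected(self):
        vol = lc.TumorVolume([lc.SlicePair(np.zeros((3, 3), bool), np.zeros((3, 3), bool))])
        with pytest.raises(ValueError, match="no tumor pixels"):
            lc.rdc(vol)


class TestGeometryScores:
    def test_span_examples(self):
        assert lc.span(block_volume(7)) == pytest.approx(6 * np.sqrt(2))
        row = np.zeros((3, 7), dtype=bool)
        row[1, 1:6] = True
        assert lc.span(lc.TumorVolume.from_arrays([row])) == pytest.approx(4.0)
        single = np.zeros((3, 3), dtype=bool)
        single[1, 1] = True
        assert lc.span(lc.TumorVolume.from_arrays([single])) == 0.0

    def test_losa_examples(self):
        assert lc.losa(block_volume(7, hole=1)) == pytest.approx(3.0)
        assert lc.losa(block_volume(7, hole=3)) == pytest.approx(2.0)

    def test_losa_ratio(self):
        vol = block_volume(7, hole=1)
        assert lc.losa_ratio(vol) == pytest.approx(3.0 / (6 * np.sqrt(2)))
        assert lc.losa_ratio(block_volume(7)) == 0.0

    def test_losa_ratio_degenerate_mask(self):
        single = np.zeros((3, 3), dtype=bool)
        single[1, 1] = True
        with pytest.raises(ValueError, match="degenerate mask"):
            lc.losa_ratio(lc.TumorVolume.from_arrays([single]))

    def test_inner_diameter_examples(self):
        sl = block_volume(7, hole=1).slices[0]
        assert lc.inner_diameter(sl) == pytest.approx(2 * np.sqrt(1 / np.pi))
        sl = block_volume(7, hole=3).slices[0]
        assert lc.inner_diameter(sl) == pytest.approx(2 * np.sqrt(9 / np.pi))

    def test_inner_diameter_two_holes_averaged(self):
        a = np.ones((9, 13), dtype=bool)
        a[4, 2] = False          # area-1 hole
        a[3:6, 8:11] = False     # area-9 hole
        sl = lc.SlicePair.from_solid(a)
        expected = (2 * np.sqrt(1 / np.pi) + 2 * np.sqrt(9 / np.pi)) / 2
        assert lc.inner_diameter(sl) == pytest.approx(expected)

    def test_inner_diameter_requires_hole(self):
        with pytest.raises(ValueError, match="no lucent area"):
            lc.inner_diameter(block_volume(3).slices[0])

    def test_loca_examples(self):
        assert lc.loca(block_volume(7, hole=3)) == pytest.approx(2 * np.sqrt(9 / np.pi))
        assert lc.loca_ratio(block_volume(7, hole=3)) == pytest.approx(
            2 * np.sqrt(9 / np.pi) / (6 * np.sqrt(2))
        )

    def test_loca_averages_over_lucent_slices_only(self):
        a1 = np.ones((7, 7), dtype=bool)
        a1[3, 3] = False
        a2 = np.ones((7, 7), dtype=bool)
        a2[2:5, 2:5] = False
        solid = np.ones((7, 7), dtype=bool)
        vol = lc.TumorVolume.from_arrays([a1, solid, a2])
        expected = (2 * np.sqrt(1 / np.pi) + 2 * np.sqrt(9 / np.pi)) / 2
        assert lc.loca(vol) == pytest.approx(expected)

    def test_spacing_scales_distances(self):
        unscaled = block_volume(7, hole=1)
        scaled = block_volume(7, hole=1, spacing=0.7)
        assert lc.span(scaled) == pytest.approx(0.7 * lc.span(unscaled))
        assert lc.losa(scaled) == pytest.approx(0.7 * lc.losa(unscaled))
        assert lc.loca(scaled) == pytest.approx(0.7 * lc.loca(unscaled))
        # ratios are scale-free
        assert lc.losa_ratio(scaled) == pytest.approx(lc.losa_ratio(unscaled))


class TestSolidity:
    def test_full_block(self):
        assert lc.solidity(block_volume(3)) == 1.0

    def test_center_hole(self):
        assert lc.solidity(block_volume(3, hole=1)) == pytest.approx(8 / 9)

    def test_l_shape(self):
        a = np.zeros((4, 4), dtype=bool)
        a[1, 1] = a[2, 1] = a[2, 2] = True
        assert lc.solidity(lc.TumorVolume.from_arrays([a])) == pytest.approx(0.75)


class TestComputeAll:
    def test_solid_tumor_vector(self):
        vec = lc.compute_all(block_volume(5))
        assert (vec.rdc, vec.rlc, vec.doc) == (1.0, 0.0, 1.0)
        assert (vec.at_r, vec.losa, vec.losa_r, vec.loca, vec.loca_r) == (0, 0, 0, 0, 0)
        assert vec.solidity == 1.0

    def test_center_hole_vector(self):
        vec = lc.compute_all(block_volume(7, hole=1))
        assert vec.rdc == pytest.approx(48 / 49)
        assert vec.at_r == pytest.approx(1 / 48)
        assert vec.losa == pytest.approx(3.0)
        assert vec.losa_r == pytest.approx(3.0 / (6 * np.sqrt(2)))

    def test_max_pair_method_dominates_directed(self):
        vol = block_volume(9, hole=3)
        assert lc.losa(vol, method="max_pair") >= lc.losa(vol, method="directed")
        with pytest.raises(ValueError, match="unknown LoSA method"):
            lc.losa(vol, method="bogus")


# ---------------------------------------------------------------------------
# properties

class TestInvariants:
    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_composition_identities(self, seed):
        rng = np.random.default_rng(seed)
        a = random_blob_mask(rng, size=24)
        vol = lc.TumorVolume.from_arrays([a])
        r, l = lc.rdc(vol), lc.rlc(vol)
        assert abs(r + l - 1) < 1e-12
        assert abs(lc.doc(r, l) - abs(2 * r - 1)) < 1e-12
        # single-slice volume: AT_R reduces to RLC/RDC
        assert abs(lc.at_ratio(vol) - l / r) < 1e-12

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_rotation_leaves_scores_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        a = random_blob_mask(rng, size=24)
        v1 = lc.TumorVolume.from_arrays([a])
        v2 = lc.TumorVolume.from_arrays([np.rot90(a)])
        for k, x in lc.compute_all(v1).as_dict().items():
            assert lc.compute_all(v2).as_dict()[k] == pytest.approx(x, abs=1e-12), k

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_enlarging_a_hole_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        b = np.zeros((20, 20), dtype=bool)
        yy, xx = np.mgrid[0:20, 0:20]
        b[(yy - 10) ** 2 + (xx - 10) ** 2 <= 64] = True
        r_small = float(rng.uniform(1, 3))
        r_big = r_small + float(rng.uniform(0.5, 3))
        small = b & ~((yy - 10) ** 2 + (xx - 10) ** 2 <= r_small**2)
        big = b & ~((yy - 10) ** 2 + (xx - 10) ** 2 <= r_big**2)
        vs = lc.TumorVolume([lc.SlicePair(small, b)])
        vb = lc.TumorVolume([lc.SlicePair(big, b)])
        assert lc.rdc(vb) <= lc.rdc(vs)
        assert lc.rlc(vb) >= lc.rlc(vs)
        assert lc.at_ratio(vb) >= lc.at_ratio(vs)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_losa_ratio_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = random_blob_mask(rng, size=28)
        vol = lc.TumorVolume.from_arrays([a])
        if lc.span(vol) == 0:
            return
        assert 0.0 <= lc.losa_ratio(vol) <= 1.0


class TestGeometricOracles:
    def test_span_and_losa_match_brute_force(self):
        rng = np.random.default_rng(7)
        checked_holes = 0
        for _ in range(50):
            a = random_blob_mask(rng, size=32)
            vol = lc.TumorVolume.from_arrays([a])
            sl = vol.slices[0]
            assert lc.span(vol) == pytest.approx(_oracle_span(sl.b), abs=1e-12)
            assert lc.losa(vol) == pytest.approx(_oracle_losa(sl.a, sl.b), abs=1e-12)
            checked_holes += sl.has_hole
        assert checked_holes >= 5  # the fixture family must exercise lucency

    def test_boundary_definition_matches_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = random_blob_mask(rng, size=16)
            got = {tuple(p) for p in boundary_pixels(a)}
            assert got == set(_oracle_boundary(a))
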