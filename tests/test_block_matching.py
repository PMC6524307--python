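"""Block matching: distances, similarity search, reference iteration."""

import numpy as np
import pytest

from mvct_enhance.block_matching import (BlockIndex, MatchConfig,
                                         anchor_positions, find_similar,
                                         iterate_references, prefilter_distance)
from mvct_enhance.errors import ValidationError


@pytest.fixture
def cfg():
    return MatchConfig()


class TestPrefilterDistance:
    def test_identical_blocks_give_zero(self, cfg, rng):
        b = rng.normal(size=(8, 8))
        assert prefilter_distance(b, b, cfg) == 0.0

    def test_symmetry(self, cfg, rng):
        a, b = rng.normal(size=(2, 8, 8))
        assert prefilter_distance(a, b, cfg) == pytest.approx(
            prefilter_distance(b, a, cfg))

    def test_constant_offset_matches_pixel_domain_oracle(self, cfg, rng):
        # the block transform preserves constants, so a +1 offset must give
        # exactly ||1||^2 / 64 = 1, the same as the pixel-domain distance
        a = rng.normal(size=(8, 8))
        b = a + 1.0
        pixel_oracle = np.sum((a - b) ** 2) / 64.0
        assert prefilter_distance(a, b, cfg) == pytest.approx(1.0, abs=1e-10)
        assert pixel_oracle == pytest.approx(1.0)

    def test_size_mismatch_rejected(self, cfg):
        with pytest.raises(ValidationError):
            prefilter_distance(np.zeros((8, 8)), np.zeros((4, 4)), cfg)


def _brute_force_members(img, ref, cfg):
    """Exhaustive oracle: scan every in-window candidate with the public
    per-pair distance, sort ascending with row-major tie-break."""
    n, half = cfg.n_block, cfg.window // 2
    mr, mc = img.shape[0] - n, img.shape[1] - n
    ref_block = img[ref[0]:ref[0] + n, ref[1]:ref[1] + n]
    cands = []
    for r in range(max(0, ref[0] - half), min(mr, ref[0] + half) + 1):
        for c in range(max(0, ref[1] - half), min(mc, ref[1] + half) + 1):
            d = prefilter_distance(ref_block, img[r:r + n, c:c + n], cfg)
            cands.append((d, (r, c)))
    cands.sort(key=lambda t: t[0])  # stable: preserves row-major tie order
    members = [ref]
    for d, rc in cands:
        if len(members) >= cfg.n_number:
            break
        if rc == ref or d > cfg.tau_match:
            continue
        members.append(rc)
    return members


class TestFindSimilar:
    def test_matches_brute_force_oracle_on_random_images(self, rng):
        cfg = MatchConfig(window=15, n_number=4, tau_match=2000.0)
        for _ in range(5):
            img = rng.normal(100, 30, (32, 32))
            ref = (int(rng.integers(0, 25)), int(rng.integers(0, 25)))
            g = find_similar(img, ref, cfg)
            assert g.members == _brute_force_members(img, ref, cfg)

    def test_duplicate_inside_window_is_found(self, rng):
        cfg = MatchConfig(window=21, n_number=5, tau_match=10.0)
        img = rng.uniform(0, 255, (40, 40))  # uniform noise: huge distances
        ref = (16, 16)
        img[24:32, 6:14] = img[16:24, 16:24].copy()  # plant an exact duplicate
        g = find_similar(img, ref, cfg)
        assert set(g.members) == {ref, (24, 6)}

    def test_duplicate_outside_window_is_ignored(self, rng):
        cfg = MatchConfig(window=9, n_number=5, tau_match=10.0)
        img = rng.uniform(0, 255, (64, 64))
        ref = (8, 8)
        img[40:48, 40:48] = img[8:16, 8:16]  # duplicate far outside 9x9 window
        g = find_similar(img, ref, cfg)
        assert g.members == [ref]

    def test_constant_image_tie_break_is_row_major_after_ref(self):
        cfg = MatchConfig(window=11, n_number=4)
        g = find_similar(np.full((32, 32), 7.0), (10, 10), cfg)
        assert g.members[0] == (10, 10)
        assert g.members[1:] == [(5, 5), (5, 6), (5, 7)]
        assert np.all(g.distances == 0)

    def test_stack_first_slice_is_reference_block(self, rng):
        img = rng.normal(size=(32, 32))
        g = find_similar(img, (4, 6), MatchConfig(window=15))
        assert np.array_equal(g.stack[:, :, 0], img[4:12, 6:14])

    def test_shrinking_tau_never_grows_membership(self, rng):
        img = rng.normal(100, 20, (32, 32))
        taus = [4000.0, 400.0, 40.0, 4.0, 0.0]
        sizes = [len(find_similar(img, (12, 12), MatchConfig(window=15, tau_match=t)).members)
                 for t in taus]
        assert sizes == sorted(sizes, reverse=True)

    def test_out_of_bounds_reference_rejected(self, rng):
        with pytest.raises(ValidationError):
            find_similar(np.zeros((16, 16)), (10, 10), MatchConfig())

    def test_exact_group_size_ignores_tau(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        cfg = MatchConfig(window=15, tau_match=1e-6, exact_group_size=True)
        assert len(find_similar(img, (12, 12), cfg).members) == cfg.n_number


class TestIterateReferences:
    def test_anchor_enumeration_with_border_clamp(self):
        pos = anchor_positions(64, 8, 3)
        assert list(pos) == list(range(0, 55, 3)) + [56]
        assert len(pos) == 20
        groups = list(iterate_references(np.zeros((64, 64)), MatchConfig()))
        assert len(groups) == 400

    def test_degenerate_step_keeps_border_anchor(self):
        pos = anchor_positions(64, 8, 64)
        assert list(pos) == [0, 56]

    def test_every_pixel_covered_by_some_reference_patch(self, rng):
        img = rng.normal(size=(30, 45))
        cfg = MatchConfig(window=9, step=7)
        covered = np.zeros(img.shape, bool)
        for g in iterate_references(img, cfg):
            r, c = g.ref_coord
            covered[r:r + 8, c:c + 8] = True
        assert covered.all()
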