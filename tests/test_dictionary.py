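"""Discriminative dictionary: candidate extraction, selection, persistence."""

import numpy as np
import pytest

from mvct_enhance import (CTImage, DegenerateTrainingError, DictionaryConfig,
                          Modality, TrainingPair, ValidationError,
                          build_dictionary, load_dictionary, save_dictionary)
from mvct_enhance.dictionary import extract_candidates, select_atoms


def _pairs_from_volumes(hq_vol, lq_vol):
    return [TrainingPair(CTImage(hq_vol[:, :, k], slice_index=k),
                         CTImage(lq_vol[:, :, k], slice_index=k))
            for k in range(hq_vol.shape[2])]


@pytest.fixture
def noisy_pairs(rng):
    """16x16, 5 slices: structured HQ + Gaussian-difference LQ."""
    base = np.add.outer(np.linspace(0, 80, 16), np.linspace(0, 40, 16))
    hq = np.repeat(base[:, :, None], 5, axis=2) + rng.normal(0, 1, (16, 16, 5))
    lq = hq + rng.normal(0, 15, (16, 16, 5))
    return _pairs_from_volumes(hq, lq)


class TestExtractCandidates:
    def test_anchor_grid_count(self, noisy_pairs):
        hq, na = extract_candidates(noisy_pairs, dims=(8, 8, 5), stride=8)
        assert len(hq) == len(na) == 4  # 2 x 2 anchors on a 16x16 grid

    def test_identical_pairs_give_zero_energy_noise_candidates(self, rng):
        vol = rng.normal(50, 20, (16, 16, 5))
        _, na = extract_candidates(_pairs_from_volumes(vol, vol.copy()),
                                   dims=(8, 8, 5), stride=8)
        assert all(e == 0.0 for _, e in na)

    def test_constant_volume_gives_zero_hq_candidates_after_dc_removal(self):
        vol = np.full((16, 16, 5), 70.0)
        hq, _ = extract_candidates(_pairs_from_volumes(vol, vol + 1.0),
                                   dims=(8, 8, 5), stride=8)
        assert all(np.allclose(v, 0) and e < 1e-9 for v, e in hq)

    def test_too_few_slices_rejected(self, noisy_pairs):
        with pytest.raises(ValidationError):
            extract_candidates(noisy_pairs[:3], dims=(8, 8, 5), stride=8)


class TestSelectAtoms:
    def test_rho_one_returns_highest_energy_candidates(self, rng):
        cands = [(v, float(np.linalg.norm(v)))
                 for v in rng.normal(size=(20, 32))]
        picked = select_atoms(cands, k=5, rho_max=1.0)
        # brute-force oracle: sort candidates by energy, take the top 5
        oracle = sorted(cands, key=lambda t: -t[1])[:5]
        for atom, (vec, e) in zip(picked, oracle):
            assert np.allclose(atom, vec / e)

    def test_duplicate_candidate_rejected_for_redundancy(self, rng):
        v = rng.normal(size=16)
        w = rng.normal(size=16)
        w -= w @ v / (v @ v) * v  # orthogonal: always admissible
        cands = [(v * 3, float(np.linalg.norm(v * 3))),
                 (v * 2.9, float(np.linalg.norm(v * 2.9))),  # same direction
                 (w, float(np.linalg.norm(w)))]
        picked = select_atoms(cands, k=2, rho_max=0.99)
        assert len(picked) == 2
        assert np.allclose(picked[1], w / np.linalg.norm(w))

    def test_exhaustion_returns_all_with_warning(self, rng):
        cands = [(v, float(np.linalg.norm(v))) for v in rng.normal(size=(3, 8))]
        with pytest.warns(RuntimeWarning):
            picked = select_atoms(cands, k=10, rho_max=1.0)
        assert len(picked) == 3

    def test_all_zero_candidates_is_degenerate(self):
        with pytest.raises(DegenerateTrainingError):
            select_atoms([(np.zeros(8), 0.0)] * 4, k=2)


class TestBuildDictionary:
    def _config(self):
        return DictionaryConfig(atom_dims=(8, 8, 5), stride=4, k_hq=8, k_na=8)

    def test_atoms_are_zero_mean_unit_norm_and_labeled(self, noisy_pairs):
        d = build_dictionary(noisy_pairs, self._config())
        assert d.n_atoms == len(d.labels)
        assert int(d.hq_mask.sum()) + int((~d.hq_mask).sum()) == d.n_atoms
        assert np.allclose(d.atoms.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(np.linalg.norm(d.atoms, axis=0), 1, atol=1e-10)

    def test_noise_subdictionary_respects_redundancy_cap(self, noisy_pairs):
        d = build_dictionary(noisy_pairs, self._config())
        na = d.atoms[:, ~d.hq_mask]
        gram = np.abs(na.T @ na)
        off_diag = gram[~np.eye(gram.shape[0], dtype=bool)]
        assert off_diag.mean() < self._config().rho_max

    def test_noiseless_pairs_raise_degenerate_error(self, rng):
        vol = rng.normal(0, 30, (16, 16, 5))
        with pytest.raises(DegenerateTrainingError):
            build_dictionary(_pairs_from_volumes(vol, vol.copy()), self._config())

    def test_save_load_round_trip_bit_identical(self, noisy_pairs, tmp_path):
        d = build_dictionary(noisy_pairs, self._config())
        save_dictionary(d, tmp_path / "dict")
        back = load_dictionary(tmp_path / "dict.json")
        assert np.array_equal(d.atoms, back.atoms)
        assert np.array_equal(d.labels, back.labels)
        assert d.atom_dims == back.atom_dims

    def test_selection_is_deterministic(self, noisy_pairs):
        a = build_dictionary(noisy_pairs, self._config())
        b = build_dictionary(noisy_pairs, self._config())
        assert np.array_equal(a.atoms, b.atoms)

    def test_mismatched_pair_rejected(self):
        with pytest.raises(ValidationError):
            TrainingPair(CTImage(np.zeros((8, 8))), CTImage(np.zeros((9, 9))))
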