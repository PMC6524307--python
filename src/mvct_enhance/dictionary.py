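"""Discriminative feature dictionary built from registered KVCT/MVCT pairs.

The dictionary D = [D_hq | D_na] concatenates two sub-dictionaries of
vectorized 3D patches (default 8x8x5):

* D_hq — "high-quality" atoms sampled from the stacked kilovoltage (KVCT)
  training volume; these carry the anatomy/structure content that a sparse
  code is allowed to keep.
* D_na — "noise/artifact" atoms sampled from the voxelwise difference
  volume (KVCT - MVCT); these model what the enhancement must remove.

Candidates are DC-removed per 2D slice, ranked by energy (pre-normalization
L2 norm), and greedily selected under a redundancy cap: a candidate is
skipped when its absolute correlation with any already selected atom
exceeds ``rho_max``.  Every stored atom is zero-mean and unit-norm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateTrainingError, ValidationError
from .image_io import CTImage, WindowingSpec, apply_window

HQ = "HQ"
NA = "NA"


@dataclass
class TrainingPair:
    """A registered high-quality / low-quality slice pair on one grid."""

    hq: CTImage
    lq: CTImage

    def __post_init__(self) -> None:
        if self.hq.shape != self.lq.shape or self.hq.spacing != self.lq.spacing:
            raise ValidationError("training pair must share shape and spacing")


@dataclass
class DictionaryConfig:
    atom_dims: tuple[int, int, int] = (8, 8, 5)
    stride: int = 4          # candidate grid spacing (atom side / 2)
    k_hq: int = 256
    k_na: int = 256
    rho_max: float = 0.9
    jitter: bool = False     # seeded random offset of the candidate grid
    seed: int = 0
    window: WindowingSpec = field(default_factory=WindowingSpec)

    def __post_init__(self) -> None:
        if min(self.atom_dims) < 1:
            raise ValidationError("atom dims must be positive")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if self.k_hq < 1 or self.k_na < 0:
            raise ValidationError("atom counts must be positive")
        if not (0 < self.rho_max <= 1):
            raise ValidationError("rho_max must lie in (0, 1]")


@dataclass
class FeatureDictionary:
    """Atoms as columns of a (n_x*n_y*n_z) x K matrix with HQ/NA labels."""

    atoms: np.ndarray
    labels: np.ndarray
    atom_dims: tuple[int, int, int]
    selection_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.atoms.ndim != 2:
            raise ValidationError("atoms must be a 2D matrix")
        if self.atoms.shape[0] != int(np.prod(self.atom_dims)):
            raise ValidationError("atom length must equal prod(atom_dims)")
        if self.labels.shape[0] != self.atoms.shape[1]:
            raise ValidationError("one label per atom required")
        if not np.any(self.labels == HQ):
            raise ValidationError("dictionary needs at least one HQ atom")
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValidationError("atoms must be unit-norm")
        means = self.atoms.mean(axis=0)
        if np.any(np.abs(means) > 1e-8):
            raise ValidationError("atoms must be zero-mean")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def hq_mask(self) -> np.ndarray:
        return self.labels == HQ


def _center_per_slice(patch: np.ndarray) -> np.ndarray:
    """Remove the mean of each 2D slice of an (nx, ny, nz) patch."""
    return patch - patch.mean(axis=(0, 1), keepdims=True)


def _stack_volumes(pairs: list[TrainingPair], window: WindowingSpec):
    hq = np.stack([apply_window(p.hq, window) for p in pairs], axis=-1)
    lq = np.stack([apply_window(p.lq, window) for p in pairs], axis=-1)
    return hq, hq - lq


def extract_candidates(pairs: list[TrainingPair],
                       dims: tuple[int, int, int] = (8, 8, 5),
                       stride: int = 4,
                       seed: int = 0,
                       jitter: bool = False,
                       window: "WindowingSpec | None" = None):
    """Sample candidate atoms from the HQ volume and the HQ-LQ difference.

    Returns two lists of (patch_vector, energy) tuples, on the windowed
    processing scale, DC-removed per slice.  Anchors lie on a regular grid
    of the given stride (optionally jittered by a seeded offset) in-plane
    and on a stride-``n_z`` grid along the slice axis.
    """
    nx, ny, nz = dims
    if len(pairs) < nz:
        raise ValidationError(f"need at least {nz} slice pairs, got {len(pairs)}")
    window = window or WindowingSpec()
    hq_vol, na_vol = _stack_volumes(pairs, window)
    H, W, Z = hq_vol.shape
    if H < nx or W < ny:
        raise ValidationError("training slices smaller than the atom footprint")
    rng = np.random.default_rng(seed)
    off_r = int(rng.integers(0, stride)) if jitter else 0
    off_c = int(rng.integers(0, stride)) if jitter else 0
    rows = [r for r in range(off_r, H - nx + 1, stride)]
    cols = [c for c in range(off_c, W - ny + 1, stride)]
    zs = list(range(0, Z - nz + 1, nz))
    out = ([], [])
    for vol, bucket in ((hq_vol, out[0]), (na_vol, out[1])):
        for z in zs:
            for r in rows:
                for c in cols:
                    patch = _center_per_slice(vol[r:r + nx, c:c + ny, z:z + nz])
                    vec = patch.ravel()
                    bucket.append((vec, float(np.linalg.norm(vec))))
    return out


def select_atoms(candidates, k: int, rho_max: float = 0.9) -> list[np.ndarray]:
    """Greedy energy-ranked selection under a correlation redundancy cap.

    Candidates are visited by descending energy (stable order on ties); one
    is admitted if its absolute normalized inner product with every already
    selected atom is <= rho_max.  Returned atoms are unit-norm.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not (0 < rho_max <= 1):
        raise ValidationError("rho_max must lie in (0, 1]")
    energies = np.array([e for _, e in candidates])
    usable = energies > 1e-12
    if not np.any(usable):
        raise DegenerateTrainingError(
            "all candidate atoms have zero energy; training pairs carry no "
            "usable features (identical hq/lq images?)")
    order = np.argsort(-energies, kind="stable")
    selected: list[np.ndarray] = []
    sel_mat: np.ndarray | None = None
    for idx in order:
        if len(selected) >= k:
            break
        vec, energy = candidates[idx]
        if energy <= 1e-12:
            continue
        atom = np.asarray(vec, float) / energy
        if sel_mat is not None and rho_max < 1.0:
            if np.max(np.abs(sel_mat.T @ atom)) > rho_max:
                continue
        selected.append(atom)
        sel_mat = atom[:, None] if sel_mat is None else np.column_stack([sel_mat, atom])
    if len(selected) < k:
        warnings.warn(
            f"only {len(selected)} admissible atoms for k={k}; returning all",
            RuntimeWarning, stacklevel=2)
    return selected


def build_dictionary(pairs: list[TrainingPair],
                     config: "DictionaryConfig | None" = None) -> FeatureDictionary:
    """Extract, select and assemble D = [D_hq | D_na] from training pairs."""
    cfg = config or DictionaryConfig()
    hq_cand, na_cand = extract_candidates(
        pairs, cfg.atom_dims, cfg.stride, cfg.seed, cfg.jitter, cfg.window)
    hq_atoms = select_atoms(hq_cand, cfg.k_hq, cfg.rho_max)
    na_atoms = select_atoms(na_cand, cfg.k_na, cfg.rho_max) if cfg.k_na else []
    atoms = np.column_stack(hq_atoms + na_atoms)
    labels = np.array([HQ] * len(hq_atoms) + [NA] * len(na_atoms))
    meta = {
        "k_hq": len(hq_atoms), "k_na": len(na_atoms),
        "rho_max": cfg.rho_max, "stride": cfg.stride, "seed": cfg.seed,
        "window_width": cfg.window.width, "window_level": cfg.window.level,
        "n_pairs": len(pairs), "format_version": 1,
    }
    return FeatureDictionary(atoms, labels, cfg.atom_dims, meta)


def save_dictionary(d: FeatureDictionary, path) -> Path:
    """Write atoms as flat float64 binary plus a JSON sidecar."""
    stem = Path(path)
    if stem.suffix in {".bin", ".json"}:
        stem = stem.with_suffix("")
    stem.parent.mkdir(parents=True, exist_ok=True)
    d.atoms.astype(np.float64).tofile(stem.with_suffix(".bin"))
    sidecar = {
        "atom_dims": list(d.atom_dims),
        "n_atoms": d.n_atoms,
        "labels": d.labels.tolist(),
        "selection_meta": d.selection_meta,
        "dtype": "float64",
        "format_version": 1,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return stem.with_suffix(".bin")


def load_dictionary(path) -> FeatureDictionary:
    stem = Path(path)
    if stem.suffix in {".bin", ".json"}:
        stem = stem.with_suffix("")
    meta = json.loads(stem.with_suffix(".json").read_text())
    dims = tuple(meta["atom_dims"])
    atoms = np.fromfile(stem.with_suffix(".bin"), dtype=np.float64)
    atoms = atoms.reshape(int(np.prod(dims)), int(meta["n_atoms"]))
    return FeatureDictionary(atoms, np.array(meta["labels"]), dims,
                             meta.get("selection_meta", {}))
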