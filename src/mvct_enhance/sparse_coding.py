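"""Orthogonal matching pursuit over the discriminative dictionary.

A matched group (an n x n x m stack of blocks) is coded as follows: the
per-block DC (mean) is removed, the centred stack is vectorized and
greedily approximated by dictionary atoms — at each OMP iteration the atom
with the largest absolute correlation with the current residual is added
and the coefficients are refit by least squares on the selected set.  The
code stops at the joint sparsity cap ``c_dfr`` (default 10) or when the
residual drops below tolerance.

The enhancement step keeps only the high-quality part of the code:
``reconstruct_hq`` rebuilds D_hq @ alpha_hq and adds the DC back, silently
discarding everything the noise-model atoms captured.

Groups shorter than the atom depth (possible when the distance cap prunes
members) are coded against atoms truncated to the group depth, re-centred
per slice and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import HQ, FeatureDictionary, _center_per_slice
from .errors import ValidationError


@dataclass
class SparseCode:
    """OMP output split by atom label."""

    indices: np.ndarray          # selected atom columns, in selection order
    coeffs: np.ndarray           # aligned least-squares coefficients
    hq_indices: np.ndarray
    hq_coeffs: np.ndarray
    na_indices: np.ndarray
    na_coeffs: np.ndarray
    residual_norm: float
    dc: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if len(set(self.indices.tolist())) != len(self.indices):
            raise ValidationError("selected atom indices must be distinct")
        if self.residual_norm < 0:
            raise ValidationError("residual norm must be >= 0")


def remove_dc(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each 2D block's mean; returns (centred stack, dc per block)."""
    s = np.asarray(stack, dtype=np.float64)
    if s.ndim != 3:
        raise ValidationError("stack must be 3D (n x n x m)")
    dc = s.mean(axis=(0, 1))
    return s - dc[None, None, :], dc


def add_dc(stack: np.ndarray, dc: np.ndarray) -> np.ndarray:
    return np.asarray(stack, float) + np.asarray(dc, float)[None, None, :]


class _TruncatedAtoms:
    """Dictionary atoms cut to a shallower stack depth, renormalized."""

    __slots__ = ("matrix", "labels", "keep")

    def __init__(self, D: FeatureDictionary, depth: int):
        nx, ny, nz = D.atom_dims
        if depth == nz:
            self.matrix = D.atoms
            self.labels = D.labels
            self.keep = np.arange(D.n_atoms)
            return
        cut = D.atoms.reshape(nx, ny, nz, D.n_atoms)[:, :, :depth, :]
        cut = cut - cut.mean(axis=(0, 1), keepdims=True)
        flat = cut.reshape(nx * ny * depth, D.n_atoms)
        norms = np.linalg.norm(flat, axis=0)
        self.keep = np.flatnonzero(norms > 1e-10)
        self.matrix = flat[:, self.keep] / norms[self.keep]
        self.labels = D.labels[self.keep]


def atoms_for_depth(D: FeatureDictionary, depth: int) -> _TruncatedAtoms:
    """Atoms usable for a group of the given depth (cached per dictionary)."""
    cache = getattr(D, "_depth_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(D, "_depth_cache", cache)
    if depth not in cache:
        if depth < 1 or depth > D.atom_dims[2]:
            raise ValidationError("group depth must lie in [1, atom depth]")
        cache[depth] = _TruncatedAtoms(D, depth)
    return cache[depth]


def omp(signal: np.ndarray, D: "FeatureDictionary | np.ndarray",
        c_dfr: int = 10, tol: "float | None" = None,
        labels: "np.ndarray | None" = None,
        dc: "np.ndarray | None" = None) -> SparseCode:
    """Greedy sparse approximation of ``signal`` over the dictionary.

    Atom-selection ties are broken by the lowest column index; the residual
    tolerance defaults to ``1e-6 * ||signal||``.
    """
    if c_dfr < 1:
        raise ValidationError("sparsity cap must be >= 1")
    if isinstance(D, FeatureDictionary):
        A = D.atoms
        labels = D.labels
    else:
        A = np.asarray(D, float)
        if labels is None:
            labels = np.array([HQ] * A.shape[1])
    s = np.asarray(signal, dtype=np.float64).ravel()
    if s.size != A.shape[0]:
        raise ValidationError(
            f"signal length {s.size} != atom length {A.shape[0]}")
    snorm = float(np.linalg.norm(s))
    tol = 1e-6 * snorm if tol is None else float(tol)
    indices: list[int] = []
    coeffs = np.zeros(0)
    residual = s.copy()
    rnorm = snorm
    max_iter = min(c_dfr, A.shape[1])
    for _ in range(max_iter):
        if rnorm <= tol:
            break
        corr = np.abs(A.T @ residual)
        corr[indices] = -1.0  # never reselect
        j = int(np.argmax(corr))  # argmax returns the lowest index on ties
        if corr[j] <= 0:
            break
        indices.append(j)
        sub = A[:, indices]
        coeffs, *_ = np.linalg.lstsq(sub, s, rcond=None)
        residual = s - sub @ coeffs
        rnorm = float(np.linalg.norm(residual))
    idx = np.asarray(indices, dtype=int)
    coeffs = np.asarray(coeffs, dtype=np.float64)
    hq_mask = np.array([labels[j] == HQ for j in idx], dtype=bool)
    return SparseCode(
        indices=idx, coeffs=coeffs,
        hq_indices=idx[hq_mask], hq_coeffs=coeffs[hq_mask],
        na_indices=idx[~hq_mask], na_coeffs=coeffs[~hq_mask],
        residual_norm=rnorm,
        dc=np.zeros(0) if dc is None else np.asarray(dc, float))


def code_group(stack: np.ndarray, D: FeatureDictionary,
               c_dfr: int = 10, tol: "float | None" = None) -> SparseCode:
    """remove_dc -> vectorize -> OMP, handling shallow groups."""
    centred, dc = remove_dc(stack)
    trunc = atoms_for_depth(D, stack.shape[2])
    code = omp(centred.ravel(), trunc.matrix, c_dfr, tol, trunc.labels, dc)
    # map truncated-column indices back to original dictionary columns
    remap = trunc.keep
    code.indices = remap[code.indices]
    code.hq_indices = remap[code.hq_indices] if code.hq_indices.size else code.hq_indices
    code.na_indices = remap[code.na_indices] if code.na_indices.size else code.na_indices
    return code


def _reconstruct(code: SparseCode, D: FeatureDictionary, depth: int,
                 which: str) -> np.ndarray:
    nx, ny, _ = D.atom_dims
    trunc = atoms_for_depth(D, depth)
    pos = {int(j): k for k, j in enumerate(trunc.keep)}
    if which == HQ:
        idx, cf = code.hq_indices, code.hq_coeffs
    else:
        idx, cf = code.na_indices, code.na_coeffs
    out = np.zeros(nx * ny * depth)
    for j, a in zip(idx, cf):
        out += a * trunc.matrix[:, pos[int(j)]]
    return out.reshape(nx, ny, depth)


def reconstruct_hq(code: SparseCode, D: FeatureDictionary,
                   depth: "int | None" = None) -> np.ndarray:
    """D_hq @ alpha_hq reshaped to the stack, with per-block DC added back."""
    depth = len(code.dc) if depth is None and len(code.dc) else (depth or D.atom_dims[2])
    stack = _reconstruct(code, D, depth, HQ)
    if len(code.dc):
        stack = add_dc(stack, code.dc)
    return stack


def reconstruct_na(code: SparseCode, D: FeatureDictionary,
                   depth: "int | None" = None) -> np.ndarray:
    """D_na @ alpha_na reshaped to the stack (no DC: noise content only)."""
    depth = len(code.dc) if depth is None and len(code.dc) else (depth or D.atom_dims[2])
    return _reconstruct(code, D, depth, "NA")
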