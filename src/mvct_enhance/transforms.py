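"""Linear transforms and hard thresholding for collaborative filtering.

The 3D transform applied to a matched group factorizes into a separable 2D
biorthogonal-1.5 wavelet transform on each block and a 1D orthonormal
transform along the stack axis.  The 2D transform is realized as a dense
block-transform matrix obtained by running the full dyadic bior-1.5
decomposition (periodic boundary handling) on the canonical basis, so that a
constant block concentrates on a single approximation coefficient and the
forward/inverse pair is exact to machine precision.

Along the stack axis an orthonormal Walsh–Hadamard transform is used when
the depth is a power of two; other depths (the default group depth of 5 in
particular) fall back to the orthonormal DCT-II, which is likewise unitary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt
from scipy.fft import dct, idct
from scipy.linalg import hadamard

from .errors import ValidationError

_WAVELET = "bior1.5"


@dataclass(frozen=True)
class TransformSpec:
    """Names the separable 3D transform used by collaborative filtering."""

    two_d: str = _WAVELET
    one_d: str = "hadamard|dct"
    normalization: str = "orthonormal"


@dataclass
class Coefficients3D:
    """3D transform coefficients plus the post-threshold support size."""

    values: np.ndarray
    retained_count: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.retained_count != int(np.count_nonzero(self.values)):
            raise ValidationError("retained_count must equal the nonzero count")


def hard_threshold(coeffs: np.ndarray, lam: float) -> tuple[np.ndarray, int]:
    """Zero all coefficients with ``|c| <= lam``; report the survivors.

    The boundary convention kills exact hits (``|c| == lam`` maps to 0);
    with ``lam = 0`` only exact zeros are removed, so the operator is the
    identity on its support.  Idempotent for fixed ``lam``.
    """
    if lam < 0:
        raise ValidationError("threshold must be >= 0")
    c = np.asarray(coeffs, dtype=np.float64)
    out = np.where(np.abs(c) > lam, c, 0.0)
    return out, int(np.count_nonzero(out))


def _is_pow2(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@lru_cache(maxsize=None)
def _bior_matrices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward/synthesis matrices of the full-depth bior-1.5 DWT on length n."""
    if not _is_pow2(n) or n < 2:
        raise ValidationError(f"block side must be a power of 2 >= 2, got {n}")
    level = int(np.log2(n))
    with warnings.catch_warnings():
        # pywt warns that level exceeds dwt_max_level for short signals; the
        # periodized transform is still exactly invertible at these sizes.
        warnings.simplefilter("ignore")
        cols = []
        for i in range(n):
            e = np.zeros(n)
            e[i] = 1.0
            cs = pywt.wavedec(e, _WAVELET, mode="periodization", level=level)
            cols.append(np.concatenate(cs))
        fwd = np.array(cols).T
        bounds = np.cumsum([1] + [2 ** k for k in range(level)])
        syn_cols = []
        for i in range(n):
            v = np.zeros(n)
            v[i] = 1.0
            parts = np.split(v, bounds[:-1])
            syn_cols.append(pywt.waverec(list(parts), _WAVELET, mode="periodization"))
        syn = np.array(syn_cols).T
    return fwd, syn


def forward_2d(block: np.ndarray) -> np.ndarray:
    """Separable bior-1.5 transform of a square (power-of-2) block."""
    b = np.asarray(block, dtype=np.float64)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise ValidationError("block must be square")
    T, _ = _bior_matrices(b.shape[0])
    return T @ b @ T.T


def inverse_2d(coeffs: np.ndarray) -> np.ndarray:
    c = np.asarray(coeffs, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError("coefficient grid must be square")
    _, S = _bior_matrices(c.shape[0])
    return S @ c @ S.T


def forward_1d(vec: np.ndarray) -> np.ndarray:
    """Orthonormal transform along the group stack.

    Walsh–Hadamard (scaled by 1/sqrt(m)) for power-of-two lengths, DCT-II
    with orthonormal scaling otherwise; identity for m = 1.  Parseval holds
    in every case.
    """
    v = np.asarray(vec, dtype=np.float64)
    m = v.shape[-1]
    if m == 1:
        return v.copy()
    if _is_pow2(m):
        H = hadamard(m) / np.sqrt(m)
        return v @ H.T
    return dct(v, type=2, norm="ortho", axis=-1)


def inverse_1d(vec: np.ndarray) -> np.ndarray:
    v = np.asarray(vec, dtype=np.float64)
    m = v.shape[-1]
    if m == 1:
        return v.copy()
    if _is_pow2(m):
        H = hadamard(m) / np.sqrt(m)
        return v @ H  # symmetric orthonormal matrix: inverse = itself
    return idct(v, type=2, norm="ortho", axis=-1)


def forward_3d(group: np.ndarray) -> np.ndarray:
    """2D transform per block, then the 1D transform along the stack axis."""
    g = np.asarray(group, dtype=np.float64)
    if g.ndim != 3 or g.shape[0] != g.shape[1]:
        raise ValidationError("group must be an n x n x m stack")
    T, _ = _bior_matrices(g.shape[0])
    c2 = np.einsum("ij,jkm,lk->ilm", T, g, T)
    return forward_1d(c2)


def inverse_3d(coeffs: np.ndarray) -> np.ndarray:
    c = np.asarray(coeffs, dtype=np.float64)
    if c.ndim != 3 or c.shape[0] != c.shape[1]:
        raise ValidationError("coefficients must be an n x n x m stack")
    _, S = _bior_matrices(c.shape[0])
    c1 = inverse_1d(c)
    return np.einsum("ij,jkm,lk->ilm", S, c1, S)
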