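"""Grouping of similar image blocks (the block-matching stage).

For every reference block, the image is scanned inside an L x L search
window and the blocks closest in a prefiltered transform-domain distance
are stacked into a 3D group.  The distance between two blocks is

    d(Z_ref, Z_cand) = || g'(T2D(Z_ref)) - g'(T2D(Z_cand)) ||_2^2 / N_block^2

where T2D is the block transform and g' hard-thresholds coefficients at
``lambda_2d * sigma`` (no shrinkage by default).  The squared-norm-over-N^2
convention gives the distance cap ``tau_match`` its customary meaning on
the 0-255 processing scale.

Matching is fully deterministic: ties at equal distance are broken by
ascending row-major candidate order, and the reference block always heads
the member list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError
from .transforms import _bior_matrices

Coord = tuple[int, int]


@dataclass
class MatchConfig:
    """Block-matching parameters.

    Defaults: 8x8 patches, groups of up to 5 blocks, a 39x39 search window,
    a sliding interval of 3 pixels and a distance cap of 400 on the
    windowed intensity scale.
    """

    n_block: int = 8
    n_number: int = 5
    window: int = 39
    step: int = 3
    tau_match: float = 400.0
    lambda_2d: float = 0.0
    sigma: float = 0.0
    exact_group_size: bool = False  # keep exactly n_number, ignoring tau_match

    def __post_init__(self) -> None:
        if self.n_block < 2:
            raise ValidationError("n_block must be >= 2")
        if self.n_number < 1:
            raise ValidationError("n_number must be >= 1")
        if self.window < self.n_block:
            raise ValidationError("window must be >= n_block")
        if self.step < 1:
            raise ValidationError("step must be >= 1")
        if self.tau_match < 0:
            raise ValidationError("tau_match must be >= 0")
        if self.lambda_2d < 0 or self.sigma < 0:
            raise ValidationError("lambda_2d and sigma must be >= 0")


@dataclass
class Group:
    """A stack of matched blocks anchored at ``ref_coord``."""

    ref_coord: Coord
    members: list[Coord]
    stack: np.ndarray  # n_block x n_block x len(members)
    distances: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if tuple(self.ref_coord) not in {tuple(m) for m in self.members}:
            raise ValidationError("reference must be a group member")
        if self.stack.shape[2] != len(self.members):
            raise ValidationError("stack depth must match member count")


class BlockIndex:
    """Precomputed patches and prefiltered block-transform coefficients.

    Built once per image so that repeated ``find_similar`` calls share the
    per-anchor 2D transforms.  ``patches[r, c]`` is the block anchored at
    (r, c) (a view, no copy); ``coeffs[r, c]`` its thresholded transform.
    """

    def __init__(self, img: np.ndarray, cfg: MatchConfig):
        img = np.asarray(img, dtype=np.float64)
        if img.ndim != 2:
            raise ValidationError("image must be 2D")
        n = cfg.n_block
        if img.shape[0] < n or img.shape[1] < n:
            raise ValidationError("image smaller than one block")
        self.cfg = cfg
        self.shape = img.shape
        self.patches = sliding_window_view(img, (n, n))
        T, _ = _bior_matrices(n)
        coeffs = np.einsum("ij,abjk,lk->abil", T, self.patches, T, optimize=True)
        lam = cfg.lambda_2d * cfg.sigma
        if lam > 0:
            coeffs = np.where(np.abs(coeffs) > lam, coeffs, 0.0)
        self.coeffs = coeffs

    @property
    def max_anchor(self) -> Coord:
        n = self.cfg.n_block
        return (self.shape[0] - n, self.shape[1] - n)


def prefilter_distance(ref: np.ndarray, cand: np.ndarray, cfg: MatchConfig) -> float:
    """Transform-domain distance between two blocks (symmetric, >= 0)."""
    ref = np.asarray(ref, float)
    cand = np.asarray(cand, float)
    n = cfg.n_block
    if ref.shape != (n, n) or cand.shape != (n, n):
        raise ValidationError(f"blocks must be {n}x{n}")
    T, _ = _bior_matrices(n)
    lam = cfg.lambda_2d * cfg.sigma
    a = T @ ref @ T.T
    b = T @ cand @ T.T
    if lam > 0:
        a = np.where(np.abs(a) > lam, a, 0.0)
        b = np.where(np.abs(b) > lam, b, 0.0)
    return float(np.sum((a - b) ** 2) / n**2)


def find_similar(img: "np.ndarray | BlockIndex", ref_coord: Coord,
                 cfg: "MatchConfig | None" = None) -> Group:
    """Group the blocks most similar to the one anchored at ``ref_coord``.

    Candidates are all blocks anchored inside the L x L window centred on
    the reference anchor (clipped at image borders), at every integer
    offset.  Members are the candidates with distance <= tau_match, sorted
    ascending (stable row-major tie-break), truncated to ``n_number``; the
    reference is always first.
    """
    index = img if isinstance(img, BlockIndex) else BlockIndex(img, cfg)
    cfg = index.cfg
    r0, c0 = int(ref_coord[0]), int(ref_coord[1])
    mr, mc = index.max_anchor
    if not (0 <= r0 <= mr and 0 <= c0 <= mc):
        raise ValidationError(f"reference block at {ref_coord} out of bounds")
    half = cfg.window // 2
    rlo, rhi = max(0, r0 - half), min(mr, r0 + half)
    clo, chi = max(0, c0 - half), min(mc, c0 + half)
    cand = index.coeffs[rlo:rhi + 1, clo:chi + 1]
    d = np.sum((cand - index.coeffs[r0, c0]) ** 2, axis=(2, 3)) / cfg.n_block**2
    rows, cols = np.unravel_index(np.arange(d.size), d.shape)
    dist = d.ravel()  # already row-major candidate order
    order = np.argsort(dist, kind="stable")
    members: list[Coord] = [(r0, c0)]
    dists = [0.0]
    limit = np.inf if cfg.exact_group_size else cfg.tau_match
    for k in order:
        if len(members) >= cfg.n_number:
            break
        rc = (int(rows[k]) + rlo, int(cols[k]) + clo)
        if rc == (r0, c0):
            continue
        if dist[k] > limit:
            break
        members.append(rc)
        dists.append(float(dist[k]))
    stack = np.stack([index.patches[r, c] for r, c in members], axis=-1)
    return Group((r0, c0), members, stack, np.asarray(dists))


def anchor_positions(extent: int, n_block: int, step: int) -> np.ndarray:
    """Reference anchors along one axis: 0, step, 2*step, ... plus a final
    anchor clamped so the last patch touches the border (full coverage)."""
    last = extent - n_block
    pos = list(range(0, last + 1, step))
    if pos[-1] != last:
        pos.append(last)
    return np.asarray(pos, dtype=int)


def iterate_references(img: "np.ndarray | BlockIndex", cfg: "MatchConfig | None" = None):
    """Yield one Group per reference anchor, scanning row-major."""
    index = img if isinstance(img, BlockIndex) else BlockIndex(img, cfg)
    cfg = index.cfg
    rows = anchor_positions(index.shape[0], cfg.n_block, cfg.step)
    cols = anchor_positions(index.shape[1], cfg.n_block, cfg.step)
    for r in rows:
        for c in cols:
            yield find_similar(index, (int(r), int(c)))
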