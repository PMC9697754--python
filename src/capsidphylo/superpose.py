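"""Rigid-body superposition and structure-based residue correspondence.

``kabsch_superpose`` is the least-squares rigid fit (SVD with reflection
suppression).  ``pair_align`` derives a residue correspondence between two
C-alpha traces by the usual iterative scheme: seed from sequence alignment
and gapless threading, superpose on the current pairs, re-align by dynamic
programming on a TM-style distance score S(i,j) = 1/(1 + (d_ij/d0)^2), and
repeat to a fixed point.  ``core_rmsd`` then reports the overall RMSD over
a deviation-trimmed core, which is how the "1.5 A over 164 C-alpha"-style
numbers of capsid-protein comparisons are produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from Bio.Align import substitution_matrices

from ._dp import gotoh_align
from .structio import CaStructure

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class AlignmentFailure(RuntimeError):
    """No usable residue correspondence could be established."""


class DegenerateCoreError(RuntimeError):
    """Core trimming collapsed the pair set below the minimum size."""


@dataclass(frozen=True)
class AlignParams:
    """Parameters of the iterative structural aligner.

    ``d0`` is the distance scale (A) of the TM-style score; ``gap_open``
    and ``gap_extend`` are penalties (<= 0) on that score scale;
    ``core_cutoff`` (A) is the deviation threshold of the trimmed core.
    """

    d0: float = 5.0
    gap_open: float = -1.0
    gap_extend: float = -0.1
    max_iter: int = 20
    tol: float = 1e-8
    core_cutoff: float = 4.0

    def __post_init__(self):
        if self.d0 <= 0:
            raise ValueError("d0 must be > 0")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.core_cutoff <= 0:
            raise ValueError("core_cutoff must be > 0")


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid fit of structure B onto structure A.

    ``transform`` maps B coordinates into A's frame:
    ``x_b @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class Correspondence:
    """Monotone, crossing-free residue-index pairing between two traces."""

    pairs: tuple[tuple[int, int], ...]
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self):
        ia = [p[0] for p in self.pairs]
        ib = [p[1] for p in self.pairs]
        if sorted(set(ia)) != ia or sorted(set(ib)) != ib:
            raise ValueError("correspondence indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def idx_a(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def idx_b(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares optimal rigid fit of ``coords_b`` onto ``coords_a``.

    Standard Kabsch/SVD solution; a reflection in the raw solution is
    suppressed by flipping the sign of the smallest singular vector, so
    chirality is preserved.  Requires >= 3 paired points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (b - cb).T @ (a - ca)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = (b @ R.T + t) - a
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return Superposition(R, t, rmsd, n)


def trim_nterm_arm(s: CaStructure, boundary: int) -> CaStructure:
    """Drop residues with seq_id below ``boundary`` (the N-terminal arm)."""
    kept = [r for r in s.residues if r.seq_id >= boundary]
    if not kept:
        raise ValueError(
            f"{s.label}: trimming at {boundary} removes every residue "
            f"(range {s.residues[0].seq_id}-{s.residues[-1].seq_id})"
        )
    return CaStructure(s.label, kept)


def _tm_score_matrix(coords_a: np.ndarray, coords_b_fit: np.ndarray, d0: float) -> np.ndarray:
    d = cdist(coords_a, coords_b_fit)
    return 1.0 / (1.0 + (d / d0) ** 2)


def _pairs_score(coords_a, coords_b, pairs, d0) -> float:
    sup = kabsch_superpose(coords_a[pairs[:, 0]], coords_b[pairs[:, 1]])
    d = np.linalg.norm(sup.transform(coords_b[pairs[:, 1]]) - coords_a[pairs[:, 0]], axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)))


def _sequence_seed(a: CaStructure, b: CaStructure) -> np.ndarray | None:
    """Global NW alignment of the amino-acid strings under BLOSUM62."""
    sa, sb = a.sequence, b.sequence
    alpha = _BLOSUM62.alphabet
    ia = np.array([alpha.index(c) if c in alpha else alpha.index("X") for c in sa])
    ib = np.array([alpha.index(c) if c in alpha else alpha.index("X") for c in sb])
    S = np.asarray(_BLOSUM62)[np.ix_(ia, ib)]
    _, pairs = gotoh_align(S, gap_open=-10.0, gap_extend=-0.5)
    return pairs if len(pairs) >= 3 else None


def _threading_seed(a: CaStructure, b: CaStructure, d0: float, min_overlap: int = 10) -> np.ndarray | None:
    """Best gapless offset seed: superpose on every >=min_overlap overlap."""
    ca, cb = a.coords, b.coords
    na, nb = len(ca), len(cb)
    best, best_pairs = -np.inf, None
    for off in range(-(nb - min_overlap), na - min_overlap + 1):
        lo_a = max(0, off)
        hi_a = min(na, nb + off)
        if hi_a - lo_a < min_overlap:
            continue
        ia = np.arange(lo_a, hi_a)
        ib = ia - off
        pairs = np.stack([ia, ib], axis=1)
        score = _pairs_score(ca, cb, pairs, d0)
        if score > best:
            best, best_pairs = score, pairs
    return best_pairs


def pair_align(
    a: CaStructure, b: CaStructure, params: AlignParams | None = None
) -> tuple[Correspondence, Superposition]:
    """Iterative structure-based residue correspondence between two traces.

    Seeds from (1) a global sequence alignment and (2) the best gapless
    threading offset; from each seed, alternates rigid superposition with
    affine-gap DP on the TM-style score matrix until the pair set is
    unchanged (or ``max_iter``); returns the best-scoring result.

    Raises :class:`AlignmentFailure` if no correspondence of >= 5 pairs
    can be established.
    """
    params = params or AlignParams()
    if len(a) < 10 or len(b) < 10:
        raise ValueError("pair_align requires structures of >= 10 residues")
    ca, cb = a.coords, b.coords

    seeds = []
    sp = _sequence_seed(a, b)
    if sp is not None:
        seeds.append(sp)
    tp = _threading_seed(a, b, params.d0)
    if tp is not None:
        seeds.append(tp)
    if not seeds:
        raise AlignmentFailure(f"{a.label} vs {b.label}: no usable seed alignment")

    best_score, best_pairs = -np.inf, None
    for seed in seeds:
        pairs = seed
        seen: set[bytes] = set()
        for _ in range(params.max_iter):
            if len(pairs) < 3:
                break
            sup = kabsch_superpose(ca[pairs[:, 0]], cb[pairs[:, 1]])
            S = _tm_score_matrix(ca, sup.transform(cb), params.d0)
            _, new_pairs = gotoh_align(S, params.gap_open, params.gap_extend)
            key = new_pairs.tobytes()
            if np.array_equal(new_pairs, pairs) or key in seen:
                pairs = new_pairs
                break
            seen.add(key)
            pairs = new_pairs
        if len(pairs) >= 3:
            score = _pairs_score(ca, cb, pairs, params.d0)
            if score > best_score:
                best_score, best_pairs = score, pairs
    if best_pairs is None or len(best_pairs) < 5:
        raise AlignmentFailure(
            f"{a.label} vs {b.label}: fewer than 5 aligned pairs"
        )
    corr = Correspondence(tuple(map(tuple, best_pairs.tolist())), a.label, b.label)
    sup = kabsch_superpose(ca[best_pairs[:, 0]], cb[best_pairs[:, 1]])
    return corr, sup


def core_rmsd(
    a: CaStructure,
    b: CaStructure,
    corr: Correspondence,
    core_cutoff: float = 4.0,
) -> tuple[float, int, Superposition]:
    """Overall RMSD over a deviation-trimmed core.

    Iteratively superposes on the current core and drops pairs deviating
    by more than ``core_cutoff`` A until a fixed point; returns
    ``(rmsd, n_core, superposition)``.  ``core_cutoff=inf`` reduces to a
    plain all-pair fit.
    """
    if len(corr) == 0:
        raise ValueError("empty correspondence")
    ca, cb = a.coords, b.coords
    ia, ib = corr.idx_a, corr.idx_b
    keep = np.ones(len(corr), dtype=bool)
    while True:
        if keep.sum() < 5:
            raise DegenerateCoreError(
                f"core collapsed to {int(keep.sum())} pairs (cutoff {core_cutoff} A)"
            )
        sup = kabsch_superpose(ca[ia[keep]], cb[ib[keep]])
        dev = np.linalg.norm(sup.transform(cb[ib]) - ca[ia], axis=1)
        new_keep = keep & (dev <= core_cutoff)
        if np.array_equal(new_keep, keep):
            return sup.rmsd, int(keep.sum()), sup
        keep = new_keep
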