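"""Pairwise local alignment used for the all-vs-all similarity matrix.

The production scorer wraps Bio.Align.PairwiseAligner (exact affine-gap
Smith-Waterman in C).  A deliberately naive quadratic-space implementation
is kept here as an independent reference; the test suite cross-checks the
two on every fixture.  Gap of length g costs open + (g - 1) * extend.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


@lru_cache(maxsize=8)
def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = load_matrix(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def sw_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Raw Smith-Waterman score of the best local alignment."""
    if not a or not b:
        return 0.0
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    return float(aligner.score(a, b))


def sw_score_naive(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Reference quadratic-space affine-gap Smith-Waterman (Gotoh)."""
    if not a or not b:
        return 0.0
    S = load_matrix(matrix_name)
    la, lb = len(a), len(b)
    H = np.zeros((la + 1, lb + 1))
    E = np.full((la + 1, lb + 1), -np.inf)  # gap in a (consume b)
    F = np.full((la + 1, lb + 1), -np.inf)  # gap in b (consume a)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return float(best)


def fractional_identity(row_a: str, row_b: str) -> float:
    """Identity over columns where both rows carry a residue."""
    both = [(x, y) for x, y in zip(row_a.upper(), row_b.upper()) if x != "-" and y != "-"]
    if not both:
        return 0.0
    return sum(x == y for x, y in both) / len(both)
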