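"""Built-in progressive multiple aligner.

Guide tree: UPGMA on pairwise Smith-Waterman distances.  Merge step:
profile-profile Needleman-Wunsch with sum-of-pairs BLOSUM62 scoring and a
linear gap penalty.  This stands in for an external aligner; callers may
also supply a ready-made alignment file instead.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster import hierarchy

from pestiscan.align import load_matrix, sw_score
from pestiscan.alphabet import AMBIGUITY_MAP, AMINO_ACIDS, GAP
from pestiscan.hmm_core import Msa

_SYMBOLS = AMINO_ACIDS + GAP  # 21 columns; gap is last
_SYM_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}
GAP_VS_RESIDUE = -4.0
GAP_VS_GAP = 0.0


def _pair_score_table() -> np.ndarray:
    S = load_matrix("BLOSUM62")
    n = len(_SYMBOLS)
    tab = np.zeros((n, n))
    for i, x in enumerate(_SYMBOLS):
        for j, y in enumerate(_SYMBOLS):
            if x == GAP and y == GAP:
                tab[i, j] = GAP_VS_GAP
            elif x == GAP or y == GAP:
                tab[i, j] = GAP_VS_RESIDUE
            else:
                tab[i, j] = S[x, y]
    return tab


_PAIR_TABLE = _pair_score_table()


def _column_counts(rows: list[str]) -> np.ndarray:
    """(n_cols, 21) symbol counts per column."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, len(_SYMBOLS)))
    for row in rows:
        for j, ch in enumerate(row):
            ch = AMBIGUITY_MAP.get(ch.upper(), ch.upper())
            if ch == "X":  # spread X uniformly over residues
                counts[j, :20] += 1.0 / 20.0
            else:
                counts[j, _SYM_INDEX[ch]] += 1
    return counts


def _merge(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment; returns gap-padded row groups."""
    ca = _column_counts(rows_a)
    cb = _column_counts(rows_b)
    la, lb = ca.shape[0], cb.shape[0]
    # sum-of-pairs column score, fully vectorized
    score = ca @ _PAIR_TABLE @ cb.T
    na, nb = len(rows_a), len(rows_b)
    gap_a = GAP_VS_RESIDUE * na * nb / max(na, nb)  # per-column gap penalty
    gap_b = gap_a

    H = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up(gap in b), 2 left(gap in a)
    H[1:, 0] = np.arange(1, la + 1) * gap_b
    H[0, 1:] = np.arange(1, lb + 1) * gap_a
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        diag = H[i - 1, :-1] + score[i - 1]
        up = H[i - 1, 1:] + gap_b
        row = H[i]
        prow = ptr[i]
        for j in range(1, lb + 1):
            d, u, l = diag[j - 1], up[j - 1], row[j - 1] + gap_a
            if d >= u and d >= l:
                row[j], prow[j] = d, 0
            elif u >= l:
                row[j], prow[j] = u, 1
            else:
                row[j], prow[j] = l, 2
    # traceback
    i, j = la, lb
    cols_a: list[int] = []  # source column of a per output column, -1 for gap
    cols_b: list[int] = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            i, j = i - 1, j - 1
        elif p == 1:
            cols_a.append(i - 1)
            cols_b.append(-1)
            i -= 1
        else:
            cols_a.append(-1)
            cols_b.append(j - 1)
            j -= 1
    cols_a.reverse()
    cols_b.reverse()

    def expand(rows: list[str], cols: list[int]) -> list[str]:
        return ["".join(row[c] if c >= 0 else GAP for c in cols) for row in rows]

    return expand(rows_a, cols_a), expand(rows_b, cols_b)


def progressive_align(records: list[tuple[str, str]]) -> Msa:
    """Align (name, sequence) pairs progressively along a UPGMA guide tree."""
    if not records:
        raise ValueError("need at least one sequence to align")
    if len(records) == 1:
        return Msa(names=[records[0][0]], rows=[records[0][1].upper()])

    names = [name for name, _ in records]
    seqs = [seq.upper() for _, seq in records]
    n = len(seqs)

    self_scores = [sw_score(s, s) for s in seqs]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = sw_score(seqs[i], seqs[j])
            denom = min(self_scores[i], self_scores[j])
            d = 1.0 - (s / denom if denom > 0 else 0.0)
            dist[i, j] = dist[j, i] = max(d, 0.0)
    condensed = dist[np.triu_indices(n, k=1)]
    link = hierarchy.linkage(condensed, method="average")

    # each cluster id -> (member indices, aligned rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }
    for step, (a, b, _d, _cnt) in enumerate(link):
        ia, ib = int(a), int(b)
        mem_a, rows_a = clusters.pop(ia)
        mem_b, rows_b = clusters.pop(ib)
        new_a, new_b = _merge(rows_a, rows_b)
        clusters[n + step] = (mem_a + mem_b, new_a + new_b)

    members, rows = clusters.popitem()[1]
    order = np.argsort(members)
    return Msa(
        names=[names[members[i]] for i in order],
        rows=[rows[i] for i in order],
    )
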