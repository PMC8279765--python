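"""Independent oracles used by the test suite.

These deliberately re-derive quantities by brute force / naive algorithms,
sharing no code path with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np

from pestiscan.alphabet import AMINO_ACIDS

T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)


def enumerate_path_weights(hmm, seq: str) -> list[float]:
    """Every legal local path's odds weight P(path, subseq)/P(subseq|bg).

    Paths enter at any match state (probability 1/n_match), consume a
    contiguous subsequence starting at any offset, move through M/I/D states
    using the node transition probabilities, and exit free from any match
    state.  Exponential enumeration; only for tiny models/sequences.
    """
    n = hmm.n_match
    L = len(seq)
    idx = [AMINO_ACIDS.index(c) for c in seq]
    me, ie, tr, bg = hmm.match_emissions, hmm.insert_emissions, hmm.transitions, hmm.background
    weights: list[float] = []

    def emit(table, k, pos):
        return table[k][idx[pos]] / bg[idx[pos]]

    def walk(state: str, k: int, pos: int, w: float) -> None:
        # state at node k (0-based), having just consumed up to pos (exclusive)
        if state == "M":
            weights.append(w)  # free exit from any match state
            if k + 1 < n:
                if pos < L:
                    walk("M", k + 1, pos + 1, w * tr[k][T_MM] * emit(me, k + 1, pos))
                    walk("I", k, pos + 1, w * tr[k][T_MI] * emit(ie, k, pos))
                walk("D", k + 1, pos, w * tr[k][T_MD])
        elif state == "I":
            if pos < L:
                walk("M", k + 1, pos + 1, w * tr[k][T_IM] * emit(me, k + 1, pos))
                walk("I", k, pos + 1, w * tr[k][T_II] * emit(ie, k, pos))
        else:  # D
            if k + 1 < n:
                if pos < L:
                    walk("M", k + 1, pos + 1, w * tr[k][T_DM] * emit(me, k + 1, pos))
                walk("D", k + 1, pos, w * tr[k][T_DD])

    for start in range(L):
        for k0 in range(n):
            walk("M", k0, start + 1, (1.0 / n) * emit(me, k0, start))
    return weights


def brute_viterbi_bits(hmm, seq: str) -> float:
    weights = enumerate_path_weights(hmm, seq)
    return math.log2(max(weights)) if weights else -math.inf


def brute_forward_bits(hmm, seq: str) -> float:
    weights = enumerate_path_weights(hmm, seq)
    return math.log2(sum(weights)) if weights else -math.inf


def random_profile(rng: np.random.Generator, n_match: int):
    """A random, fully normalized profile for oracle cross-checks."""
    from pestiscan.hmm_core import ProfileHMM

    bg = rng.dirichlet(np.ones(20) * 5)
    me = rng.dirichlet(np.ones(20), size=n_match)
    ie = rng.dirichlet(np.ones(20), size=n_match)
    tr = np.zeros((n_match, 7))
    tr[:, :3] = rng.dirichlet(np.ones(3), size=n_match)
    tr[:, 3:5] = rng.dirichlet(np.ones(2), size=n_match)
    tr[:, 5:7] = rng.dirichlet(np.ones(2), size=n_match)
    tr[-1] = (1, 0, 0, 1, 0, 1, 0)
    return ProfileHMM(
        name="rand", group_label="", n_match=n_match,
        match_emissions=me, insert_emissions=ie, transitions=tr, background=bg,
    )


def naive_global_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length ungapped segments."""
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a.upper(), b.upper())) / len(a)
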