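"""Profile HMM construction and Viterbi/forward scoring.

A profile is built from a multiple alignment: columns whose gap fraction is
below a threshold become match states, the remainder generate insert states.
Scoring is local (uniform entry over match states, free exit from any match
state) and reported in bits (log2-odds against a background model).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from pestiscan.alphabet import (
    AMINO_ACIDS,
    GAP,
    SequenceAlphabetError,
    X_INDEX,
    encode_sequence,
    swissprot_background,
)

NEG_INF = -np.inf

# transition row layout per node
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)
TRANS_NAMES = ("MM", "MI", "MD", "IM", "II", "DM", "DD")


class NoConsensusColumnsError(ValueError):
    """No alignment column qualifies as a match column under the threshold."""


class MsaError(ValueError):
    pass


@dataclass
class Msa:
    """A multiple sequence alignment over the amino-acid alphabet plus '-'."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise MsaError("alignment needs at least one row")
        if len(self.names) != len(self.rows):
            raise MsaError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            raise MsaError("duplicate sequence identifiers in alignment")
        width = len(self.rows[0])
        if width < 1:
            raise MsaError("alignment width must be >= 1")
        for name, row in zip(self.names, self.rows):
            if len(row) != width:
                raise MsaError(f"row {name!r} has length {len(row)} != {width}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass
class ProfileConfig:
    """Settings controlling profile construction."""

    gap_threshold: float = 0.5          # column is match when gap fraction < this
    alpha: float = 1.0                  # emission pseudocount weight
    trans_alpha: float = 0.1            # transition pseudocount
    background: np.ndarray | None = None
    henikoff_weights: bool = True

    def resolved_background(self) -> np.ndarray:
        if self.background is None:
            return swissprot_background()
        bg = np.asarray(self.background, dtype=float)
        return bg / bg.sum()


@dataclass
class ProfileHMM:
    """Plan7-style profile with per-node match/insert/delete states.

    ``transitions[k]`` holds the seven move probabilities out of node ``k+1``
    (1-based nodes): M->M, M->I, M->D, I->M, I->I, D->M, D->D.  The final
    node's match state always transitions to the end.
    """

    name: str
    group_label: str
    n_match: int
    match_emissions: np.ndarray    # (n_match, 20)
    insert_emissions: np.ndarray   # (n_match, 20); last row unused in scoring
    transitions: np.ndarray        # (n_match, 7)
    background: np.ndarray         # (20,)
    gathering_cutoff: float | None = None
    source_size: int = 0
    score_basis: str = "forward_full_sequence"

    def __post_init__(self) -> None:
        if self.n_match < 1:
            raise ValueError("n_match must be >= 1")
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.gathering_cutoff is not None and not np.isfinite(self.gathering_cutoff):
            raise ValueError("gathering_cutoff must be finite when present")
        self.validate_normalization()

    def validate_normalization(self, tol: float = 1e-9) -> None:
        for label, arr in (("match", self.match_emissions), ("insert", self.insert_emissions)):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=tol):
                raise ValueError(f"{label} emissions do not sum to 1")
        t = self.transitions
        for k in range(self.n_match):
            if not np.isclose(t[k, T_MM] + t[k, T_MI] + t[k, T_MD], 1.0, atol=tol):
                raise ValueError(f"node {k + 1} M transitions do not sum to 1")
            if not np.isclose(t[k, T_IM] + t[k, T_II], 1.0, atol=tol):
                raise ValueError(f"node {k + 1} I transitions do not sum to 1")
            if not np.isclose(t[k, T_DM] + t[k, T_DD], 1.0, atol=tol):
                raise ValueError(f"node {k + 1} D transitions do not sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=tol):
            raise ValueError("background does not sum to 1")

    def consensus(self) -> str:
        """Most probable residue per match state."""
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.match_emissions, axis=1))

    def with_cutoff(self, cutoff: float) -> "ProfileHMM":
        return dataclasses.replace(self, gathering_cutoff=float(cutoff))


@dataclass
class ScoreResult:
    model_name: str
    query_name: str
    viterbi_bits: float
    forward_bits: float
    alignment: list[tuple[int | None, tuple[str, int]]] = field(default_factory=list)
    query_span: tuple[int, int] = (0, 0)


# ---------------------------------------------------------------------------
# construction


def henikoff_weights(msa: Msa) -> np.ndarray:
    """Position-based sequence weights, normalized to sum to n_rows."""
    n = msa.n_rows
    w = np.zeros(n)
    for j in range(msa.n_cols):
        col = msa.column(j)
        residues = [c for c in col if c != GAP]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for i, c in enumerate(col):
            if c != GAP:
                w[i] += 1.0 / (r * counts[c])
    if w.sum() == 0:
        return np.ones(n)
    return w * (n / w.sum())


def _residue_index(ch: str, name: str, col: int) -> int:
    from pestiscan.alphabet import AMBIGUITY_MAP, AA_INDEX

    ch = AMBIGUITY_MAP.get(ch.upper(), ch.upper())
    if ch == "X":
        return X_INDEX
    if ch in AA_INDEX:
        return AA_INDEX[ch]
    raise SequenceAlphabetError(
        f"invalid residue {ch!r} in row {name!r}, column {col + 1}"
    )


def build_profile(
    msa: Msa,
    config: ProfileConfig | None = None,
    name: str = "model",
    group_label: str = "",
) -> ProfileHMM:
    """Estimate a profile HMM from a multiple alignment.

    Match columns are those with gap fraction below ``config.gap_threshold``.
    Emissions are Henikoff-weighted counts plus Laplace-style pseudocounts
    scaled by the background (uniform background reproduces classic +alpha
    Laplace smoothing); transitions come from the observed state paths of the
    rows plus a small pseudocount.
    """
    cfg = config or ProfileConfig()
    bg = cfg.resolved_background()
    n_aa = len(AMINO_ACIDS)
    n_rows, n_cols = msa.n_rows, msa.n_cols

    gap_frac = np.array(
        [msa.column(j).count(GAP) / n_rows for j in range(n_cols)]
    )
    is_match = gap_frac < cfg.gap_threshold
    match_cols = np.flatnonzero(is_match)
    n_match = len(match_cols)
    if n_match == 0:
        raise NoConsensusColumnsError(
            f"no consensus columns: every column has gap fraction >= {cfg.gap_threshold}"
        )

    weights = henikoff_weights(msa) if cfg.henikoff_weights else np.ones(n_rows)

    # residue indices per cell (-2 gap, -1 X)
    enc = np.full((n_rows, n_cols), -2, dtype=np.int64)
    for i, (rname, row) in enumerate(zip(msa.names, msa.rows)):
        for j, ch in enumerate(row):
            if ch == GAP:
                continue
            enc[i, j] = _residue_index(ch, rname, j)

    # emission pseudocount vector: alpha per residue under uniform background
    pseudo = cfg.alpha * n_aa * bg

    match_counts = np.zeros((n_match, n_aa))
    insert_counts = np.zeros((n_match, n_aa))
    # transition counts per node: rows M(3), I(2), D(2)
    m_counts = np.zeros((n_match, 3))   # MM MI MD
    i_counts = np.zeros((n_match, 2))   # IM II
    d_counts = np.zeros((n_match, 2))   # DM DD

    col_to_node = np.cumsum(is_match)  # node index (1-based) active at/after column

    for i in range(n_rows):
        w = weights[i]
        # state path over nodes; leading/trailing inserts outside node span ignored
        path: list[tuple[str, int]] = []
        for j in range(n_cols):
            node = int(col_to_node[j])
            if is_match[j]:
                if enc[i, j] == -2:
                    path.append(("D", node))
                else:
                    path.append(("M", node))
                    if enc[i, j] >= 0:
                        match_counts[node - 1, enc[i, j]] += w
            else:
                if enc[i, j] != -2 and 1 <= node < n_match:
                    path.append(("I", node))
                    if enc[i, j] >= 0:
                        insert_counts[node - 1, enc[i, j]] += w
        for (s1, k1), (s2, _k2) in zip(path, path[1:]):
            idx = k1 - 1
            if s1 == "M":
                m_counts[idx, {"M": 0, "I": 1, "D": 2}[s2]] += w
            elif s1 == "I" and s2 != "D":  # I->D has no Plan7 transition
                i_counts[idx, {"M": 0, "I": 1}[s2]] += w
            elif s1 == "D" and s2 != "I":  # D->I likewise dropped
                d_counts[idx, {"M": 0, "D": 1}[s2]] += w

    # cap the pseudo-mass so no unseen residue can outweigh an observed one
    # (relevant for single-sequence models); classic Laplace behaviour is
    # retained whenever observed weight dominates
    def smoothed(counts: np.ndarray) -> np.ndarray:
        totals = counts.sum(axis=1, keepdims=True)
        scale = np.minimum(1.0, 0.5 * totals / pseudo.max())
        scale[totals.ravel() == 0] = 1.0
        out = counts + scale * pseudo
        return out / out.sum(axis=1, keepdims=True)

    match_emissions = smoothed(match_counts)
    insert_emissions = smoothed(insert_counts)

    ta = cfg.trans_alpha
    transitions = np.zeros((n_match, 7))
    m_dist = m_counts + ta
    m_dist /= m_dist.sum(axis=1, keepdims=True)
    i_dist = i_counts + ta
    i_dist /= i_dist.sum(axis=1, keepdims=True)
    d_dist = d_counts + ta
    d_dist /= d_dist.sum(axis=1, keepdims=True)
    transitions[:, T_MM:T_MD + 1] = m_dist
    transitions[:, T_IM:T_II + 1] = i_dist
    transitions[:, T_DM:T_DD + 1] = d_dist
    # final node: match always proceeds to end
    transitions[-1] = (1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0)

    return ProfileHMM(
        name=name,
        group_label=group_label,
        n_match=n_match,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=bg,
        source_size=n_rows,
    )


# ---------------------------------------------------------------------------
# scoring


def _log_odds_tables(hmm: ProfileHMM):
    with np.errstate(divide="ignore"):
        lo_m = np.log2(hmm.match_emissions) - np.log2(hmm.background)[None, :]
        lo_i = np.log2(hmm.insert_emissions) - np.log2(hmm.background)[None, :]
        lt = np.log2(hmm.transitions)
    return lo_m, lo_i, lt


def _emission_column(lo: np.ndarray, residue: int) -> np.ndarray:
    if residue == X_INDEX:
        return np.zeros(lo.shape[0])
    return lo[:, residue]


def _dp_matrices(hmm: ProfileHMM, encoded: np.ndarray, mode: str):
    """Fill local-alignment DP matrices in log2 space.

    mode 'max' gives Viterbi, 'sum' gives forward.  Entry into any match
    state costs log2(1/n_match); exit from any match state is free.
    """
    n = hmm.n_match
    L = len(encoded)
    lo_m, lo_i, lt = _log_odds_tables(hmm)
    entry = -np.log2(n)

    combine = np.maximum if mode == "max" else np.logaddexp2

    M = np.full((L, n), NEG_INF)
    I = np.full((L, n), NEG_INF)
    D = np.full((L, n), NEG_INF)

    t_mm, t_mi, t_md = lt[:, T_MM], lt[:, T_MI], lt[:, T_MD]
    t_im, t_ii = lt[:, T_IM], lt[:, T_II]
    t_dm, t_dd = lt[:, T_DM], lt[:, T_DD]

    for i in range(L):
        em = _emission_column(lo_m, encoded[i])
        ei = _emission_column(lo_i, encoded[i])
        best = np.full(n, entry)
        if i > 0:
            prev_m = np.concatenate(([NEG_INF], M[i - 1, :-1] + t_mm[:-1]))
            prev_i = np.concatenate(([NEG_INF], I[i - 1, :-1] + t_im[:-1]))
            prev_d = np.concatenate(([NEG_INF], D[i - 1, :-1] + t_dm[:-1]))
            best = combine(combine(best, prev_m), combine(prev_i, prev_d))
        M[i] = em + best
        if i > 0:
            I[i] = ei + combine(M[i - 1] + t_mi, I[i - 1] + t_ii)
        else:
            I[i] = NEG_INF
        # delete run along k within this row: D[k] reached from node k-1
        if n > 1:
            S = np.concatenate(([0.0], np.cumsum(t_dd[1:n - 1])))  # S[k-1] prefix for node k
            a = M[i, :-1] + t_md[:-1] - S  # term entering D at node j+2... aligned below
            acc = combine.accumulate(a)
            D[i, 1:] = acc + S
        else:
            D[i, :] = NEG_INF
    return M, I, D


def _final_score(M: np.ndarray, mode: str) -> float:
    if mode == "max":
        return float(np.max(M)) if M.size else NEG_INF
    flat = M[np.isfinite(M)]
    if flat.size == 0:
        return NEG_INF
    m = flat.max()
    return float(m + np.log2(np.sum(np.exp2(flat - m))))


def _traceback(hmm: ProfileHMM, encoded: np.ndarray, M, I, D):
    """Recover the Viterbi path from filled matrices."""
    n = hmm.n_match
    lo_m, lo_i, lt = _log_odds_tables(hmm)
    entry = -np.log2(n)
    end_i, end_k = np.unravel_index(np.argmax(M), M.shape)
    path: list[tuple[int | None, tuple[str, int]]] = []
    state, i, k = "M", int(end_i), int(end_k)
    tol = 1e-9

    def close(a, b):
        return np.isfinite(a) and np.isfinite(b) and abs(a - b) <= tol * max(1, abs(b))

    while True:
        if state == "M":
            path.append((i, ("M", k + 1)))
            em = _emission_column(lo_m, encoded[i])[k]
            rest = M[i, k] - em
            if close(rest, entry) and not (
                i > 0 and k > 0 and (
                    close(rest, M[i - 1, k - 1] + lt[k - 1, T_MM])
                    or close(rest, I[i - 1, k - 1] + lt[k - 1, T_IM])
                    or close(rest, D[i - 1, k - 1] + lt[k - 1, T_DM])
                )
            ):
                break
            if i == 0 or k == 0:
                break
            if close(rest, M[i - 1, k - 1] + lt[k - 1, T_MM]):
                state, i, k = "M", i - 1, k - 1
            elif close(rest, I[i - 1, k - 1] + lt[k - 1, T_IM]):
                state, i, k = "I", i - 1, k - 1
            elif close(rest, D[i - 1, k - 1] + lt[k - 1, T_DM]):
                state, i, k = "D", i - 1, k - 1
            else:
                break
        elif state == "I":
            path.append((i, ("I", k + 1)))
            ei = _emission_column(lo_i, encoded[i])[k]
            rest = I[i, k] - ei
            if i == 0:
                break
            if close(rest, M[i - 1, k] + lt[k, T_MI]):
                state, i = "M", i - 1
            else:
                state, i = "I", i - 1
        else:  # D
            path.append((None, ("D", k + 1)))
            if k == 0:
                break
            if close(D[i, k], M[i, k - 1] + lt[k - 1, T_MD]):
                state, k = "M", k - 1
            else:
                k = k - 1
    path.reverse()
    qpos = [p for p, _ in path if p is not None]
    span = (min(qpos), max(qpos) + 1) if qpos else (0, 0)
    return path, span


def _score(hmm: ProfileHMM, seq: str, query_name: str, with_alignment: bool) -> ScoreResult:
    if len(seq) == 0:
        raise ValueError("empty sequence")
    encoded = encode_sequence(seq, context=f"query {query_name!r}")
    if len(encoded) == 0:
        raise ValueError("sequence has no residues before terminator")
    M, I, D = _dp_matrices(hmm, encoded, "max")
    vit = _final_score(M, "max")
    Mf, _, _ = _dp_matrices(hmm, encoded, "sum")
    fwd = _final_score(Mf, "sum")
    alignment: list = []
    span = (0, 0)
    if with_alignment and np.isfinite(vit):
        alignment, span = _traceback(hmm, encoded, M, I, D)
    return ScoreResult(
        model_name=hmm.name,
        query_name=query_name,
        viterbi_bits=vit,
        forward_bits=fwd,
        alignment=alignment,
        query_span=span,
    )


def viterbi_score(hmm: ProfileHMM, seq: str, query_name: str = "query") -> ScoreResult:
    """Best-path local log2-odds score with alignment traceback."""
    return _score(hmm, seq, query_name, with_alignment=True)


def forward_score(hmm: ProfileHMM, seq: str, query_name: str = "query") -> ScoreResult:
    """All-paths local log2-odds score (and Viterbi, without traceback)."""
    return _score(hmm, seq, query_name, with_alignment=False)


# ---------------------------------------------------------------------------
# profile alignment


class UnalignableSequenceWarning(UserWarning):
    pass


def align_to_profile(
    hmm: ProfileHMM,
    seqs: list[tuple[str, str]],
    score_floor: float = NEG_INF,
) -> Msa:
    """Align sequences independently to the model via their Viterbi paths.

    Match states define the columns; inserted residues are rendered as
    lower-case letters in gap-padded extra columns.  Sequences whose Viterbi
    score falls below ``score_floor`` (or that align no column at all) are
    excluded with a warning.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    n = hmm.n_match
    kept_names: list[str] = []
    per_seq: list[tuple[dict[int, str], dict[int, str]]] = []
    max_ins = [0] * (n + 1)

    for name, seq in seqs:
        res = viterbi_score(hmm, seq, query_name=name)
        match_res: dict[int, str] = {}
        ins_res: dict[int, str] = {}
        clean = seq.upper().split("*")[0]
        for qi, (state, node) in res.alignment:
            if state == "M" and qi is not None:
                match_res[node] = clean[qi]
            elif state == "I" and qi is not None:
                ins_res[node] = ins_res.get(node, "") + clean[qi].lower()
        if res.viterbi_bits < score_floor or not match_res:
            warnings.warn(
                f"sequence {name!r} is unalignable (score {res.viterbi_bits:.2f}); excluded",
                UnalignableSequenceWarning,
            )
            continue
        kept_names.append(name)
        per_seq.append((match_res, ins_res))
        for node, chars in ins_res.items():
            max_ins[node] = max(max_ins[node], len(chars))

    if not kept_names:
        raise ValueError("no sequence could be aligned to the profile")

    rows = []
    for match_res, ins_res in per_seq:
        chunks = []
        for node in range(1, n + 1):
            chunks.append(match_res.get(node, GAP))
            if max_ins[node]:
                ins = ins_res.get(node, "")
                chunks.append(ins.ljust(max_ins[node], GAP))
        rows.append("".join(chunks))
    return Msa(names=kept_names, rows=rows)


# ---------------------------------------------------------------------------
# serialization: native round-trip format + HMMER3 ASCII export/import


def write_model(hmm: ProfileHMM, path) -> None:
    """Write the native plain-text profile format (round-trips bit-exactly)."""
    lines = ["PESTISCAN-HMM 1"]
    lines.append(f"NAME {hmm.name}")
    lines.append(f"GROUP {hmm.group_label}")
    lines.append(f"NMATCH {hmm.n_match}")
    cutoff = "NONE" if hmm.gathering_cutoff is None else repr(float(hmm.gathering_cutoff))
    lines.append(f"CUTOFF {cutoff}")
    lines.append(f"SOURCE_SIZE {hmm.source_size}")
    lines.append(f"SCORE_BASIS {hmm.score_basis}")
    lines.append("BACKGROUND " + " ".join(repr(float(x)) for x in hmm.background))
    for k in range(hmm.n_match):
        lines.append(f"MATCH {k + 1} " + " ".join(repr(float(x)) for x in hmm.match_emissions[k]))
        lines.append(f"INSERT {k + 1} " + " ".join(repr(float(x)) for x in hmm.insert_emissions[k]))
        lines.append(f"TRANS {k + 1} " + " ".join(repr(float(x)) for x in hmm.transitions[k]))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_model(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("PESTISCAN-HMM"):
        raise ValueError(f"{path}: not a pestiscan model file")
    meta: dict[str, str] = {}
    match_rows: dict[int, np.ndarray] = {}
    insert_rows: dict[int, np.ndarray] = {}
    trans_rows: dict[int, np.ndarray] = {}
    background = None
    for ln in lines[1:]:
        if ln == "END":
            break
        key, _, rest = ln.partition(" ")
        if key in ("MATCH", "INSERT", "TRANS"):
            idx_s, _, vals = rest.partition(" ")
            arr = np.array([float(x) for x in vals.split()])
            {"MATCH": match_rows, "INSERT": insert_rows, "TRANS": trans_rows}[key][int(idx_s)] = arr
        elif key == "BACKGROUND":
            background = np.array([float(x) for x in rest.split()])
        else:
            meta[key] = rest
    n_match = int(meta["NMATCH"])
    cutoff = None if meta.get("CUTOFF", "NONE") == "NONE" else float(meta["CUTOFF"])
    return ProfileHMM(
        name=meta.get("NAME", "model"),
        group_label=meta.get("GROUP", ""),
        n_match=n_match,
        match_emissions=np.vstack([match_rows[k + 1] for k in range(n_match)]),
        insert_emissions=np.vstack([insert_rows[k + 1] for k in range(n_match)]),
        transitions=np.vstack([trans_rows[k + 1] for k in range(n_match)]),
        background=background,
        gathering_cutoff=cutoff,
        source_size=int(meta.get("SOURCE_SIZE", 0)),
        score_basis=meta.get("SCORE_BASIS", "forward_full_sequence"),
    )


def _neg_ln(p: float) -> str:
    if p <= 0:
        return "*"
    return f"{-np.log(p):.5f}"


def export_hmmer3(hmm: ProfileHMM, path) -> None:
    """Export to HMMER3/f ASCII layout for interoperability."""
    lines = []
    lines.append("HMMER3/f [pestiscan export]")
    lines.append(f"NAME  {hmm.name}")
    lines.append(f"LENG  {hmm.n_match}")
    lines.append("ALPH  amino")
    lines.append(f"NSEQ  {hmm.source_size}")
    if hmm.gathering_cutoff is not None:
        lines.append(f"GA    {hmm.gathering_cutoff:.2f} {hmm.gathering_cutoff:.2f};")
    lines.append("HMM          " + "        ".join(AMINO_ACIDS))
    lines.append("            m->m     m->i     m->d     i->m     i->i     d->m     d->d")
    lines.append("  COMPO   " + " ".join(f"{-np.log(p):.5f}" for p in hmm.background))
    # node 0: insert emissions = background, begin transitions uniform-ish
    lines.append("          " + " ".join(f"{-np.log(p):.5f}" for p in hmm.background))
    lines.append("          0.00000  *  *  0.00000  *  *  *")
    for k in range(hmm.n_match):
        me = " ".join(_neg_ln(p) for p in hmm.match_emissions[k])
        ie = " ".join(_neg_ln(p) for p in hmm.insert_emissions[k])
        tr = " ".join(_neg_ln(p) for p in hmm.transitions[k])
        lines.append(f"{k + 1:7d}   {me} {k + 1} - - -")
        lines.append("          " + ie)
        lines.append("          " + tr)
    lines.append("//")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def import_hmmer3(path) -> ProfileHMM:
    """Best-effort import of a HMMER3 ASCII profile.

    Reads match/insert emissions and the seven core transitions; fields this
    model does not represent (E-value statistics, priors) are ignored, and
    '*' probabilities become 0.
    """
    def parse(tok: str) -> float:
        return 0.0 if tok == "*" else float(np.exp(-float(tok)))

    name, n_match, cutoff = "imported", None, None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and not lines[i].startswith("HMM "):
        ln = lines[i]
        if ln.startswith("NAME"):
            name = ln.split(None, 1)[1].strip()
        elif ln.startswith("LENG"):
            n_match = int(ln.split()[1])
        elif ln.startswith("GA"):
            cutoff = float(ln.split()[1].rstrip(";"))
        i += 1
    if n_match is None:
        raise ValueError(f"{path}: missing LENG header")
    i += 2  # skip HMM header + transition header
    if i < len(lines) and lines[i].lstrip().startswith("COMPO"):
        background = np.array([parse(t) for t in lines[i].split()[1:21]])
        i += 1
    else:
        background = swissprot_background()
    i += 2  # node-0 insert emission + transition lines
    match_e, insert_e, trans = [], [], []
    while i < len(lines) and not lines[i].startswith("//"):
        toks = lines[i].split()
        match_e.append([parse(t) for t in toks[1:21]])
        insert_e.append([parse(t) for t in lines[i + 1].split()[:20]])
        trans.append([parse(t) for t in lines[i + 2].split()[:7]])
        i += 3
    me = np.array(match_e)
    ie = np.array(insert_e)
    tr = np.array(trans)

    def fix(rows: np.ndarray) -> np.ndarray:
        sums = rows.sum(axis=1, keepdims=True)
        bad = (sums <= 0).ravel()
        rows = np.where(sums > 0, rows / np.where(sums > 0, sums, 1.0), rows)
        rows[bad] = background  # mean-emission backfill
        return rows

    me, ie = fix(me), fix(ie)
    for k, (lo, hi) in enumerate(((0, 3), (3, 5), (5, 7))):
        block = tr[:, lo:hi]
        s = block.sum(axis=1, keepdims=True)
        tr[:, lo:hi] = np.where(s > 0, block / np.where(s > 0, s, 1.0), block)
        zero = (s <= 0).ravel()
        if zero.any():
            tr[zero, lo] = 1.0
            tr[zero, lo + 1:hi] = 0.0
    tr[-1] = (1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0)
    bg = background / background.sum()
    return ProfileHMM(
        name=name,
        group_label="",
        n_match=len(me),
        match_emissions=me,
        insert_emissions=ie,
        transitions=tr,
        background=bg,
        gathering_cutoff=cutoff,
    )
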