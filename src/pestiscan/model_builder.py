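"""Family model construction pipeline.

Redundancy removal at 100% identity, all-vs-all similarity graph, native
Markov clustering, per-cluster alignment and profile construction
(including the dedicated C-terminal model for long Cry toxins), gathering
cutoff calibration from score distributions, and the four-criterion model
validation report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import gaussian_kde

from pestiscan.align import sw_score
from pestiscan.hmm_core import Msa, ProfileConfig, ProfileHMM, build_profile, forward_score
from pestiscan.msa import progressive_align

log = logging.getLogger(__name__)

LONG_CRY_THRESHOLD = 1000  # aa; C-terminal models only accept longer sequences
DEFAULT_MIN_CLUSTER_SIZE = 5
DEFAULT_EDGE_FLOOR = 50.0
DEFAULT_INFLATION = 2.0
CUTOFF_EPSILON = 0.5  # bits; degenerate cutoff = min(positive) - epsilon


@dataclass
class SeqRecord:
    id: str
    sequence: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimilarityGraph:
    nodes: list[str]
    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if w < 0:
                raise ValueError(f"negative edge weight {a!r}-{b!r}")


@dataclass
class ClusterSet:
    clusters: list[list[str]]
    singletons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cl in self.clusters:
            for node in cl:
                if node in seen:
                    raise ValueError(f"node {node!r} appears in more than one cluster")
                seen.add(node)

    @property
    def node_count(self) -> int:
        return sum(len(c) for c in self.clusters)


@dataclass
class CalibrationReport:
    model_name: str
    positive_scores: list[float]
    background_scores: list[float]
    proposed_cutoff: float
    criteria_passed: list[bool]
    density_curve: list[tuple[float, float]]
    review_matches: list[str] = field(default_factory=list)
    separable: bool = True

    def __post_init__(self) -> None:
        if len(self.criteria_passed) != 4:
            raise ValueError("criteria_passed must have exactly 4 entries")


# ---------------------------------------------------------------------------
# redundancy removal


def deduplicate(seqs: list[SeqRecord]) -> tuple[ClusterSet, list[SeqRecord]]:
    """Merge exact duplicates and full-length substrings; keep the longest.

    Two sequences share a cluster only at 100% identity: either identical,
    or one a contiguous substring of the other.  The representative is the
    longest member (ties broken lexicographically by id).
    """
    if not seqs:
        raise ValueError("deduplicate requires at least one sequence")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in input")

    ordered = sorted(seqs, key=lambda s: (-len(s.sequence), s.id))
    reps: list[SeqRecord] = []
    members: dict[str, list[str]] = {}
    for rec in ordered:
        home = None
        for rep in reps:
            if rec.sequence in rep.sequence:
                home = rep
                break
        if home is None:
            reps.append(rec)
            members[rec.id] = [rec.id]
        else:
            members[home.id].append(rec.id)

    clusters = [sorted(members[rep.id]) for rep in reps]
    singletons = [cl[0] for cl in clusters if len(cl) == 1]
    return ClusterSet(clusters=clusters, singletons=singletons), reps


# ---------------------------------------------------------------------------
# similarity graph + Markov clustering


def similarity_graph(
    reps: list[SeqRecord],
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    edge_floor: float = DEFAULT_EDGE_FLOOR,
) -> SimilarityGraph:
    """All-vs-all local-alignment scores; pairs under the floor get no edge."""
    if len(reps) < 2:
        raise ValueError("similarity_graph requires at least two representatives")
    nodes = sorted(r.id for r in reps)
    by_id = {r.id: r for r in reps}
    edges: list[tuple[str, str, float]] = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            w = sw_score(
                by_id[a].sequence, by_id[b].sequence,
                matrix_name=matrix_name, gap_open=gap_open, gap_extend=gap_extend,
            )
            if w >= edge_floor:
                edges.append((a, b, w))
    return SimilarityGraph(nodes=nodes, edges=edges)


class MclConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"MCL did not converge after {max_iter} iterations (residual {residual:.3e})"
        )
        self.residual = residual


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = DEFAULT_INFLATION,
    expansion: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    _trace: list | None = None,
) -> ClusterSet:
    """Native Markov clustering of the similarity graph.

    Self-loops are set to each node's maximum incident edge weight (1.0 for
    isolated nodes), columns are normalized, then expansion (matrix power)
    and inflation (elementwise power + renormalization) alternate until the
    matrix stabilizes.  Clusters are the connected components of the limit
    matrix's support.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if not graph.nodes:
        raise ValueError("mcl_cluster requires at least one node")
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for a, b, w in graph.edges:
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M = M / M.sum(axis=0, keepdims=True)

    residual = np.inf
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M ** inflation
        M = M / M.sum(axis=0, keepdims=True)
        M[M < 1e-12] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        M = M / colsum
        if _trace is not None:
            _trace.append(M.copy())
        residual = float(np.abs(M - prev).max())
        if residual < tol:
            break
    else:
        raise MclConvergenceError(residual, max_iter)

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > 1e-8)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(support)]
    comps.sort(key=lambda c: c[0])
    singles = [c[0] for c in comps if len(c) == 1]
    return ClusterSet(clusters=comps, singletons=singles)


# ---------------------------------------------------------------------------
# model construction


def build_models(
    clusters: ClusterSet,
    seqs: list[SeqRecord],
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    config: ProfileConfig | None = None,
    single_model_ids: list[str] | None = None,
    name_prefix: str = "family",
    group_labels: dict[int, str] | None = None,
) -> list[ProfileHMM]:
    """Align and model every cluster with at least ``min_size`` members.

    ``single_model_ids`` designates singletons that get a one-sequence model
    regardless of the size floor.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    by_id = {s.id: s for s in seqs}
    singles = set(single_model_ids or [])
    models: list[ProfileHMM] = []
    for ci, cluster in enumerate(clusters.clusters):
        is_designated_single = len(cluster) == 1 and cluster[0] in singles
        if len(cluster) < min_size and not is_designated_single:
            continue
        records = [(cid, by_id[cid].sequence) for cid in sorted(cluster)]
        label = (group_labels or {}).get(ci, f"{name_prefix}{ci}")
        try:
            msa = progressive_align(records)
            model = build_profile(msa, config=config, name=f"{name_prefix}{ci}", group_label=label)
        except Exception as exc:  # keep going on per-cluster failure
            log.error("cluster %d (%d members) failed: %s", ci, len(cluster), exc)
            continue
        models.append(model)
    return models


class ShortSequenceError(ValueError):
    pass


def make_cterm_model(
    long_sequences: list[SeqRecord],
    core_boundary: dict[str, int] | int,
    length_threshold: int = LONG_CRY_THRESHOLD,
    config: ProfileConfig | None = None,
    name: str = "cry_cterm",
) -> ProfileHMM:
    """Model only the C-terminal part of long Cry-type sequences.

    Every input must exceed ``length_threshold`` residues; the toxin core
    (everything before each sequence's boundary) is removed before the
    alignment and model-construction step.
    """
    if not long_sequences:
        raise ValueError("need at least one sequence")
    for rec in long_sequences:
        if len(rec.sequence) <= length_threshold:
            raise ShortSequenceError(
                f"sequence {rec.id!r} has length {len(rec.sequence)} <= threshold "
                f"{length_threshold}; only longer sequences get a C-terminal model"
            )
    boundaries = (
        {r.id: core_boundary for r in long_sequences}
        if isinstance(core_boundary, int)
        else dict(core_boundary)
    )
    tails = []
    for rec in long_sequences:
        b = boundaries[rec.id]
        if not 0 < b < len(rec.sequence):
            raise ValueError(f"invalid core boundary {b} for {rec.id!r}")
        tails.append((rec.id, rec.sequence[b:]))
    msa = progressive_align(tails)
    model = build_profile(msa, config=config, name=name, group_label="Cry_Cterm")
    return model


# ---------------------------------------------------------------------------
# cutoff calibration + validation


def _score_set(model: ProfileHMM, records: list[SeqRecord]) -> list[float]:
    return [forward_score(model, r.sequence, query_name=r.id).forward_bits for r in records]


def calibrate_cutoff(
    model: ProfileHMM,
    positives: list[SeqRecord],
    background: list[SeqRecord] | None = None,
    bandwidth: float | str = "silverman",
    epsilon: float = CUTOFF_EPSILON,
    grid_points: int = 512,
    precomputed: tuple[list[float], list[float]] | None = None,
) -> CalibrationReport:
    """Propose a gathering cutoff from the score distributions.

    Scores positives and background with the forward algorithm, fits a
    Gaussian KDE to the pooled scores and places the cutoff at the deepest
    density minimum between the positive mode and the rest.  With no
    background (or a unimodal pool) the rule degenerates to
    ``min(positive scores) - epsilon``.
    """
    if not positives and precomputed is None:
        raise ValueError("calibrate_cutoff requires at least one positive")
    if precomputed is not None:
        pos_scores, bg_scores = list(precomputed[0]), list(precomputed[1])
    else:
        pos_scores = _score_set(model, positives)
        bg_scores = _score_set(model, background or [])

    pooled = np.array(pos_scores + bg_scores, dtype=float)
    min_pos = min(pos_scores)
    density_curve: list[tuple[float, float]] = []
    separable = (not bg_scores) or max(bg_scores) < min_pos

    if not bg_scores or pooled.std() == 0:
        cutoff = min_pos - epsilon
    else:
        kde = gaussian_kde(pooled, bw_method=bandwidth)
        grid = np.linspace(pooled.min(), pooled.max(), grid_points)
        dens = kde(grid)
        density_curve = list(zip(grid.tolist(), dens.tolist()))
        if separable:
            lo, hi = max(bg_scores), min_pos
        else:
            lo, hi = float(np.median(bg_scores)), float(np.median(pos_scores))
        if hi <= lo:
            cutoff = min_pos - epsilon
        else:
            inner = (grid > lo) & (grid < hi)
            if inner.sum() >= 1:
                sub = np.flatnonzero(inner)
                cutoff = float(grid[sub[np.argmin(dens[sub])]])
            else:
                cutoff = (lo + hi) / 2.0
        # never let the KDE minimum cross into the positive support
        if separable and not (max(bg_scores) < cutoff <= min_pos):
            cutoff = (max(bg_scores) + min_pos) / 2.0

    calibrated = model.with_cutoff(cutoff)
    report = validate_model(calibrated, positives, [], background or [],
                            precomputed=(pos_scores, [], bg_scores))
    report.density_curve = density_curve
    report.separable = separable
    return report


def validate_model(
    model: ProfileHMM,
    positives: list[SeqRecord],
    negatives: list[SeqRecord],
    database: list[SeqRecord] | None = None,
    precomputed: tuple[list[float], list[float], list[float]] | None = None,
) -> CalibrationReport:
    """Evaluate the four quality criteria for a model with a set cutoff.

    1. every true positive scores at or above the cutoff;
    2. additional high-scoring matches are listed for manual review
       (informational, always passes);
    3. every true negative is absent or below the cutoff;
    4. the lowest positive is strictly above the highest other score.
    """
    if model.gathering_cutoff is None:
        raise ValueError("validate_model requires a model with a set cutoff")
    cutoff = model.gathering_cutoff
    database = database or []
    if precomputed is not None:
        pos_scores, neg_scores, db_scores = (list(x) for x in precomputed)
    else:
        pos_scores = _score_set(model, positives)
        neg_scores = _score_set(model, negatives)
        db_scores = _score_set(model, database)

    other_scores = neg_scores + db_scores
    c1 = all(s >= cutoff for s in pos_scores)
    review = [
        rec.id
        for rec, s in zip((negatives + (database or [])), other_scores)
        if s >= cutoff
    ]
    c2 = True
    c3 = all(s < cutoff for s in neg_scores)
    c4 = (not other_scores) or (min(pos_scores) > max(other_scores))
    return CalibrationReport(
        model_name=model.name,
        positive_scores=pos_scores,
        background_scores=other_scores,
        proposed_cutoff=cutoff,
        criteria_passed=[c1, c2, c3, c4],
        density_curve=[],
        review_matches=review,
        separable=c4,
    )


# ---------------------------------------------------------------------------
# whole pipeline


def build_pipeline(
    seqs: list[SeqRecord],
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    inflation: float = DEFAULT_INFLATION,
    edge_floor: float = DEFAULT_EDGE_FLOOR,
    config: ProfileConfig | None = None,
    single_model_ids: list[str] | None = None,
) -> tuple[list[ProfileHMM], ClusterSet, ClusterSet]:
    """Dedup -> similarity graph -> MCL -> per-cluster models.

    Returns (models, mcl_clusters, dedup_clusters).
    """
    dedup_clusters, reps = deduplicate(seqs)
    if len(reps) >= 2:
        graph = similarity_graph(reps, edge_floor=edge_floor)
        clusters = mcl_cluster(graph, inflation=inflation)
    else:
        clusters = ClusterSet(clusters=[[reps[0].id]], singletons=[reps[0].id])
    models = build_models(
        clusters, reps, min_size=min_size, config=config,
        single_model_ids=single_model_ids,
    )
    return models, clusters, dedup_clusters
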