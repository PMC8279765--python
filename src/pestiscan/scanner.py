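"""Detection unit: scan proteins or GenBank genomes against a model
collection, gate hits by the gathering cutoffs, and report a nearest-
neighbour tree per hit."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import skbio
from Bio.Seq import Seq

from pestiscan.align import fractional_identity
from pestiscan.hmm_core import ProfileHMM, align_to_profile, forward_score
from pestiscan.model_builder import SeqRecord
from pestiscan.orf import TRANSLATION_TABLE, find_orfs, translate_orf

log = logging.getLogger(__name__)

DEFAULT_NEIGHBORS = 10


@dataclass
class GenomicLocus:
    record_id: str
    strand: str
    start: int  # 0-based half-open on the source record
    end: int


@dataclass
class Hit:
    query_id: str
    model_name: str
    group_label: str
    bits: float
    above_cutoff: bool
    query_span: tuple[int, int]
    genomic_locus: GenomicLocus | None = None
    rank: int = 0
    query_sequence: str = ""


@dataclass
class NeighborTree:
    hit: Hit
    leaves: list[str]
    newick: str
    distances: dict[str, float] = field(default_factory=dict)


def _score_pair(model: ProfileHMM, rec: SeqRecord) -> tuple[float, tuple[int, int]]:
    res = forward_score(model, rec.sequence, query_name=rec.id)
    return res.forward_bits, res.query_span


def scan_proteins(
    seqs: list[SeqRecord],
    collection: list[ProfileHMM],
    use_cutoff: bool = True,
) -> list[Hit]:
    """Score every (query, model) pair with the forward algorithm.

    With ``use_cutoff`` only matches at or above each model's gathering
    cutoff are reported; disabling it also reports sub-threshold matches
    (any positive-bit hit) flagged ``above_cutoff=False`` for manual review.
    """
    if not collection:
        raise ValueError("empty model collection; configure at least one model")
    if not seqs:
        raise ValueError("no query sequences")
    hits: list[Hit] = []
    for rec in sorted(seqs, key=lambda r: r.id):
        per_query: list[Hit] = []
        for model in sorted(collection, key=lambda m: m.name):
            bits, span = _score_pair(model, rec)
            above = model.gathering_cutoff is not None and bits >= model.gathering_cutoff
            if use_cutoff and not above:
                continue
            if not use_cutoff and bits <= 0 and not above:
                continue
            per_query.append(
                Hit(
                    query_id=rec.id,
                    model_name=model.name,
                    group_label=model.group_label,
                    bits=bits,
                    above_cutoff=above,
                    query_span=span,
                    query_sequence=rec.sequence,
                )
            )
        per_query.sort(key=lambda h: (-h.bits, h.model_name))
        for rank, hit in enumerate(per_query, start=1):
            hit.rank = rank
        hits.extend(per_query)
    return hits


def _cds_queries(record) -> list[tuple[SeqRecord, GenomicLocus]]:
    queries = []
    n_cds = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        n_cds += 1
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        label = feat.qualifiers.get("locus_tag", feat.qualifiers.get("protein_id", [f"cds{n_cds}"]))[0]
        qual = feat.qualifiers.get("translation", [None])[0]
        if qual:
            aa = qual.rstrip("*")
            expected = (end - start) // 3 - 1
            if abs(len(aa) - expected) > 1:
                log.warning(
                    "CDS %s: /translation length %d inconsistent with span %d..%d; "
                    "using the qualifier text", label, len(aa), start, end,
                )
            if "*" in aa:
                log.warning("CDS %s: internal stop in /translation; trusting qualifier", label)
                aa = aa.replace("*", "X")
        else:
            sub = feat.extract(record.seq)
            aa = str(Seq(sub).translate(table=TRANSLATION_TABLE)).rstrip("*").replace("*", "X")
        if not aa:
            continue
        queries.append(
            (
                SeqRecord(id=f"{record.id}|{label}", sequence=aa),
                GenomicLocus(record.id, strand, start, end),
            )
        )
    return queries


def _orf_queries(record) -> list[tuple[SeqRecord, GenomicLocus]]:
    seq = str(record.seq)
    queries = []
    for i, orf in enumerate(find_orfs(seq), start=1):
        aa = translate_orf(seq, orf)
        if not aa:
            continue
        queries.append(
            (
                SeqRecord(id=f"{record.id}|orf{i}", sequence=aa),
                GenomicLocus(record.id, orf.strand, orf.start, orf.end),
            )
        )
    return queries


def scan_genome(
    genome: list,
    collection: list[ProfileHMM],
    use_cutoff: bool = True,
) -> list[Hit]:
    """Scan GenBank records (Bio.SeqRecord objects).

    Protein queries come from CDS features (/translation preferred, else
    conceptual translation, table 11); records without CDS annotation are
    six-frame ORF-called first.  Every hit carries its genomic locus.
    """
    if not genome:
        raise ValueError("no genome records")
    loci: dict[str, GenomicLocus] = {}
    queries: list[SeqRecord] = []
    for record in genome:
        extracted = _cds_queries(record)
        if not extracted:
            extracted = _orf_queries(record)
        for rec, locus in extracted:
            loci[rec.id] = locus
            queries.append(rec)
    if not queries:
        return []
    hits = scan_proteins(queries, collection, use_cutoff=use_cutoff)
    for hit in hits:
        hit.genomic_locus = loci[hit.query_id]
    return hits


def neighbor_tree(
    hit: Hit,
    model: ProfileHMM,
    group_members: list[SeqRecord],
    k: int = DEFAULT_NEIGHBORS,
) -> NeighborTree:
    """Neighbor-joining tree of the query and its k nearest group members.

    Distances are 1 - fractional identity under the model's profile
    alignment; with fewer than k members the whole group is used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not group_members:
        raise ValueError("group_members must be non-empty")
    query_label = hit.query_id
    entries = [(query_label, hit.query_sequence)] + [
        (m.id, m.sequence) for m in sorted(group_members, key=lambda m: m.id)
        if m.id != query_label
    ]
    msa = align_to_profile(model, entries)
    rows = dict(zip(msa.names, msa.rows))
    if query_label not in rows:
        raise ValueError(f"query {query_label!r} could not be aligned to the model")
    qrow = rows[query_label]
    dists = {
        name: 1.0 - fractional_identity(qrow, row)
        for name, row in rows.items()
        if name != query_label
    }
    nearest = sorted(dists, key=lambda n: (dists[n], n))[:k]
    leaves = [query_label] + nearest

    if len(leaves) == 2:
        d = dists[nearest[0]]
        newick = f"({leaves[0]}:{d / 2:.6f},{leaves[1]}:{d / 2:.6f});"
    else:
        n = len(leaves)
        mat = [[0.0] * n for _ in range(n)]
        lrows = {name: rows[name] if name != query_label else qrow for name in leaves}
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - fractional_identity(lrows[leaves[i]], lrows[leaves[j]])
                mat[i][j] = mat[j][i] = d
        dm = skbio.DistanceMatrix(mat, ids=leaves)
        tree = skbio.tree.nj(dm)
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
        newick = str(tree).strip()
    return NeighborTree(hit=hit, leaves=leaves, newick=newick, distances=dists)
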