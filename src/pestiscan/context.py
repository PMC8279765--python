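"""Genetic-environment comparison around genomic hits.

Extracts up to 5000 bp of flanking sequence on each side of a hit, applies a
uniform ORF-based re-annotation, computes pairwise identity blocks between
regions by exact k-mer seeding with ungapped X-drop extension, and renders
an EasyFig-style stacked SVG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from pestiscan.orf import find_orfs, translate_orf, validate_dna
from pestiscan.scanner import Hit

log = logging.getLogger(__name__)

DEFAULT_FLANK = 5000
DEFAULT_MIN_BLOCK = 100
DEFAULT_MIN_IDENTITY = 60.0
DEFAULT_SEED_K = 12
DEFAULT_XDROP = 20.0
SEED_MERGE_GAP = 80  # max distance between same-diagonal seeds merged into one run


@dataclass
class RegionFeature:
    start: int   # region-local, 0-based half-open
    end: int
    strand: str
    kind: str    # "CDS" or "ORF"
    label: str


@dataclass
class ContextRegion:
    hit: Hit | None
    record_id: str
    region_interval: tuple[int, int]   # on the source record
    sequence: str
    features: list[RegionFeature] = field(default_factory=list)
    anchor_interval: tuple[int, int] = (0, 0)  # region-local
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def region_id(self) -> str:
        a, b = self.region_interval
        return f"{self.record_id}:{a + 1}-{b}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ComparisonBlock:
    region_a: str
    region_b: str
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    percent_identity: float
    orientation: str  # "same" | "inverted"


# ---------------------------------------------------------------------------
# flank extraction


def extract_flanks(genome: list, hit: Hit, flank: int = DEFAULT_FLANK) -> ContextRegion:
    """Cut the window [start - flank, end + flank) around a genomic hit.

    Windows are clipped at contig edges (with truncation flags) unless the
    record is marked circular, in which case the flanks wrap the origin and
    the region is linearized with the anchor centered.  CDS annotations
    falling inside the window are carried over.
    """
    if hit.genomic_locus is None:
        raise ValueError(
            "hit has no genomic locus; run scan_genome (not scan_proteins) first"
        )
    locus = hit.genomic_locus
    record = next((r for r in genome if r.id == locus.record_id), None)
    if record is None:
        raise ValueError(f"record {locus.record_id!r} not present in the genome")
    n = len(record.seq)
    seq = str(record.seq).upper()
    circular = record.annotations.get("topology", "linear") == "circular"

    gene_len = locus.end - locus.start
    needs_wrap = circular and (locus.start - flank < 0 or locus.end + flank > n)
    if needs_wrap and gene_len + 2 * flank < n:
        offset = (locus.start - flank) % n
        rot = seq[offset:] + seq[:offset]
        region_seq = rot[: gene_len + 2 * flank]
        start, end = offset, offset + gene_len + 2 * flank  # end may exceed n (wrapped)
        anchor = (flank, flank + gene_len)
        trunc_l = trunc_r = False
        features = _carry_features(record, offset, len(region_seq), n, wrap=True)
    else:
        start = max(0, locus.start - flank)
        end = min(n, locus.end + flank)
        region_seq = seq[start:end]
        anchor = (locus.start - start, locus.end - start)
        trunc_l = locus.start - flank < 0
        trunc_r = locus.end + flank > n
        features = _carry_features(record, start, end - start, n, wrap=False)
    return ContextRegion(
        hit=hit,
        record_id=record.id,
        region_interval=(start, end),
        sequence=region_seq,
        features=features,
        anchor_interval=anchor,
        truncated_left=trunc_l,
        truncated_right=trunc_r,
    )


def _carry_features(record, offset: int, length: int, n: int, wrap: bool) -> list[RegionFeature]:
    out: list[RegionFeature] = []
    for i, feat in enumerate(record.features):
        if feat.type != "CDS":
            continue
        fs, fe = int(feat.location.start), int(feat.location.end)
        if wrap:
            ls = (fs - offset) % n
            le = ls + (fe - fs)
        else:
            ls, le = fs - offset, fe - offset
        if ls < 0 or le > length:
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        label = feat.qualifiers.get(
            "locus_tag", feat.qualifiers.get("protein_id", [f"cds{i + 1}"])
        )[0]
        out.append(RegionFeature(ls, le, strand, "CDS", label))
    return out


# ---------------------------------------------------------------------------
# re-annotation


def annotate_region(region: ContextRegion, min_orf_aa: int = 50) -> ContextRegion:
    """Add uniform six-frame ORF calls to a region.

    ORFs overlapping a carried-over CDS by more than 80% of their length are
    suppressed; every reported ORF translates without internal stops.
    """
    seq = validate_dna(region.sequence)
    cds = [(f.start, f.end) for f in region.features if f.kind == "CDS"]
    added: list[RegionFeature] = []
    idx = 0
    for orf in find_orfs(seq, min_aa=min_orf_aa):
        olen = orf.end - orf.start
        covered = max(
            (min(orf.end, ce) - max(orf.start, cs) for cs, ce in cds),
            default=0,
        )
        if olen > 0 and covered / olen > 0.8:
            continue
        aa = translate_orf(seq, orf)
        if "*" in aa:
            continue
        idx += 1
        added.append(
            RegionFeature(orf.start, orf.end, orf.strand, "ORF", f"{region.region_id}_orf{idx}")
        )
    region.features = region.features + added
    region.features.sort(key=lambda f: (f.start, f.end, f.label))
    return region


# ---------------------------------------------------------------------------
# pairwise identity blocks


def _seed_runs(a: str, b: str, k: int) -> list[tuple[int, int, int]]:
    """Merge same-diagonal exact k-mer matches into runs (a_start, b_start, length)."""
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i:i + k], []).append(i)
    by_diag: dict[int, list[int]] = {}
    for j in range(len(b) - k + 1):
        for i in index.get(b[j:j + k], ()):
            by_diag.setdefault(i - j, []).append(i)
    runs: list[tuple[int, int, int]] = []
    for diag, starts in sorted(by_diag.items()):
        starts.sort()
        run_start = prev = starts[0]
        for s in starts[1:]:
            if s - prev <= SEED_MERGE_GAP:
                prev = s
            else:
                runs.append((run_start, run_start - diag, prev + k - run_start))
                run_start = prev = s
        runs.append((run_start, run_start - diag, prev + k - run_start))
    return runs


def _extend_xdrop(a: str, b: str, ai: int, bi: int, length: int, xdrop: float):
    """Ungapped extension of a diagonal run in both directions."""
    match, mismatch = 1.0, -2.0

    def step(i, j, direction):
        score, best, best_off = 0.0, 0.0, 0
        off = 0
        while True:
            off += 1
            x, y = i + direction * off, j + direction * off
            if x < 0 or y < 0 or x >= len(a) or y >= len(b):
                break
            score += match if a[x] == b[y] else mismatch
            if score > best:
                best, best_off = score, off
            if best - score > xdrop:
                break
        return best_off

    left = step(ai, bi, -1)
    right = step(ai + length - 1, bi + length - 1, +1)
    return ai - left, bi - left, length + left + right


def _block_identity(a: str, b: str, ai: int, bi: int, length: int) -> float:
    seg_a, seg_b = a[ai:ai + length], b[bi:bi + length]
    return 100.0 * sum(x == y for x, y in zip(seg_a, seg_b)) / length


def _pair_blocks(
    ra: ContextRegion,
    rb: ContextRegion,
    k: int,
    min_block: int,
    min_identity: float,
    xdrop: float,
) -> list[ComparisonBlock]:
    a = ra.sequence.upper()
    candidates: list[tuple[int, int, int, float, str]] = []
    for orientation, b in (("same", rb.sequence.upper()),
                           ("inverted", str(Seq(rb.sequence).reverse_complement()).upper())):
        for ai, bi, length in _seed_runs(a, b, k):
            ai2, bi2, length2 = _extend_xdrop(a, b, ai, bi, length, xdrop)
            ident = _block_identity(a, b, ai2, bi2, length2)
            if length2 >= min_block and ident >= min_identity:
                candidates.append((ai2, bi2, length2, ident, orientation))
    # greedy selection, longest first; no substantial overlap on region a
    candidates.sort(key=lambda c: (-c[2], c[0], c[1]))
    chosen: list[tuple[int, int, int, float, str]] = []
    for cand in candidates:
        ai, bi, length, ident, orientation = cand
        overlap_tol = max(10, length // 10)
        clash = any(
            min(ai + length, xa + xl) - max(ai, xa) > overlap_tol
            for xa, _xb, xl, _xi, _xo in chosen
        )
        if not clash:
            chosen.append(cand)
    blocks = []
    nb = len(rb.sequence)
    for ai, bi, length, ident, orientation in sorted(chosen):
        if orientation == "same":
            interval_b = (bi, bi + length)
        else:
            interval_b = (nb - (bi + length), nb - bi)
        blocks.append(
            ComparisonBlock(
                region_a=ra.region_id,
                region_b=rb.region_id,
                interval_a=(ai, ai + length),
                interval_b=interval_b,
                percent_identity=round(ident, 2),
                orientation=orientation,
            )
        )
    return blocks


def compare_regions(
    regions: list[ContextRegion],
    min_block: int = DEFAULT_MIN_BLOCK,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = DEFAULT_SEED_K,
    xdrop: float = DEFAULT_XDROP,
    all_pairs: bool = False,
) -> list[ComparisonBlock]:
    """Identity blocks between consecutive regions (or all pairs).

    Exact k-mer seeds on the same diagonal are merged, extended ungapped with
    an X-drop rule, and filtered by block length and percent identity;
    reverse-complement matches are reported with orientation "inverted".
    """
    if len(regions) < 2:
        raise ValueError("compare_regions needs at least two regions")
    pairs = (
        [(i, j) for i in range(len(regions)) for j in range(i + 1, len(regions))]
        if all_pairs
        else [(i, i + 1) for i in range(len(regions) - 1)]
    )
    blocks: list[ComparisonBlock] = []
    for i, j in pairs:
        ra, rb = regions[i], regions[j]
        if len(ra) < k or len(rb) < k:
            log.warning("pair (%s, %s) shorter than seed size %d; skipped",
                        ra.region_id, rb.region_id, k)
            continue
        blocks.extend(_pair_blocks(ra, rb, k, min_block, min_identity, xdrop))
    return blocks


# ---------------------------------------------------------------------------
# rendering


def _shade(identity: float) -> str:
    # 60% -> light grey, 100% -> dark grey
    level = int(225 - (max(60.0, min(identity, 100.0)) - 60.0) * (160.0 / 40.0))
    return f"rgb({level},{level},{level})"


def render_comparison(
    regions: list[ContextRegion],
    blocks: list[ComparisonBlock],
    width: int = 1000,
    row_height: int = 90,
) -> str:
    """Deterministic EasyFig-style stacked SVG (returned as a string).

    One row per region labelled with record id and 1-based coordinates;
    features drawn as strand-aware arrows with the anchor gene highlighted;
    identity blocks as shaded trapezoids between consecutive rows.
    """
    if not regions:
        raise ValueError("render_comparison needs at least one region")
    margin = 120
    scale = (width - margin - 20) / max(len(r) for r in regions)
    height = row_height * len(regions) + 40
    row_y = {r.region_id: 40 + i * row_height for i, r in enumerate(regions)}

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect x="0" y="0" width="{width}" height="{height}" fill="white"/>',
    ]

    def px(region: ContextRegion, pos: int) -> float:
        return margin + pos * scale

    # trapezoids first so arrows draw on top
    for blk in blocks:
        if blk.region_a not in row_y or blk.region_b not in row_y:
            continue
        ya = row_y[blk.region_a] + 8
        yb = row_y[blk.region_b] - 8
        ra = next(r for r in regions if r.region_id == blk.region_a)
        rb = next(r for r in regions if r.region_id == blk.region_b)
        a1, a2 = (px(ra, p) for p in blk.interval_a)
        b1, b2 = (px(rb, p) for p in blk.interval_b)
        if blk.orientation == "inverted":
            b1, b2 = b2, b1
        parts.append(
            f'<polygon points="{a1:.1f},{ya} {a2:.1f},{ya} {b2:.1f},{yb} {b1:.1f},{yb}" '
            f'fill="{_shade(blk.percent_identity)}" fill-opacity="0.85" stroke="none">'
            f"<title>{blk.percent_identity:.1f}% {blk.orientation}</title></polygon>"
        )

    for region in regions:
        y = row_y[region.region_id]
        x0, x1 = px(region, 0), px(region, len(region))
        a, b = region.region_interval
        parts.append(
            f'<text x="8" y="{y + 4}" font-size="11" font-family="monospace">'
            f"{region.record_id} {a + 1}-{b}</text>"
        )
        parts.append(
            f'<line x1="{x0:.1f}" y1="{y}" x2="{x1:.1f}" y2="{y}" '
            'stroke="black" stroke-width="1"/>'
        )
        for feat in region.features:
            fx0, fx1 = px(region, feat.start), px(region, feat.end)
            is_anchor = (
                feat.kind == "CDS"
                and feat.start <= region.anchor_interval[0] < feat.end
            ) or (feat.start, feat.end) == region.anchor_interval
            color = "#c0392b" if is_anchor else ("#2e86c1" if feat.kind == "CDS" else "#7f8c8d")
            head = min(8.0, fx1 - fx0)
            if feat.strand == "+":
                pts = (
                    f"{fx0:.1f},{y - 6} {fx1 - head:.1f},{y - 6} {fx1:.1f},{y} "
                    f"{fx1 - head:.1f},{y + 6} {fx0:.1f},{y + 6}"
                )
            else:
                pts = (
                    f"{fx1:.1f},{y - 6} {fx0 + head:.1f},{y - 6} {fx0:.1f},{y} "
                    f"{fx0 + head:.1f},{y + 6} {fx1:.1f},{y + 6}"
                )
            parts.append(
                f'<polygon points="{pts}" fill="{color}" stroke="black" stroke-width="0.4">'
                f"<title>{feat.label}</title></polygon>"
            )
    parts.append("</svg>")
    return "\n".join(parts)


def blocks_table(blocks: list[ComparisonBlock]) -> str:
    """Blocks as a TSV string (1-based inclusive user-facing coordinates)."""
    lines = ["region_a\ta_start\ta_end\tregion_b\tb_start\tb_end\tpct_identity\torientation"]
    for blk in blocks:
        lines.append(
            f"{blk.region_a}\t{blk.interval_a[0] + 1}\t{blk.interval_a[1]}\t"
            f"{blk.region_b}\t{blk.interval_b[0] + 1}\t{blk.interval_b[1]}\t"
            f"{blk.percent_identity:.2f}\t{blk.orientation}"
        )
    return "\n".join(lines) + "\n"
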