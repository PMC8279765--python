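"""Six-frame ORF calling (bacterial translation table 11).

A lightweight, uniform stand-in for a full annotation pipeline: stop-to-stop
frames scanned for the first ATG/GTG/TTG start, minimum length enforced in
amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}
TRANSLATION_TABLE = 11

IUPAC_DNA = set("ACGTNRYSWKMBDHV")


class DnaAlphabetError(ValueError):
    pass


@dataclass(frozen=True)
class Orf:
    start: int      # 0-based, includes the start codon
    end: int        # half-open, includes the stop codon when present
    strand: str     # '+' or '-'
    frame: int      # 0..2 on the reported strand

    @property
    def aa_length(self) -> int:
        return (self.end - self.start) // 3 - 1


def validate_dna(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise DnaAlphabetError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    return seq


def translate_orf(seq: str, orf: Orf) -> str:
    sub = seq[orf.start:orf.end]
    if orf.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    aa = str(Seq(sub).translate(table=TRANSLATION_TABLE))
    return aa.rstrip("*")


def _scan_strand(seq: str, length: int, strand: str, min_aa: int) -> list[Orf]:
    found: list[Orf] = []
    for frame in range(3):
        start_candidate: int | None = None
        for pos in range(frame, length - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if start_candidate is not None:
                    aa_len = (pos - start_candidate) // 3
                    if aa_len >= min_aa:
                        found.append(Orf(start_candidate, pos + 3, strand, frame))
                start_candidate = None
            elif codon in START_CODONS and start_candidate is None:
                start_candidate = pos
    return found


def find_orfs(sequence: str, min_aa: int = 50) -> list[Orf]:
    """Locate ORFs on both strands; minus-strand coordinates are given on the
    forward strand (mirrored), sorted by start position."""
    seq = validate_dna(sequence)
    n = len(seq)
    orfs = _scan_strand(seq, n, "+", min_aa)
    rc = str(Seq(seq).reverse_complement())
    for orf in _scan_strand(rc, n, "-", min_aa):
        orfs.append(Orf(n - orf.end, n - orf.start, "-", orf.frame))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs
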