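"""Amino-acid alphabet, ambiguity handling and background frequencies."""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Ambiguity handling: X scores as background (index -1 sentinel),
# B/Z/U are mapped to D/E/C, '*' terminates a sequence.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C"}
X_INDEX = -1

GAP = "-"

# Swiss-Prot-style amino-acid composition, normalized to sum to 1.
_SWISSPROT_RAW = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}


def swissprot_background() -> np.ndarray:
    bg = np.array([_SWISSPROT_RAW[aa] for aa in AMINO_ACIDS], dtype=float)
    return bg / bg.sum()


def uniform_background() -> np.ndarray:
    return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))


class SequenceAlphabetError(ValueError):
    """Raised when a residue outside the accepted alphabet is encountered."""


def encode_sequence(seq: str, context: str = "sequence") -> np.ndarray:
    """Encode a protein sequence into alphabet indices.

    Ambiguity codes B/Z/U are mapped to D/E/C, X becomes the background
    sentinel ``-1`` and ``*`` terminates the sequence.  Any other character
    raises :class:`SequenceAlphabetError` naming the offending position.
    """
    out = []
    for pos, ch in enumerate(seq.upper()):
        if ch == "*":
            break
        ch = AMBIGUITY_MAP.get(ch, ch)
        if ch == "X":
            out.append(X_INDEX)
        elif ch in AA_INDEX:
            out.append(AA_INDEX[ch])
        else:
            raise SequenceAlphabetError(
                f"invalid residue {ch!r} at position {pos + 1} in {context}"
            )
    return np.array(out, dtype=np.int64)
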