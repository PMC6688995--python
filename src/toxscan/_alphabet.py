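"""Amino-acid alphabet and background frequencies shared across modules."""

from __future__ import annotations

import numpy as np

#: The 20 canonical amino acids, in fixed index order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Non-canonical letters mapped to X on read.
AMBIGUOUS_AA = set("BZUOJ")

#: Robinson & Robinson-style background amino-acid frequencies, renormalised
#: over the 20 canonical letters.  Used as the default profile background and
#: as the decoy-emission distribution in the synthetic generator.
BACKGROUND_FREQS = {
    "A": 0.0780, "C": 0.0152, "D": 0.0535, "E": 0.0668, "F": 0.0405,
    "G": 0.0722, "H": 0.0220, "I": 0.0591, "K": 0.0592, "L": 0.0964,
    "M": 0.0229, "N": 0.0426, "P": 0.0469, "Q": 0.0392, "R": 0.0519,
    "S": 0.0714, "T": 0.0553, "V": 0.0667, "W": 0.0131, "Y": 0.0321,
}

_total = sum(BACKGROUND_FREQS.values())
BACKGROUND_FREQS = {a: v / _total for a, v in BACKGROUND_FREQS.items()}

#: Background as a vector aligned with AMINO_ACIDS.
BACKGROUND_VECTOR = np.array([BACKGROUND_FREQS[a] for a in AMINO_ACIDS])


def sanitize_protein(seq: str) -> str:
    """Uppercase a protein sequence and map non-canonical letters to X.

    B/Z/U/O/J (ambiguity and rare residues) become X; gap characters are
    rejected; anything else unknown raises.
    """
    out = []
    for ch in seq.upper():
        if ch in AA_INDEX or ch == "X":
            out.append(ch)
        elif ch in AMBIGUOUS_AA:
            out.append("X")
        elif ch == "*":
            continue  # trailing stop in some annotation exports
        else:
            raise ValueError(f"invalid amino-acid letter {ch!r}")
    return "".join(out)


def encode_protein(seq: str) -> np.ndarray:
    """Encode a sanitized protein as int indices; X (and any non-canonical)
    encodes as 20, which every profile scores as 0."""
    return np.array([AA_INDEX.get(ch, 20) for ch in seq], dtype=np.int64)
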