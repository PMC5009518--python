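"""Small DNA alphabet helpers shared across the package.

Internal symbol codes: sentinel $ = 0, then A=1, C=2, G=3, T=4 in sort
order.  Complement is ``5 - code`` for the four bases, which keeps the
hot loops branch-free.
"""

from __future__ import annotations

import numpy as np

SENT = 0
A, C, G, T = 1, 2, 3, 4
ALPHABET = "ACGT"

_CODE_OF = {"A": A, "C": C, "G": G, "T": T, "$": SENT}
_CHAR_OF = "$ACGT"

# byte -> code lookup (255 = invalid) for vectorised encoding
_BYTE_CODE = np.full(256, 255, dtype=np.uint8)
for _ch, _cd in _CODE_OF.items():
    _BYTE_CODE[ord(_ch)] = _cd
    _BYTE_CODE[ord(_ch.lower())] = _cd

_COMP_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def comp(code: int) -> int:
    """Complement of a base code (A<->T, C<->G)."""
    return 5 - code


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string into a uint8 code array."""
    codes = _BYTE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(_CHAR_OF[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (5 - codes[::-1]).astype(np.uint8)
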