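"""Binary matrix encoding of short peptides.

Each residue maps to a 5-bit code: the 5-bit binary representation of its
alphabetical rank among the 20 standard amino acids (A=1 ... Y=20), so
``A -> [0,0,0,0,1]`` and ``Y -> [1,0,1,0,0]``.  Rank 21 (``[1,0,1,0,1]``) pads
peptides shorter than the matrix height and rank 23 (``[1,0,1,1,1]``) stands
for the non-standard symbols O, U, B, Z, J and X.  A peptide of up to
``MAX_UNIT_LENGTH`` residues becomes a fixed 30 x 5 {0,1} matrix, the input
consumed by the convolutional classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Longest repeat unit the classifier accepts (residues).
MAX_UNIT_LENGTH = 30
#: Shortest repeat unit considered (residues).
MIN_UNIT_LENGTH = 20

#: The 20 standard amino acids in alphabetical order (rank = index + 1).
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Symbols outside the standard alphabet, all sharing the "unknown" code.
NONSTANDARD_AA = "OUBZJX"

PAD_SYMBOL = "-"
UNKNOWN_SYMBOL = "X"

_PAD_RANK = 21
_UNKNOWN_RANK = 23


def _rank_to_bits(rank: int) -> tuple[int, ...]:
    return tuple((rank >> (4 - i)) & 1 for i in range(5))


def _build_table() -> dict[str, tuple[int, ...]]:
    table = {aa: _rank_to_bits(i + 1) for i, aa in enumerate(STANDARD_AA)}
    table[PAD_SYMBOL] = _rank_to_bits(_PAD_RANK)
    unknown = _rank_to_bits(_UNKNOWN_RANK)
    for aa in NONSTANDARD_AA:
        table[aa] = unknown
    return table


#: residue symbol -> 5-bit code (20 standard aa + pad + unknown, all distinct)
ENCODING_TABLE: dict[str, tuple[int, ...]] = _build_table()

# inverse lookup for round-trips; non-standard symbols collapse to UNKNOWN_SYMBOL
_DECODING_TABLE: dict[tuple[int, ...], str] = {
    code: aa for aa, code in _build_table().items() if aa not in NONSTANDARD_AA
}
_DECODING_TABLE[_rank_to_bits(_UNKNOWN_RANK)] = UNKNOWN_SYMBOL


@dataclass(frozen=True)
class EncodedPeptide:
    """A peptide as a fixed-height binary matrix plus its true length."""

    matrix: np.ndarray  # (MAX_UNIT_LENGTH, 5) of {0,1}
    true_length: int

    def __post_init__(self) -> None:
        if not 1 <= self.true_length <= self.matrix.shape[0]:
            raise ValueError(f"true_length {self.true_length} out of range")


def encode_residue(aa: str) -> np.ndarray:
    """Return the 5-bit code of a single residue symbol.

    Non-standard residues (O, U, B, Z, J, X) map to the shared unknown code;
    anything that is not a single alphabetic character (or the pad symbol)
    is rejected.
    """
    if len(aa) != 1:
        raise ValueError(f"expected a single residue symbol, got {aa!r}")
    sym = aa.upper()
    if sym != PAD_SYMBOL and not sym.isalpha():
        raise ValueError(f"invalid residue symbol {aa!r}")
    try:
        return np.array(ENCODING_TABLE[sym], dtype=np.uint8)
    except KeyError:
        raise ValueError(f"invalid residue symbol {aa!r}") from None


def encode_peptide(seq: str, max_len: int = MAX_UNIT_LENGTH) -> EncodedPeptide:
    """Encode ``seq`` into a ``max_len`` x 5 binary matrix, padding the tail.

    Raises ``ValueError`` on an empty or over-length sequence.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    if len(seq) > max_len:
        raise ValueError(f"sequence of length {len(seq)} exceeds max_len={max_len}")
    rows = [encode_residue(aa) for aa in seq]
    pad = np.array(ENCODING_TABLE[PAD_SYMBOL], dtype=np.uint8)
    rows.extend([pad] * (max_len - len(seq)))
    return EncodedPeptide(matrix=np.stack(rows), true_length=len(seq))


def decode_peptide(encoded: EncodedPeptide) -> str:
    """Inverse of :func:`encode_peptide`; unknown rows decode to ``X``."""
    out = []
    for row in encoded.matrix[: encoded.true_length]:
        out.append(_DECODING_TABLE[tuple(int(v) for v in row)])
    return "".join(out)


def encode_batch(seqs: list[str], max_len: int = MAX_UNIT_LENGTH) -> np.ndarray:
    """Stack encodings of many peptides into an (n, max_len, 5) float array."""
    return np.stack(
        [encode_peptide(s, max_len).matrix for s in seqs]
    ).astype(np.float32)
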