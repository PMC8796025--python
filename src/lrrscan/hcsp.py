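"""The highly conserved segment pattern (HCSP) of leucine-rich-repeat units.

An LRR unit splits into a highly conserved segment (HCS) and a highly
variable segment (HVS).  The HCS follows the 11-residue degenerate template
``LxxLxLxxNxL``: positions 1, 4, 6, 9 and 11 are constrained to
position-specific residue sets (hydrophobic substitutions of L, and
C/T/S substitutions of N at position 9), the remaining positions admit any
residue.  Peptides lacking any match to this template define the negative
class for the unit classifier.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

HCSP_LENGTH = 11

#: canonical template; positions are 1-based
CANONICAL = "LxxLxLxxNxL"

#: constrained positions (1-based) and their default allowed residue sets
DEFAULT_ALLOWED: dict[int, frozenset[str]] = {
    1: frozenset("LIVMTF"),
    4: frozenset("LIVFM"),
    6: frozenset("LVIFMAC"),
    9: frozenset("NCTS"),
    11: frozenset("LIFVMSN"),
}


@dataclass(frozen=True)
class HCSPattern:
    """Degenerate 11-position template with per-position allowed residues."""

    allowed: dict[int, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_ALLOWED)
    )
    length: int = HCSP_LENGTH

    def __post_init__(self) -> None:
        for pos, residues in self.allowed.items():
            if not 1 <= pos <= self.length:
                raise ValueError(f"constrained position {pos} outside pattern")
            canonical = CANONICAL[pos - 1]
            if canonical != "x" and canonical not in residues:
                raise ValueError(
                    f"position {pos} set {sorted(residues)} lacks canonical "
                    f"residue {canonical}"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {str(p): sorted(s) for p, s in self.allowed.items()}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HCSPattern":
        payload = json.loads(Path(path).read_text())
        return cls(allowed={int(p): frozenset(s) for p, s in payload.items()})


def matches_at(seq: str, i: int, pattern: HCSPattern | None = None) -> bool:
    """True iff the window of ``seq`` starting at 1-based ``i`` fits the pattern."""
    pattern = pattern or HCSPattern()
    if i < 1 or i + pattern.length - 1 > len(seq):
        raise ValueError(
            f"window [{i}, {i + pattern.length - 1}] exceeds sequence of "
            f"length {len(seq)}"
        )
    window = seq[i - 1 : i - 1 + pattern.length].upper()
    return all(window[p - 1] in residues for p, residues in pattern.allowed.items())


def contains_hcsp(seq: str, pattern: HCSPattern | None = None) -> bool:
    """True iff any window of ``seq`` matches; sequences < 11 aa never match."""
    pattern = pattern or HCSPattern()
    return any(
        matches_at(seq, i, pattern) for i in range(1, len(seq) - pattern.length + 2)
    )


def build_substitution_sets(
    segments: list[str], min_freq: float = 0.005
) -> HCSPattern:
    """Derive per-position allowed sets from aligned 11-mer conserved segments.

    At each constrained position the allowed set is every residue whose
    relative column frequency is >= ``min_freq`` (ties at the threshold are
    included).  Raises if the canonical residue of a constrained position
    drops out, since that would no longer be a valid repeat-unit pattern.
    """
    if not segments:
        raise ValueError("cannot build substitution sets from an empty list")
    for seg in segments:
        if len(seg) != HCSP_LENGTH:
            raise ValueError(f"segment {seg!r} is not {HCSP_LENGTH} aa long")
    n = len(segments)
    allowed: dict[int, frozenset[str]] = {}
    for pos in DEFAULT_ALLOWED:
        counts = Counter(seg[pos - 1].upper() for seg in segments)
        kept = {aa for aa, c in counts.items() if c / n >= min_freq}
        allowed[pos] = frozenset(kept)
    return HCSPattern(allowed=allowed)
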