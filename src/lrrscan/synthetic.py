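"""Seeded generator of synthetic LRR units, decoy peptides and whole proteins.

The generator emulates the statistical structure of a curated repeat-unit
corpus: positive units are 20-30 aa peptides carrying one highly conserved
segment drawn position-wise from the HCSP substitution sets (the canonical
residue is the most likely draw at each constrained position), embedded in
variable-segment background; negatives are peptides of the same length
rejection-sampled until they contain no HCSP match.  Whole proteins
interleave HCSP-free spacers with units whose coordinates are recorded as
ground truth, so every stage of the caller can be benchmarked against known
answers.

An optional per-position mutation rate corrupts HCS residues of positive
units after the draw.  At the default rate 0.0 every positive satisfies
``contains_hcsp`` by construction; a small positive rate (the benchmark runs
use 0.05) makes the classification task strictly harder than literal motif
matching.

Residue composition matters.  Real LRR units are strongly leucine-enriched
throughout (roughly three times the proteome average), while real negative
segments have ordinary proteome composition; this composition contrast
carries a large share of the discriminative signal in any corpus derived
from curated proteins.  The generator therefore defaults to proteome-average
(Swiss-Prot) background frequencies for negatives and spacers and a
leucine-enriched variant of the same table for the variable segment of
positive units.  A uniform alphabet is available through the config, but it
produces a corpus in which the two classes are composition-matched and the
only signal is the sparse degenerate motif — a far harder learning problem
than any real repeat-unit corpus poses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import MAX_UNIT_LENGTH, MIN_UNIT_LENGTH, STANDARD_AA
from .datasets import UnitRecord
from .hcsp import CANONICAL, HCSPattern, contains_hcsp

#: weight given to the canonical residue at each constrained HCS position;
#: the remaining mass is spread uniformly over the allowed substitutions
CANONICAL_WEIGHT = 0.6

_REJECTION_CAP = 1000

_SWISSPROT_RAW = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

#: Swiss-Prot average amino-acid frequencies (UniProtKB release statistics,
#: renormalized to sum exactly to 1)
SWISSPROT_FREQS: dict[str, float] = {
    aa: f / sum(_SWISSPROT_RAW.values()) for aa, f in _SWISSPROT_RAW.items()
}


def _leucine_enriched(freqs: dict[str, float], factor: float = 3.0) -> dict[str, float]:
    out = {aa: (f * factor if aa == "L" else f) for aa, f in freqs.items()}
    total = sum(out.values())
    return {aa: f / total for aa, f in out.items()}


#: default composition of the variable segment of positive units: the
#: proteome table with leucine at ~3x its background share (~25% of residues)
LRR_HVS_FREQS: dict[str, float] = _leucine_enriched(SWISSPROT_FREQS)


@dataclass(frozen=True)
class SyntheticProtein:
    """A generated protein with ground-truth unit coordinates (1-based)."""

    protein_id: str
    sequence: str
    true_units: tuple[tuple[int, int], ...]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    ``unit_lengths`` gives the support of the unit-length distribution
    (uniform over it by default); ``spacer_range`` bounds the HCSP-free
    gap between consecutive units inside a protein and ``flank_range`` the
    termini; ``mutation_rate`` is the per-position corruption probability
    applied to the 11 HCS residues of positive units.  ``background_freqs``
    and ``hvs_freqs`` default to the proteome-average and leucine-enriched
    tables; pass explicit dictionaries (e.g. uniform) to override.
    """

    seed: int
    unit_lengths: tuple[int, ...] = tuple(range(MIN_UNIT_LENGTH, MAX_UNIT_LENGTH + 1))
    n_units_range: tuple[int, int] = (3, 8)
    spacer_range: tuple[int, int] = (2, 8)
    flank_range: tuple[int, int] = (10, 50)
    background_freqs: dict[str, float] | None = None  # None -> SWISSPROT_FREQS
    hvs_freqs: dict[str, float] | None = None  # None -> LRR_HVS_FREQS
    mutation_rate: float = 0.0
    pattern: HCSPattern = field(default_factory=HCSPattern)

    def __post_init__(self) -> None:
        for length in self.unit_lengths:
            if not MIN_UNIT_LENGTH <= length <= MAX_UNIT_LENGTH:
                raise ValueError(f"unit length {length} outside [20, 30]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _freq_arrays(freqs: dict[str, float] | None) -> tuple[list[str], np.ndarray]:
    if freqs is None:
        return list(STANDARD_AA), np.full(len(STANDARD_AA), 1 / len(STANDARD_AA))
    symbols = sorted(freqs)
    weights = np.array([freqs[s] for s in symbols], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("residue frequencies must have positive mass")
    return symbols, weights / weights.sum()


def _draw(rng: np.random.Generator, symbols: list[str], p: np.ndarray, n: int) -> str:
    return "".join(rng.choice(symbols, size=n, p=p)) if n else ""


def _draw_hcs(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    symbols, p = _freq_arrays(cfg.hvs_freqs or LRR_HVS_FREQS)
    out = []
    for pos in range(1, cfg.pattern.length + 1):
        allowed = cfg.pattern.allowed.get(pos)
        if allowed is None:
            out.append(_draw(rng, symbols, p, 1))
            continue
        canonical = CANONICAL[pos - 1]
        subs = sorted(allowed - {canonical})
        if subs and rng.random() >= CANONICAL_WEIGHT:
            out.append(subs[rng.integers(len(subs))])
        else:
            out.append(canonical)
    return "".join(out)


def gen_lrr_unit(
    cfg: GeneratorConfig, length: int, rng: np.random.Generator | None = None
) -> str:
    """Generate one positive unit of the given length.

    The unit is an HCS (placed uniformly among valid offsets) surrounded by
    variable-segment residues; with ``cfg.mutation_rate == 0`` the result is
    guaranteed to satisfy ``contains_hcsp``.
    """
    if not MIN_UNIT_LENGTH <= length <= MAX_UNIT_LENGTH:
        raise ValueError(f"unit length {length} outside [20, 30]")
    rng = cfg.rng() if rng is None else rng
    hcs = _draw_hcs(rng, cfg)
    if cfg.mutation_rate > 0:
        symbols, p = _freq_arrays(cfg.hvs_freqs or LRR_HVS_FREQS)
        hcs = "".join(
            _draw(rng, symbols, p, 1) if rng.random() < cfg.mutation_rate else aa
            for aa in hcs
        )
    symbols, p = _freq_arrays(cfg.hvs_freqs or LRR_HVS_FREQS)
    offset = int(rng.integers(length - cfg.pattern.length + 1))
    left = _draw(rng, symbols, p, offset)
    right = _draw(rng, symbols, p, length - cfg.pattern.length - offset)
    return left + hcs + right


def _gen_hcsp_free(
    cfg: GeneratorConfig, length: int, rng: np.random.Generator
) -> str:
    symbols, p = _freq_arrays(cfg.background_freqs or SWISSPROT_FREQS)
    for _ in range(_REJECTION_CAP):
        seq = _draw(rng, symbols, p, length)
        if not contains_hcsp(seq, cfg.pattern):
            return seq
    raise RuntimeError(
        f"could not sample an HCSP-free segment of length {length} in "
        f"{_REJECTION_CAP} attempts"
    )


def gen_non_lrr(
    cfg: GeneratorConfig, length: int, rng: np.random.Generator | None = None
) -> str:
    """Generate one negative unit: background residues with no HCSP match."""
    if not MIN_UNIT_LENGTH <= length <= MAX_UNIT_LENGTH:
        raise ValueError(f"unit length {length} outside [20, 30]")
    rng = cfg.rng() if rng is None else rng
    return _gen_hcsp_free(cfg, length, rng)


def gen_protein(
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    protein_id: str = "synthetic",
) -> SyntheticProtein:
    """Generate a protein of HCSP-free flanks/spacers with embedded LRR units."""
    rng = cfg.rng() if rng is None else rng
    n_units = int(rng.integers(cfg.n_units_range[0], cfg.n_units_range[1] + 1))
    parts: list[str] = []
    truth: list[tuple[int, int]] = []
    pos = 0
    flank = int(rng.integers(cfg.flank_range[0], cfg.flank_range[1] + 1))
    parts.append(_gen_hcsp_free(cfg, flank, rng) if flank else "")
    pos += flank
    for k in range(n_units):
        if k > 0:
            spacer = int(rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))
            parts.append(_gen_hcsp_free(cfg, spacer, rng) if spacer else "")
            pos += spacer
        length = int(cfg.unit_lengths[rng.integers(len(cfg.unit_lengths))])
        parts.append(gen_lrr_unit(cfg, length, rng))
        truth.append((pos + 1, pos + length))
        pos += length
    flank = int(rng.integers(cfg.flank_range[0], cfg.flank_range[1] + 1))
    parts.append(_gen_hcsp_free(cfg, flank, rng) if flank else "")
    return SyntheticProtein(
        protein_id=protein_id, sequence="".join(parts), true_units=tuple(truth)
    )


def _per_length_counts(total: int, lengths: tuple[int, ...]) -> dict[int, int]:
    base, rem = divmod(total, len(lengths))
    return {L: base + (1 if i < rem else 0) for i, L in enumerate(lengths)}


def gen_benchmark(
    cfg: GeneratorConfig,
    n_pos_units: int,
    n_neg_units: int,
    n_proteins: int,
) -> tuple[list[UnitRecord], list[SyntheticProtein]]:
    """Generate a balanced unit dataset plus proteins with ground truth.

    Unit counts are spread deterministically over ``cfg.unit_lengths`` (the
    same allocation for both classes up to totals), so per-length class
    balance holds exactly when ``n_pos_units == n_neg_units``.  Everything is
    reproducible from ``cfg.seed``.
    """
    if min(n_pos_units, n_neg_units, n_proteins) < 0:
        raise ValueError("counts must be non-negative")
    rng = cfg.rng()
    units: list[UnitRecord] = []
    for L, count in _per_length_counts(n_pos_units, cfg.unit_lengths).items():
        for i in range(count):
            units.append(
                UnitRecord(gen_lrr_unit(cfg, L, rng), "positive", f"pos_L{L}_{i}")
            )
    for L, count in _per_length_counts(n_neg_units, cfg.unit_lengths).items():
        for i in range(count):
            units.append(
                UnitRecord(gen_non_lrr(cfg, L, rng), "negative", f"neg_L{L}_{i}")
            )
    proteins = [
        gen_protein(cfg, rng, protein_id=f"synthetic_{i}") for i in range(n_proteins)
    ]
    return units, proteins
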