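"""Construction of positive/negative unit datasets and train/test splits.

Positive units come from annotated repeat intervals: units shorter than 20 aa
or longer than 30 aa are dropped, and a protein only contributes if at least
three of its units survive.  Redundancy removal follows a deterministic
greedy identity clustering (longest sequence first, a unit joins the first
representative it matches at >= the identity threshold).  Negatives are
segments cut from non-LRR background sequences and kept only if they contain
no HCSP match.  Splits are 80/20 train/test with five folds over the
training set, stratified so that per-length 1:1 class balance is preserved
in every partition up to rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import MAX_UNIT_LENGTH, MIN_UNIT_LENGTH
from .hcsp import HCSPattern, contains_hcsp

NEGATIVE_SAMPLING_CAP = 1000  # attempts per needed segment


@dataclass(frozen=True)
class UnitRecord:
    sequence: str
    label: str  # "positive" | "negative"
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    n_folds: int = 5
    seed: int = 0


@dataclass
class SplitDataset:
    """An 80/20 split with five disjoint folds covering the training set."""

    folds: list[list[UnitRecord]]
    test: list[UnitRecord]

    @property
    def train(self) -> list[UnitRecord]:
        return [r for fold in self.folds for r in fold]


def filter_positive_units(
    proteins: list[tuple[str, str, list[tuple[int, int]]]],
) -> list[UnitRecord]:
    """Extract positive units from (protein_id, sequence, intervals) triples.

    Intervals are 1-based inclusive.  Units with length outside [20, 30] are
    dropped first; a protein retaining fewer than three units contributes
    nothing.
    """
    records: list[UnitRecord] = []
    for protein_id, seq, intervals in proteins:
        kept = []
        for start, end in intervals:
            if start < 1 or end > len(seq) or start > end:
                raise ValueError(
                    f"interval ({start}, {end}) outside protein {protein_id!r} "
                    f"of length {len(seq)}"
                )
            if MIN_UNIT_LENGTH <= end - start + 1 <= MAX_UNIT_LENGTH:
                kept.append((start, end))
        if len(kept) >= 3:
            records.extend(
                UnitRecord(seq[s - 1 : e], "positive", f"{protein_id}:{s}-{e}")
                for s, e in kept
            )
    return records


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped identity: best offset alignment, normalized by the shorter length.

    Equal lengths compare position-wise at offset 0; otherwise the shorter
    sequence slides along the longer one and the best match count is used.
    """
    if not a or not b:
        raise ValueError("cannot compare empty sequences")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for off in range(len(long_) - len(short) + 1):
        matches = sum(x == y for x, y in zip(short, long_[off:]))
        best = max(best, matches)
    return best / len(short)


def greedy_identity_cluster(
    units: list[str], identity_threshold: float = 0.8
) -> list[str]:
    """Greedy longest-first redundancy removal; returns representatives only."""
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    representatives: list[str] = []
    for unit in sorted(units, key=lambda s: (-len(s), s)):
        if not any(
            pairwise_identity(unit, rep) >= identity_threshold
            for rep in representatives
        ):
            representatives.append(unit)
    return representatives


def sample_negative_units(
    background: list[str],
    length_histogram: dict[int, int],
    pattern: HCSPattern | None = None,
    seed: int = 0,
) -> list[UnitRecord]:
    """Cut HCSP-free segments from background sequences, matching a length histogram.

    For each length L exactly ``length_histogram[L]`` segments are returned.
    Sampling is seed-reproducible; if a length cannot be satisfied within the
    attempt cap a ``RuntimeError`` names it.
    """
    pattern = pattern or HCSPattern()
    for L in length_histogram:
        if not MIN_UNIT_LENGTH <= L <= MAX_UNIT_LENGTH:
            raise ValueError(f"histogram length {L} outside [20, 30]")
    rng = np.random.default_rng(seed)
    records: list[UnitRecord] = []
    for L in sorted(length_histogram):
        eligible = [i for i, seq in enumerate(background) if len(seq) >= L]
        needed = length_histogram[L]
        for k in range(needed):
            for _ in range(NEGATIVE_SAMPLING_CAP):
                if not eligible:
                    break
                i = eligible[rng.integers(len(eligible))]
                seq = background[i]
                start = int(rng.integers(len(seq) - L + 1))
                segment = seq[start : start + L]
                if not contains_hcsp(segment, pattern):
                    records.append(
                        UnitRecord(segment, "negative", f"bg{i}:{start + 1}-{start + L}")
                    )
                    break
            else:
                raise RuntimeError(
                    f"could not sample an HCSP-free segment of length {L} "
                    f"within {NEGATIVE_SAMPLING_CAP} attempts"
                )
            if not eligible:
                raise RuntimeError(f"no background sequence of length >= {L}")
    return records


def _by_stratum(records: list[UnitRecord]) -> dict[int, list[UnitRecord]]:
    strata: dict[int, list[UnitRecord]] = {}
    for r in records:
        strata.setdefault(len(r.sequence), []).append(r)
    return strata


def make_splits(
    positives: list[UnitRecord],
    negatives: list[UnitRecord],
    spec: SplitSpec | None = None,
) -> SplitDataset:
    """Stratified 80/20 split plus five folds, keeping per-length 1:1 balance.

    Requires per-length positive and negative counts to be equal.  Within
    each (length, class) stratum records are shuffled with the spec seed,
    ``round((1 - train_fraction) * n)`` go to the test set and the remainder
    are dealt round-robin into the folds, so every partition preserves the
    balance up to rounding.
    """
    spec = spec or SplitSpec()
    pos_strata = _by_stratum(positives)
    neg_strata = _by_stratum(negatives)
    pos_counts = {L: len(v) for L, v in pos_strata.items()}
    neg_counts = {L: len(v) for L, v in neg_strata.items()}
    if pos_counts != neg_counts:
        raise ValueError(
            f"per-length class counts differ: positives {pos_counts}, "
            f"negatives {neg_counts}"
        )
    rng = np.random.default_rng(spec.seed)
    folds: list[list[UnitRecord]] = [[] for _ in range(spec.n_folds)]
    test: list[UnitRecord] = []
    offset = 0
    for L in sorted(pos_strata):
        for stratum in (pos_strata[L], neg_strata[L]):
            order = rng.permutation(len(stratum))
            n_test = round((1 - spec.train_fraction) * len(stratum))
            for j, idx in enumerate(order):
                if j < n_test:
                    test.append(stratum[idx])
                else:
                    folds[(offset + j - n_test) % spec.n_folds].append(stratum[idx])
            offset += max(0, len(stratum) - n_test)
    return SplitDataset(folds=folds, test=test)


# ---------------------------------------------------------------------------
# on-disk formats: two-column TSV for unit datasets, JSON for split manifests

def write_units_tsv(records: list[UnitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tlabel\tsource_id\n")
        for r in records:
            fh.write(f"{r.sequence}\t{r.label}\t{r.source_id}\n")


def read_units_tsv(path: str | Path) -> list[UnitRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sequence", "label"]:
            raise ValueError(f"{path}: expected header 'sequence\\tlabel[...]'")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            records.append(
                UnitRecord(parts[0], parts[1], parts[2] if len(parts) > 2 else "")
            )
    return records


def write_split_manifest(split: SplitDataset, seed: int, path: str | Path) -> None:
    payload = {
        "seed": seed,
        "folds": [[r.source_id for r in fold] for fold in split.folds],
        "test": [r.source_id for r in split.test],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
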