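"""Whole-protein LRR unit and domain calling.

Phase one scores every 20-30 aa window of a protein with the convolutional
classifier (up to 11 candidate windows per start position).  Phase two
assembles unit calls into domains under three knobs:

* ``Lscp`` (score control): a start position survives only if at least Lscp
  of its windows score at or above the LPS threshold.
* 20-aa segmentation: the protein is divided into fixed consecutive 20-aa
  segments anchored at residue 1; within each segment only the surviving
  start whose 20-mer window has the largest LPS is kept (ties to the
  smallest start).
* ``Ldcp`` (distance control): consecutive kept starts whose 20-mer units
  are separated by more than Ldcp intervening residues
  (``next.start - prev.start - 20``) fall into different groups.
* ``Lncp`` (number control): groups with fewer than Lncp units are dropped.
* Unit resolution: within a surviving group each start contributes its
  highest-LPS window; overlaps are resolved greedily by descending LPS
  (ties to smaller start, then shorter length), a start falling back to its
  best non-overlapping window or dropping out entirely.  The Lncp filter is
  re-applied afterwards so every reported domain keeps >= Lncp units.

Defaults Lscp=4, Ldcp=9, Lncp=3 with LPS threshold 0.5.  All coordinates
are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cnn import ConvUnitClassifier
from .encoding import MAX_UNIT_LENGTH, MIN_UNIT_LENGTH


@dataclass(frozen=True)
class CandidateWindow:
    start: int  # 1-based
    length: int
    lps: float

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class AssemblyParams:
    lscp: int = 4
    ldcp: int = 9
    lncp: int = 3
    lps_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.lscp <= 11:
            raise ValueError("lscp must be in [1, 11]")
        if self.ldcp < 0:
            raise ValueError("ldcp must be non-negative")
        if self.lncp < 1:
            raise ValueError("lncp must be >= 1")


@dataclass(frozen=True)
class LRRUnitCall:
    start: int
    end: int
    lps: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LRRDomainCall:
    units: tuple[LRRUnitCall, ...]

    @property
    def start(self) -> int:
        return self.units[0].start

    @property
    def end(self) -> int:
        return self.units[-1].end


def scan_windows(
    protein: str,
    model: ConvUnitClassifier | None = None,
    score_fn=None,
) -> list[CandidateWindow]:
    """Score every (start, length) window with 20 <= length <= 30.

    ``score_fn`` (a callable mapping a list of peptide strings to scores)
    may replace the model, e.g. for oracle scoring in benchmarks.  Proteins
    shorter than 20 aa yield no windows.
    """
    windows: list[tuple[int, int]] = []
    n = len(protein)
    for start in range(1, n - MIN_UNIT_LENGTH + 2):
        for length in range(MIN_UNIT_LENGTH, MAX_UNIT_LENGTH + 1):
            if start + length - 1 <= n:
                windows.append((start, length))
    if not windows:
        return []
    if score_fn is None:
        if model is None:
            raise ValueError("either a model or a score_fn is required")
        score_fn = model.score_sequences
    peptides = [protein[s - 1 : s - 1 + L] for s, L in windows]
    scores = score_fn(peptides)
    return [
        CandidateWindow(s, L, float(lps))
        for (s, L), lps in zip(windows, scores)
    ]


def _windows_by_start(
    windows: list[CandidateWindow],
) -> dict[int, list[CandidateWindow]]:
    by_start: dict[int, list[CandidateWindow]] = {}
    for w in windows:
        by_start.setdefault(w.start, []).append(w)
    return by_start


def local_filter(
    windows: list[CandidateWindow], params: AssemblyParams
) -> list[int]:
    """Starts where >= Lscp windows reach the LPS threshold, ascending."""
    survivors = []
    for start, ws in sorted(_windows_by_start(windows).items()):
        k = sum(w.lps >= params.lps_threshold for w in ws)
        if k >= params.lscp:
            survivors.append(start)
    return survivors


def segment_select(
    surviving_starts: list[int],
    windows: list[CandidateWindow],
    params: AssemblyParams,
) -> list[int]:
    """Keep, per fixed 20-aa segment, the start with the largest 20-mer LPS.

    Segments are [1,20], [21,40], ... anchored at residue 1; a trailing
    partial segment is treated like a full one.  Ties go to the smallest
    start.
    """
    lps20 = {
        w.start: w.lps for w in windows if w.length == MIN_UNIT_LENGTH
    }
    best: dict[int, int] = {}  # segment index -> chosen start
    for start in sorted(surviving_starts):
        seg = (start - 1) // 20
        if seg not in best or lps20[start] > lps20[best[seg]]:
            best[seg] = start
    return [best[seg] for seg in sorted(best)]


def group_by_distance(
    kept_starts: list[int], params: AssemblyParams
) -> list[list[int]]:
    """Split sorted starts where the 20-mer gap (next - prev - 20) exceeds Ldcp."""
    groups: list[list[int]] = []
    for start in sorted(kept_starts):
        if groups and start - groups[-1][-1] - 20 <= params.ldcp:
            groups[-1].append(start)
        else:
            groups.append([start])
    return groups


def filter_groups(
    groups: list[list[int]], params: AssemblyParams
) -> list[list[int]]:
    """Drop groups with fewer than Lncp units."""
    return [g for g in groups if len(g) >= params.lncp]


def resolve_units(
    group: list[int],
    windows: list[CandidateWindow],
    params: AssemblyParams,
) -> list[LRRUnitCall]:
    """Emit one non-overlapping unit per start, greedily by descending LPS.

    Candidates at a start are its windows scoring >= the LPS threshold.  All
    candidates across the group are visited in order of (-lps, start,
    length); the first candidate of a start that does not overlap an
    already-emitted unit is emitted, so a start whose best window clashes
    falls back to its best non-overlapping one and drops out if none exists.
    """
    by_start = _windows_by_start(windows)
    candidates = [
        w
        for start in group
        for w in by_start.get(start, [])
        if w.lps >= params.lps_threshold
    ]
    candidates.sort(key=lambda w: (-w.lps, w.start, w.length))
    emitted: list[LRRUnitCall] = []
    resolved: set[int] = set()
    for w in candidates:
        if w.start in resolved:
            continue
        if all(w.end < u.start or w.start > u.end for u in emitted):
            emitted.append(LRRUnitCall(w.start, w.end, w.lps))
            resolved.add(w.start)
    return sorted(emitted, key=lambda u: u.start)


def assemble(
    windows: list[CandidateWindow],
    params: AssemblyParams | None = None,
) -> list[LRRDomainCall]:
    """Run the full assembly phase over pre-scored windows."""
    params = params or AssemblyParams()
    surviving = local_filter(windows, params)
    kept = segment_select(surviving, windows, params)
    groups = filter_groups(group_by_distance(kept, params), params)
    domains = []
    for group in groups:
        units = resolve_units(group, windows, params)
        if len(units) >= params.lncp:  # resolution may drop clashing starts
            domains.append(LRRDomainCall(units=tuple(units)))
    return domains


def predict_protein(
    protein: str,
    model: ConvUnitClassifier | None = None,
    params: AssemblyParams | None = None,
    score_fn=None,
) -> list[LRRDomainCall]:
    """Score all windows of a protein and assemble LRR domain calls."""
    return assemble(scan_windows(protein, model, score_fn), params)
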