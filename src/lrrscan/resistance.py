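"""Domain-architecture classification of plant resistance proteins.

Combines called LRR domains with externally produced annotations (Pfam-style
domain hits, transmembrane segments, signal-peptide calls, consumed as
tables — the upstream tools are never executed) to label each protein:

* ``NLR``   — NB-ARC domain (PF00931) plus at least one LRR domain; with a
  TIR domain (PF01582) the label refines to ``TNL``.  Coiled-coil subtyping
  (CNL) is out of scope since the CC domain has no Pfam model.
* ``LRR-RLK`` — signal peptide + LRR domain + >= 1 transmembrane segment +
  kinase domain (PF00069 or PF07714).
* ``LRR-RLP`` — same but without a kinase domain.
* ``LRR-other`` / ``other`` — LRR only, or none of the above.

NLR rules take precedence over the receptor rules.  Non-canonical domains
are all remaining Pfam hits that are not class-defining and do not lie
mostly (> 50% of the hit) inside a called LRR unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .caller import LRRDomainCall

PFAM_TIR = "PF01582"
PFAM_NBARC = "PF00931"
PFAM_KINASES = ("PF00069", "PF07714")
CANONICAL_PFAM = frozenset({PFAM_TIR, PFAM_NBARC, *PFAM_KINASES})


@dataclass(frozen=True)
class PfamHit:
    accession: str
    name: str
    start: int
    end: int

    @property
    def base_accession(self) -> str:
        return self.accession.split(".")[0]


@dataclass
class DomainAnnotation:
    protein_id: str
    pfam_hits: list[PfamHit] = field(default_factory=list)
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    has_signal_peptide: bool = False
    lrr_domains: list[LRRDomainCall] = field(default_factory=list)


@dataclass(frozen=True)
class ProteinClass:
    label: str  # TNL | NLR | LRR-RLK | LRR-RLP | LRR-other | other
    evidence: tuple[str, ...]


def _has_pfam(ann: DomainAnnotation, accessions) -> bool:
    wanted = {a.split(".")[0] for a in (
        accessions if isinstance(accessions, (tuple, list, set)) else [accessions]
    )}
    return any(h.base_accession in wanted for h in ann.pfam_hits)


def classify(ann: DomainAnnotation) -> ProteinClass:
    """Label a protein by its domain architecture (pure function)."""
    has_lrr = bool(ann.lrr_domains)
    has_nbarc = _has_pfam(ann, PFAM_NBARC)
    has_tir = _has_pfam(ann, PFAM_TIR)
    has_kinase = _has_pfam(ann, PFAM_KINASES)
    has_tm = bool(ann.tm_segments)
    evidence = [
        f"lrr_domain:{'present' if has_lrr else 'absent'}",
        f"nb_arc:{'present' if has_nbarc else 'absent'}",
        f"tir:{'present' if has_tir else 'absent'}",
        f"signal_peptide:{'present' if ann.has_signal_peptide else 'absent'}",
        f"tm_segments:{len(ann.tm_segments)}",
        f"kinase:{'present' if has_kinase else 'absent'}",
    ]
    if has_nbarc and has_lrr:
        label = "TNL" if has_tir else "NLR"
    elif ann.has_signal_peptide and has_lrr and has_tm and has_kinase:
        label = "LRR-RLK"
    elif ann.has_signal_peptide and has_lrr and has_tm:
        label = "LRR-RLP"
    elif has_lrr:
        label = "LRR-other"
    else:
        label = "other"
    return ProteinClass(label=label, evidence=tuple(evidence))


def noncanonical_domains(ann: DomainAnnotation) -> list[PfamHit]:
    """Pfam hits that are neither class-defining nor mostly inside LRR units.

    A hit is excluded when more than 50% of its span overlaps called LRR
    units (units are disjoint, so per-unit overlaps add up).
    """
    unit_spans = [
        (u.start, u.end) for d in ann.lrr_domains for u in d.units
    ]
    out = []
    for hit in ann.pfam_hits:
        if hit.base_accession in CANONICAL_PFAM:
            continue
        length = hit.end - hit.start + 1
        covered = sum(
            max(0, min(hit.end, e) - max(hit.start, s) + 1) for s, e in unit_spans
        )
        if covered > 0.5 * length:
            continue
        out.append(hit)
    return out


# ---------------------------------------------------------------------------
# adapters for the upstream tools' tabular outputs


def _error(path, lineno, msg):
    return ValueError(f"{path}:{lineno}: {msg}")


def parse_pfam_table(path: str | Path) -> dict[str, list[PfamHit]]:
    """Parse Pfam hits from hmmscan --domtblout or a simple 5-column TSV.

    domtblout rows (>= 23 whitespace-separated fields) contribute the
    envelope coordinates; the simple format is
    ``protein_id  accession  name  start  end``.  Lines starting with '#'
    are ignored, unknown extra columns tolerated.
    """
    hits: dict[str, list[PfamHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) >= 23:  # hmmscan domtblout
                    name, acc, protein = fields[0], fields[1], fields[3]
                    start, end = int(fields[19]), int(fields[20])
                else:
                    protein, acc, name = fields[0], fields[1], fields[2]
                    start, end = int(fields[3]), int(fields[4])
            except (IndexError, ValueError):
                raise _error(path, lineno, f"malformed Pfam line: {line!r}")
            hits.setdefault(protein, []).append(PfamHit(acc, name, start, end))
    return hits


def parse_tm_table(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Parse transmembrane segments (TMHMM long format or a simple TSV).

    Any non-comment line mentioning ``TMhelix`` contributes its final two
    integers as a segment; otherwise ``protein_id  start  end`` is expected.
    """
    segments: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            try:
                if "TMhelix" in fields:
                    start, end = int(fields[-2]), int(fields[-1])
                    segments.setdefault(fields[0], []).append((start, end))
                elif "inside" in fields or "outside" in fields:
                    continue  # TMHMM topology lines without a helix
                elif len(fields) >= 3:
                    segments.setdefault(fields[0], []).append(
                        (int(fields[1]), int(fields[2]))
                    )
                else:
                    raise ValueError
            except (IndexError, ValueError):
                raise _error(path, lineno, f"malformed TM line: {line!r}")
    return segments


def parse_sp_table(path: str | Path) -> dict[str, bool]:
    """Parse signal-peptide calls (SignalP-style summary or a simple TSV).

    A protein has a signal peptide when its prediction field starts with
    ``SP`` (e.g. ``SP(Sec/SPI)``) or equals ``1``/``true``/``yes``.
    """
    calls: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise _error(path, lineno, f"malformed signal-peptide line: {line!r}")
            value = fields[1]
            calls[fields[0]] = value.upper().startswith("SP") or value.lower() in (
                "1",
                "true",
                "yes",
            )
    return calls


def build_annotations(
    protein_ids: list[str],
    lrr_calls: dict[str, list[LRRDomainCall]],
    pfam: dict[str, list[PfamHit]] | None = None,
    tm: dict[str, list[tuple[int, int]]] | None = None,
    sp: dict[str, bool] | None = None,
) -> list[DomainAnnotation]:
    """Merge per-source fragments into one DomainAnnotation per protein."""
    pfam, tm, sp = pfam or {}, tm or {}, sp or {}
    return [
        DomainAnnotation(
            protein_id=pid,
            pfam_hits=pfam.get(pid, []),
            tm_segments=tm.get(pid, []),
            has_signal_peptide=sp.get(pid, False),
            lrr_domains=lrr_calls.get(pid, []),
        )
        for pid in protein_ids
    ]
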