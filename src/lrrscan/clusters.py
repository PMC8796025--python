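"""Gene-cluster and tandem-repeat detection over gene coordinate tables.

Target genes (e.g. LRR-RLKs) on one chromosome form a gene cluster when
consecutive targets are separated by less than 200 kb (end-to-start
intergenic distance) and by no more than 8 non-target genes; maximal chains
of at least two targets are reported.  Tandem repeats use the stricter rule:
adjacent targets closer than 100 kb whose protein sequences are more than
70% identical under a global alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

from Bio import Align


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chromosome: str
    start: int  # bp, 1-based inclusive
    end: int
    is_target: bool = False
    sequence: str | None = None  # protein sequence, for tandem identity

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class ClusterParams:
    max_gap_bp: int = 200_000
    max_intervening: int = 8
    tandem_max_gap_bp: int = 100_000
    tandem_min_identity: float = 0.70

    def __post_init__(self) -> None:
        if min(self.max_gap_bp, self.tandem_max_gap_bp) <= 0:
            raise ValueError("distance thresholds must be positive")
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be non-negative")


def _sorted_chromosome(genes: list[GeneRecord]) -> list[GeneRecord]:
    chroms = {g.chromosome for g in genes}
    if len(chroms) > 1:
        raise ValueError(f"expected genes from one chromosome, got {sorted(chroms)}")
    return sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))


def find_clusters(
    genes: list[GeneRecord], params: ClusterParams | None = None
) -> list[list[GeneRecord]]:
    """Maximal chains of >= 2 target genes satisfying both adjacency rules.

    The chain between consecutive target genes breaks when the intergenic
    distance (``next.start - prev.end``) reaches ``max_gap_bp`` or more than
    ``max_intervening`` non-target genes lie between them in genomic order.
    """
    params = params or ClusterParams()
    ordered = _sorted_chromosome(genes)
    chains: list[list[GeneRecord]] = []
    current: list[GeneRecord] = []
    intervening = 0
    for gene in ordered:
        if not gene.is_target:
            intervening += 1
            continue
        if current:
            gap = gene.start - current[-1].end
            if gap < params.max_gap_bp and intervening <= params.max_intervening:
                current.append(gene)
            else:
                chains.append(current)
                current = [gene]
        else:
            current = [gene]
        intervening = 0
    if current:
        chains.append(current)
    return [c for c in chains if len(c) >= 2]


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment length, symmetric.

    Scoring: match +1, mismatch 0, linear gap -1.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    alignment = aligner.align(seq_a, seq_b)[0]
    matches = sum(
        a == b
        for a, b in zip(alignment[0], alignment[1])
        if a != "-" and b != "-"
    )
    return matches / alignment.length


def find_tandem_repeats(
    genes: list[GeneRecord],
    params: ClusterParams | None = None,
    identity_fn: Callable[[str, str], float] | None = None,
) -> list[list[GeneRecord]]:
    """Maximal chains of adjacent targets < 100 kb apart at > 70% identity.

    Pairs with a missing protein sequence are skipped with a warning.
    """
    params = params or ClusterParams()
    identity_fn = identity_fn or global_identity
    targets = [g for g in _sorted_chromosome(genes) if g.is_target]
    chains: list[list[GeneRecord]] = []
    current: list[GeneRecord] = []
    for gene in targets:
        if current:
            prev = current[-1]
            if prev.sequence is None or gene.sequence is None:
                warnings.warn(
                    f"missing protein sequence for pair ({prev.gene_id}, "
                    f"{gene.gene_id}); pair skipped"
                )
                linked = False
            else:
                gap = gene.start - prev.end
                linked = (
                    gap < params.tandem_max_gap_bp
                    and identity_fn(prev.sequence, gene.sequence)
                    > params.tandem_min_identity
                )
            if linked:
                current.append(gene)
            else:
                chains.append(current)
                current = [gene]
        else:
            current = [gene]
    if current:
        chains.append(current)
    return [c for c in chains if len(c) >= 2]
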