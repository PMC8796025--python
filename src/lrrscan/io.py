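"""FASTA / TSV / GFF3 input-output helpers shared by the CLI."""

from __future__ import annotations

import csv
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import LRRDomainCall
from .clusters import GeneRecord
from .synthetic import SyntheticProtein

CALLS_COLUMNS = [
    "protein_id",
    "domain_index",
    "unit_index",
    "start",
    "end",
    "length",
    "lps",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered mapping of record id -> upper-case sequence."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()],
        str(path),
        "fasta",
    )


def write_calls_tsv(
    calls: dict[str, list[LRRDomainCall]], path: str | Path
) -> None:
    """One row per called unit; stable column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CALLS_COLUMNS)
        for pid, domains in calls.items():
            for d_idx, domain in enumerate(domains, start=1):
                for u_idx, unit in enumerate(domain.units, start=1):
                    writer.writerow(
                        [pid, d_idx, u_idx, unit.start, unit.end, unit.length,
                         f"{unit.lps:.6f}"]
                    )


def read_calls_tsv(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Unit intervals per protein from a calls TSV (truth or predictions)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "protein_id" not in reader.fieldnames:
            raise ValueError(f"{path}: missing header with protein_id column")
        for row in reader:
            intervals.setdefault(row["protein_id"], []).append(
                (int(row["start"]), int(row["end"]))
            )
    return intervals


def write_calls_gff3(
    calls: dict[str, list[LRRDomainCall]], path: str | Path
) -> None:
    """GFF3 export (1-based inclusive) with LRR_domain / LRR_unit features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pid, domains in calls.items():
            for d_idx, domain in enumerate(domains, start=1):
                did = f"{pid}.domain{d_idx}"
                fh.write(
                    f"{pid}\tlrrscan\tLRR_domain\t{domain.start}\t{domain.end}"
                    f"\t.\t.\t.\tID={did}\n"
                )
                for u_idx, unit in enumerate(domain.units, start=1):
                    fh.write(
                        f"{pid}\tlrrscan\tLRR_unit\t{unit.start}\t{unit.end}"
                        f"\t{unit.lps:.4f}\t.\t.\tID={did}.unit{u_idx};Parent={did}\n"
                    )


def write_truth_tsv(proteins: list[SyntheticProtein], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\n")
        for p in proteins:
            for start, end in p.true_units:
                fh.write(f"{p.protein_id}\t{start}\t{end}\n")


def read_truth_tsv(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein_id", "start", "end"]:
            raise ValueError(f"{path}: expected header protein_id\\tstart\\tend")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            intervals.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return intervals


def read_gene_table(
    path: str | Path, target_ids: set[str], sequences: dict[str, str] | None = None
) -> dict[str, list[GeneRecord]]:
    """Genes per chromosome from a 4-column TSV (gene_id, chrom, start, end)."""
    sequences = sequences or {}
    per_chrom: dict[str, list[GeneRecord]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["gene_id", "chrom", "start", "end"]:
            raise ValueError(f"{path}: expected header gene_id\\tchrom\\tstart\\tend")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end = int(parts[2]), int(parts[3])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad coordinates {parts[2:4]}")
            gene = GeneRecord(
                gene_id=parts[0],
                chromosome=parts[1],
                start=start,
                end=end,
                is_target=parts[0] in target_ids,
                sequence=sequences.get(parts[0]),
            )
            per_chrom.setdefault(gene.chromosome, []).append(gene)
    return per_chrom


def write_gene_sets_tsv(
    sets_by_kind: dict[str, list[list[GeneRecord]]], path: str | Path
) -> None:
    """Clusters and tandem sets as TSV: kind, set_id, chrom, span, members."""
    with open(path, "w") as fh:
        fh.write("kind\tset_id\tchrom\tstart\tend\tn_genes\tmembers\n")
        for kind, sets in sets_by_kind.items():
            for i, members in enumerate(sets, start=1):
                fh.write(
                    f"{kind}\t{kind}_{i}\t{members[0].chromosome}"
                    f"\t{members[0].start}\t{members[-1].end}\t{len(members)}"
                    f"\t{','.join(g.gene_id for g in members)}\n"
                )


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
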