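"""File-format helpers (FASTA, gene-model TSV)."""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .community import Community, GeneModel, Genome


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[Tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def write_gene_models(path, genome: Genome) -> None:
    """GFF3-like TSV: seqid, start, end, strand, id, copy_class (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open\n")
        fh.write("seqid\tstart\tend\tstrand\tid\tcopy_class\n")
        for g in genome.genes:
            fh.write(
                f"{genome.genome_id}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{g.gene_id}\t{g.copy_class}\n"
            )


def read_gene_models(path, genome_id: str) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("seqid"):
                continue
            seqid, start, end, strand, gid, copy_class = line.rstrip("\n").split("\t")
            if seqid != genome_id:
                continue
            genes.append(GeneModel(gid, int(start), int(end), strand, copy_class))
    return genes


def write_references(path, community: Community) -> None:
    write_fasta(
        path,
        ((gid, g.sequence) for gid, g in sorted(community.genomes.items())),
    )
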