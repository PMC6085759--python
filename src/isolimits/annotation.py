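"""GTF / FASTA serialization of synthetic transcriptomes.

Internal coordinates are 0-based half-open; they are converted to the GTF
convention (1-based, inclusive) only at this boundary.  Reading goes through
``gffutils`` (GTF) and Biopython (FASTA); writing is plain text emission from
the in-memory types.
"""

from __future__ import annotations


import gffutils
from Bio.Seq import Seq

from .transcriptome import Exon, Gene, Isoform, Transcriptome

__all__ = [
    "write_gtf",
    "write_genome_fasta",
    "write_transcript_fasta",
    "write_annotation",
    "transcript_sequence",
    "read_gtf",
]

_SOURCE = "isolimits"


def transcript_sequence(tx: Transcriptome, isoform: Isoform) -> str:
    """Spliced, strand-corrected transcript sequence of ``isoform``."""
    chrom_seq = tx.genome[isoform.chrom]
    spliced = b"".join(chrom_seq[e.start:e.end] for e in isoform.exons)
    seq = spliced.decode("ascii")
    if isoform.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def write_gtf(tx: Transcriptome, path) -> None:
    """GTF 2.2 with one transcript feature plus exon features per isoform."""
    with open(path, "w") as fh:
        for gene in tx.genes:
            for iso in gene.isoforms:
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{iso.isoform_id}";'
                )
                s, e = iso.span
                fh.write(
                    f"{iso.chrom}\t{_SOURCE}\ttranscript\t{s + 1}\t{e}\t.\t"
                    f"{iso.strand}\t.\t{attrs}\n"
                )
                for ex in iso.exons:
                    fh.write(
                        f"{ex.chrom}\t{_SOURCE}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{ex.strand}\t.\t{attrs}\n"
                    )


def _write_fasta_record(fh, name: str, seq: str, width: int = 60) -> None:
    fh.write(f">{name}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i:i + width] + "\n")


def write_genome_fasta(tx: Transcriptome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in tx.genome.items():
            _write_fasta_record(fh, chrom, seq.decode("ascii"), width)


def write_transcript_fasta(tx: Transcriptome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for iso in tx.isoforms():
            _write_fasta_record(fh, iso.isoform_id, transcript_sequence(tx, iso), width)


def write_annotation(
    tx: Transcriptome, gtf_path, genome_fasta=None, transcript_fasta=None
) -> None:
    """Emit the GTF and, optionally, genome and transcript FASTA files."""
    write_gtf(tx, gtf_path)
    if genome_fasta is not None:
        write_genome_fasta(tx, genome_fasta)
    if transcript_fasta is not None:
        write_transcript_fasta(tx, transcript_fasta)


def read_gtf(path) -> Transcriptome:
    """Re-read a GTF written by :func:`write_gtf` into gene/isoform structures.

    The genome map is left empty; only coordinates are recovered.
    """
    db = gffutils.create_db(
        str(path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict[str, list[Exon]]] = {}
    for feat in db.features_of_type("exon"):
        gene_id = feat.attributes["gene_id"][0]
        iso_id = feat.attributes["transcript_id"][0]
        exon = Exon(feat.seqid, feat.start - 1, feat.end, feat.strand)
        by_gene.setdefault(gene_id, {}).setdefault(iso_id, []).append(exon)
    genes = []
    for gene_id in sorted(by_gene):
        isoforms = tuple(
            Isoform(iso_id, gene_id, tuple(sorted(exons, key=lambda e: e.start)))
            for iso_id, exons in sorted(by_gene[gene_id].items())
        )
        genes.append(Gene(gene_id, isoforms))
    return Transcriptome(tuple(genes), {}, {"source": str(path)})
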