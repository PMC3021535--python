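"""File formats: FASTA, GFF3, BED, and the pipeline's TSV tables.

Internal coordinates are 0-based half-open; GFF3 is emitted 1-based inclusive
per the standard and BED 0-based half-open. GFF3 is read back through
gffutils; FASTA through pyfaidx.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .annotation import GeneModel, GenomeAnnotation, Isoform
from .segments import BoundSegment, segments_to_frame, frame_to_segments


def write_fasta(genome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    fasta = Fasta(str(path), build_index=True, rebuild=True)
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_lengths[chrom]}\n")
        for gene in sorted(annotation.genes, key=lambda g: (g.chrom, g.span[0])):
            gs, ge = gene.span
            fh.write(
                f"{gene.chrom}\thsfchip\tgene\t{gs + 1}\t{ge}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for iso in gene.isoforms:
                fh.write(
                    f"{gene.chrom}\thsfchip\tmRNA\t{iso.start + 1}\t{iso.end}\t.\t"
                    f"{iso.strand}\t.\tID={iso.isoform_id};Parent={gene.gene_id}\n"
                )
                for k, (es, ee) in enumerate(iso.exons, start=1):
                    fh.write(
                        f"{gene.chrom}\thsfchip\texon\t{es + 1}\t{ee}\t.\t{iso.strand}"
                        f"\t.\tID={iso.isoform_id}.exon{k};Parent={iso.isoform_id}\n"
                    )


def read_gff3(path, chrom_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    if chrom_lengths is None:
        chrom_lengths = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _start, end = line.split()
                    chrom_lengths[chrom] = int(end)
                elif not line.startswith("#"):
                    break
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        # a header-only file is a valid empty annotation
        return GenomeAnnotation([], chrom_lengths)
    genes: list[GeneModel] = []
    for gene_feat in db.features_of_type("gene"):
        isoforms = []
        for mrna in db.children(gene_feat, featuretype="mRNA"):
            exons = [
                (exon.start - 1, exon.end)
                for exon in db.children(mrna, featuretype="exon")
            ]
            isoforms.append(
                Isoform(
                    isoform_id=mrna.id,
                    start=mrna.start - 1,
                    end=mrna.end,
                    strand=mrna.strand,
                    exons=exons,
                )
            )
        if not isoforms:
            isoforms = [
                Isoform(
                    isoform_id=gene_feat.id + ".t1",
                    start=gene_feat.start - 1,
                    end=gene_feat.end,
                    strand=gene_feat.strand,
                    exons=[(gene_feat.start - 1, gene_feat.end)],
                )
            ]
        genes.append(
            GeneModel(
                gene_id=gene_feat.id,
                chrom=gene_feat.seqid,
                strand=gene_feat.strand,
                isoforms=isoforms,
            )
        )
    if not chrom_lengths:
        chrom_lengths = {}
        for gene in genes:
            chrom_lengths[gene.chrom] = max(
                chrom_lengths.get(gene.chrom, 0), gene.span[1]
            )
    return GenomeAnnotation(genes, chrom_lengths)


# --- tabular formats ---------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_probes_bed(probes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(probes.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tprobe{i}\n")


def write_segments(segments: list[BoundSegment], path) -> None:
    write_tsv(segments_to_frame(segments), path)


def read_segments(path) -> list[BoundSegment]:
    return frame_to_segments(read_tsv(path))


def write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, set):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
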