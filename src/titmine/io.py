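"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates on disk are 1-based fully closed, matching GFF3 and
BLAST tabular conventions.  Every writer accepts ``comments`` — lines emitted
with a leading ``#`` so a stage can stamp its name, parameters and seed into
its outputs; every reader skips ``#`` lines.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import ContigAlignment, Feature, Gene, GenomeAnnotation

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

SNP_COLUMNS = [
    "contig_id", "position", "ref_allele", "alt_allele", "depth",
    "minor_count", "snp_quality", "min_neighbour_quality", "is_indel",
]


def _write_comments(handle, comments: Sequence[str] | None) -> None:
    for line in comments or ():
        handle.write(f"# {line}\n")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        path,
        "fasta",
    )


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# GFF3 + chrom.sizes

def write_gff3(path: str, genome: GenomeAnnotation, comments: Sequence[str] | None = None) -> None:
    """Emit genes and their tiled features (1-based closed, GFF3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        _write_comments(fh, comments)
        for chrom, length in genome.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene in sorted(genome.genes, key=lambda g: (g.chromosome, g.start)):
            fh.write(
                f"{gene.chromosome}\ttitmine\tgene\t{gene.start}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.id}\n"
            )
            for feat in sorted(gene.features, key=lambda f: f.start):
                fid = f"{gene.id}.{feat.type}.{feat.ordinal}"
                fh.write(
                    f"{gene.chromosome}\ttitmine\t{feat.type}\t{feat.start}\t{feat.end}\t.\t"
                    f"{gene.strand}\t.\tID={fid};Parent={gene.id};ordinal={feat.ordinal}\n"
                )


def read_gff3(gff_path: str, chrom_sizes_path: str) -> GenomeAnnotation:
    """Round-trip reader for the annotation written by :func:`write_gff3`."""
    sizes = read_chrom_sizes(chrom_sizes_path)
    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        db_path = tmp.name
    try:
        db = gffutils.create_db(
            gff_path, db_path, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for g in db.features_of_type("gene"):
            feats = tuple(
                Feature(
                    type=child.featuretype,
                    start=child.start,
                    end=child.end,
                    ordinal=int(child.attributes["ordinal"][0]),
                )
                for child in db.children(g.id)
            )
            genes.append(
                Gene(id=g.id, chromosome=g.seqid, strand=g.strand,
                     start=g.start, end=g.end, features=feats)
            )
    finally:
        os.unlink(db_path)
    genes.sort(key=lambda g: (g.chromosome, g.start, g.id))
    return GenomeAnnotation(chromosomes=sizes, genes=genes)


def write_chrom_sizes(path: str, chromosomes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, length in chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, length = line.split("\t")[:2]
            sizes[chrom] = int(length)
    return sizes


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

def write_outfmt6(path: str, records: pd.DataFrame, comments: Sequence[str] | None = None) -> None:
    records = records[OUTFMT6_COLUMNS]
    with open(path, "w") as fh:
        _write_comments(fh, comments)
        records.to_csv(fh, sep="\t", header=False, index=False)


def read_outfmt6(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")


def alignments_to_outfmt6(alignments: Iterable[ContigAlignment], contig_lengths: dict[str, int]) -> pd.DataFrame:
    """Express placement intervals as single full-length HSP rows."""
    rows = []
    for aln in alignments:
        qlen = contig_lengths[aln.contig_id]
        rows.append({
            "qseqid": aln.contig_id, "sseqid": aln.chromosome,
            "pident": aln.percent_identity, "length": qlen,
            "mismatch": round(qlen * (100 - aln.percent_identity) / 100),
            "gapopen": 0, "qstart": 1, "qend": qlen,
            "sstart": aln.start, "send": aln.end,
            "evalue": aln.e_value, "bitscore": round(2 * qlen * aln.percent_identity / 100, 1),
        })
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def outfmt6_to_alignments(records: pd.DataFrame) -> list[ContigAlignment]:
    out = []
    for row in records.itertuples(index=False):
        s, e = int(row.sstart), int(row.send)
        out.append(ContigAlignment(
            contig_id=str(row.qseqid), chromosome=str(row.sseqid),
            start=min(s, e), end=max(s, e),
            percent_identity=float(row.pident), e_value=float(row.evalue),
        ))
    return out


# ---------------------------------------------------------------------------
# Expression matrix TSV

def write_expression(path: str, counts: pd.DataFrame, library_sizes: pd.Series,
                     comments: Sequence[str] | None = None) -> None:
    """First header row = tissue ids, second = library sizes, then counts."""
    with open(path, "w") as fh:
        _write_comments(fh, comments)
        fh.write("contig_id\t" + "\t".join(map(str, counts.columns)) + "\n")
        fh.write("library_size\t" + "\t".join(str(int(library_sizes[t])) for t in counts.columns) + "\n")
        counts.to_csv(fh, sep="\t", header=False)


def read_expression(path: str):
    from .models import ExpressionMatrix

    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    tissues = lines[0].rstrip("\n").split("\t")[1:]
    sizes = [int(x) for x in lines[1].rstrip("\n").split("\t")[1:]]
    rows, index = [], []
    for ln in lines[2:]:
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        index.append(parts[0])
        rows.append([int(x) for x in parts[1:]])
    counts = pd.DataFrame(rows, index=index, columns=tissues)
    counts.index.name = "contig_id"
    return ExpressionMatrix(counts=counts, library_sizes=pd.Series(sizes, index=tissues))


# ---------------------------------------------------------------------------
# Generic TSV helpers (SNP tables, truth labels, reports)

def write_tsv(path: str, frame: pd.DataFrame, comments: Sequence[str] | None = None,
              index: bool = False) -> None:
    with open(path, "w") as fh:
        _write_comments(fh, comments)
        frame.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
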