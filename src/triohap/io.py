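"""Format readers/writers shared by all pipeline stages.

FASTA/FASTQ go through Biopython's SeqIO. GFF3 and VCF are 1-based
inclusive on disk, BED 0-based half-open; all internal coordinates are
0-based half-open and the conversions here are involutive.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simdata import SimRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_gff3",
    "write_gff3",
    "write_bed6",
    "read_bed6",
    "write_vcf_minimal",
    "read_vcf_minimal",
    "read_tsv",
    "write_tsv",
    "read_pileup",
    "write_pileup",
    "to_internal",
    "to_external",
]


class FormatError(ValueError):
    """Malformed record, with file/line context in the message."""


def to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_inclusive


def to_external(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> str:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
    return str(path)


def read_fastq(path) -> list[SimRead]:
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(SimRead(rec.description or rec.id, str(rec.seq), qual))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads, path) -> str:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
    return str(path)


_GFF_COLS = ["seq_id", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def write_gff3(gene_models: pd.DataFrame, path) -> str:
    """Gene models (internal 0-based half-open) -> GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in gene_models.itertuples(index=False):
            start, end = to_external(int(row.start), int(row.end))
            fh.write(
                f"{row.seq_id}\ttriohap\tgene\t{start}\t{end}\t.\t{row.strand}\t.\t"
                f"ID={row.gene_id}\n"
            )
    return str(path)


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            start, end = to_internal(int(parts[3]), int(parts[4]))
            rows.append(
                {
                    "gene_id": attrs.get("ID", f"feature{lineno}"),
                    "seq_id": parts[0],
                    "start": start,
                    "end": end,
                    "strand": parts[6],
                }
            )
    df = pd.DataFrame(rows, columns=["gene_id", "seq_id", "start", "end", "strand"])
    df["rank"] = df.groupby("seq_id").cumcount() if len(df) else pd.Series(dtype=int)
    return df


def write_bed6(regions, path) -> str:
    """Telomere regions (or similar) to BED6; score column = repeat count."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"telomere_{r.seq_id}_{r.start}"
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{name}\t{r.n_repeats}\t{r.strand}\n")
    return str(path)


def read_bed6(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            rows.append(
                {
                    "seq_id": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "name": parts[3],
                    "score": int(parts[4]),
                    "strand": parts[5],
                }
            )
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "name", "score", "strand"])


def write_vcf_minimal(diag_snps: pd.DataFrame, path) -> str:
    """Diagnostic SNPs to a minimal VCF (REF = maternal, ALT = paternal,
    parental origin in INFO). Internal 0-based positions become 1-based."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MAT,Number=1,Type=String,Description="Maternal allele">\n')
        fh.write('##INFO=<ID=PAT,Number=1,Type=String,Description="Paternal allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in diag_snps.itertuples(index=False):
            fh.write(
                f"{row.seq_id}\t{row.pos + 1}\t.\t{row.maternal}\t{row.paternal}\t.\tPASS\t"
                f"MAT={row.maternal};PAT={row.paternal}\n"
            )
    return str(path)


def read_vcf_minimal(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}:{lineno}: expected >= 8 VCF columns")
            rows.append(
                {
                    "seq_id": parts[0],
                    "pos": int(parts[1]) - 1,
                    "maternal": parts[3],
                    "paternal": parts[4],
                }
            )
    return pd.DataFrame(rows, columns=["seq_id", "pos", "maternal", "paternal"])


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> str:
    df.to_csv(path, sep="\t", index=index)
    return str(path)


def read_pileup(path) -> pd.DataFrame:
    """Pileup-style TSV: seq_id, pos (1-based), A, C, G, T[, depth]."""
    df = pd.read_csv(path, sep="\t")
    required = {"seq_id", "pos", "A", "C", "G", "T"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing pileup columns {sorted(missing)}")
    if "depth" not in df.columns:
        df["depth"] = df[["A", "C", "G", "T"]].sum(axis=1)
    return df


def write_pileup(df: pd.DataFrame, path) -> str:
    return write_tsv(df, path)
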