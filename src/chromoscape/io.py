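"""Readers and writers for the plain-text interchange formats.

FASTA goes through Biopython; GFF3 and BED writing is deliberately minimal
(gene/mRNA/exon three-level models with a ``family_id`` attribute) because
that is the full vocabulary the pipeline consumes.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AnnotationSet, GeneModel, Genome, Interval

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path: str | Path) -> Genome:
    return Genome({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def write_gff3(annotations: AnnotationSet, path: str | Path, source: str = "chromoscape") -> None:
    lines = ["##gff-version 3"]
    for g in sorted(annotations.genes, key=lambda g: (g.chrom, g.start, g.id)):
        start1, end1 = g.start + 1, g.end  # 1-based inclusive
        attrs = f"ID={g.id}"
        if g.family_id is not None:
            attrs += f";family_id={g.family_id}"
        lines.append(f"{g.chrom}\t{source}\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t{attrs}")
        lines.append(
            f"{g.chrom}\t{source}\tmRNA\t{start1}\t{end1}\t.\t{g.strand}\t.\tID={g.id}.t1;Parent={g.id}"
        )
        lines.append(
            f"{g.chrom}\t{source}\texon\t{start1}\t{end1}\t.\t{g.strand}\t.\tID={g.id}.t1.e1;Parent={g.id}.t1"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> AnnotationSet:
    genes: list[GeneModel] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or fields[2] != "gene":
            continue
        attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
        genes.append(
            GeneModel(
                id=attrs["ID"],
                chrom=fields[0],
                interval=Interval(int(fields[3]) - 1, int(fields[4])),
                strand=fields[6],
                family_id=attrs.get("family_id"),
            )
        )
    return AnnotationSet(genes)


def write_bed(features: list[tuple[str, Interval, str, float]], path: str | Path) -> None:
    """BED6 rows: (chrom, interval, name, score); strand written as '.'."""
    with open(path, "w") as fh:
        for chrom, iv, name, score in features:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t.\n")


def read_bed(path: str | Path) -> list[tuple[str, Interval, str, float]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        name = f[3] if len(f) > 3 else "."
        score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
        out.append((f[0], Interval(int(f[1]), int(f[2])), name, score))
    return out


def write_contact_tsv(matrices: dict, path: str | Path) -> None:
    """Contact matrices as ``chrom<TAB>bin_i<TAB>bin_j<TAB>count`` (upper triangle)."""
    with open(path, "w") as fh:
        for chrom, cm in matrices.items():
            n = cm.counts.shape[0]
            for i in range(n):
                for j in range(i, n):
                    fh.write(f"{chrom}\t{i}\t{j}\t{int(cm.counts[i, j])}\n")


def read_contact_tsv(path: str | Path, bin_size: int):
    import numpy as np

    from .core import ContactMatrix

    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "i", "j", "count"])
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        n = int(max(sub["i"].max(), sub["j"].max())) + 1
        m = np.zeros((n, n), dtype=np.int64)
        m[sub["i"], sub["j"]] = sub["count"]
        m[sub["j"], sub["i"]] = sub["count"]
        out[chrom] = ContactMatrix(chrom=str(chrom), bin_size=bin_size, counts=m)
    return out


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_hits_tsv(path: str | Path) -> pd.DataFrame:
    """12-column tabular homology hits, BLAST outfmt-6 column order."""
    return pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)


def write_hits_tsv(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False, columns=BLAST6_COLUMNS)


def read_config(path: str | Path) -> dict[str, str]:
    """Plain ``key: value`` config text; '#' starts a comment."""
    cfg: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, value = line.split(":", 1)
        cfg[key.strip()] = value.strip()
    return cfg


def genome_to_fasta_string(genome: Genome, width: int = 80) -> str:
    buf = _io.StringIO()
    for name, seq in genome.sequences.items():
        buf.write(f">{name}\n")
        for i in range(0, len(seq), width):
            buf.write(seq[i : i + width] + "\n")
    return buf.getvalue()
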