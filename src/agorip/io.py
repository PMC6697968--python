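"""Readers and writers for the plain-text formats used across the toolkit.

All genomic coordinates are 0-based, half-open, matching BED natively.
FASTQ qualities are Phred+33. Sequence I/O is delegated to Biopython's
``SeqIO``; tables go through pandas so every output is a deterministic TSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass
class Read:
    """A sequencing read: identifier, DNA sequence and per-base Phred scores."""

    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"]))
        )
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qual)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# BED-like tables (loci, gene models)


def write_loci_bed(loci, path: str | Path) -> None:
    """BED6 plus a 7th column carrying the phasing length class (21 or 24)."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.id}\t0\t{loc.strand}"
                f"\t{loc.length_class}\n"
            )


def read_loci_bed(path: str | Path):
    from .profile import PhasiLocus

    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 BED columns, got {len(parts)}")
            chrom, start, end, name, _score, strand, cls = parts[:7]
            loci.append(
                PhasiLocus(
                    id=name,
                    chrom=chrom,
                    strand=strand,
                    start=int(start),
                    end=int(end),
                    length_class=int(cls),
                )
            )
    return loci


def write_genes_bed12(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start = min(s for s, _ in g.exons)
            end = max(e for _, e in g.exons)
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.name}\t0\t{g.strand}\t{start}\t{end}"
                f"\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


def read_genes_bed12(path: str | Path):
    from .simulate import GeneModel

    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns, got {len(parts)}")
            chrom, start, _end, name, _score, strand = parts[:6]
            start = int(start)
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(name=name, chrom=chrom, strand=strand, exons=exons))
    return genes


# ---------------------------------------------------------------------------
# Generic tables


def write_tsv(frame: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Parse a psRNATarget-style miRNA->target TSV.

    The first two columns are taken as miRNA accession and target gene id;
    header lines starting with '#' are skipped. Raises ``ValueError`` naming
    the offending line on malformed rows.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            rows.append((parts[0], parts[1]))
    if rows and rows[0][0].lower() in {"mirna_acc.", "mirna", "mirna_acc"}:
        rows = rows[1:]
    return pd.DataFrame(rows, columns=["mirna", "target"])
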