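"""Hamming-distance read mapping against toy genomes and mature-miRNA catalogs.

The mapper reproduces the alignment contract used for AGO RIP-seq reads —
substitutions only, a caller-set mismatch ceiling (2 for genomic, 1 for
mature-miRNA matching), and best-stratum reporting (all placements at the
minimal achieved mismatch count). It is a seed-and-verify design: reads are
split into ``max_mm + 1`` non-overlapping seed segments, so by pigeonhole any
placement within the mismatch budget has at least one exact seed; candidate
positions come from an exact k-mer index and are verified by direct Hamming
count. Suitable for kilobase-to-megabase toy references, not whole genomes.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping

from .io import Read, revcomp

_ARMS = ("5p", "3p")


@dataclasses.dataclass
class AlignmentHit:
    """Placement of a read on one strand of a reference sequence."""

    read_id: str
    chrom: str
    strand: str
    start: int
    end: int
    mismatches: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("empty alignment interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class MiRNARecord:
    """A mature miRNA: name, family, hairpin arm and sequence (DNA alphabet).

    ``five_prime`` is the 5'-terminal base, reported as RNA (T -> U), the
    quantity behind AGO 5'-nucleotide sorting preferences.
    """

    name: str
    family: str
    arm: str
    seq: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.arm not in _ARMS:
            raise ValueError(f"{self.name}: arm must be 5p or 3p, got {self.arm!r}")
        for suffix in _ARMS:
            if self.name.endswith("-" + suffix) and self.arm != suffix:
                raise ValueError(f"{self.name}: name suffix contradicts arm={self.arm}")
        if not 19 <= len(self.seq) <= 25:
            raise ValueError(f"{self.name}: mature length {len(self.seq)} outside 19-25")

    @property
    def five_prime(self) -> str:
        base = self.seq[0]
        return "U" if base == "T" else base


@dataclasses.dataclass
class MiRNAMatch:
    record: MiRNARecord
    mismatches: int


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings, early-exiting past limit."""
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if limit is not None and mm > limit:
                return mm
    return mm


class GenomeIndex:
    """Exact k-mer position index over a set of named sequences.

    Indexes are built lazily per seed length, so one object serves reads of
    any length and any mismatch ceiling.
    """

    def __init__(self, genome: Mapping[str, str]):
        self.genome = dict(genome)
        self._kmer_index: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._kmer_index:
            index: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for chrom, seq in self.genome.items():
                for pos in range(len(seq) - k + 1):
                    index[seq[pos : pos + k]].append((chrom, pos))
            self._kmer_index[k] = dict(index)
        return self._kmer_index[k]

    def candidates(self, query: str, max_mm: int) -> set[tuple[str, int]]:
        length = len(query)
        parts = max_mm + 1
        seed_len = length // parts
        out: set[tuple[str, int]] = set()
        if seed_len < 4:
            # too short to seed profitably: scan every position
            for chrom, seq in self.genome.items():
                out.update((chrom, p) for p in range(len(seq) - length + 1))
            return out
        index = self._index_for(seed_len)
        for j in range(parts):
            offset = j * seed_len
            for chrom, pos in index.get(query[offset : offset + seed_len], ()):
                start = pos - offset
                if 0 <= start <= len(self.genome[chrom]) - length:
                    out.add((chrom, start))
        return out


def align_genome(
    read: Read | str,
    genome: GenomeIndex | Mapping[str, str],
    max_mm: int = 2,
    read_id: str = "",
) -> list[AlignmentHit]:
    """All best-stratum placements of a read on either strand of the genome.

    Returns every placement achieving the minimal mismatch count that is
    <= ``max_mm``, sorted by (chromosome, start, strand). Reverse-strand
    hits compare the read's reverse complement against the forward genome;
    coordinates always refer to the forward strand.
    """
    if isinstance(read, Read):
        seq, rid = read.seq, read.id
    else:
        seq, rid = read, read_id
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    length = len(seq)
    raw: list[tuple[str, int, str, int]] = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for chrom, start in index.candidates(query, max_mm):
            mm = hamming(query, index.genome[chrom][start : start + length], limit=max_mm)
            if mm <= max_mm:
                raw.append((chrom, start, strand, mm))
    if not raw:
        return []
    best = min(mm for *_, mm in raw)
    hits = [
        AlignmentHit(rid, chrom, strand, start, start + length, mm)
        for chrom, start, strand, mm in raw
        if mm == best
    ]
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def align_library(
    reads: Iterable[Read],
    genome: GenomeIndex | Mapping[str, str],
    max_mm: int = 2,
) -> dict[str, list[AlignmentHit]]:
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    out: dict[str, list[AlignmentHit]] = {}
    for read in reads:
        hits = align_genome(read, index, max_mm=max_mm)
        if hits:
            out[read.id] = hits
    return out


def align_mirna(
    read: Read | str,
    catalog: Iterable[MiRNARecord],
    max_mm: int = 1,
) -> list[MiRNAMatch]:
    """Best-stratum matches of a read against a mature-miRNA catalog.

    A read matches a mature sequence when it aligns end-to-end as a
    contiguous substring of the mature (read <= mature), or — for reads up to
    2 nt longer than the mature, e.g. untrimmed templated ends — when the
    mature aligns contiguously within the read, with at most ``max_mm``
    substitutions either way.
    """
    seq = read.seq if isinstance(read, Read) else read
    scored: list[tuple[int, MiRNARecord]] = []
    for rec in catalog:
        overhang = len(seq) - len(rec.seq)
        if overhang > 2:
            continue
        short, long_ = (seq, rec.seq) if overhang <= 0 else (rec.seq, seq)
        best = None
        for off in range(len(long_) - len(short) + 1):
            mm = hamming(short, long_[off : off + len(short)], limit=max_mm)
            if mm <= max_mm and (best is None or mm < best):
                best = mm
                if best == 0:
                    break
        if best is not None:
            scored.append((best, rec))
    if not scored:
        return []
    top = min(mm for mm, _ in scored)
    return [MiRNAMatch(rec, mm) for mm, rec in scored if mm == top]


_POLICIES = {"discard", "count_all", "fractional"}


def dedupe_multimappers(
    hits_by_read: Mapping[str, list[AlignmentHit]],
    policy: str = "fractional",
) -> dict[str, list[AlignmentHit]]:
    """Resolve reads with multiple placements.

    ``discard`` drops multi-mapped reads entirely (the mRNA RIP-seq rule:
    ambiguous placements are removed); ``count_all`` keeps every hit at
    weight 1; ``fractional`` (sRNA default) keeps every hit at weight 1/n so
    each read contributes unit mass — phasiRNA loci are repetitive enough
    that discarding would bias locus counts.
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown multimap policy {policy!r}; choose from {sorted(_POLICIES)}")
    out: dict[str, list[AlignmentHit]] = {}
    for read_id, hits in hits_by_read.items():
        if not hits:
            continue
        if policy == "discard":
            if len(hits) == 1:
                out[read_id] = [dataclasses.replace(hits[0], weight=1.0)]
        elif policy == "count_all":
            out[read_id] = [dataclasses.replace(h, weight=1.0) for h in hits]
        else:
            w = 1.0 / len(hits)
            out[read_id] = [dataclasses.replace(h, weight=w) for h in hits]
    return out
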