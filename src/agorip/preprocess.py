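"""FASTQ cleanup cascade for small-RNA libraries.

The fixed stage order is: discard reads containing N bases; clip the 3'
adapter; trim low-quality (< Q20) bases from the 3' end; drop reads shorter
than 16 nt. Each stage's in/out counts are chained in a
:class:`FilterReport`. No base is ever added: every surviving read is a
prefix of a (suffix-clipped) input read, and the cascade is idempotent.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd

from .io import Read

DEFAULT_MIN_OVERLAP = 6
DEFAULT_QUALITY = 20
DEFAULT_MIN_LENGTH = 16


@dataclasses.dataclass
class FilterReport:
    """Per-stage read accounting; out(stage k) feeds in(stage k+1)."""

    stages: list[tuple[str, int, int]] = dataclasses.field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: output {n_out} exceeds input {n_in}")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError(f"stage {name}: input {n_in} breaks the chain")
        self.stages.append((name, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "reads_in", "reads_out"])


def filter_n(reads: Iterable[Read]) -> list[Read]:
    """Discard reads containing any N base, preserving input order."""
    return [r for r in reads if "N" not in r.seq]


def clip_adapter(
    read: Read,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Read:
    """Remove the 3' adapter by exact prefix matching.

    The read is truncated at the leftmost position >= 1 where the rest of
    the read matches the start of the adapter exactly; near the read's end
    the remaining bases may match only a prefix of the adapter, but at
    least ``min_overlap`` bases must agree. Qualities are truncated in
    lockstep. Unchanged when no match exists.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    n = len(read.seq)
    for i in range(1, n - min_overlap + 1):
        needed = min(len(adapter), n - i)
        if read.seq[i : i + needed] == adapter[:needed]:
            return Read(read.id, read.seq[:i], read.qual[:i])
    return read


def trim_quality(read: Read, threshold: int = DEFAULT_QUALITY) -> Read:
    """Trim 3'-terminal bases while their quality is below the threshold.

    Trimming stops at the first terminal base >= threshold; internal
    low-quality bases are retained (3'-only semantics). A fully-trimmed
    read becomes length 0 and is removed later by the length filter.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    end = len(read.qual)
    while end > 0 and read.qual[end - 1] < threshold:
        end -= 1
    if end == len(read.qual):
        return read
    return Read(read.id, read.seq[:end], read.qual[:end])


def filter_length(reads: Iterable[Read], min_len: int = DEFAULT_MIN_LENGTH) -> list[Read]:
    """Keep reads of at least ``min_len`` nt."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in reads if len(r) >= min_len]


def preprocess_reads(
    reads: Sequence[Read],
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    quality_threshold: int = DEFAULT_QUALITY,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[Read], FilterReport]:
    """Run the full cascade and return (clean reads, stage accounting)."""
    report = FilterReport()
    reads = list(reads)

    no_n = filter_n(reads)
    report.add("n_filter", len(reads), len(no_n))

    clipped = [clip_adapter(r, adapter, min_overlap) for r in no_n]
    report.add("adapter_clip", len(no_n), len(clipped))

    trimmed = [trim_quality(r, quality_threshold) for r in clipped]
    report.add("quality_trim", len(clipped), len(trimmed))

    kept = filter_length(trimmed, min_length)
    report.add("length_filter", len(trimmed), len(kept))
    return kept, report
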