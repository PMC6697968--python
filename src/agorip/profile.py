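"""Descriptive statistics of small-RNA libraries.

Length distributions, per-position base composition (the matrix behind a
sequence logo), assignment of aligned reads to phased-siRNA (phasiRNA) loci,
and TPM / RPKM quantification. Every fraction reported here names its
denominator in the result's metadata: "fraction of 21-nt reads on phasiRNA
loci" and "fraction of all reads that are 21 nt" are different quantities
and are kept apart explicitly.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import AlignmentHit
from .io import Read

PROFILED_LENGTHS = range(16, 36)
BASES = ("A", "C", "G", "U")


@dataclasses.dataclass
class PhasiLocus:
    """A genomic interval producing phased siRNAs of one length class.

    21-nt loci are triggered by miR2118, 24-nt loci by miR2275; the class is
    the exact increment of the phased register.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    length_class: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"locus {self.id}: empty interval")
        if self.length_class not in (21, 24):
            raise ValueError(f"locus {self.id}: length class must be 21 or 24")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class LengthDistribution:
    """Read counts and fractions per length, 16-35 nt, with an 'other' bin."""

    counts: dict
    total: float

    @property
    def fractions(self) -> dict | None:
        if self.total == 0:
            return None
        return {k: v / self.total for k, v in self.counts.items()}

    def fraction(self, length: int) -> float:
        if self.total == 0:
            raise ValueError("fractions undefined for an empty library")
        return self.counts.get(length, 0) / self.total

    def to_frame(self) -> pd.DataFrame:
        keys = list(PROFILED_LENGTHS) + ["other"]
        fr = self.fractions or {}
        return pd.DataFrame(
            {
                "length": keys,
                "count": [self.counts.get(k, 0) for k in keys],
                "fraction": [fr.get(k, float("nan")) for k in keys],
            }
        )


def length_distribution(reads: Iterable[Read | str]) -> LengthDistribution:
    """Exact per-length counts of a clean library; lengths outside 16-35 nt
    are pooled into an ``"other"`` bin but still counted in the total."""
    counts: dict = {length: 0 for length in PROFILED_LENGTHS}
    counts["other"] = 0
    total = 0
    for read in reads:
        n = len(read.seq if isinstance(read, Read) else read)
        key = n if n in counts else "other"
        counts[key] += 1
        total += 1
    return LengthDistribution(counts=counts, total=total)


def composition_matrix(reads: Iterable[Read | str], length: int) -> pd.DataFrame:
    """Per-position A/C/G/U fractions over reads of exactly ``length`` nt.

    Rows are 1-based positions; T is reported as U. Returns an empty frame
    (no rows) when no read has that length, never NaNs.
    """
    counts = [[0, 0, 0, 0] for _ in range(length)]
    n = 0
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    for read in reads:
        seq = read.seq if isinstance(read, Read) else read
        if len(seq) != length:
            continue
        n += 1
        for pos, base in enumerate(seq):
            counts[pos][idx[base]] += 1
    if n == 0:
        return pd.DataFrame(columns=BASES, index=pd.Index([], name="position"))
    frame = pd.DataFrame(counts, columns=BASES, index=pd.RangeIndex(1, length + 1, name="position"))
    return frame / n


def five_prime_composition(reads: Iterable[Read | str], length: int) -> dict[str, float]:
    """A/C/G/U fractions at read position 1 among reads of the given length.

    The statistic behind AGO 5'-nucleotide sorting (e.g. 5'-U preference in
    bound 21-nt reads). Empty dict when no read has that length.
    """
    matrix = composition_matrix(reads, length)
    if matrix.empty:
        return {}
    return matrix.iloc[0].to_dict()


@dataclasses.dataclass
class PhasiAssignment:
    """Per-locus weighted read counts plus per-class summary fractions.

    ``class_fraction[k]`` = (weighted reads assigned to class-k loci) /
    (all k-nt reads), the quantity reported as "% of k-nt sRNAs mapped onto
    phasiRNA loci". The denominator used is recorded in ``denominator``.
    """

    locus_counts: dict[str, float]
    class_assigned: dict[int, float]
    class_totals: dict[int, float]
    denominator: str
    overlapping_loci: list[tuple[str, str]]

    @property
    def class_fraction(self) -> dict[int, float]:
        return {
            k: (self.class_assigned.get(k, 0.0) / t if t else float("nan"))
            for k, t in self.class_totals.items()
        }

    def to_frame(self, loci: Sequence[PhasiLocus]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": [loc.id for loc in loci],
                "length_class": [loc.length_class for loc in loci],
                "count": [self.locus_counts.get(loc.id, 0.0) for loc in loci],
            }
        )


def assign_phasi(
    hits: Iterable[AlignmentHit],
    loci: Sequence[PhasiLocus],
    totals_by_length: Mapping[int, float] | None = None,
) -> PhasiAssignment:
    """Assign aligned reads to phasiRNA loci.

    A hit is assigned to a locus when its interval is fully contained in the
    locus interval, on either strand (phasiRNAs arise from double-stranded
    precursors), and the read length equals the locus class. A hit contained
    in several same-class loci increments each locus but is counted once in
    the class summary; such locus pairs are reported in ``overlapping_loci``.

    ``totals_by_length`` supplies the summary denominators (e.g. all clean
    k-nt reads); by default the weighted k-nt reads present in ``hits``.
    """
    hits = list(hits)
    by_class: dict[int, list[PhasiLocus]] = defaultdict(list)
    for loc in loci:
        by_class[loc.length_class].append(loc)

    locus_counts: dict[str, float] = {loc.id: 0.0 for loc in loci}
    class_assigned: dict[int, float] = {k: 0.0 for k in by_class}
    derived_totals: dict[int, float] = defaultdict(float)
    overlaps: set[tuple[str, str]] = set()

    for hit in hits:
        derived_totals[hit.length] += hit.weight
        matched = []
        for loc in by_class.get(hit.length, ()):
            if loc.chrom == hit.chrom and loc.start <= hit.start and hit.end <= loc.end:
                locus_counts[loc.id] += hit.weight
                matched.append(loc.id)
        if matched:
            class_assigned[hit.length] += hit.weight
            if len(matched) > 1:
                overlaps.update(
                    (a, b) for i, a in enumerate(matched) for b in matched[i + 1 :]
                )

    if totals_by_length is None:
        totals = {k: derived_totals.get(k, 0.0) for k in by_class}
        denominator = "weighted aligned reads of each class length"
    else:
        totals = {k: float(totals_by_length.get(k, 0.0)) for k in by_class}
        denominator = "caller-supplied totals per read length"
    return PhasiAssignment(
        locus_counts=locus_counts,
        class_assigned=class_assigned,
        class_totals=totals,
        denominator=denominator,
        overlapping_loci=sorted(overlaps),
    )


def quantify_tpm(
    feature_counts: Mapping[str, float],
    total_assigned: float | None = None,
) -> pd.DataFrame:
    """Tags-per-million normalization: TPM = count * 1e6 / total.

    With the default denominator (sum of the supplied counts, i.e. every
    assigned read) the TPM column sums to exactly 1e6. The denominator used
    is recorded in ``frame.attrs["denominator"]``.
    """
    if total_assigned is None:
        total = float(sum(feature_counts.values()))
        denominator = "sum of feature counts"
    else:
        total = float(total_assigned)
        denominator = "caller-supplied total"
    if total <= 0:
        raise ValueError("TPM denominator must be positive")
    frame = pd.DataFrame(
        {
            "feature": list(feature_counts.keys()),
            "count": list(feature_counts.values()),
        }
    )
    frame["tpm"] = frame["count"] * 1e6 / total
    frame.attrs["denominator"] = denominator
    frame.attrs["total"] = total
    return frame


def quantify_rpkm(locus_count: float, locus_length_nt: int, total_mapped: float) -> float:
    """Reads per kilobase of locus per million mapped reads."""
    if locus_length_nt <= 0:
        raise ValueError("locus length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    return locus_count * 1e9 / (locus_length_nt * total_mapped)


def quantify_rpkm_table(
    locus_counts: Mapping[str, float],
    loci: Sequence[PhasiLocus],
    total_mapped: float,
) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "locus": [loc.id for loc in loci],
            "length_class": [loc.length_class for loc in loci],
            "span": [loc.span for loc in loci],
            "count": [locus_counts.get(loc.id, 0.0) for loc in loci],
        }
    )
    frame["rpkm"] = [
        quantify_rpkm(c, s, total_mapped) for c, s in zip(frame["count"], frame["span"])
    ]
    return frame
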