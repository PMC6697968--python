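"""mRNA RIP-seq peak calling by "in silico random IP" permutation.

Uniquely placed reads are collapsed by exact genomic location, overlapping
unique reads are merged into clusters, and each host gene's clusters are
scored against a permutation null: the gene's observed reads are re-placed
uniformly at random over its exonic span, collapsed and merged, and the
maximum cluster read count of each repeat (default 500) forms the null
distribution. The empirical FDR of a cluster of height h is the fraction of
repeats whose maximum reaches h; clusters at FDR <= 0.01 that also exceed
the IgG background ratio are significant peaks, and genes hosting at least
one significant peak are the bound-gene set.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentHit
from .simulate import GeneModel

DEFAULT_REPEATS = 500
DEFAULT_FDR = 0.01
DEFAULT_IGG_RATIO = 2.0


@dataclasses.dataclass(frozen=True)
class UniqueRead:
    """Reads sharing one exact (chrom, strand, start, end) placement."""

    chrom: str
    strand: str
    start: int
    end: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 1 or self.end <= self.start:
            raise ValueError("invalid unique read")


@dataclasses.dataclass
class Cluster:
    """A maximal run of transitively overlapping unique reads."""

    chrom: str
    strand: str
    start: int
    end: int
    count: int
    members: list[UniqueRead]
    gene: str | None = None


@dataclasses.dataclass
class NullDistribution:
    """Per-repeat maximum cluster read counts from the random-IP null."""

    max_counts: np.ndarray
    repeats: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.max_counts) != self.repeats:
            raise ValueError("null distribution length != repeats")


@dataclasses.dataclass
class Peak:
    cluster: Cluster
    fdr: float
    significant: bool
    igg_count: int | None = None
    igg_ratio: float | None = None


def collapse(hits: Iterable[AlignmentHit]) -> list[UniqueRead]:
    """Merge hits with identical genomic location into counted unique reads.

    Input hits must already be single-location (multi-mapped reads are
    discarded upstream); counts conserve the number of input hits.
    """
    counter: Counter[tuple[str, str, int, int]] = Counter()
    for h in hits:
        counter[(h.chrom, h.strand, h.start, h.end)] += 1
    return [
        UniqueRead(chrom, strand, start, end, n)
        for (chrom, strand, start, end), n in sorted(counter.items())
    ]


def merge(unique_reads: Iterable[UniqueRead]) -> list[Cluster]:
    """Merge unique reads whose intervals overlap by >= 1 nt on one strand.

    Merging is transitive; book-ended (half-open abutting) intervals stay
    separate. Output is sorted by (chrom, strand, start).
    """
    groups: dict[tuple[str, str], list[UniqueRead]] = defaultdict(list)
    for u in unique_reads:
        groups[(u.chrom, u.strand)].append(u)
    clusters: list[Cluster] = []
    for (chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda u: (u.start, u.end))
        current: list[UniqueRead] = []
        cur_end = None
        for u in members:
            if current and u.start < cur_end:
                current.append(u)
                cur_end = max(cur_end, u.end)
            else:
                if current:
                    clusters.append(_finish(chrom, strand, current))
                current = [u]
                cur_end = u.end
        if current:
            clusters.append(_finish(chrom, strand, current))
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.start))
    return clusters


def _finish(chrom: str, strand: str, members: list[UniqueRead]) -> Cluster:
    return Cluster(
        chrom=chrom,
        strand=strand,
        start=min(u.start for u in members),
        end=max(u.end for u in members),
        count=sum(u.count for u in members),
        members=list(members),
    )


def _max_run(new_cluster_row: np.ndarray) -> int:
    breaks = np.flatnonzero(new_cluster_row)
    sizes = np.diff(np.append(breaks, len(new_cluster_row)))
    return int(sizes.max())


def random_ip_null(
    exonic_length: int,
    read_lengths: Sequence[int],
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    gene: str = "?",
) -> NullDistribution:
    """Permutation null for one gene's read set.

    Each repeat re-places every read uniformly at random over the gene's
    concatenated exonic span (start uniform over positions where the read
    fits), merges overlapping placements, and records the maximum cluster
    read count. Identical placements merge implicitly, so collapsing and
    clustering coincide. Deterministic given the seed.
    """
    lengths = np.asarray(read_lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError(f"gene {gene}: no reads to randomize")
    if int(lengths.max()) > exonic_length:
        raise ValueError(
            f"gene {gene}: a read of {int(lengths.max())} nt exceeds the exonic span "
            f"({exonic_length} nt)"
        )
    rng = np.random.default_rng(seed)
    n = lengths.size
    starts = np.floor(rng.random((repeats, n)) * (exonic_length - lengths + 1)).astype(np.int64)
    ends = starts + lengths
    order = np.argsort(starts, axis=1, kind="stable")
    s = np.take_along_axis(starts, order, axis=1)
    e = np.take_along_axis(ends, order, axis=1)
    cummax_end = np.maximum.accumulate(e, axis=1)
    new_cluster = np.empty((repeats, n), dtype=bool)
    new_cluster[:, 0] = True
    if n > 1:
        new_cluster[:, 1:] = s[:, 1:] >= cummax_end[:, :-1]
    max_counts = np.fromiter(
        (_max_run(new_cluster[r]) for r in range(repeats)), dtype=np.int64, count=repeats
    )
    return NullDistribution(max_counts=max_counts, repeats=repeats, seed=seed)


def assign_fdr(
    clusters: Sequence[Cluster],
    null: NullDistribution,
    threshold: float = DEFAULT_FDR,
) -> list[Peak]:
    """Empirical FDR per cluster from the null's per-repeat maxima.

    FDR(h) = (# repeats with max cluster count >= h) / repeats; equal
    cluster heights get equal FDR. Significant when FDR <= threshold
    (before any IgG filtering).
    """
    if null.repeats == 0:
        raise ValueError("empty null distribution")
    maxima = np.sort(null.max_counts)
    peaks = []
    for c in clusters:
        exceed = null.repeats - np.searchsorted(maxima, c.count, side="left")
        fdr = float(exceed) / null.repeats
        peaks.append(Peak(cluster=c, fdr=fdr, significant=fdr <= threshold))
    return peaks


def igg_filter(
    peaks: Sequence[Peak],
    igg_hits: Iterable[AlignmentHit],
    min_ratio: float = DEFAULT_IGG_RATIO,
    pseudocount: float = 1.0,
) -> list[Peak]:
    """Require RIP-over-IgG enrichment inside each peak interval.

    For every peak, IgG reads overlapping the interval on the same strand
    are counted and the ratio (RIP + c) / (IgG + c) recorded; a peak keeps
    its significance only when the ratio reaches ``min_ratio``. All peaks
    are returned with count and ratio recorded either way.
    """
    starts_by: dict[tuple[str, str], np.ndarray] = {}
    ends_by: dict[tuple[str, str], np.ndarray] = {}
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for h in igg_hits:
        grouped[(h.chrom, h.strand)].append((h.start, h.end))
    for key, intervals in grouped.items():
        arr = np.array(intervals)
        starts_by[key] = np.sort(arr[:, 0])
        ends_by[key] = np.sort(arr[:, 1])
    out = []
    for p in peaks:
        key = (p.cluster.chrom, p.cluster.strand)
        if key in starts_by:
            n_start_before_end = int(np.searchsorted(starts_by[key], p.cluster.end, side="left"))
            n_end_before_start = int(np.searchsorted(ends_by[key], p.cluster.start, side="right"))
            igg = n_start_before_end - n_end_before_start
        else:
            igg = 0
        ratio = (p.cluster.count + pseudocount) / (igg + pseudocount)
        out.append(
            Peak(
                cluster=p.cluster,
                fdr=p.fdr,
                significant=p.significant and ratio >= min_ratio,
                igg_count=igg,
                igg_ratio=ratio,
            )
        )
    return out


def bound_genes(peaks: Iterable[Peak]) -> set[str]:
    """Genes hosting at least one significant peak."""
    return {p.cluster.gene for p in peaks if p.significant and p.cluster.gene is not None}


def assign_hits_to_genes(
    hits: Iterable[AlignmentHit],
    genes: Sequence[GeneModel],
) -> dict[str, list[AlignmentHit]]:
    """Group hits by host gene (maximal exonic overlap; unhosted hits drop)."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    out: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        best, best_ov = None, 0
        for g in by_chrom.get(h.chrom, ()):
            ov = sum(
                max(0, min(h.end, e) - max(h.start, s)) for s, e in g.exons
            )
            if ov > best_ov:
                best, best_ov = g, ov
        if best is not None:
            out[best.name].append(h)
    return dict(out)


def call_peaks(
    hits: Iterable[AlignmentHit],
    genes: Sequence[GeneModel],
    igg_hits: Iterable[AlignmentHit] | None = None,
    repeats: int = DEFAULT_REPEATS,
    fdr_threshold: float = DEFAULT_FDR,
    min_igg_ratio: float = DEFAULT_IGG_RATIO,
    seed: int = 0,
) -> tuple[list[Peak], dict[str, NullDistribution]]:
    """Full peak-calling pipeline over all genes.

    Per gene: collapse -> merge -> random-IP null (seeded per gene, derived
    deterministically from ``seed``) -> empirical FDR; then the IgG ratio
    filter when an IgG library is given. Returns all peaks (sorted) and the
    per-gene null distributions so alternative FDR readings can be
    recomputed.
    """
    gene_map = {g.name: g for g in genes}
    hosted = assign_hits_to_genes(hits, genes)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = dict(zip(sorted(hosted), seed_seq.generate_state(max(len(hosted), 1))))

    peaks: list[Peak] = []
    nulls: dict[str, NullDistribution] = {}
    for gname in sorted(hosted):
        ghits = hosted[gname]
        gene = gene_map[gname]
        clusters = merge(collapse(ghits))
        for c in clusters:
            c.gene = gname
        null = random_ip_null(
            exonic_length=gene.exonic_length,
            read_lengths=[h.length for h in ghits],
            repeats=repeats,
            seed=int(child_seeds[gname] % (2**31)),
            gene=gname,
        )
        nulls[gname] = null
        peaks.extend(assign_fdr(clusters, null, threshold=fdr_threshold))
    if igg_hits is not None:
        peaks = igg_filter(peaks, igg_hits, min_ratio=min_igg_ratio)
    peaks.sort(key=lambda p: (p.cluster.chrom, p.cluster.start, p.cluster.strand))
    return peaks, nulls


def target_overlap(
    bound: set[str],
    target_table: pd.DataFrame,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Intersect predicted miRNA targets with the bound-gene set.

    For each miRNA: number of targets, how many fall in the bound set, the
    bound target identities, and a hypergeometric enrichment p-value over
    the supplied gene universe (p = 1 for an empty target list).
    """
    universe_set = set(universe)
    bound_in_universe = bound & universe_set
    rows = []
    for mirna, sub in target_table.groupby("mirna", sort=True):
        targets = sorted(set(sub["target"]) & universe_set)
        inside = sorted(set(targets) & bound_in_universe)
        if not targets:
            p = 1.0
        else:
            p = float(
                stats.hypergeom.sf(
                    len(inside) - 1, len(universe_set), len(bound_in_universe), len(targets)
                )
            )
        rows.append(
            (mirna, len(targets), len(inside), ",".join(inside) if inside else ".", p)
        )
    return pd.DataFrame(
        rows, columns=["mirna", "n_targets", "n_bound", "bound_targets", "p_hypergeom"]
    )


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    """Peaks as a BED6+ table (count, FDR, IgG count/ratio, gene, flag)."""
    rows = []
    for p in peaks:
        c = p.cluster
        rows.append(
            (
                c.chrom,
                c.start,
                c.end,
                f"{c.gene or '.'}:{c.start}-{c.end}",
                c.count,
                c.strand,
                p.fdr,
                p.igg_count if p.igg_count is not None else ".",
                round(p.igg_ratio, 6) if p.igg_ratio is not None else ".",
                c.gene or ".",
                int(p.significant),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "name",
            "count",
            "strand",
            "fdr",
            "igg_count",
            "igg_ratio",
            "gene",
            "significant",
        ],
    )
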