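"""Synthetic AGO RIP-seq references and read libraries with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a toy genome carrying phased-siRNA loci of the 21-nt and 24-nt
classes, miRNA hairpins with distinct 5p/3p arms and 5' bases, small-RNA
populations with a configurable length mixture, immunoprecipitation (RIP)
resampling with length-class-dependent 5'-nucleotide selection weights, an
IgG library as uniform background, adapter-ligated reads with Phred+33
qualities, and mRNA RIP reads concentrated at planted binding sites. Every
emitted read is recorded exactly once in a truth table, so each pipeline
stage can be checked against the generating parameters.

Defaults follow the compositions observed in maize premeiotic tassels:
24-nt reads are the predominant class (47%), 21-nt the second (15%); 54% of
21-nt and 35% of 24-nt reads derive from phasiRNA loci; the bound-library
selection weights give a 75% expected 5'-U fraction among 21-nt reads and a
53% expected 5'-A fraction among 24-nt reads.

All coordinates are 0-based, half-open. Identical seeds and configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit, MiRNARecord
from .io import Read, revcomp
from .profile import PhasiLocus

_BASES = np.array(list("ACGT"))

#: Illumina TruSeq small-RNA 3' adapter (the study's own adapter is unstated).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclasses.dataclass
class GeneModel:
    """A gene as an ordered list of exon intervals on one strand."""

    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.name}: no exons")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.name}: empty exon ({s},{e})")
        self.exons = sorted(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclasses.dataclass
class ReferenceConfig:
    """Sizing of the simulated reference.

    Each phasiRNA locus spans ``phases * length_class`` nucleotides; each
    hairpin contributes a 5p and a 3p mature arm whose 5' bases are forced
    to A and U respectively (mirroring miR2275's arm asymmetry).
    """

    chrom_lengths: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"chr1": 100_000}
    )
    n_loci_21: int = 5
    n_loci_24: int = 5
    phases_21: int = 10
    phases_24: int = 10
    n_hairpins: int = 5
    mature_length: int = 21
    hairpin_loop: int = 15
    n_genes: int = 0
    exons_per_gene: int = 2
    exon_length: int = 5_000
    intron_length: int = 200


@dataclasses.dataclass
class ReferenceBundle:
    genome: dict[str, str]
    mirnas: list[MiRNARecord]
    phasi_loci: list[PhasiLocus]
    genes: list[GeneModel]

    def validate(self) -> None:
        for loc in self.phasi_loci:
            if not 0 <= loc.start < loc.end <= len(self.genome[loc.chrom]):
                raise ValueError(f"locus {loc.id} outside {loc.chrom}")
            if loc.span % loc.length_class != 0:
                raise ValueError(f"locus {loc.id}: span not a multiple of its class")
        for rec in self.mirnas:
            if self.genome[rec.chrom][rec.start : rec.end] != rec.seq:
                raise ValueError(f"{rec.name}: mature sequence absent at its coordinates")
        for gene in self.genes:
            s, e = gene.span
            if not 0 <= s < e <= len(self.genome[gene.chrom]):
                raise ValueError(f"gene {gene.name} outside {gene.chrom}")


def _place(rng: np.random.Generator, chrom_len: int, sizes: list[int]) -> list[int]:
    """Non-overlapping start positions for intervals of the given sizes,
    separated by random gaps drawn uniformly from the available slack."""
    slack = chrom_len - sum(sizes)
    if slack < 0:
        raise ValueError(
            f"features need {sum(sizes)} nt but chromosome has {chrom_len}"
        )
    gaps = rng.multinomial(slack, np.full(len(sizes) + 1, 1.0 / (len(sizes) + 1)))
    starts, cursor = [], 0
    for size, gap in zip(sizes, gaps[:-1]):
        cursor += int(gap)
        starts.append(cursor)
        cursor += size
    return starts


def simulate_reference(config: ReferenceConfig | None = None, seed: int = 0) -> ReferenceBundle:
    """Build a toy genome with planted phasiRNA loci, miRNA arms and genes.

    Deterministic for a fixed (config, seed). Features are distributed
    round-robin over chromosomes and never overlap.
    """
    config = config or ReferenceConfig()
    rng = np.random.default_rng(seed)

    hairpin_span = 2 * config.mature_length + config.hairpin_loop
    gene_span = (
        config.exons_per_gene * config.exon_length
        + (config.exons_per_gene - 1) * config.intron_length
    )
    features: list[tuple[str, int, int]] = []  # (kind, index, size)
    features += [("L21", i, config.phases_21 * 21) for i in range(config.n_loci_21)]
    features += [("L24", i, config.phases_24 * 24) for i in range(config.n_loci_24)]
    features += [("MIR", i, hairpin_span) for i in range(config.n_hairpins)]
    features += [("GENE", i, gene_span) for i in range(config.n_genes)]

    chrom_names = list(config.chrom_lengths)
    per_chrom: dict[str, list[tuple[str, int, int]]] = {c: [] for c in chrom_names}
    for j, feat in enumerate(features):
        per_chrom[chrom_names[j % len(chrom_names)]].append(feat)

    genome_chars = {
        c: rng.choice(_BASES, size=n) for c, n in config.chrom_lengths.items()
    }
    loci: list[PhasiLocus] = []
    mirnas: list[MiRNARecord] = []
    genes: list[GeneModel] = []

    for chrom in chrom_names:
        feats = per_chrom[chrom]
        starts = _place(rng, config.chrom_lengths[chrom], [f[2] for f in feats])
        for (kind, idx, size), start in zip(feats, starts):
            if kind in ("L21", "L24"):
                cls = 21 if kind == "L21" else 24
                strand = "+" if rng.random() < 0.5 else "-"
                loci.append(
                    PhasiLocus(
                        id=f"PHAS{cls}_{idx + 1}",
                        chrom=chrom,
                        strand=strand,
                        start=start,
                        end=start + size,
                        length_class=cls,
                    )
                )
            elif kind == "MIR":
                m = config.mature_length
                five_start, three_start = start, start + size - m
                # distinct arm 5' bases: 5p starts A, 3p starts T (U)
                genome_chars[chrom][five_start] = "A"
                genome_chars[chrom][three_start] = "T"
                fam = f"sim-miR{idx + 1}"
                for arm, s0 in (("5p", five_start), ("3p", three_start)):
                    seq = "".join(genome_chars[chrom][s0 : s0 + m])
                    mirnas.append(
                        MiRNARecord(
                            name=f"{fam}-{arm}",
                            family=fam,
                            arm=arm,
                            seq=seq,
                            chrom=chrom,
                            start=s0,
                            end=s0 + m,
                        )
                    )
            else:
                exons = [
                    (
                        start + k * (config.exon_length + config.intron_length),
                        start + k * (config.exon_length + config.intron_length)
                        + config.exon_length,
                    )
                    for k in range(config.exons_per_gene)
                ]
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GeneModel(name=f"gene{idx + 1}", chrom=chrom, strand=strand, exons=exons)
                )

    bundle = ReferenceBundle(
        genome={c: "".join(chars) for c, chars in genome_chars.items()},
        mirnas=mirnas,
        phasi_loci=loci,
        genes=genes,
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# small-RNA libraries


def _default_mixture() -> dict[int, float]:
    mixture = {21: 0.15, 24: 0.47}
    rest = [length for length in range(16, 36) if length not in mixture]
    for length in rest:
        mixture[length] = (1.0 - 0.15 - 0.47) / len(rest)
    return mixture


@dataclasses.dataclass
class LibraryModel:
    """Composition of a simulated small-RNA library.

    ``five_prime_weights`` maps a length class (21, 24 or "other") to
    per-5'-base selection weights used by :func:`simulate_rip_library`;
    unlisted bases default to weight 1. ``phasi_fraction`` gives, per length
    class, the fraction of that class drawn from phased locus registers.
    """

    length_mixture: dict[int, float] = dataclasses.field(default_factory=_default_mixture)
    five_prime_weights: dict = dataclasses.field(
        default_factory=lambda: {21: {"T": 9.0}, 24: {"A": 3.4}}
    )
    phasi_fraction: dict[int, float] = dataclasses.field(
        default_factory=lambda: {21: 0.54, 24: 0.35}
    )
    mirna_fraction: float = 0.02
    n_base_rate: float = 0.002
    adapter: str = DEFAULT_ADAPTER
    read_cycles: int = 50

    def __post_init__(self) -> None:
        total = sum(self.length_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length mixture sums to {total}, not 1")
        for name, frac in [("mirna_fraction", self.mirna_fraction), ("n_base_rate", self.n_base_rate)]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        for cls, frac in self.phasi_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"phasi_fraction[{cls}] outside [0, 1]")
        for cls, weights in self.five_prime_weights.items():
            for base, w in weights.items():
                if w < 0:
                    raise ValueError(f"negative 5' weight for ({cls}, {base})")


def length_class(length: int) -> object:
    return length if length in (21, 24) else "other"


TRUTH_COLUMNS = [
    "read_id",
    "origin_type",
    "origin_id",
    "chrom",
    "strand",
    "start",
    "end",
    "insert_len",
    "five_prime",
    "has_n",
]


def simulate_srna_library(
    bundle: ReferenceBundle,
    model: LibraryModel | None = None,
    n_reads: int = 10_000,
    seed: int = 0,
    id_prefix: str = "sr",
) -> tuple[list[Read], pd.DataFrame]:
    """Draw a small-RNA library from the reference.

    Each read is, in order of precedence: an exact mature-miRNA copy (with
    probability ``mirna_fraction``); a phased register of a random locus of
    its drawn length class (with probability ``phasi_fraction[class]``); or
    background — a uniformly placed genomic fragment on a random strand.
    The insert then gets the 3' adapter appended, is padded with random
    low-quality bases and truncated to ``read_cycles``, and suffers uniform
    N substitution at ``n_base_rate``. The returned truth table records each
    read's origin, genomic placement, insert length, 5' base and whether an
    N was injected.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    model = model or LibraryModel()
    rng = np.random.default_rng(seed)

    lengths_avail = sorted(model.length_mixture)
    probs = np.array([model.length_mixture[length] for length in lengths_avail])
    probs = probs / probs.sum()

    is_mirna = rng.random(n_reads) < model.mirna_fraction
    drawn_len = rng.choice(np.array(lengths_avail), size=n_reads, p=probs)
    phasi_draw = rng.random(n_reads)
    u_locus = rng.random(n_reads)
    u_register = rng.random(n_reads)
    u_mirna = rng.integers(0, max(len(bundle.mirnas), 1), size=n_reads)
    u_bg_strand = rng.random(n_reads)

    chroms = list(bundle.genome)
    chrom_lens = np.array([len(bundle.genome[c]) for c in chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    bg_chrom_idx = rng.choice(len(chroms), size=n_reads, p=chrom_p)
    u_bg_pos = rng.random(n_reads)

    loci_by_class: dict[int, list[PhasiLocus]] = {21: [], 24: []}
    for loc in bundle.phasi_loci:
        loci_by_class[loc.length_class].append(loc)

    cycles = model.read_cycles
    pad_pool = rng.choice(_BASES, size=(n_reads, cycles))
    q_hi = rng.integers(36, 41, size=(n_reads, cycles))
    q_lo = rng.integers(2, 11, size=(n_reads, cycles))
    n_mask = rng.random((n_reads, cycles)) < model.n_base_rate

    reads: list[Read] = []
    truth_rows = []
    for i in range(n_reads):
        if is_mirna[i] and bundle.mirnas:
            rec = bundle.mirnas[u_mirna[i]]
            insert = rec.seq
            origin = ("mirna", rec.name, rec.chrom, "+", rec.start, rec.end)
        else:
            length = int(drawn_len[i])
            pool = loci_by_class.get(length, [])
            if pool and phasi_draw[i] < model.phasi_fraction.get(length, 0.0):
                loc = pool[int(u_locus[i] * len(pool))]
                n_reg = loc.span // length
                k = int(u_register[i] * n_reg)
                if loc.strand == "+":
                    start = loc.start + k * length
                else:
                    start = loc.end - (k + 1) * length
                frag = bundle.genome[loc.chrom][start : start + length]
                insert = frag if loc.strand == "+" else revcomp(frag)
                origin = ("phasi", loc.id, loc.chrom, loc.strand, start, start + length)
            else:
                chrom = chroms[bg_chrom_idx[i]]
                start = int(u_bg_pos[i] * (len(bundle.genome[chrom]) - length + 1))
                strand = "+" if u_bg_strand[i] < 0.5 else "-"
                frag = bundle.genome[chrom][start : start + length]
                insert = frag if strand == "+" else revcomp(frag)
                origin = ("background", ".", chrom, strand, start, start + length)

        ins_len = len(insert)
        seq = (insert + model.adapter)[:cycles]
        n_real = len(seq)
        if n_real < cycles:
            seq = seq + "".join(pad_pool[i, : cycles - n_real])
        qual = np.where(np.arange(cycles) < min(ins_len + len(model.adapter), cycles),
                        q_hi[i], q_lo[i])
        mask = n_mask[i]
        has_n = bool(mask.any())
        if has_n:
            chars = np.frombuffer(seq.encode(), dtype="S1").copy()
            chars[mask] = b"N"
            seq = chars.tobytes().decode()
        read_id = f"{id_prefix}{i}"
        reads.append(Read(read_id, seq, tuple(int(q) for q in qual)))
        truth_rows.append(
            (read_id, *origin[:2], *origin[2:], ins_len, insert[0], has_n)
        )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


def expected_five_prime_fractions(
    base_truth: pd.DataFrame,
    five_prime_weights: Mapping,
    length: int,
) -> dict[str, float]:
    """Closed-form expected RIP 5'-base fractions for one length class.

    If ``f_b`` is the base library's 5'-base composition among inserts of
    the given length and ``w_b`` the selection weights, the expected bound
    fraction of base b is ``w_b f_b / sum_b' w_b' f_b'``.
    """
    sub = base_truth[base_truth["insert_len"] == length]
    if sub.empty:
        return {}
    weights = dict(five_prime_weights.get(length_class(length), {}))
    f = sub["five_prime"].value_counts(normalize=True)
    mass = {b: weights.get(b, 1.0) * f.get(b, 0.0) for b in "ACGT"}
    total = sum(mass.values())
    return {b: v / total for b, v in mass.items()}


def simulate_rip_library(
    base_reads: Sequence[Read],
    base_truth: pd.DataFrame,
    five_prime_weights: Mapping | None = None,
    n_reads: int = 10_000,
    seed: int = 0,
    id_prefix: str = "rip",
) -> tuple[list[Read], pd.DataFrame]:
    """Resample a base library through 5'-nucleotide selective binding.

    Emulates an AGO immunoprecipitation: each base read is drawn with
    probability proportional to ``weight(length class, 5' base)``, with
    replacement, so the expected observed 5'-base fraction per class follows
    the closed form in :func:`expected_five_prime_fractions`. Equal weights
    reproduce the base composition (an IgG-like identity).
    """
    if not base_reads:
        raise ValueError("empty base population")
    if len(base_reads) != len(base_truth):
        raise ValueError("base reads and truth table differ in size")
    weights = five_prime_weights if five_prime_weights is not None else {21: {"T": 9.0}, 24: {"A": 3.4}}

    w = np.ones(len(base_reads))
    classes = base_truth["insert_len"].map(length_class)
    for i, (cls, base) in enumerate(zip(classes, base_truth["five_prime"])):
        w[i] = weights.get(cls, {}).get(base, 1.0)
    for cls in set(classes):
        mask = (classes == cls).to_numpy()
        if mask.any() and w[mask].sum() == 0:
            raise ValueError(f"all selection weights zero for represented class {cls}")
    if w.sum() == 0:
        raise ValueError("all selection weights are zero")

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(base_reads), size=n_reads, p=w / w.sum())
    reads = []
    rows = base_truth.iloc[idx].copy().reset_index(drop=True)
    rows["source_read"] = rows["read_id"]
    rows["read_id"] = [f"{id_prefix}{i}" for i in range(n_reads)]
    for i, j in enumerate(idx):
        src = base_reads[j]
        reads.append(Read(f"{id_prefix}{i}", src.seq, src.qual))
    return reads, rows


# ---------------------------------------------------------------------------
# mRNA RIP libraries


@dataclasses.dataclass
class BindingSite:
    """A planted protein-binding interval inside one exon of a gene."""

    id: str
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"site {self.id}: empty interval")


def simulate_mrna_rip(
    bundle: ReferenceBundle,
    sites: Sequence[BindingSite] = (),
    enrichment_fold: float = 10.0,
    n_reads: int = 20_000,
    frac_background: float | None = None,
    read_length: int = 50,
    jitter: int = 20,
    seed: int = 0,
    id_prefix: str = "mr",
) -> tuple[list[Read], pd.DataFrame]:
    """mRNA RIP reads: uniform exonic background plus planted binding sites.

    With ``frac_background=None`` (the default) a density model is used:
    background density 1 per exonic nucleotide and site density
    ``enrichment_fold`` per site nucleotide, so a site at fold F collects
    F-fold the local background coverage. Passing ``frac_background``
    instead fixes the background read share directly and splits the
    remainder over sites proportional to ``fold * site length``.
    ``enrichment_fold=0`` gives pure background — the IgG model.

    Site reads start uniformly within +/- ``jitter`` of the site (clipped to
    the host exon); background reads are uniform over all exonic positions
    where the read fits. Reads lie on the host gene's strand.
    """
    if not bundle.genes:
        raise ValueError("reference bundle has no gene models")
    genes = {g.name: g for g in bundle.genes}

    host_exon: dict[str, tuple[GeneModel, tuple[int, int]]] = {}
    for site in sites:
        gene = genes.get(site.gene)
        if gene is None:
            raise ValueError(f"site {site.id}: unknown gene {site.gene}")
        exon = next(
            ((s, e) for s, e in gene.exons if s <= site.start and site.end <= e), None
        )
        if exon is None or gene.chrom != site.chrom:
            raise ValueError(f"site {site.id} does not lie within an exon of {site.gene}")
        if exon[1] - exon[0] < read_length:
            raise ValueError(f"site {site.id}: host exon shorter than the read length")
        host_exon[site.id] = (gene, exon)

    # exonic placement space for background reads
    exon_records = []  # (gene, chrom, strand, start, positions)
    for g in bundle.genes:
        for s, e in g.exons:
            fit = e - s - read_length + 1
            if fit > 0:
                exon_records.append((g.name, g.chrom, g.strand, s, fit))
    if not exon_records:
        raise ValueError("no exon can fit a read of this length")
    fit_counts = np.array([r[4] for r in exon_records], dtype=float)
    exonic_total = float(sum(g.exonic_length for g in bundle.genes))

    site_len = np.array([s.end - s.start for s in sites], dtype=float)
    if enrichment_fold == 0 or not sites:
        p_bg, p_sites = 1.0, np.zeros(len(sites))
    elif frac_background is None:
        w_sites = (enrichment_fold - 1.0) * site_len
        w_sites = np.clip(w_sites, 0.0, None)
        total = exonic_total + w_sites.sum()
        p_bg, p_sites = exonic_total / total, w_sites / total
    else:
        if not 0.0 <= frac_background <= 1.0:
            raise ValueError("frac_background outside [0, 1]")
        w_sites = enrichment_fold * site_len
        p_bg = frac_background
        p_sites = (1.0 - frac_background) * w_sites / w_sites.sum()

    rng = np.random.default_rng(seed)
    component = rng.choice(len(sites) + 1, size=n_reads, p=np.concatenate(([p_bg], p_sites)))
    u_exon = rng.choice(len(exon_records), size=n_reads, p=fit_counts / fit_counts.sum())
    u_pos = rng.random(n_reads)
    quals = rng.integers(36, 41, size=(n_reads, read_length))

    reads, rows = [], []
    for i in range(n_reads):
        if component[i] == 0:
            gname, chrom, strand, exon_start, fit = exon_records[u_exon[i]]
            start = exon_start + int(u_pos[i] * fit)
            origin = "background"
        else:
            site = sites[component[i] - 1]
            gene, (es, ee) = host_exon[site.id]
            gname, chrom, strand = gene.name, gene.chrom, gene.strand
            lo = max(es, site.start - jitter)
            hi = min(ee, site.end + jitter) - read_length
            hi = max(hi, lo)
            start = lo + int(u_pos[i] * (hi - lo + 1))
            origin = site.id
        frag = bundle.genome[chrom][start : start + read_length]
        seq = frag if strand == "+" else revcomp(frag)
        read_id = f"{id_prefix}{i}"
        reads.append(Read(read_id, seq, tuple(int(q) for q in quals[i])))
        rows.append((read_id, origin, gname, chrom, strand, start, start + read_length))

    truth = pd.DataFrame(
        rows, columns=["read_id", "origin", "gene", "chrom", "strand", "start", "end"]
    )
    return reads, truth


def simulate_igg_mrna(
    bundle: ReferenceBundle,
    n_reads: int = 20_000,
    read_length: int = 50,
    seed: int = 0,
) -> tuple[list[Read], pd.DataFrame]:
    """IgG companion library: pure uniform exonic background."""
    return simulate_mrna_rip(
        bundle,
        sites=(),
        enrichment_fold=0.0,
        n_reads=n_reads,
        read_length=read_length,
        seed=seed,
        id_prefix="igg",
    )


def hits_from_truth(truth: pd.DataFrame) -> list[AlignmentHit]:
    """Turn a truth table's recorded placements into unit-weight hits.

    Convenience for exercising coordinate-level stages (locus assignment,
    peak calling) directly from simulated ground truth.
    """
    return [
        AlignmentHit(r.read_id, r.chrom, r.strand, int(r.start), int(r.end), 0)
        for r in truth.itertuples()
    ]
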