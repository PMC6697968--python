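"""End-to-end demonstration pipelines on simulated data.

``run_srna_pipeline`` exercises the small-RNA path (simulate -> preprocess
-> align -> profile -> quantify -> compare) and ``run_mrna_pipeline`` the
mRNA peak-calling path; both write every result table as TSV so two runs
with the same seed are byte-identical. These drive the CLI ``demo``
subcommand and the reproducibility checks.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io
from .align import GenomeIndex, align_library, align_mirna, dedupe_multimappers
from .enrichment import rip_vs_igg
from .peakcall import bound_genes, call_peaks, peaks_to_frame
from .preprocess import preprocess_reads
from .profile import assign_phasi, composition_matrix, length_distribution, quantify_rpkm_table, quantify_tpm
from .simulate import (
    BindingSite,
    LibraryModel,
    ReferenceConfig,
    hits_from_truth,
    simulate_igg_mrna,
    simulate_mrna_rip,
    simulate_reference,
    simulate_rip_library,
    simulate_srna_library,
)


def run_srna_pipeline(
    outdir: str | Path,
    seed: int = 0,
    n_reads: int = 20_000,
    model: LibraryModel | None = None,
    config: ReferenceConfig | None = None,
) -> dict:
    """Simulate an sRNA + RIP library pair and run the full sRNA analysis.

    Writes: reference files, FASTQs, truth tables, the filter report,
    length distributions, 21-nt composition matrices, per-locus counts and
    RPKM, miRNA TPM, and RIP-vs-IgG miRNA enrichment. Returns the main
    in-memory results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = model or LibraryModel()

    bundle = simulate_reference(config, seed=seed)
    io.write_fasta(bundle.genome, outdir / "genome.fa")
    io.write_fasta({m.name: m.seq for m in bundle.mirnas}, outdir / "mirnas.fa")
    io.write_loci_bed(bundle.phasi_loci, outdir / "phasi_loci.bed")

    base_reads, base_truth = simulate_srna_library(bundle, model, n_reads, seed=seed + 1)
    rip_reads, rip_truth = simulate_rip_library(
        base_reads, base_truth, model.five_prime_weights, n_reads, seed=seed + 2
    )
    # IgG: selection-free resampling of the same pool
    igg_reads, igg_truth = simulate_rip_library(
        base_reads, base_truth, {}, n_reads, seed=seed + 3, id_prefix="igg"
    )
    io.write_fastq(base_reads, outdir / "srna.fastq")
    io.write_fastq(rip_reads, outdir / "rip.fastq")
    io.write_tsv(base_truth, outdir / "srna_truth.tsv")
    io.write_tsv(rip_truth, outdir / "rip_truth.tsv")

    results: dict = {"bundle": bundle}
    index = GenomeIndex(bundle.genome)
    for label, reads in (("srna", base_reads), ("rip", rip_reads), ("igg", igg_reads)):
        clean, report = preprocess_reads(reads, adapter=model.adapter)
        io.write_tsv(report.to_frame(), outdir / f"{label}_filter_report.tsv")

        dist = length_distribution(clean)
        io.write_tsv(dist.to_frame(), outdir / f"{label}_length_distribution.tsv")
        comp21 = composition_matrix(clean, 21)
        comp21.reset_index().to_csv(
            outdir / f"{label}_composition_21nt.tsv", sep="\t", index=False, float_format="%.6g"
        )

        hits = dedupe_multimappers(align_library(clean, index, max_mm=2), "fractional")
        flat = [h for hs in hits.values() for h in hs]
        assignment = assign_phasi(flat, bundle.phasi_loci, totals_by_length=dist.counts)
        io.write_tsv(assignment.to_frame(bundle.phasi_loci), outdir / f"{label}_phasi_counts.tsv")
        total_mapped = sum(h.weight for h in flat)
        rpkm = quantify_rpkm_table(assignment.locus_counts, bundle.phasi_loci, total_mapped)
        io.write_tsv(rpkm, outdir / f"{label}_phasi_rpkm.tsv")

        mirna_counts = {m.name: 0.0 for m in bundle.mirnas}
        for read in clean:
            matches = align_mirna(read, bundle.mirnas, max_mm=1)
            for m in matches:
                mirna_counts[m.record.name] += 1.0 / len(matches)
        tpm = quantify_tpm(mirna_counts) if sum(mirna_counts.values()) else None
        if tpm is not None:
            io.write_tsv(tpm, outdir / f"{label}_mirna_tpm.tsv")
        results[label] = {
            "clean": clean,
            "report": report,
            "length_distribution": dist,
            "phasi": assignment,
            "mirna_tpm": tpm,
        }

    if results["rip"]["mirna_tpm"] is not None and results["igg"]["mirna_tpm"] is not None:
        enr = rip_vs_igg(
            dict(zip(results["rip"]["mirna_tpm"]["feature"], results["rip"]["mirna_tpm"]["tpm"])),
            dict(zip(results["igg"]["mirna_tpm"]["feature"], results["igg"]["mirna_tpm"]["tpm"])),
        )
        io.write_tsv(enr, outdir / "mirna_rip_vs_igg.tsv")
        results["mirna_enrichment"] = enr
    return results


def default_mrna_config() -> ReferenceConfig:
    """Sparse-coverage mRNA reference: 100 two-exon genes, ~1 Mb exonic.

    At 2e4 reads of 50 nt this gives ~1x background coverage — the sparse
    regime real RIP libraries occupy, where chance read clusters stay small.
    """
    return ReferenceConfig(
        chrom_lengths={"chr1": 600_000, "chr2": 600_000},
        n_loci_21=0,
        n_loci_24=0,
        n_hairpins=0,
        n_genes=100,
        exons_per_gene=2,
        exon_length=5_000,
        intron_length=200,
    )


def plant_sites(bundle, n_sites: int = 3, site_length: int = 200, seed: int = 0) -> list[BindingSite]:
    """Choose binding sites centered in exons of distinct genes."""
    import numpy as np

    rng = np.random.default_rng(seed)
    gene_idx = rng.choice(len(bundle.genes), size=n_sites, replace=False)
    sites = []
    for j, gi in enumerate(gene_idx):
        gene = bundle.genes[int(gi)]
        s, e = gene.exons[int(rng.integers(len(gene.exons)))]
        mid = (s + e) // 2
        sites.append(
            BindingSite(
                id=f"site{j + 1}",
                gene=gene.name,
                chrom=gene.chrom,
                start=mid - site_length // 2,
                end=mid + site_length // 2,
            )
        )
    return sites


def run_mrna_pipeline(
    outdir: str | Path,
    seed: int = 0,
    n_reads: int = 20_000,
    n_sites: int = 3,
    enrichment_fold: float = 10.0,
    repeats: int = 500,
) -> dict:
    """Simulate an mRNA RIP/IgG pair with planted sites and call peaks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = simulate_reference(default_mrna_config(), seed=seed)
    sites = plant_sites(bundle, n_sites=n_sites, seed=seed + 10)
    rip_reads, rip_truth = simulate_mrna_rip(
        bundle, sites, enrichment_fold=enrichment_fold, n_reads=n_reads, seed=seed + 11
    )
    igg_reads, igg_truth = simulate_igg_mrna(bundle, n_reads=n_reads, seed=seed + 12)
    io.write_genes_bed12(bundle.genes, outdir / "genes.bed")
    io.write_fastq(rip_reads, outdir / "mrna_rip.fastq")
    io.write_tsv(rip_truth, outdir / "mrna_rip_truth.tsv")

    peaks, nulls = call_peaks(
        hits_from_truth(rip_truth),
        bundle.genes,
        igg_hits=hits_from_truth(igg_truth),
        repeats=repeats,
        seed=seed + 13,
    )
    frame = peaks_to_frame(peaks)
    io.write_tsv(frame, outdir / "peaks.tsv")
    genes_bound = sorted(bound_genes(peaks))
    pd.DataFrame({"gene": genes_bound}).to_csv(outdir / "bound_genes.tsv", sep="\t", index=False)
    null_frame = pd.DataFrame(
        [(g, i, int(v)) for g in sorted(nulls) for i, v in enumerate(nulls[g].max_counts)],
        columns=["gene", "repeat", "max_cluster_count"],
    )
    io.write_tsv(null_frame, outdir / "null_distributions.tsv")
    return {
        "bundle": bundle,
        "sites": sites,
        "peaks": peaks,
        "peaks_frame": frame,
        "bound_genes": genes_bound,
        "nulls": nulls,
        "rip_truth": rip_truth,
        "igg_truth": igg_truth,
    }
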