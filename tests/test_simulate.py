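"""Generator tests: invariants, determinism, closed-form compositions."""

import math

import numpy as np
import pandas as pd
import pytest

from agorip import io
from agorip.simulate import (
    BindingSite,
    LibraryModel,
    ReferenceConfig,
    expected_five_prime_fractions,
    simulate_igg_mrna,
    simulate_mrna_rip,
    simulate_reference,
    simulate_rip_library,
    simulate_srna_library,
)


class TestReference:
    def test_bundle_invariants(self, small_bundle):
        small_bundle.validate()
        assert len(small_bundle.phasi_loci) == 10
        assert len(small_bundle.mirnas) == 10

    def test_locus_span_is_phase_multiple(self, small_bundle):
        for loc in small_bundle.phasi_loci:
            assert loc.span % loc.length_class == 0
        spans21 = {loc.span for loc in small_bundle.phasi_loci if loc.length_class == 21}
        assert spans21 == {210}  # 10 phases x 21 nt

    def test_arm_five_prime_bases_distinct(self, small_bundle):
        by_family = {}
        for rec in small_bundle.mirnas:
            by_family.setdefault(rec.family, {})[rec.arm] = rec.five_prime
        for arms in by_family.values():
            assert arms == {"5p": "A", "3p": "U"}

    def test_deterministic_outputs(self, tmp_path):
        config = ReferenceConfig(chrom_lengths={"chr1": 30_000})
        paths = []
        for run in (1, 2):
            bundle = simulate_reference(config, seed=9)
            fa = tmp_path / f"g{run}.fa"
            bed = tmp_path / f"l{run}.bed"
            io.write_fasta(bundle.genome, fa)
            io.write_loci_bed(bundle.phasi_loci, bed)
            paths.append((fa.read_bytes(), bed.read_bytes()))
        assert paths[0] == paths[1]

    def test_oversized_demand_errors(self):
        config = ReferenceConfig(chrom_lengths={"chr1": 500}, n_loci_21=10, phases_21=10)
        with pytest.raises(ValueError):
            simulate_reference(config, seed=0)


class TestSrnaLibrary:
    def test_pure_21_mixture(self, small_bundle):
        model = LibraryModel(
            length_mixture={21: 1.0}, mirna_fraction=0.0, n_base_rate=0.0
        )
        _, truth = simulate_srna_library(small_bundle, model, 500, seed=2)
        assert set(truth["insert_len"]) == {21}

    def test_phasi_reads_respect_register(self, small_bundle):
        model = LibraryModel(
            length_mixture={21: 1.0},
            phasi_fraction={21: 1.0},
            mirna_fraction=0.0,
            n_base_rate=0.0,
        )
        _, truth = simulate_srna_library(small_bundle, model, 400, seed=3)
        loci = {loc.id: loc for loc in small_bundle.phasi_loci}
        for row in truth.itertuples():
            assert row.origin_type == "phasi"
            loc = loci[row.origin_id]
            offset = row.start - loc.start if loc.strand == "+" else loc.end - row.end
            assert offset % 21 == 0

    def test_mixture_recovered_within_3se(self, small_bundle, library_model):
        n = 30_000
        _, truth = simulate_srna_library(small_bundle, library_model, n, seed=4)
        non_mirna = truth[truth["origin_type"] != "mirna"]
        for length, expect in ((21, 0.15), (24, 0.47)):
            obs = (non_mirna["insert_len"] == length).mean()
            se = math.sqrt(expect * (1 - expect) / len(non_mirna))
            assert abs(obs - expect) < 3 * se

    def test_truth_table_conservation(self, small_bundle, library_model):
        reads, truth = simulate_srna_library(small_bundle, library_model, 300, seed=5)
        assert [r.id for r in reads] == list(truth["read_id"])
        assert truth["read_id"].is_unique

    def test_adapter_present_and_reads_at_cycle_length(self, small_bundle):
        model = LibraryModel(n_base_rate=0.0)
        reads, truth = simulate_srna_library(small_bundle, model, 200, seed=6)
        for read, row in zip(reads, truth.itertuples()):
            assert len(read) == model.read_cycles
            tail = read.seq[row.insert_len :]
            expect = (model.adapter)[: len(tail)]
            # the adapter (possibly truncated, then padded) follows the insert
            assert tail[: len(model.adapter)] == expect[: len(tail)]

    def test_byte_identical_for_same_seed(self, small_bundle, library_model, tmp_path):
        blobs = []
        for run in (1, 2):
            reads, _ = simulate_srna_library(small_bundle, library_model, 200, seed=11)
            p = tmp_path / f"r{run}.fastq"
            io.write_fastq(reads, p)
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            LibraryModel(length_mixture={21: 0.6, 24: 0.6})


@pytest.fixture(scope="module")
def base(small_bundle):
    model = LibraryModel(mirna_fraction=0.0, n_base_rate=0.0)
    return simulate_srna_library(small_bundle, model, 20_000, seed=21)


class TestRipLibrary:
    def test_equal_weights_reproduce_base_composition(self, base):
        reads, truth = base
        _, rip_truth = simulate_rip_library(reads, truth, {}, 20_000, seed=22)
        for length in (21, 24):
            b = truth[truth.insert_len == length]["five_prime"].value_counts(normalize=True)
            r = rip_truth[rip_truth.insert_len == length]["five_prime"].value_counts(
                normalize=True
            )
            n = (rip_truth.insert_len == length).sum()
            for base_ in "ACGT":
                se = math.sqrt(max(b.get(base_, 0) * (1 - b.get(base_, 0)), 1e-9) / n)
                assert abs(r.get(base_, 0) - b.get(base_, 0)) < 4 * se

    def test_closed_form_selection(self, base):
        reads, truth = base
        weights = {21: {"T": 9.0}}
        _, rip_truth = simulate_rip_library(reads, truth, weights, 30_000, seed=23)
        expect = expected_five_prime_fractions(truth, weights, 21)
        sub = rip_truth[rip_truth.insert_len == 21]
        obs = (sub["five_prime"] == "T").mean()
        se = math.sqrt(expect["T"] * (1 - expect["T"]) / len(sub))
        assert abs(obs - expect["T"]) < 3 * se

    def test_zero_weight_excludes_base(self, base):
        reads, truth = base
        weights = {21: {"G": 0.0, "A": 1.0, "C": 1.0, "T": 1.0}}
        _, rip_truth = simulate_rip_library(reads, truth, weights, 5_000, seed=24)
        sub = rip_truth[rip_truth.insert_len == 21]
        assert (sub["five_prime"] == "G").sum() == 0

    def test_empty_base_population_errors(self):
        with pytest.raises(ValueError):
            simulate_rip_library([], pd.DataFrame(), {}, 10, seed=0)


@pytest.fixture(scope="module")
def gene_bundle():
    config = ReferenceConfig(
        chrom_lengths={"chr1": 80_000},
        n_loci_21=0,
        n_loci_24=0,
        n_hairpins=0,
        n_genes=6,
        exons_per_gene=2,
        exon_length=5_000,
        intron_length=200,
    )
    return simulate_reference(config, seed=31)


class TestMrnaRip:
    def site_in(self, bundle, gene_idx, width=200):
        gene = bundle.genes[gene_idx]
        s, e = gene.exons[0]
        mid = (s + e) // 2
        return BindingSite(f"site{gene_idx}", gene.name, gene.chrom, mid - width // 2, mid + width // 2)

    def test_fold_zero_is_pure_background(self, gene_bundle):
        site = self.site_in(gene_bundle, 0)
        _, truth = simulate_mrna_rip(gene_bundle, [site], 0.0, 500, seed=32)
        assert set(truth["origin"]) == {"background"}

    def test_no_background_all_reads_on_site(self, gene_bundle):
        site = self.site_in(gene_bundle, 1)
        _, truth = simulate_mrna_rip(
            gene_bundle, [site], 10.0, 200, frac_background=0.0, seed=33
        )
        assert set(truth["origin"]) == {site.id}
        assert ((truth["start"] < site.end) & (truth["end"] > site.start)).all()

    def test_per_site_counts_match_multinomial(self, gene_bundle):
        sites = [self.site_in(gene_bundle, i) for i in range(3)]
        n = 20_000
        _, truth = simulate_mrna_rip(gene_bundle, sites, 10.0, n, seed=34)
        exonic = sum(g.exonic_length for g in gene_bundle.genes)
        w_site = 9.0 * 200
        p = w_site / (exonic + 3 * w_site)
        counts = truth["origin"].value_counts()
        for s in sites:
            se = math.sqrt(n * p * (1 - p))
            assert abs(counts[s.id] - n * p) < 3 * se

    def test_site_outside_exon_errors(self, gene_bundle):
        gene = gene_bundle.genes[0]
        bad = BindingSite("bad", gene.name, gene.chrom, gene.exons[0][1] - 50, gene.exons[0][1] + 50)
        with pytest.raises(ValueError):
            simulate_mrna_rip(gene_bundle, [bad], 10.0, 100, seed=35)

    def test_igg_matches_fold_zero_model(self, gene_bundle):
        _, igg = simulate_igg_mrna(gene_bundle, 300, seed=36)
        assert set(igg["origin"]) == {"background"}
        # uniform over exonic space: every read inside some exon
        for row in igg.itertuples():
            gene = next(g for g in gene_bundle.genes if g.name == row.gene)
            assert any(s <= row.start and row.end <= e for s, e in gene.exons)
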