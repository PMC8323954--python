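"""Pileup parsing, VarScan-style calling, and heteroplasmy summaries."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodiv.genome_model import GeneAnnotation
from mitodiv.heteroplasmy import (
    DELETION,
    GAPPED,
    INSERTION,
    LONE_HIGH,
    PROGRESSIVE,
    HetCallerParams,
    HeteroplasmyCaller,
    PileupParseError,
    PileupSite,
    call_variants,
    frequency_gap_pattern,
    indel_composition,
    invariable_regions,
    read_pileup,
    read_vcf_variants,
    summarize_by_gene,
    write_pileup,
    write_vcf,
)
from mitodiv.simulate import HetSimConfig, generate_het_pileup


class TestPileupParsing:
    def test_substitution_symbols(self, tmp_path):
        p = tmp_path / "x.pileup"
        p.write_text("chrM\t5\tA\t10\t....,,..T,\tIIIIIIIIII\n")
        (site,) = read_pileup(p)
        assert site.base_calls == {"A": 9, "T": 1}
        assert (site.position, site.ref_base, site.coverage) == (5, "A", 10)

    def test_insertion_dialect(self, tmp_path):
        p = tmp_path / "x.pileup"
        p.write_text("chrM\t7\tC\t4\t..+2AT..\tIIII\n")
        (site,) = read_pileup(p)
        assert site.base_calls == {"C": 4, "+AT": 1}

    def test_deletion_and_read_markers(self, tmp_path):
        p = tmp_path / "x.pileup"
        p.write_text("chrM\t9\tG\t5\t^I..-1T.,$*\tIIIII\n")
        (site,) = read_pileup(p)
        assert site.base_calls == {"G": 4, "-T": 1, "*": 1}

    def test_malformed_indel_reports_line(self, tmp_path):
        p = tmp_path / "x.pileup"
        p.write_text("chrM\t1\tA\t2\t..\tII\nchrM\t2\tC\t2\t.+X.\tII\n")
        with pytest.raises(PileupParseError, match="line 2"):
            read_pileup(p)

    def test_round_trip_preserves_counts(self, tmp_path, het_exact):
        sites, *_ = het_exact
        subset = sites[:200]
        p = tmp_path / "x.pileup"
        write_pileup(subset, p)
        back = read_pileup(p)
        assert [s.base_calls for s in back] == [s.base_calls for s in subset]


def one_site(ref="A", cov=100, **calls):
    base = {ref: cov - sum(c for k, c in calls.items() if not k.startswith(("+", "-")))}
    base.update(calls)
    return PileupSite(position=1, ref_base=ref, coverage=cov, base_calls=base)


class TestCalling:
    def test_insertion_called_heteroplasmic(self):
        (v,) = call_variants([one_site(**{"+T": 30})])
        assert v.var_type == INSERTION
        assert (v.ref_allele, v.alt_allele) == ("A", "AT")
        assert v.frequency == pytest.approx(0.30)
        assert v.zygosity_call == "heteroplasmic" and v.called

    def test_below_min_reads_not_called(self):
        assert call_variants([one_site(G=3)]) == []

    def test_majority_deletion_is_consensus(self):
        (v,) = call_variants([one_site(**{"-AA": 60})])
        assert v.var_type == DELETION
        assert (v.ref_allele, v.alt_allele) == ("AAA", "A")
        assert v.zygosity_call == "consensus"

    def test_zero_coverage_site_skipped(self):
        site = PileupSite(position=1, ref_base="A", coverage=0, base_calls={})
        assert call_variants([site]) == []

    def test_pvalue_monotone_in_support(self):
        ps = [call_variants([one_site(G=k)])[0].p_value for k in range(4, 40, 5)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_failing_error_test_flagged_not_called(self):
        # 4 of 400 reads is consistent with a 1% error rate
        (v,) = call_variants([one_site(cov=400, G=4)])
        assert not v.called

    def test_homopolymer_context_annotated(self):
        genome = "ACGTTTTTAC"
        site = PileupSite(position=3, ref_base="G", coverage=50, base_calls={"G": 50, "+T": 10})
        (v,) = call_variants([site], genome_sequence=genome)
        assert v.homopolymer_run == 5

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=200),  # coverage
                st.integers(min_value=0, max_value=200),  # variant reads
            ),
            min_size=1, max_size=20,
        )
    )
    def test_threshold_contract_on_random_pileups(self, spec):
        sites = [
            PileupSite(
                position=i + 1, ref_base="A", coverage=cov,
                base_calls={"A": max(cov - min(var, cov), 0), "G": min(var, cov)},
            )
            for i, (cov, var) in enumerate(spec)
        ]
        for v in call_variants(sites):
            assert v.supporting_reads >= 4
            assert v.frequency == v.supporting_reads / v.coverage


class TestSummaries:
    def test_gene_bins_and_vi(self, het_exact):
        sites, genome, annotations, truth = het_exact
        caller = HeteroplasmyCaller().fit(sites)
        table = caller.gene_table(annotations, L=genome.length)
        nd3 = table.vi("ND3")
        assert nd3 == pytest.approx(100 * 13 / 352, abs=1e-6)
        # every planted per-gene count is recovered under noise-off conditions
        planted = {}
        for v in truth.variants:
            planted[v["gene"]] = planted.get(v["gene"], 0) + 1
        for gene, n in planted.items():
            assert table.row_total(gene) == n

    def test_gene_without_variants_absent(self, het_exact):
        sites, genome, annotations, _ = het_exact
        table = HeteroplasmyCaller().fit(sites).gene_table(annotations, L=genome.length)
        assert "CS6" in table.rows  # has one planted variant
        assert all(table.row_total(g) > 0 for g in table.rows)

    def test_indel_composition_counts(self):
        variants = call_variants(
            [
                one_site(**{"+T": 20}),
                dataclasses.replace(one_site(**{"+T": 10}), position=5),
                dataclasses.replace(one_site(**{"-A": 10}), position=9),
            ]
        )
        comp = indel_composition(variants)
        assert comp["insertions_by_seq"] == {"T": 2}
        assert comp["deletions_by_seq"] == {"A": 1}

    def test_cg_deletion_share(self):
        sites = []
        seqs = ["C"] * 9 + ["G"] * 6 + ["T"] * 36 + ["A"] * 20 + ["AA"]
        for i, s in enumerate(seqs):
            sites.append(dataclasses.replace(one_site(**{f"-{s}": 30}), position=4 * i + 1))
        comp = indel_composition(call_variants(sites))
        assert comp["n_deletions"] == 72
        cg = comp["deletion_base_share_pct"]["C"] + comp["deletion_base_share_pct"]["G"]
        assert cg == pytest.approx(100 * 15 / 72, abs=1e-6)

    def test_planted_composition_recovered_exactly(self, het_exact):
        sites, genome, _, _ = het_exact
        comp = HeteroplasmyCaller().fit(sites).composition()
        assert (comp["n_insertions"], comp["n_deletions"], comp["n_substitutions"]) == (
            112, 72, 2,
        )
        assert comp["insertion_base_counts"]["T"] >= 66
        assert comp["largest_indel_bp"] == 2


class TestInvariableRegions:
    def test_circular_gaps(self):
        gaps = invariable_regions([100, 700], L=1000)
        assert [g["gap_bp"] for g in gaps] == [600, 400]

    def test_single_variant_full_circle(self):
        (g,) = invariable_regions([123], L=1000)
        assert g["gap_bp"] == 1000

    def test_planted_stretch_recovered(self, het_exact):
        sites, genome, _, truth = het_exact
        caller = HeteroplasmyCaller().fit(sites)
        max_gap = caller.invariable_regions(genome.length)[0]["gap_bp"]
        assert max_gap >= 548


class TestFrequencyPattern:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([3, 2, 1, 0, 0, 0], PROGRESSIVE),
            ([1, 0, 0, 0, 0, 0], PROGRESSIVE),
            ([5, 4, 2, 0, 0, 1], GAPPED),
            ([0, 0, 1, 0, 0, 0], LONE_HIGH),
            ([0, 2, 1, 0, 0, 0], GAPPED),
        ],
    )
    def test_shapes(self, counts, expected):
        assert frequency_gap_pattern(np.array(counts)) == expected

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            frequency_gap_pattern(np.zeros(6))


class TestVcf:
    def test_round_trip(self, tmp_path):
        variants = call_variants(
            [one_site(**{"+T": 30}), dataclasses.replace(one_site(**{"-A": 10}), position=7)]
        )
        p = tmp_path / "c.vcf"
        write_vcf(variants, p, contig_length=100)
        back = read_vcf_variants(p)
        assert [(v.position, v.ref_allele, v.alt_allele, v.var_type) for v in back] == [
            (v.position, v.ref_allele, v.alt_allele, v.var_type) for v in variants
        ]


class TestFrequencyRecovery:
    def test_binomial_mode_mean_frequency_within_sampling_noise(self):
        # 100 planted loci at ~25% on constant depth 100: the mean recovered
        # frequency must sit within the single-locus 3-sigma binomial band
        cfg = HetSimConfig(
            genome_length=6000,
            genes=(("G1", "ND", 5000, (0, 0, 100, 0, 0, 0)),),
            composition=(("+", "T", 50), ("-", "A", 50)),
            mean_coverage=100.0,
            coverage_sd=0.0,
            min_coverage=100,
            seed=23,
        )
        sites, genome, annotations, truth = generate_het_pileup(cfg)
        called = HeteroplasmyCaller().fit(sites).called_variants_
        by_pos = {v.position: v for v in called}
        recovered, planted = [], []
        for t in truth.variants:
            assert t["position"] in by_pos
            recovered.append(by_pos[t["position"]].frequency)
            planted.append(t["fraction"])
        f = float(np.mean(planted))
        bound = 3 * np.sqrt(f * (1 - f) / 100)
        assert abs(np.mean(recovered) - f) <= bound
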