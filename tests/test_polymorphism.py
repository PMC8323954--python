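"""Polymorphic-site scanning, reference designation, typing and binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodiv.genome_model import Msa
from mitodiv.polymorphism import (
    ConsistencyError,
    FreqBinTable,
    PolymorphicSite,
    PolymorphismScanner,
    classify_site,
    designate_reference,
    per_gene_variant_table,
    scan_sites,
    site_type_tabulation,
    variability_index,
    weighted_bin_distribution,
)


def make_site(alleles, denom=None, column=1):
    return PolymorphicSite(
        msa_column=column,
        reference_position=column,
        alleles=dict(alleles),
        denominator=denom or sum(alleles.values()),
    )


class TestScan:
    def test_monomorphic_and_all_n_columns_skipped(self):
        msa = Msa([("a", "AANA"), ("b", "AANG"), ("c", "AANG")])
        sites = scan_sites(msa)
        assert [s.msa_column for s in sites] == [4]

    def test_allele_counts(self):
        msa = Msa([(f"s{i}", "A" if i < 40 else "G") for i in range(45)])
        (site,) = scan_sites(msa)
        assert site.alleles == {"A": 40, "G": 5}
        assert site.reference_allele == "A"
        assert site.variant_frequencies == [5 / 45]

    def test_n_excluded_from_denominator(self):
        msa = Msa([("a", "A"), ("b", "A"), ("c", "G"), ("d", "N")])
        (site,) = scan_sites(msa)
        assert site.denominator == 3
        assert site.variant_frequencies == [pytest.approx(1 / 3)]

    def test_panel_recovers_planted_columns_and_frequencies(self, panel):
        msa, truth = panel
        sites = scan_sites(msa)
        assert len(sites) == truth.n_polymorphic
        planted = truth.frequencies()
        by_col = {s.msa_column: s for s in sites}
        assert set(by_col) == set(planted)
        for col, freqs in planted.items():
            assert sorted(by_col[col].variant_frequencies) == pytest.approx(sorted(freqs))

    def test_site_count_invariant_under_row_and_column_permutation(self, tiny_msa):
        n0 = len(scan_sites(tiny_msa))
        rng = np.random.default_rng(0)
        shuffled_rows = Msa(list(np.random.default_rng(1).permutation(tiny_msa.records)))
        assert len(scan_sites(shuffled_rows)) == n0
        perm = rng.permutation(tiny_msa.n_cols)
        assert len(scan_sites(tiny_msa.resample_columns(perm))) == n0


class TestDesignation:
    def test_majority_is_reference(self):
        site = designate_reference(make_site({"A": 27, "G": 18}))
        assert site.reference_allele == "A" and site.variant_alleles == ["G"]

    def test_50_50_tie_yields_single_variant(self):
        site = designate_reference(make_site({"A": 22, "G": 22}), reference_char="G")
        assert site.reference_allele == "G"
        assert site.variant_alleles == ["A"]
        assert site.variant_frequencies == [pytest.approx(0.5)]

    def test_50_50_tie_without_reference_char_is_lexicographic(self):
        site = designate_reference(make_site({"T": 2, "C": 2}))
        assert site.reference_allele == "C"

    def test_multiallelic_most_frequent_is_reference(self):
        site = designate_reference(make_site({"A": 22, "G": 14, "T": 8}))
        assert site.reference_allele == "A"
        assert site.variant_alleles == ["G", "T"]

    @settings(deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(list("ACGT-")),
            st.integers(min_value=1, max_value=50),
            min_size=2, max_size=5,
        )
    )
    def test_no_designated_variant_exceeds_half(self, alleles):
        site = designate_reference(make_site(alleles))
        assert all(f <= 0.5 + 1e-12 for f in site.variant_frequencies)


class TestClassification:
    @pytest.mark.parametrize(
        "alleles,ref_char,expected",
        [
            ({"A": 3, "G": 1}, None, {"transition"}),
            ({"A": 3, "T": 1}, None, {"transversion"}),
            ({"C": 3, "T": 2, "G": 1}, None, {"transition", "transversion"}),
            ({"A": 3, "-": 1}, None, {"indel"}),
            ({"C": 4, "-": 1, "T": 1}, None, {"indel", "transition"}),
        ],
    )
    def test_flag_combinations(self, alleles, ref_char, expected):
        site = designate_reference(make_site(alleles), reference_char=ref_char)
        assert classify_site(site) == frozenset(expected)

    def test_every_site_has_a_flag_and_tabulation_partitions(self, panel):
        msa, _ = panel
        sites = scan_sites(msa)
        assert all(s.type_flags for s in sites)
        assert sum(site_type_tabulation(sites).values()) == len(sites)


class TestVariabilityIndex:
    @pytest.mark.parametrize(
        "n,length,decimals,expected",
        [(95, 354, 1, 26.8), (3, 11, 1, 27.3), (0, 100, 1, 0.0), (13, 352, 2, 3.69)],
    )
    def test_reported_percentages(self, n, length, decimals, expected):
        assert round(variability_index(n, length).vi, decimals) == expected

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            variability_index(1, 0)


class TestWeightedBins:
    def test_two_variant_site_splits_weight(self):
        site = make_site({"A": 16, "C": 1, "G": 3}, denom=20)
        designate_reference(site)
        classify_site(site)
        table = weighted_bin_distribution([site])
        # variants at 5% and 15% -> half a unit in each of the two lowest bins
        assert list(table.rows["all"][:2]) == [0.5, 0.5]
        assert table.grand_total == pytest.approx(1.0)

    def test_single_variant_unit_weight(self):
        site = designate_reference(make_site({"A": 6, "G": 4}))
        table = weighted_bin_distribution([site])
        assert table.rows["all"][3] == 1.0  # 40% -> (30, 40]

    def test_variant_above_half_raises(self):
        site = make_site({"A": 2, "G": 8})
        site.reference_allele = "A"
        site.variant_alleles = ["G"]
        site.variant_frequencies = [0.8]
        with pytest.raises(ConsistencyError):
            weighted_bin_distribution([site])

    def test_grand_total_equals_site_count_on_random_panels(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            arr = rng.choice(list("ACGT-"), size=(8, 30), p=[0.3, 0.2, 0.2, 0.25, 0.05])
            msa = Msa([(f"s{i}", "".join(row)) for i, row in enumerate(arr)])
            sites = scan_sites(msa)
            if not sites:
                continue
            table = weighted_bin_distribution(sites)
            assert table.grand_total == pytest.approx(len(sites))


class TestPerGeneTable:
    def test_quartet_singleton_and_doubleton_classes(self, quartet):
        msa, annotations, truth = quartet
        scanner = PolymorphismScanner().fit(msa)
        table = scanner.gene_table(annotations)
        for name, info in truth.per_gene.items():
            if info["n25"] + info["n50"] == 0:
                continue
            assert list(table.rows[name]) == [info["n25"], info["n50"]]
        cox1 = table.vi("COX1")
        assert cox1 == pytest.approx(6.00, abs=0.005)

    def test_two_vs_two_split_counts_single_50pct_variant(self):
        msa = Msa([("a", "A"), ("b", "A"), ("c", "G"), ("d", "G")])
        from mitodiv.genome_model import GeneAnnotation

        table = per_gene_variant_table(
            scan_sites(msa), [GeneAnnotation("g", "ND", ((1, 1),))], n_seqs=4
        )
        assert list(table.rows["g"]) == [0, 1]

    def test_intergenic_sites_excluded_by_default(self, quartet):
        msa, annotations, truth = quartet
        table = PolymorphismScanner().fit(msa).gene_table(annotations)
        assert table.grand_total == truth.n_sites  # all planted sites lie in genes
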