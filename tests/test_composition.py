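import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from compbias import composition as comp
from compbias.genome_io import CdsSequence


class TestGcFraction:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ATAT", 0.0), ("GCGC", 1.0), ("ATGN", 1 / 3), ("AcGt", 0.5)],
    )
    def test_values(self, seq, expected):
        assert comp.gc_fraction(seq) == pytest.approx(expected)

    def test_count_as_non_gc_policy(self):
        assert comp.gc_fraction("ATGN", policy="count_as_non_gc") == pytest.approx(0.25)

    def test_all_ambiguous_signalled(self):
        with pytest.raises(ValueError, match="ambiguous"):
            comp.gc_fraction("NNNN")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            comp.gc_fraction("")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_purine_swap_complements_gc(self, seq):
        # A<->G, T<->C swaps GC for AT, so the fractions sum to 1
        swapped = seq.translate(str.maketrans("AGTC", "GACT"))
        assert comp.gc_fraction(seq) + comp.gc_fraction(swapped) == pytest.approx(1.0)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_reverse_complement(self, seq):
        from compbias.genome_io import reverse_complement

        assert comp.gc_fraction(seq) == pytest.approx(
            comp.gc_fraction(reverse_complement(seq))
        )


class TestGc3:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ATGAAATGA", 0.5),  # thirds G, A; stop excluded
            ("ATGGGCGGG", 1.0),  # no stop: thirds G, C, G — all G/C
            ("ATGGGAGGG", 2 / 3),  # thirds G, A, G
        ],
    )
    def test_values(self, seq, expected):
        assert comp.gc3(seq) == pytest.approx(expected)

    def test_trailing_partial_codon_truncated(self):
        assert comp.gc3("ATGAAATGAG") == pytest.approx(0.5)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            comp.gc3("ATG")

    def test_pooled_excludes_each_terminal_stop(self):
        # thirds: {G, A} from gene 1 (stop dropped), {G} from gene 2
        assert comp.pooled_gc3(["ATGAAATGA", "ATGTAA"]) == pytest.approx(2 / 3)


class TestCodonCountsAndRscu:
    def test_single_codon(self):
        profile = comp.codon_counts(["ATGATG"])
        assert profile.counts["ATG"] == 2
        assert profile.total_codons == 2

    def test_pooled_counts(self):
        profile = comp.codon_counts(["ATGAAA", "AAATGA"])
        assert profile.counts["ATG"] == 1
        assert profile.counts["AAA"] == 2
        assert profile.counts["TGA"] == 1

    def test_empty_input_all_zero(self):
        profile = comp.codon_counts([])
        assert profile.total_codons == 0
        assert all(v == 0 for v in profile.counts.values())

    def test_ambiguous_codons_skipped_and_tallied(self):
        profile = comp.codon_counts(["ATGNNNAAA"])
        assert profile.total_codons == 2
        assert profile.skipped_ambiguous == 1

    def test_pooling_linearity(self, cds_set):
        pooled = comp.codon_counts(cds_set)
        summed = {c: 0 for c in comp.ALL_CODONS}
        for cds in cds_set:
            single = comp.codon_counts([cds])
            for c in comp.ALL_CODONS:
                summed[c] += single.counts[c]
        assert pooled.counts == summed

    def test_rscu_uniform_two_fold_family(self):
        profile = comp.codon_counts(["AAAAAG"])  # Lys family used equally
        comp.rscu(profile)
        assert profile.rscu["AAA"] == pytest.approx(1.0)
        assert profile.rscu["AAG"] == pytest.approx(1.0)

    def test_rscu_three_one_split(self):
        profile = comp.codon_counts(["AAAAAAAAAAAG"])  # Lys 3:1
        comp.rscu(profile)
        assert profile.rscu["AAA"] == pytest.approx(1.5)
        assert profile.rscu["AAG"] == pytest.approx(0.5)

    def test_met_single_codon_family(self):
        profile = comp.rscu(comp.codon_counts(["ATGATG"]))
        assert profile.rscu["ATG"] == pytest.approx(1.0)

    def test_family_sums_equal_family_size(self, cds_set):
        profile = comp.rscu(comp.codon_counts(cds_set))
        for aa, family in comp.SYNONYMOUS_FAMILIES.items():
            total = sum(profile.counts[c] for c in family)
            if total == 0:
                continue
            assert sum(profile.rscu[c] for c in family) == pytest.approx(len(family))

    def test_rscu_recovers_generating_bias(self):
        # sampling convergence: estimated RSCU within 3 SE at 1e5 codons
        from compbias.simulate import SimulationSpec, at_rich_codon_table, sim_cds_set, sim_genome

        spec = SimulationSpec(seed=2)
        spec.genome.length = 500_000
        spec.cds.n_genes = 400
        spec.cds.mean_codons = 180
        genome = sim_genome(spec)
        _, _, truth = sim_cds_set(spec, genome)
        profile = comp.rscu(comp.codon_counts(list(truth["cds"])))
        assert profile.total_codons > 5e4
        freqs = at_rich_codon_table()
        for aa, family in comp.SYNONYMOUS_FAMILIES.items():
            fam_total_p = sum(freqs[c] for c in family)
            n_fam = sum(profile.counts[c] for c in family)
            for c in family:
                p_within = freqs[c] / fam_total_p
                expected = len(family) * p_within
                se = len(family) * math.sqrt(p_within * (1 - p_within) / n_fam)
                assert abs(profile.rscu[c] - expected) <= max(3 * se, 1e-9), (aa, c)


class TestNitrogen:
    @pytest.mark.parametrize(
        "seq, expected", [("GGG", 5.0), ("TT", 2.0), ("AT", 3.5), ("GC", 4.0)]
    )
    def test_per_base(self, seq, expected):
        assert comp.nitrogen_per_base(seq) == pytest.approx(expected)

    def test_duplex_pair_accounting(self):
        # G:C pair carries 8 N, A:T pair 7 N
        assert comp.nitrogen_per_base("GC", duplex=True) == pytest.approx(8.0)
        assert comp.nitrogen_per_base("AT", duplex=True) == pytest.approx(7.0)

    @pytest.mark.parametrize("prot, expected", [("G", 1.0), ("R", 4.0), ("KR", 3.0)])
    def test_per_residue(self, prot, expected):
        assert comp.nitrogen_per_residue(prot) == pytest.approx(expected)

    def test_sidechain_only_excludes_backbone(self):
        assert comp.nitrogen_per_residue("KR", sidechain_only=True) == pytest.approx(2.0)

    def test_empty_and_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            comp.nitrogen_per_residue("")
        with pytest.raises(ValueError):
            comp.nitrogen_per_base("NNN")


class TestTranslate:
    @pytest.mark.parametrize(
        "seq, expected", [("ATGAAATGA", "MK"), ("ATG", "M"), ("ATGNNN", "MX")]
    )
    def test_values(self, seq, expected):
        assert comp.translate(seq) == expected


class TestProfileComparison:
    def test_identical_profiles_distance_zero(self, cds_set):
        p1 = comp.rscu(comp.codon_counts(cds_set))
        p2 = comp.rscu(comp.codon_counts(cds_set))
        dist, _, _ = comp.compare_codon_profiles({"a": p1, "b": p2})
        assert dist.loc["a", "b"] == pytest.approx(0.0)

    def test_single_family_difference(self):
        # profiles identical except the Lys family: RSCU (1,1) vs (1.5,0.5)
        pa = comp.rscu(comp.codon_counts(["AAAAAGATG"]))
        pb = comp.rscu(comp.codon_counts(["AAAAAAAAAAAGATG"]))
        dist, _, _ = comp.compare_codon_profiles({"a": pa, "b": pb})
        assert dist.loc["a", "b"] == pytest.approx(math.hypot(0.5, 0.5))

    def test_projection_variance_nonincreasing(self, cds_set, rng):
        profiles = {}
        for k in range(3):
            subset = [cds_set[i] for i in rng.permutation(len(cds_set))[:20]]
            profiles[f"p{k}"] = comp.rscu(comp.codon_counts(subset))
        _, proj, var = comp.compare_codon_profiles(profiles)
        assert np.all(np.diff(var) <= 1e-12)

    def test_fewer_than_two_profiles_rejected(self, cds_set):
        with pytest.raises(ValueError):
            comp.compare_codon_profiles({"a": comp.rscu(comp.codon_counts(cds_set))})


class TestWelch:
    def test_identical_groups(self):
        c = comp.compare_gene_sets_gc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.t_statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_textbook_example(self):
        # hand computation: t = -10/sqrt(8/3), df = 4
        c = comp.compare_gene_sets_gc([10, 12, 14], [20, 22, 24])
        assert c.t_statistic == pytest.approx(-6.123724, abs=1e-5)
        assert c.df == pytest.approx(4.0)
        assert c.p_value == pytest.approx(0.003602, abs=1e-5)

    def test_zero_variance_equal_means(self):
        c = comp.compare_gene_sets_gc([5.0, 5.0], [5.0, 5.0])
        assert (c.t_statistic, c.p_value) == (0.0, 1.0)

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(2, 40))
            b = rng.normal(0.3, 1.7, rng.integers(2, 40))
            t, p, _ = comp.welch_ttest(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert abs(t - ref.statistic) < 1e-10
            assert abs(p - ref.pvalue) < 1e-10
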