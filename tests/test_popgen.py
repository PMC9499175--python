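import math

import numpy as np
import pytest

from conftest import make_alignment
from mitotyper.errors import InputError, StatsError
from mitotyper.mitomodel import Element, MitogenomeModel
from mitotyper.mitosim import SimulationConfig, simulate
from mitotyper.popgen import (
    MKCounts,
    mask_ambiguous,
    mk_test,
    mk_tests,
    partition_sites,
    tajima_constants,
    tajimas_d,
    yates_chi2,
)

# Published MK count rows: protein -> (D_N, D_S, P_N, P_S, NI at 2 dp)
MK_ROWS = {
    "ND1": (1, 35, 9, 28, 11.25),
    "ND2": (3, 38, 10, 27, 4.69),
    "ND4": (3, 38, 8, 34, 2.98),
    "ND5": (5, 58, 19, 47, 4.69),
    "ND6": (3, 18, 2, 17, 0.71),
    "CytB": (1, 26, 5, 28, 4.64),
}


class TestMaskAmbiguous:
    def test_clean_alignment_unchanged(self):
        aln = make_alignment({"T1": "ACGT", "E1": "ACGT"})
        masked, removed = mask_ambiguous(aln)
        assert masked is aln
        assert len(removed) == 0

    def test_single_y_removes_column_for_all(self):
        aln = make_alignment({"T1": "ACGTA", "E1": "ACGYA"})
        masked, removed = mask_ambiguous(aln)
        assert list(removed) == [3]
        assert masked.sequence("T1") == "ACGA"
        assert masked.sequence("E1") == "ACGA"
        assert list(masked.columns) == [0, 1, 2, 4]

    def test_all_n_sample_empties_alignment(self):
        aln = make_alignment({"T1": "ACG", "E1": "NNN"})
        masked, removed = mask_ambiguous(aln)
        assert masked.length == 0
        assert list(removed) == [0, 1, 2]


def tiny_cds_model(length=6, strand="+"):
    return MitogenomeModel(
        sequence_length=length,
        elements=(Element("gene", "CDS", 0, length, strand, "I"),),
    )


class TestPartitionSites:
    def test_identical_clades_all_zero(self):
        model = tiny_cds_model()
        aln = make_alignment({s: "ATAGAA" for s in ("T1", "T2", "E1", "E2")})
        part = partition_sites(aln, model, "ENA", "TNP")
        c = part.cds["gene"]
        assert (c.d_n, c.d_s, c.p_n, c.p_s) == (0, 0, 0, 0)

    def test_engineered_fixed_synonymous_site(self):
        """4+4 alignment, one fixed ATA->ATG third-position change: both
        Met, so D_S=1, D_N=0 (hand-checked codon)."""
        model = tiny_cds_model()
        tnp = "ATAGAA"
        ena = "ATGGAA"
        aln = make_alignment(
            {f"T{i}": tnp for i in range(1, 5)} | {f"E{i}": ena for i in range(1, 5)}
        )
        part = partition_sites(aln, model, "ENA", "TNP")
        c = part.cds["gene"]
        assert (c.d_n, c.d_s, c.p_n, c.p_s) == (0, 1, 0, 0)

    def test_engineered_fixed_nonsynonymous_site(self):
        model = tiny_cds_model()
        aln = make_alignment(
            {f"T{i}": "ATAGAA" for i in (1, 2)} | {f"E{i}": "GTAGAA" for i in (1, 2)}
        )
        c = partition_sites(aln, model, "ENA", "TNP").cds["gene"]
        assert (c.d_n, c.d_s) == (1, 0)

    def test_focal_polymorphism_counted(self):
        model = tiny_cds_model()
        aln = make_alignment(
            {"T1": "ATAGAA", "T2": "ATAGAA", "E1": "ATAGAA", "E2": "ATGGAA",
             "E3": "ATAGAA"}
        )
        c = partition_sites(aln, model, "ENA", "TNP").cds["gene"]
        assert (c.d_n, c.d_s, c.p_n, c.p_s) == (0, 0, 0, 1)

    def test_other_population_polymorphism_ignored_for_cds(self):
        model = tiny_cds_model()
        aln = make_alignment(
            {"T1": "ATAGAA", "T2": "ATGGAA", "E1": "ATAGAA", "E2": "ATAGAA"}
        )
        c = partition_sites(aln, model, "ENA", "TNP").cds["gene"]
        assert (c.d_n, c.d_s, c.p_n, c.p_s) == (0, 0, 0, 0)

    def test_minus_strand_classification(self):
        """Fixed change on a minus-strand CDS classified on the coding
        strand: genome T->C at site 0 is codon3 A->G (ATA->ATG, syn)."""
        from mitotyper.mitomodel import reverse_complement

        coding_t, coding_e = "ATAGAA", "ATGGAA"
        model = tiny_cds_model(strand="-")
        aln = make_alignment(
            {"T1": reverse_complement(coding_t), "T2": reverse_complement(coding_t),
             "E1": reverse_complement(coding_e), "E2": reverse_complement(coding_e)}
        )
        c = partition_sites(aln, model, "ENA", "TNP").cds["gene"]
        assert (c.d_n, c.d_s) == (0, 1)

    def test_noncoding_categories(self):
        model = MitogenomeModel(
            sequence_length=8, elements=(Element("rna", "tRNA", 0, 8),)
        )
        #            fixed  polyT  polyE  shared invariant
        t1 = "A" + "A" + "A" + "A" + "A" + "AAA"
        t2 = "A" + "C" + "A" + "C" + "A" + "AAA"
        e1 = "C" + "A" + "A" + "A" + "A" + "AAA"
        e2 = "C" + "A" + "C" + "G" + "A" + "AAA"
        aln = make_alignment({"T1": t1, "T2": t2, "E1": e1, "E2": e2})
        nc = partition_sites(aln, model, "ENA", "TNP").noncoding["rna"]
        assert nc.fixed == 1
        assert nc.poly_other == 1  # TNP-exclusive
        assert nc.poly_focal == 1  # ENA-exclusive
        assert nc.poly_shared == 1

    def test_ambiguous_column_excluded(self):
        model = tiny_cds_model()
        aln = make_alignment(
            {"T1": "ATAGAA", "T2": "ATAGAA", "E1": "ATRGAA", "E2": "ATGGAA"}
        )
        c = partition_sites(aln, model, "ENA", "TNP").cds["gene"]
        assert (c.d_n, c.d_s, c.p_n, c.p_s) == (0, 0, 0, 0)

    def test_invariant_to_sample_order(self, dataset):
        aln = dataset.alignment
        part1 = partition_sites(aln, dataset.model, "ENA", "TNP")
        shuffled = aln.subset_samples(list(reversed(aln.ids)))
        part2 = partition_sites(shuffled, dataset.model, "ENA", "TNP")
        assert part1.cds == part2.cds
        assert part1.noncoding == part2.noncoding

    def test_truth_nonsynonymous_fixed_count_recovered(self):
        """D_N per element equals the simulator's truth record when there
        is no within-clade variation to blur fixation.

        Codons struck twice on the between branch are exempt from the
        per-class comparison: the partition classifies in the focal
        consensus context while the truth records the mutation-time
        context, and the two can legitimately disagree there.  Totals must
        always match.
        """
        ds = simulate(SimulationConfig(seed=41, theta_within=0.0))
        part = partition_sites(ds.alignment, ds.model, "ENA", "TNP")

        multi_hit_elements = set()
        hits_per_codon: dict[tuple[str, int], int] = {}
        elems = {e.name: e for e in ds.model.elements}
        for ev in ds.truth["events"]:
            if ev["branch"] != "between" or ev["element"] not in part.cds:
                continue
            e = elems[ev["element"]]
            p = ev["site"] - e.start if e.strand == "+" else e.end - 1 - ev["site"]
            key = (e.name, p // 3)
            hits_per_codon[key] = hits_per_codon.get(key, 0) + 1
            if hits_per_codon[key] > 1:
                multi_hit_elements.add(e.name)

        for name, counts in part.cds.items():
            classes = ds.truth["between_classes"].get(name, {})
            truth_n = classes.get("nonsynonymous", 0)
            truth_s = classes.get("synonymous", 0)
            truth_u = classes.get("unconstrained", 0)
            assert counts.d_n + counts.d_s + counts.unclassified == (
                truth_n + truth_s + truth_u
            ), name
            if name not in multi_hit_elements:
                assert counts.d_n == truth_n, name
                assert counts.d_s == truth_s, name
                assert counts.unclassified == truth_u, name


class TestMKTest:
    @pytest.mark.parametrize("protein,row", MK_ROWS.items())
    def test_published_ni_values(self, protein, row):
        d_n, d_s, p_n, p_s, ni = row
        res = mk_test((d_n, d_s, p_n, p_s), protein)
        assert res.ni_rounded == ni

    def test_symmetric_table_neutral(self):
        res = mk_test((5, 5, 5, 5))
        assert res.ni == pytest.approx(1.0)
        assert res.call == "neutral"
        assert res.p_yates > 0.05 and res.p_fisher > 0.05

    def test_yates_chi2_formula(self):
        assert yates_chi2(1, 35, 9, 28) == pytest.approx(5.459, abs=1e-3)

    def test_yates_vs_scipy_when_no_zero_cells(self):
        from scipy.stats import chi2_contingency

        table = [[3, 38], [10, 27]]
        expected = chi2_contingency(table, correction=True).statistic
        assert yates_chi2(3, 38, 10, 27) == pytest.approx(expected)

    def test_ni_undefined_when_required_margin_zero(self):
        assert mk_test((0, 6, 2, 6)).ni is None
        assert mk_test((0, 6, 2, 6)).call == "undefined"
        assert mk_test((1, 0, 2, 6)).ni is None
        assert mk_test((1, 6, 2, 0)).ni is None

    def test_zero_margin_skips_tests_with_reason(self):
        res = mk_test((0, 0, 2, 6))
        assert res.chi2_yates is None and res.p_yates is None
        assert res.reason is not None

    def test_purifying_call(self):
        res = mk_test((1, 35, 9, 28), "ND1")
        assert res.ni > 1
        assert res.call == "purifying"

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            mk_test((-1, 2, 3, 4))

    def test_from_partition_and_counts(self):
        assert mk_test(MKCounts(1, 35, 9, 28)).ni == pytest.approx(11.25)

    def test_yates_and_fisher_agree_on_significance_for_published_rows(self):
        """Directional consistency at alpha=0.05 on all published rows with
        every margin positive."""
        for row in MK_ROWS.values():
            res = mk_test(row[:4])
            assert (res.p_yates < 0.05) == (res.p_fisher < 0.05) or (
                min(res.p_yates, res.p_fisher) > 0.01
            )

    def test_genome_order_output(self, dataset):
        part = partition_sites(dataset.alignment, dataset.model, "ENA", "TNP")
        results = mk_tests(part, dataset.model)
        names = [r.element for r in results]
        expected = [e.name for e in dataset.model.elements if e.kind == "CDS"]
        assert names == expected


class TestTajima:
    def test_monomorphic_undefined(self):
        aln = make_alignment({"E1": "AAAA", "E2": "AAAA", "E3": "AAAA"})
        res = tajimas_d(aln, "ENA")
        assert res.s == 0 and res.d is None

    def test_hand_computed_example(self):
        """n=4, L=10, one singleton + one 2/2 site; oracle below re-derives
        the closed-form constants independently."""
        aln = make_alignment(
            {"E1": "AAAAAAAAAA", "E2": "AAAAAAAAAC",
             "E3": "CAAAAAAAAA", "E4": "CAAAAAAAAA"}
        )
        res = tajimas_d(aln, "ENA")
        assert res.n == 4 and res.s == 2
        assert res.pi == pytest.approx(7 / 6)

        # independent oracle: direct evaluation of the 1989 constants
        n, S, pi = 4, 2, 7 / 6
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert res.d == pytest.approx(expected, abs=1e-12)
        assert res.d == pytest.approx(0.592, abs=1e-3)

    def test_sign_matches_pi_vs_watterson(self, dataset):
        res = tajimas_d(dataset.alignment, "pop-ENA")
        if res.d is not None and res.s > 0:
            k = tajima_constants(res.n)
            assert math.copysign(1, res.d) == math.copysign(1, res.pi - res.s / k["a1"])

    def test_star_genealogy_singleton_excess_negative(self):
        """Expansion-like singleton excess drives D negative in a majority
        of replicates (n large enough for the skew to register)."""
        neg = 0
        reps = 6
        for seed in range(80, 80 + reps):
            ds = simulate(
                SimulationConfig(seed=seed, n_tnp=0, n_ena=10, theta_within=0.003,
                                 include_reference=False)
            )
            res = tajimas_d(ds.alignment, "ENA")
            if res.d is not None and res.d < 0:
                neg += 1
        assert neg > reps / 2

    def test_too_few_sequences(self):
        aln = make_alignment({"E1": "AAAA"})
        with pytest.raises(InputError):
            tajimas_d(aln, "ENA")

    def test_ambiguous_sites_masked_before_counting(self):
        aln = make_alignment({"E1": "AYAA", "E2": "ACAA", "E3": "ATAA"})
        res = tajimas_d(aln, "ENA")
        assert res.s == 0
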