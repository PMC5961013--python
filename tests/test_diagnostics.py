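"""Composition statistics, analytic expectations and the bias report."""

import itertools
import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from nnkqc import (
    LibraryDesign,
    SynthesisModel,
    build_bias_report,
    build_naive_pool,
    composition_deviation,
    expected_uag_fraction,
    normalized_aa_distribution,
    nucleotide_composition,
    overrepresentation_report,
    tabulate,
)
from nnkqc.design import NNK_CODONS
from nnkqc.diagnostics import (
    BiasReport,
    aa_class_degeneracy,
    bias_adjusted_uag_expectation,
    codon_uniform_peptide_table,
)
from nnkqc.preprocess import FilterReport, InsertTable
from nnkqc.synth import HostModel, passage


def make_table(counts, design):
    total = sum(counts.values())
    return InsertTable(
        counts=counts, design=design,
        report=FilterReport(total_reads=total, accepted=total),
    )


@pytest.fixture
def codon_design():
    return LibraryDesign(name="codon", n_random_codons=1)


class TestComposition:
    def test_single_insert_indicator(self, codon_design):
        profile = nucleotide_composition(make_table({"GGT": 1}, codon_design))
        assert profile.fractions.loc[0].tolist() == [0.0, 0.0, 1.0, 0.0]
        assert profile.fractions.loc[2].tolist() == [0.0, 0.0, 0.0, 1.0]

    def test_read_weighting(self, codon_design):
        profile = nucleotide_composition(
            make_table({"GGT": 3, "AGT": 1}, codon_design)
        )
        assert profile.fractions.loc[0, "G"] == pytest.approx(0.75)
        assert profile.fractions.loc[0, "A"] == pytest.approx(0.25)

    def test_constrained_design_drops_cys_positions(self):
        design = LibraryDesign(name="C1C", n_random_codons=1, constrained=True)
        profile = nucleotide_composition(make_table({"TGTGGTTGT": 1}, design))
        assert profile.n_positions == 3  # only the random codon

    def test_row_order_invariance(self, codon_design):
        a = nucleotide_composition(make_table({"GGT": 3, "AGT": 1}, codon_design))
        b = nucleotide_composition(make_table({"AGT": 1, "GGT": 3}, codon_design))
        assert np.allclose(a.fractions.to_numpy(), b.fractions.to_numpy())

    def test_empty_table_raises(self, codon_design):
        with pytest.raises(ValueError):
            nucleotide_composition(make_table({}, codon_design))


class TestDeviation:
    def test_exact_expectation_scores_zero(self, codon_design):
        counts = {c: 1 for c in NNK_CODONS}
        profile = nucleotide_composition(make_table(counts, codon_design))
        dev = composition_deviation(profile, codon_design)
        assert np.allclose(dev["chi2"], 0.0, atol=1e-9)

    def test_all_g_n_position_chi2(self, codon_design):
        # n=100 all G at an N slot: (100-25)^2/25 + 3*(0-25)^2/25 = 300
        profile = nucleotide_composition(make_table({"GGT": 100}, codon_design))
        dev = composition_deviation(profile, codon_design)
        assert dev.loc[0, "chi2"] == pytest.approx(300.0)

    def test_k_slot_60_40_chi2(self, codon_design):
        # (60-50)^2/50 + (40-50)^2/50 = 4
        profile = nucleotide_composition(
            make_table({"GGG": 60, "GGT": 40}, codon_design)
        )
        dev = composition_deviation(profile, codon_design)
        assert dev.loc[2, "chi2"] == pytest.approx(4.0)
        assert dev.loc[2, "fold_G"] == pytest.approx(1.2)
        assert math.isnan(dev.loc[2, "fold_A"])


class TestNormalizedAA:
    def test_codon_uniform_is_flat_at_1_over_21(self):
        dist = normalized_aa_distribution(codon_uniform_peptide_table())
        assert len(dist) == 21
        for freq in dist.values():
            assert freq == pytest.approx(1 / 21, abs=1e-12)

    def test_gly_only_input(self, codon_design):
        peps = tabulate(make_table({"GGT": 4, "GGG": 4}, codon_design))
        dist = normalized_aa_distribution(peps)
        assert dist["G"] == pytest.approx(1.0)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_class_degeneracy_enumeration(self):
        deg = aa_class_degeneracy()
        assert len(deg) == 21 and sum(deg.values()) == 32
        assert deg["Q"] == 1 and deg["Q_amber"] == 1
        assert deg["L"] == deg["R"] == deg["S"] == 3

    def test_two_codon_enumeration_is_flat(self):
        # brute force: all 32^2 two-codon inserts, weight 1 each
        design = LibraryDesign(name="lin2", n_random_codons=2)
        counts = {a + b: 1 for a in NNK_CODONS for b in NNK_CODONS}
        dist = normalized_aa_distribution(tabulate(make_table(counts, design)))
        for freq in dist.values():
            assert freq == pytest.approx(1 / 21, abs=1e-12)

    def test_requires_amber_as_q(self, codon_design):
        peps = tabulate(make_table({"GGT": 1}, codon_design), amber_as_q=False)
        with pytest.raises(ValueError):
            normalized_aa_distribution(peps)


class TestExpectedUag:
    @pytest.mark.parametrize(
        "n,expected", [(0, 0.0), (1, 1 / 32), (10, 0.27202384332787144)]
    )
    def test_closed_form(self, n, expected):
        assert expected_uag_fraction(n) == pytest.approx(expected)

    def test_rounds_to_27_percent_at_n10(self):
        assert round(100 * expected_uag_fraction(10)) == 27

    @pytest.mark.parametrize("n", [2, 3])
    def test_brute_force_enumeration(self, n):
        # exact counting over all 32^n inserts
        hits = sum(
            1
            for combo in itertools.product(NNK_CODONS, repeat=n)
            if "TAG" in combo
        )
        assert Fraction(hits, 32 ** n) == 1 - Fraction(31, 32) ** n
        assert expected_uag_fraction(n) == pytest.approx(hits / 32 ** n)

    def test_monotone_increasing_to_one(self):
        values = [expected_uag_fraction(n) for n in range(0, 200, 10)]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] > 0.997

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            expected_uag_fraction(-1)

    def test_bias_adjusted_matches_ideal_on_uniform_input(self):
        design = LibraryDesign(name="lin2", n_random_codons=2)
        counts = {a + b: 1 for a in NNK_CODONS for b in NNK_CODONS}
        profile = nucleotide_composition(make_table(counts, design))
        assert bias_adjusted_uag_expectation(profile) == pytest.approx(
            expected_uag_fraction(2), abs=1e-12
        )


class TestOverrepresentation:
    def test_equal_counts_fold_one(self, codon_design):
        peps = tabulate(make_table({"GGT": 2, "AAT": 2, "CAT": 2}, codon_design))
        report = overrepresentation_report(peps, top_k=3)
        assert np.allclose(report["fold"], 1.0)

    def test_parasite_fold(self):
        # counts (100, 1 x 100) over 101 rows, total 200: fold = 100/(200/101)
        design = LibraryDesign(name="lin2", n_random_codons=2)
        inserts = [a + b for a in NNK_CODONS for b in NNK_CODONS][:100]
        counts = {s: 1 for s in inserts}
        counts["TTGTTG"] = 100
        peps = tabulate(make_table(counts, design))
        report = overrepresentation_report(peps, top_k=1)
        assert report.loc[0, "fold"] == pytest.approx(100 / (200 / 101))
        assert report.loc[0, "fold"] == pytest.approx(50.5)

    def test_top_k_larger_than_table(self, codon_design):
        peps = tabulate(make_table({"GGT": 1, "AAT": 1}, codon_design))
        assert len(overrepresentation_report(peps, top_k=50)) == 2

    def test_ties_break_lexicographically(self, codon_design):
        peps = tabulate(make_table({"GGT": 1, "AAT": 1, "CAT": 1}, codon_design))
        report = overrepresentation_report(peps, top_k=3)
        assert report["peptide"].tolist() == sorted(report["peptide"])


class TestBiasReport:
    def test_equal_model_report_is_unbiased(self, rng):
        design = LibraryDesign(name="lin7", n_random_codons=7)
        pool = build_naive_pool(design, SynthesisModel(), 100_000, rng)
        table = make_table(dict(Counter(pool.inserts)), design)
        report = build_bias_report(table)
        folds = report.deviation[[f"fold_{b}" for b in "ACGT"]].to_numpy()
        assert np.nanmax(np.abs(folds - 1.0)) < 0.05
        assert report.uag_expected == pytest.approx(expected_uag_fraction(7))

    def test_supe44_minus_passage_inflates_uag(self, rng):
        design = LibraryDesign(name="lin7", n_random_codons=7)
        pool = build_naive_pool(design, SynthesisModel(), 5_000, rng)
        grown = passage(
            pool, HostModel(supE44=False, display_burden=0.1, generations=19)
        )
        counts = {
            s: max(1, round(1000 * w))
            for s, w in zip(grown.inserts, grown.weights)
        }
        report = build_bias_report(make_table(counts, design))
        assert report.uag_observed > report.uag_expected

    def test_json_round_trip_lossless(self, rng):
        design = LibraryDesign(name="lin3", n_random_codons=3)
        pool = build_naive_pool(design, SynthesisModel(), 500, rng)
        report = build_bias_report(make_table(dict(Counter(pool.inserts)), design))
        clone = BiasReport.from_json(report.to_json())
        assert clone.to_json() == report.to_json()
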