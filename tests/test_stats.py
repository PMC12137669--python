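"""Yields, fold changes, the random-copolymerisation null, classes and ratios."""

import math

import numpy as np
import pytest

from oligoms.chemistry import BaseCount, parse_species
from oligoms.quantify import CalibrationModel, ConcentrationTable, enumerate_candidates, quantify
from oligoms.stats import (
    LinkageIntegrals,
    ReactionCondition,
    ReactionRecord,
    composition_class,
    composition_class_average,
    cyclic_terminus_fraction,
    fold_change,
    g_fraction,
    multiplicity,
    natural_linkage_fraction,
    null_deviation,
    null_expectation,
    total_yield,
    yield_report,
)
from oligoms.synthetic import PoolModel, SpectrumNoise, generate_pool, simulate_spectrum


def record(items, input_mM):
    return ReactionRecord(
        ReactionCondition(ph=10.0, input_mM=input_mM),
        ConcentrationTable.from_species(items),
    )


class TestYield:
    def test_dimer_trimer_example(self):
        r = record(
            [(parse_species("C2>p"), 0.1), (parse_species("C3>p"), 0.05)], {"C": 10.0}
        )
        assert total_yield(r) == pytest.approx(3.5)

    def test_empty_products_zero(self):
        r = record([(parse_species("C1>p"), 10.0)], {"C": 10.0})
        assert total_yield(r) == 0.0

    def test_full_conversion_is_100(self):
        r = record([(parse_species("C5>p"), 2.0)], {"C": 10.0})
        assert total_yield(r) == pytest.approx(100.0)

    def test_pool_yield_equals_generating_phi(self):
        m = PoolModel(alphabet="AU", converted_fraction=0.073, c0_mM=10.0)
        r = ReactionRecord(
            ReactionCondition(ph=10.0, input_mM={"A": 5.0, "U": 5.0}), generate_pool(m)
        )
        assert total_yield(r) == pytest.approx(7.3, rel=1e-9)

    def test_yield_report_consistency(self):
        m = PoolModel(alphabet="AU", converted_fraction=0.1, cyclic_fraction=0.33)
        r = ReactionRecord(
            ReactionCondition(ph=10.0, input_mM={"A": 5.0, "U": 5.0}), generate_pool(m)
        )
        rep = yield_report(r)
        assert sum(rep.per_length_pct.values()) == pytest.approx(rep.total_pct)
        assert 0.0 < rep.long_fraction < 1.0
        assert rep.cyclic_fraction == pytest.approx(0.33, rel=1e-9)


class TestFoldChange:
    # printed yields: valine (5 equiv.) vs no amino acid, per nucleotide
    @pytest.mark.parametrize(
        "treated,control,reported",
        [(7.3, 0.06, 122), (8.4, 0.17, 49), (39.0, 26.0, 1.5)],
    )
    def test_reported_fold_changes(self, treated, control, reported):
        fc = fold_change(treated, control)
        digits = 1 if reported < 10 else 0
        assert round(fc, digits) == reported

    def test_identical_records_unity(self):
        r = record([(parse_species("C2>p"), 0.5)], {"C": 10.0})
        assert fold_change(r, r) == pytest.approx(1.0)

    def test_zero_control_flagged_infinite(self):
        assert fold_change(5.0, 0.0) == math.inf

    def test_mismatched_systems_rejected(self):
        r1 = record([(parse_species("C2>p"), 0.5)], {"C": 10.0})
        r2 = record([(parse_species("A2>p"), 0.5)], {"A": 10.0})
        with pytest.raises(ValueError):
            fold_change(r1, r2)


class TestMultiplicity:
    def test_a2u_has_three_sequences(self):
        assert multiplicity(BaseCount(nA=2, nU=1)) == 3

    def test_homopolymer_single_sequence(self):
        assert multiplicity(BaseCount(nA=3)) == 1

    def test_acgu_enumeration_oracle(self):
        import itertools

        n_seqs = len(set(itertools.permutations("ACGU")))
        assert multiplicity(BaseCount(1, 1, 1, 1)) == n_seqs == 24


class TestNullExpectation:
    def test_au_trimer_binomial_split(self):
        """T3 = 8 units splits 1:3:3:1 over A3, A2U, AU2, U3."""
        products = ConcentrationTable.from_species(
            [
                (parse_species("A3>p"), 2.0),
                (parse_species("A2U1>p"), 2.0),
                (parse_species("A1U2>p"), 2.0),
                (parse_species("U3>p"), 2.0),
            ]
        )
        null = null_expectation(products, "AU")
        assert null.expected(BaseCount(nA=3)) == pytest.approx(1.0)
        assert null.expected(BaseCount(nA=2, nU=1)) == pytest.approx(3.0)
        assert null.expected(BaseCount(nA=1, nU=2)) == pytest.approx(3.0)
        assert null.expected(BaseCount(nU=3)) == pytest.approx(1.0)

    def test_normalisation_exact_per_length(self):
        pool = generate_pool(
            PoolModel(alphabet="ACGU", efficiencies={"A": 4, "C": 3, "G": 2, "U": 1})
        )
        null = null_expectation(pool, "ACGU")
        for n, t in null.t_n.items():
            total = null.table.loc[null.table["length"] == n, "expected_mM"].sum()
            assert total == pytest.approx(t, abs=1e-9 * max(t, 1))

    def test_single_base_system_matches_observed_totals(self):
        products = ConcentrationTable.from_species(
            [(parse_species("C2>p"), 0.4), (parse_species("C3>p"), 0.1)]
        )
        null = null_expectation(products, "C")
        assert null.expected(BaseCount(nC=2)) == pytest.approx(0.4)
        assert null.expected(BaseCount(nC=3)) == pytest.approx(0.1)

    def test_four_letter_dimer_shares(self):
        products = ConcentrationTable.from_species([(parse_species("G2>p"), 16.0)])
        null = null_expectation(products, "ACGU")
        assert null.expected(BaseCount(nG=2)) == pytest.approx(1.0)  # T2 x 1/16
        dimers = null.table[null.table["length"] == 2]
        assert len(dimers) == 10
        assert dimers["expected_mM"].sum() == pytest.approx(16.0)

    def test_alphabet_mismatch_rejected(self):
        products = ConcentrationTable.from_species([(parse_species("G2>p"), 1.0)])
        with pytest.raises(ValueError):
            null_expectation(products, "AU")

    def test_equal_efficiency_is_special_case_of_weighted(self):
        pool = generate_pool(PoolModel(alphabet="ACGU"))
        equal = null_expectation(pool, "ACGU")
        weighted = null_expectation(
            pool, "ACGU", efficiencies={b: 1.0 for b in "ACGU"}
        )
        np.testing.assert_allclose(
            equal.table["expected_mM"], weighted.table["expected_mM"], rtol=1e-12
        )


class TestCompositionClasses:
    def test_hh_class_is_the_six_printed_dimers(self):
        members = {str(c) for c in composition_class(2, 0)}
        expected = {
            str(BaseCount.from_sequence(s))
            for s in ["AA", "AU", "AC", "CC", "CU", "UU"]
        }
        assert members == expected

    def test_gg_class_single_member(self):
        assert [str(c) for c in composition_class(2, 2)] == ["G2"]

    def test_ghhh_class_has_ten_members(self):
        assert len(composition_class(4, 1)) == 10  # multisets of size 3 over {A,C,U}

    def test_class_average_and_completeness(self):
        ratios = {str(c): 2.0 for c in composition_class(2, 0)}
        mean, complete, members = composition_class_average(ratios, 2, 0)
        assert mean == pytest.approx(2.0) and complete and len(members) == 6
        del ratios[members[0]]
        mean, complete, _ = composition_class_average(ratios, 2, 0)
        assert mean == pytest.approx(2.0) and not complete

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            composition_class_average({}, 2, 0)


class TestFractions:
    def test_pure_g_pool(self):
        products = ConcentrationTable.from_species([(parse_species("G4>p"), 1.0)])
        assert g_fraction(products) == 1.0

    def test_mixed_pool_example(self):
        products = ConcentrationTable.from_species(
            [(parse_species("C2G2>p"), 1.0), (parse_species("C4>p"), 1.0)]
        )
        assert g_fraction(products) == pytest.approx(0.25)

    def test_equal_efficiency_pool_quarter_g(self):
        pool = generate_pool(PoolModel(alphabet="ACGU"))
        assert g_fraction(pool) == pytest.approx(0.25, rel=1e-9)

    def test_linkage_fraction(self):
        assert natural_linkage_fraction(LinkageIntegrals(58, 42)) == pytest.approx(58.0)
        assert natural_linkage_fraction(LinkageIntegrals(1, 0)) == 100.0
        assert natural_linkage_fraction(LinkageIntegrals(1, 1)) == 50.0
        with pytest.raises(ValueError):
            LinkageIntegrals(0, 0)

    def test_cyclic_terminus_fraction(self):
        all_cyclic = ConcentrationTable.from_species([(parse_species("A2>p"), 1.0)])
        assert cyclic_terminus_fraction(all_cyclic) == 1.0
        mixed = ConcentrationTable.from_species(
            [(parse_species("A2>p"), 1.0), (parse_species("A2-p"), 2.0)]
        )
        assert cyclic_terminus_fraction(mixed) == pytest.approx(1.0 / 3.0)

    def test_generator_theta_recovered(self):
        pool = generate_pool(PoolModel(alphabet="AU", cyclic_fraction=0.33))
        assert cyclic_terminus_fraction(pool) == pytest.approx(0.33, rel=1e-9)


class TestNullDeviation:
    def test_products_at_null_give_zero_deviation(self):
        pool = generate_pool(PoolModel(alphabet="AU"))
        null = null_expectation(pool, "AU")
        table, chi2 = null_deviation(pool, null)
        np.testing.assert_allclose(table["log2_ratio"], 0.0, atol=1e-9)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_homopolymer_pool_flags_missing_heteropolymers(self):
        products = ConcentrationTable.from_species(
            [(parse_species("A3>p"), 1.0), (parse_species("U3>p"), 1.0)]
        )
        null = null_expectation(products, "AU")
        table, chi2 = null_deviation(products, null)
        homo = table[table["composition"].isin(["A3", "U3"])]
        assert (homo["log2_ratio"] > 0).all()
        hetero = table[table["composition"].isin(["A2U1", "A1U2"])]
        assert hetero["missing"].all()
        assert hetero["log2_ratio"].isna().all()
        assert chi2 > 0

    def test_log_ratios_invariant_to_global_scaling(self):
        pool = generate_pool(PoolModel(alphabet="AU", efficiencies={"A": 2, "U": 1}))
        doubled = ConcentrationTable(pool.df.assign(conc_mM=pool.df["conc_mM"] * 2))
        t1, _ = null_deviation(pool, null_expectation(pool, "AU"))
        t2, _ = null_deviation(doubled, null_expectation(doubled, "AU"))
        np.testing.assert_allclose(t1["log2_ratio"], t2["log2_ratio"], atol=1e-12)


def test_efficiency_recovery_through_full_pipeline():
    """Quantified composition shares reproduce the generating incorporation biases."""
    eff = {"A": 0.7, "U": 0.3}
    pool = generate_pool(PoolModel(alphabet="AU", efficiencies=eff, max_length=5))
    cal = CalibrationModel.constant(1000.0, range(1, 6))
    pl = simulate_spectrum(pool, cal, SpectrumNoise.none(), seed=0)
    table = quantify(pl, enumerate_candidates("AU", 5), cal)
    olig = table.oligomers(2)
    comps = [parse_species(s).composition for s in olig["species"]]
    a_frac = sum(c.nA * v for c, v in zip(comps, olig["conc_mM"])) / sum(
        c.n * v for c, v in zip(comps, olig["conc_mM"])
    )
    assert a_frac == pytest.approx(0.7, abs=0.01)
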