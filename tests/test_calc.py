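import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftmspeaks import (
    ElementCounts,
    aromaticity,
    assign_elemental_composition,
    compound_calcs,
    dbe,
    element_ratios,
    elemental_composition_class,
    gibbs_cox,
    kendrick,
    nosc,
    parse_formula,
)


def C(text):
    return parse_formula(text)


class TestElementRatios:
    def test_values(self):
        r = element_ratios(C("C8H14O7"))
        assert r["oc"] == pytest.approx(0.875)
        assert r["hc"] == pytest.approx(1.75)
        r2 = element_ratios(C("C6H12O6"))
        assert (r2["oc"], r2["hc"]) == (1.0, 2.0)

    def test_np_missing_when_no_phosphorus(self):
        assert math.isnan(element_ratios(C("C6H12O6"))["np"])
        assert element_ratios(ElementCounts(C=2, H=4, N=3, P=2))["np"] == 1.5


class TestKendrick:
    def test_base_compound_is_integer(self):
        kv = kendrick(14.01565, "CH2")
        assert kv.kendrick_mass == pytest.approx(14.0)
        assert kv.kendrick_defect == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        kv = kendrick(221.06665, "CH2")
        km = 221.06665 * 14 / 14.01565
        assert kv.kendrick_mass == pytest.approx(km)
        assert kv.kendrick_defect == pytest.approx(math.ceil(km) - km)
        assert 0 <= kv.kendrick_defect < 1

    @pytest.mark.parametrize("base", ["CH2", "CO2", "O2", "CHO"])
    def test_homologous_series_constant_defect(self, base):
        from ftmspeaks.constants import KENDRICK_BASES

        _, exact = KENDRICK_BASES[base]
        defects = [kendrick(300.1234 + k * exact, base).kendrick_defect for k in range(6)]
        assert max(defects) - min(defects) < 1e-9

    def test_round_convention(self):
        kv = kendrick(221.06665, "CH2", convention="round")
        km = 221.06665 * 14 / 14.01565
        assert kv.kendrick_defect == pytest.approx(round(km) - km)

    def test_errors(self):
        with pytest.raises(ValueError):
            kendrick(0.0, "CH2")
        with pytest.raises(ValueError):
            kendrick(100.0, "NH3")


class TestNosc:
    @pytest.mark.parametrize(
        "formula, expected",
        [("C6H12O6", 0.0), ("CH4", -4.0), ("C8H14O7", 0.0)],
    )
    def test_reference_compounds(self, formula, expected):
        assert nosc(C(formula)) == pytest.approx(expected)

    def test_co2_upper_limit(self):
        assert nosc(ElementCounts(C=1, H=0, O=2)) == pytest.approx(4.0)

    @settings(max_examples=400, derandomize=True)
    @given(c=st.integers(1, 40), h_frac=st.floats(0, 1), o_frac=st.floats(0, 1))
    def test_bounded_on_cho_grid(self, c, h_frac, o_frac):
        """NOSC stays within the methane/CO2 limits [-4, 4] on the full CHO
        grid with H <= 2C+2 and O <= 2C (heteroatom-rich corner cases can
        leave the interval, so the bound is a CHO property)."""
        counts = ElementCounts(C=c, H=max(1, int(h_frac * (2 * c + 2))),
                               O=int(o_frac * 2 * c))
        assert -4.0 <= nosc(counts) <= 4.0

    def test_bounded_for_generated_organic_matter_formulas(self, synth_small):
        ds, _ = synth_small
        out = compound_calcs(ds, ["calc_nosc"])
        vals = out.annotation["nosc"].dropna()
        assert ((vals >= -4) & (vals <= 4)).all()


class TestGibbs:
    def test_linear_form(self):
        assert gibbs_cox(C("C6H12O6")) == pytest.approx(60.3)
        assert gibbs_cox(C("CH4")) == pytest.approx(60.3 + 114.0)

    def test_monotone_decreasing_in_nosc(self):
        formulas = [C("CH4"), C("C6H12O6"), C("C2H2O4")]  # increasing NOSC
        noscs = [nosc(f) for f in formulas]
        gibbs = [gibbs_cox(f) for f in formulas]
        assert noscs == sorted(noscs)
        assert gibbs == sorted(gibbs, reverse=True)


class TestAromaticity:
    def test_benzene(self):
        ai, ai_mod = aromaticity(C("C6H6"))
        assert ai == pytest.approx(4 / 6)
        assert ai_mod == pytest.approx(4 / 6)

    def test_clamp_to_zero(self):
        ai, ai_mod = aromaticity(C("C6H12O6"))
        assert ai == 0.0  # numerator 1 + 6 - 6 - 6 = -5
        assert ai_mod == 0.0

    def test_oxygen_discount_direction_on_random_grid(self, rng):
        """Discounting half the oxygen moves the index toward 1: for
        O-containing formulas with both indices unclamped, ai_mod >= ai when
        ai <= 1 and ai_mod <= ai when ai >= 1 (adding the same positive
        amount to numerator and denominator contracts the ratio toward 1)."""
        checked = 0
        for _ in range(800):
            counts = ElementCounts(
                C=int(rng.integers(1, 40)), H=int(rng.integers(1, 80)),
                N=int(rng.integers(0, 5)), O=int(rng.integers(0, 30)),
                S=int(rng.integers(0, 3)), P=int(rng.integers(0, 2)),
            )
            ai, ai_mod = aromaticity(counts)
            assert ai >= 0 and ai_mod >= 0
            if counts.O > 0 and ai > 0 and ai_mod > 0:
                checked += 1
                if ai <= 1:
                    assert ai_mod >= ai - 1e-12
                else:
                    assert ai_mod <= ai + 1e-12
        assert checked > 50


class TestDbe:
    def test_benzene(self):
        d, _ = dbe(C("C6H6"))
        assert d == pytest.approx(4.0)

    def test_table1_formula(self):
        d, d_o = dbe(C("C8H14O7"))
        assert d == pytest.approx(2.0)
        assert d_o == pytest.approx(-5.0)

    @pytest.mark.parametrize("n", [1, 2, 5, 20])
    def test_saturated_acyclic_is_zero(self, n):
        d, _ = dbe(ElementCounts(C=n, H=2 * n + 2))
        assert d == pytest.approx(0.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        c=st.integers(1, 40), h=st.integers(1, 80), n=st.integers(0, 8),
        o=st.integers(0, 20), s=st.integers(0, 4), p=st.integers(0, 3),
    )
    def test_matches_closed_form(self, c, h, n, o, s, p):
        d, d_o = dbe(ElementCounts(C=c, H=h, N=n, O=o, S=s, P=p))
        assert d == pytest.approx(1 + c - h / 2 + n / 2 + p / 2)
        assert d_o == pytest.approx(d - o)

    def test_custom_valence_and_errors(self):
        d, _ = dbe(C("C6H6"), valences={"N": 5})
        assert d == pytest.approx(4.0)  # no N present, unchanged
        with pytest.raises(ValueError):
            dbe(C("C6H6"), valences={"N": -1})


class TestCompositionClass:
    @pytest.mark.parametrize(
        "formula, label",
        [("C9H5O6N1", "CHNO"), ("C8H14O7", "CHO"), ("CH4", "CH"),
         ("C2H6S1", "CHS"), ("C3H9O6N1S1P1", "CHNOSP")],
    )
    def test_labels(self, formula, label):
        assert elemental_composition_class(C(formula)) == label


class TestCompoundCalcs:
    def test_kendrick_columns_added(self, table1_dataset):
        ds = compound_calcs(table1_dataset, ["calc_kendrick"])
        assert {"kendrick_mass", "kendrick_defect"} <= set(ds.annotation.columns)

    def test_empty_request_is_noop(self, table1_dataset):
        ds = compound_calcs(table1_dataset, [])
        assert ds is table1_dataset

    def test_unknown_name_rejected(self, table1_dataset):
        with pytest.raises(ValueError, match="unknown calculation"):
            compound_calcs(table1_dataset, ["calc_bogus"])

    def test_formula_less_peaks_get_missing_not_zero(self, synth_small):
        ds, _ = synth_small
        out = compound_calcs(ds, ["calc_nosc", "calc_element_ratios"])
        unassigned = out.annotation["formula"].isna()
        assert unassigned.any()
        assert out.annotation.loc[unassigned, "nosc"].isna().all()
        assert out.annotation.loc[unassigned, "oc"].isna().all()

    def test_isotope_peaks_excluded(self, table1_tables):
        from ftmspeaks import build_dataset

        e_data, f_data, e_meta = table1_tables
        e_meta = e_meta.assign(iso=["0", "1"])
        ds = build_dataset(e_data, f_data, e_meta, peak_id="mass",
                           sample_id="sample", formula="molecular formula",
                           isotope="iso", isotope_symbol="1")
        out = compound_calcs(ds, ["calc_nosc"])
        assert math.isnan(out.annotation.loc[222.00432, "nosc"])
        assert out.annotation.loc[221.06665, "nosc"] == pytest.approx(0.0)
        assert out.summarize().n_assigned_formulae == 1

    def test_idempotent_recompute(self, table1_dataset):
        once = compound_calcs(table1_dataset, ["calc_nosc"])
        twice = compound_calcs(once, ["calc_nosc"])
        assert twice.annotation["nosc"].equals(once.annotation["nosc"])

    def test_elemental_composition_column(self, table1_dataset):
        out = assign_elemental_composition(table1_dataset)
        assert list(out.annotation["el_comp"]) == ["CHO", "CHNO"]
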