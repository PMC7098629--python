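import numpy as np
import pandas as pd
import pytest

from ftmspeaks import (
    cognostics,
    compare_groups,
    compound_calcs,
    density_data,
    get_boundary_set,
    kendrick_data,
    render,
    scatter_data,
    summarize_groups,
    summary_plot,
    van_krevelen_data,
)


@pytest.fixture(scope="module")
def calc_dataset(request):
    from ftmspeaks import SynthSpec, synthetic_dataset

    ds, truth = synthetic_dataset(
        SynthSpec(n_peaks=400, n_samples=10, n_groups=2, seed=7,
                  formula_assignment_rate=0.8)
    )
    return compound_calcs(ds, ["calc_element_ratios", "calc_kendrick",
                               "calc_nosc", "calc_gibbs", "calc_aroma"])


class TestVanKrevelen:
    def test_fixture_point(self, table1_dataset):
        ds = compound_calcs(table1_dataset, ["calc_element_ratios"])
        pd_ = van_krevelen_data(ds)
        row = pd_.data.set_index("peak_id").loc[221.06665]
        assert (row["oc"], row["hc"]) == (0.875, 1.75)
        assert (pd_.x, pd_.y) == ("oc", "hc")

    def test_formula_less_and_isotope_peaks_absent(self, calc_dataset):
        pd_ = van_krevelen_data(calc_dataset)
        eligible = calc_dataset.formula_assigned
        assert len(pd_.data) == int(eligible.sum())
        assert set(pd_.data["peak_id"]) <= set(calc_dataset.peak_ids[eligible])

    def test_comparison_colors_by_verdict(self, calc_dataset):
        cmp_ = compare_groups(calc_dataset, "G1", "G2", method="gtest")
        pd_ = van_krevelen_data(cmp_)
        assert pd_.color_by == "verdict"
        assert set(pd_.data["verdict"]) <= {
            "unique_to_g1", "unique_to_g2", "observed_in_both", "observed_in_neither"
        }
        # the both/neither verdicts are present but deselected
        assert pd_.include is not None
        assert (~pd_.include[pd_.data["verdict"] == "observed_in_both"]).all()

    def test_group_summary_colors_by_presence(self, calc_dataset):
        gs = summarize_groups(calc_dataset, ["n_present"])
        pd_ = van_krevelen_data(gs)
        assert "G1:n_present" in pd_.data.columns and "G2:n_present" in pd_.data.columns

    def test_requires_ratios(self, table1_dataset):
        with pytest.raises(ValueError, match="compound_calcs"):
            van_krevelen_data(table1_dataset)


class TestKendrickPlot:
    def test_homologous_series_is_horizontal(self):
        from ftmspeaks import build_dataset

        masses = [200.0 + k * 14.01565 for k in range(5)]
        e_data = pd.DataFrame({"m": masses, "s1": [1.0] * 5})
        f_data = pd.DataFrame({"s": ["s1"]})
        e_meta = pd.DataFrame({"m": masses, "f": [f"C{10+k}H{12+2*k}O2" for k in range(5)]})
        ds = build_dataset(e_data, f_data, e_meta, peak_id="m", sample_id="s", formula="f")
        pd_ = kendrick_data(compound_calcs(ds, ["calc_kendrick"]))
        assert pd_.data["kendrick_defect"].max() - pd_.data["kendrick_defect"].min() < 1e-9

    def test_point_count_equals_eligible_peaks(self, calc_dataset):
        pd_ = kendrick_data(calc_dataset)
        assert len(pd_.data) == int(calc_dataset.formula_assigned.sum())


class TestScatter:
    def test_gibbs_nosc_collinear(self, calc_dataset):
        pd_ = scatter_data(calc_dataset, "nosc", "gibbs_cox")
        resid = pd_.data["gibbs_cox"] - (60.3 - 28.5 * pd_.data["nosc"])
        assert np.abs(resid).max() < 1e-9

    def test_consistent_with_van_krevelen(self, calc_dataset):
        a = scatter_data(calc_dataset, "oc", "hc")
        b = van_krevelen_data(calc_dataset)
        pd.testing.assert_frame_equal(a.data[["peak_id", "oc", "hc"]],
                                      b.data[["peak_id", "oc", "hc"]])

    def test_missing_rows_dropped_pairwise(self, calc_dataset):
        pd_ = scatter_data(calc_dataset, "nosc", "np" if "np" in
                           calc_dataset.annotation.columns else "nosc")
        assert pd_.data.notna().all().all()

    def test_unknown_variable(self, calc_dataset):
        with pytest.raises(ValueError):
            scatter_data(calc_dataset, "nosc", "unknown_var")


class TestDensity:
    def test_curves_integrate_to_one(self, calc_dataset):
        pd_ = density_data(calc_dataset, "nosc")
        for _, grp in pd_.data.groupby("curve"):
            area = np.trapezoid(grp["density"], grp["x"])
            assert area == pytest.approx(1.0, abs=1e-3)

    def test_group_curve_equals_pooled_recompute(self, calc_dataset):
        pd_ = density_data(calc_dataset, "nosc", groups=["G1"], include_group_curve=True)
        gcurve = pd_.data[pd_.data["level"] == "group"]
        assert set(gcurve["curve"]) == {"G1"}
        # independent pooled recomputation
        from scipy.stats import gaussian_kde

        vals = []
        ann = calc_dataset.annotation["nosc"]
        for s in calc_dataset.groups["G1"]:
            vals.append(ann[calc_dataset.presence[s] & ann.notna()].to_numpy())
        pooled = np.concatenate(vals)
        kde = gaussian_kde(pooled, bw_method="silverman")
        xs = gcurve["x"].to_numpy()
        assert np.allclose(gcurve["density"].to_numpy(), kde(xs), atol=1e-12)

    def test_non_numeric_variable_rejected(self, calc_dataset):
        with pytest.raises(TypeError):
            density_data(calc_dataset, "formula")

    def test_histogram_is_density_normalized(self, calc_dataset):
        pd_ = density_data(calc_dataset, "nosc", samples=[calc_dataset.sample_ids[0]])
        hist = pd_.meta["histogram"]
        widths = hist["bin_right"] - hist["bin_left"]
        assert (hist["density"] * widths).sum() == pytest.approx(1.0, abs=1e-9)


class TestDeterminism:
    @pytest.mark.parametrize("builder", ["vk", "kendrick", "scatter", "density", "summary"])
    def test_double_invocation_identical(self, calc_dataset, builder):
        def build():
            if builder == "vk":
                return van_krevelen_data(calc_dataset).data
            if builder == "kendrick":
                return kendrick_data(calc_dataset).data
            if builder == "scatter":
                return scatter_data(calc_dataset, "nosc", "gibbs_cox").data
            if builder == "density":
                return density_data(calc_dataset, "nosc").data
            return summary_plot(calc_dataset).data

        pd.testing.assert_frame_equal(build(), build())


class TestCognostics:
    def test_counts_and_class_proportions(self, calc_dataset):
        cog = cognostics(calc_dataset, "van_krevelen")
        assert cog.metrics["n_peaks"] == calc_dataset.n_peaks
        assert cog.metrics["n_formula_assigned"] == int(calc_dataset.formula_assigned.sum())
        props = [v for k, v in cog.metrics.items() if k.startswith("prop_")]
        assert sum(props) == pytest.approx(1.0)

    def test_means_equal_direct_recomputation(self, calc_dataset):
        cog = cognostics(calc_dataset, "van_krevelen")
        assert cog.metrics["mean_nosc"] == pytest.approx(
            calc_dataset.annotation["nosc"].dropna().mean()
        )

    def test_empty_subset_rejected(self, calc_dataset):
        empty = calc_dataset._replace(
            intensities=calc_dataset.intensities.iloc[:0],
            annotation=calc_dataset.annotation.iloc[:0],
            _raw=calc_dataset.raw.iloc[:0],
        )
        with pytest.raises(ValueError, match="empty"):
            cognostics(empty)


class TestRender:
    def test_same_input_twice_is_byte_identical_svg(self, calc_dataset, tmp_path):
        pd_ = van_krevelen_data(calc_dataset, color_by="nosc")
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        render(pd_, str(p1), {"boundary_set": get_boundary_set("bs1")})
        render(pd_, str(p2), {"boundary_set": get_boundary_set("bs1")})
        assert p1.read_bytes() == p2.read_bytes()

    def test_all_kinds_render(self, calc_dataset, tmp_path):
        for i, pd_ in enumerate([
            van_krevelen_data(calc_dataset),
            kendrick_data(calc_dataset),
            density_data(calc_dataset, "nosc", samples=list(calc_dataset.sample_ids[:2])),
            summary_plot(calc_dataset.transform_scale("presence_absence")),
            summary_plot(calc_dataset.transform_scale("log2")),
        ]):
            out = tmp_path / f"fig{i}.png"
            render(pd_, str(out))
            assert out.stat().st_size > 0

    def test_empty_plot_rejected(self, calc_dataset, tmp_path):
        pd_ = van_krevelen_data(calc_dataset)
        pd_.data = pd_.data.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            render(pd_, str(tmp_path / "x.svg"))
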