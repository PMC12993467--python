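"""Trend crossovers (alternation points), case classification and SARA assessment."""

import numpy as np
import pytest

from rumengrad import (
    FermentationSample,
    TrendModel,
    alternation_report,
    classify_case,
    find_crossover,
    fit_taxon_trends,
    predict,
    sara_assess,
)
from rumengrad.reference import BACTEROIDETES_LINE, FIRMICUTES_LINE


def linear(slope, intercept, r2=0.95, rng=(0.2, 0.8), n=5):
    return TrendModel("linear", {"slope": slope, "intercept": intercept}, r2, rng, n)


def as_quadratic(line: TrendModel) -> TrendModel:
    """The same line disguised as a parabola with b2=0: forces the scan solver."""
    return TrendModel(
        "quadratic",
        {"b2": 0.0, "b1": line.params["slope"], "b0": line.params["intercept"]},
        line.r2, line.x_range, max(line.n, 3),
    )


BACT = linear(*BACTEROIDETES_LINE, r2=0.9582)
FIRM = linear(FIRMICUTES_LINE[0], FIRMICUTES_LINE[1], r2=0.959)


class TestFindCrossover:
    def test_symmetric_pair_crosses_at_half(self):
        a = linear(1.0, 0.0, rng=(0, 1))
        b = linear(-1.0, 1.0, rng=(0, 1))
        (pt,) = find_crossover(a, b, (0, 1))
        assert pt.x_star == pytest.approx(0.5)
        assert pt.y_star == pytest.approx(0.5)

    def test_core_phyla_lines_cross_at_0_7711(self):
        (pt,) = find_crossover(BACT, FIRM, (0.15, 0.85), data_range=(0.2, 0.8))
        assert round(pt.x_star, 4) == 0.7711
        assert pt.in_range
        assert pt.case == "opposite_direction"

    def test_parallel_lines_no_crossing(self):
        assert find_crossover(linear(1, 0), linear(1, 1), (0, 1)) == []

    def test_coincident_models_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            find_crossover(linear(1, 0), linear(1, 0), (0, 1))

    def test_symmetry_under_pair_swap(self):
        pts_ab = find_crossover(BACT, FIRM, (0.15, 0.85))
        pts_ba = find_crossover(FIRM, BACT, (0.15, 0.85))
        assert [p.x_star for p in pts_ab] == pytest.approx(
            [p.x_star for p in pts_ba], abs=1e-12
        )

    def test_bisection_path_agrees_with_closed_form(self):
        # same two lines, one disguised as a degenerate parabola so the
        # sign-change scan + Brent path runs instead of the closed form
        (closed,) = find_crossover(BACT, FIRM, (0.15, 0.85))
        (scanned,) = find_crossover(as_quadratic(BACT), FIRM, (0.15, 0.85))
        assert scanned.x_star == pytest.approx(closed.x_star, abs=1e-8)
        assert scanned.case == "curve_involved"

    def test_model_agreement_invariant_both_paths(self):
        for pts in (
            find_crossover(BACT, FIRM, (0.15, 0.85)),
            find_crossover(as_quadratic(BACT), FIRM, (0.15, 0.85)),
        ):
            for p in pts:
                assert abs(predict(p.model_a, p.x_star) - predict(p.model_b, p.x_star)) < 1e-9

    def test_quadratic_can_cross_twice(self):
        para = TrendModel("quadratic", {"b2": -4.0, "b1": 4.0, "b0": 0.0}, 1.0, (0, 1), 5)
        flat = linear(0.0, 0.5, rng=(0, 1))
        pts = find_crossover(para, flat, (0, 1))
        assert len(pts) == 2

    def test_out_of_range_crossing_flagged(self):
        a = linear(1.0, 0.0, rng=(0, 0.4))
        b = linear(-1.0, 1.0, rng=(0, 0.4))
        (pt,) = find_crossover(a, b, (0, 1), data_range=(0, 0.4))
        assert not pt.in_range


class TestClassifyCase:
    def test_opposite_slopes(self):
        assert classify_case(BACT, FIRM, 0.77) == "opposite_direction"

    def test_same_direction(self):
        assert classify_case(linear(-0.2, 0.5), linear(-0.5, 0.6), 0.3) == "same_direction"

    def test_curve_involved(self):
        para = TrendModel("quadratic", {"b2": -1, "b1": 1, "b0": 0}, 0.9, (0, 1), 5)
        assert classify_case(para, linear(0.1, 0.2), 0.5) == "curve_involved"


class TestFitTaxonTrends:
    def test_recovers_core_phyla_slopes_from_noiseless_table(self, core_phyla_table):
        trends = fit_taxon_trends(core_phyla_table, family="linear")
        assert trends["p_Bacteroidetes"].params["slope"] == pytest.approx(-0.4605, abs=1e-4)
        assert trends["p_Firmicutes"].params["slope"] == pytest.approx(0.4233, abs=1e-4)
        assert trends["p_Bacteroidetes"].r2 == pytest.approx(1.0)

    def test_constant_taxon_gets_zero_slope_r2_one(self, core_phyla_table):
        values = core_phyla_table.values.copy()
        # replace residual pool with a constant taxon and rescale dominants
        const = 0.05
        scale = (1 - const) / (values.iloc[0] + values.iloc[1])
        values.iloc[0] *= scale
        values.iloc[1] *= scale
        values.iloc[2] = const
        table = type(core_phyla_table)(values, core_phyla_table.metadata, "proportions")
        trends = fit_taxon_trends(table, family="linear")
        assert trends["p_Other"].params["slope"] == 0.0
        assert trends["p_Other"].r2 == 1.0

    def test_spirochaetes_rate_recovered_exponentially(self):
        import pandas as pd
        from rumengrad import AbundanceTable
        from rumengrad.reference import CONCENTRATE_FRACTIONS, SPIROCHAETES_ABUNDANCE

        x = np.array(CONCENTRATE_FRACTIONS)
        spiro = SPIROCHAETES_ABUNDANCE.to_numpy()
        labels = list(SPIROCHAETES_ABUNDANCE.index)
        values = pd.DataFrame(
            [spiro, 1 - spiro], index=["p_Spirochaetes", "p_Rest"], columns=labels
        )
        meta = pd.DataFrame(
            {"group_label": labels, "concentrate_fraction": x},
            index=pd.Index(labels, name="sample_id"),
        )
        table = AbundanceTable(values, meta, "proportions")
        trends = fit_taxon_trends(table, family="exponential")
        assert round(trends["p_Spirochaetes"].params["k"], 3) == 4.156

    def test_too_few_gradient_levels_rejected(self, core_phyla_table):
        sub = type(core_phyla_table)(
            core_phyla_table.values.iloc[:, :2],
            core_phyla_table.metadata.iloc[:2],
            "proportions",
        )
        with pytest.raises(ValueError, match="gradient"):
            fit_taxon_trends(sub)


class TestAlternationReport:
    def test_two_taxon_system_with_known_intersection(self):
        trends = {"up": linear(1.0, 0.0, rng=(0, 1)), "down": linear(-1.0, 1.0, rng=(0, 1))}
        rep = alternation_report(trends, (0, 1))
        assert len(rep["crossovers"]) == 1
        assert rep["warning_point"] == pytest.approx(0.5)

    def test_core_pair_defaults_to_dominants_at_low_gradient(self, core_phyla_table):
        trends = fit_taxon_trends(core_phyla_table, family="linear")
        rep = alternation_report(trends, (0.2, 0.8))
        assert set(rep["core_pair"]) == {"p_Bacteroidetes", "p_Firmicutes"}
        assert rep["warning_point"] == pytest.approx(0.7711, abs=1e-3)

    def test_sorted_by_position(self, core_phyla_table):
        trends = fit_taxon_trends(core_phyla_table, family="linear")
        rep = alternation_report(trends, (0.2, 0.8))
        xs = [c.x_star for c in rep["crossovers"]]
        assert xs == sorted(xs)

    def test_no_crossing_gives_none_narrative(self):
        trends = {"a": linear(1.0, 0.0, rng=(0, 1)), "b": linear(1.0, 0.5, rng=(0, 1))}
        rep = alternation_report(trends, (0, 1))
        assert rep["crossovers"] == []
        assert rep["warning_point"] is None
        assert rep["narrative"].startswith("none")

    def test_generator_truth_recovered(self, cfg):
        from rumengrad import gen_abundance, gen_diets
        from rumengrad.simulate import analytic_crossing

        exact = gen_abundance(gen_diets(cfg), cfg, exact=True)
        trends = fit_taxon_trends(exact, family="exponential")
        rep = alternation_report(
            trends, (0.2, 0.8),
            focus_pairs=[("p_Bacteroidetes", "p_Firmicutes")],
        )
        truth = analytic_crossing(cfg, "p_Bacteroidetes", "p_Firmicutes")
        assert rep["crossovers"][0].x_star == pytest.approx(truth, abs=1e-6)


class TestSaraAssess:
    def test_all_normal(self):
        a = sara_assess(None, ph=6.5, nh3n=15.0, subject_id="x")
        assert a.ph_status == "normal"
        assert a.nh3n_status == "optimal"
        assert a.alternation_flags == []

    @pytest.mark.parametrize(
        "ph, status",
        [(6.5, "normal"), (5.8, "caution"), (5.3, "subacute"), (4.9, "acute")],
    )
    def test_ph_bands(self, ph, status):
        assert sara_assess(None, ph=ph).ph_status == status

    @pytest.mark.parametrize(
        "nh3n, status",
        [(3.0, "deficient"), (15.0, "optimal"), (31.0, "excess")],
    )
    def test_nh3n_bands(self, nh3n, status):
        assert sara_assess(None, nh3n=nh3n).nh3n_status == status

    def test_crossovers_below_eval_fraction_flagged(self):
        trends = {"up": linear(1.0, 0.0, rng=(0, 1)), "down": linear(-1.0, 1.0, rng=(0, 1))}
        rep = alternation_report(trends, (0, 1))
        flagged = sara_assess(None, report=rep, x_eval=0.8, ph=6.3)
        clean = sara_assess(None, report=rep, x_eval=0.3, ph=6.3)
        assert len(flagged.alternation_flags) == 1
        assert clean.alternation_flags == []

    def test_from_fermentation_sample(self):
        ferm = FermentationSample("A1", "80:20", ph=5.4, nh3n=31.0)
        a = sara_assess(ferm)
        assert a.ph_status == "subacute"
        assert a.nh3n_status == "excess"
        assert "subacute" in a.narrative

    def test_missing_both_measurements_rejected(self):
        with pytest.raises(ValueError):
            sara_assess(None)
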