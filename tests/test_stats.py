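import math
import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from anova_oracle import bruteforce_mixed_anova
from spiralfield.stats import (
    CellTable,
    accuracy_table,
    arcsine_transform,
    dprime_4afc,
    linear_trend_analysis,
    mixed_rm_anova,
    pc_from_dprime,
)


def make_cell_table(y: np.ndarray, groups, levels, factor="level") -> CellTable:
    rows = []
    for i in range(y.shape[0]):
        for c, lev in enumerate(levels):
            rows.append({"subject": f"s{i:02d}", "group": groups[i],
                         factor: lev, "p_correct": y[i, c], "n_trials": 1})
    return CellTable(data=pd.DataFrame(rows), factors=(factor,))


class TestAccuracyTable:
    def test_toy_proportion(self):
        rec = pd.DataFrame({
            "subject": ["a"] * 8, "group": ["younger"] * 8,
            "jitter_deg": [0] * 8,
            "correct": [1, 1, 1, 1, 1, 0, 0, 0]})
        tab = accuracy_table(rec, ["jitter_deg"])
        assert tab.data.loc[0, "p_correct"] == 0.625
        assert tab.data.loc[0, "n_trials"] == 8

    def test_all_correct_and_chance_limits(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame({
            "subject": np.repeat(["a", "b"], 400),
            "group": "younger",
            "jitter_deg": np.tile(np.repeat([0, 30], 200), 2),
            "correct": rng.random(800) < 0.25})
        tab = accuracy_table(rec, ["jitter_deg"])
        assert tab.data["p_correct"].mean() == pytest.approx(0.25, abs=0.05)
        rec["correct"] = True
        assert (accuracy_table(rec, ["jitter_deg"]).data["p_correct"] == 1).all()

    def test_missing_cell_names_subject(self):
        rec = pd.DataFrame({
            "subject": ["a", "a", "b"], "group": "younger",
            "jitter_deg": [0, 30, 0], "correct": [1, 0, 1]})
        with pytest.raises(ValueError, match="'b'"):
            accuracy_table(rec, ["jitter_deg"])


class TestArcsine:
    def test_endpoints_and_chance(self):
        assert arcsine_transform(0.0) == 0.0
        assert arcsine_transform(1.0) == pytest.approx(math.pi / 2)
        assert arcsine_transform(0.25) == pytest.approx(math.pi / 6)

    def test_monotone(self):
        p = np.linspace(0, 1, 101)
        y = arcsine_transform(p)
        assert np.all(np.diff(y) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            arcsine_transform(1.2)


class TestDprime:
    def test_chance_maps_to_zero(self):
        assert dprime_4afc(0.25) == pytest.approx(0.0, abs=1e-6)

    def test_round_trip_against_quadrature_oracle(self):
        """Forward model by independent fixed-order Gauss-Legendre
        quadrature, inverted by the package."""
        nodes, weights = np.polynomial.legendre.leggauss(400)
        for d in (0.3, 1.0, 2.2, 4.0):
            lo, hi = -9.0, 9.0 + d
            z = (hi - lo) / 2 * nodes + (hi + lo) / 2
            pc = float(np.sum(weights * (hi - lo) / 2 * sps.norm.pdf(z)
                              * sps.norm.cdf(z + d) ** 3))
            assert dprime_4afc(pc) == pytest.approx(d, abs=1e-6)

    def test_pc_strictly_increasing_in_dprime(self):
        d = np.linspace(0, 5, 26)
        pcs = [pc_from_dprime(x) for x in d]
        assert all(a < b for a, b in zip(pcs, pcs[1:]))

    def test_ceiling_capped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            d = dprime_4afc(1.0)
        assert d > 5.0

    def test_below_chance_gives_negative_dprime(self):
        assert dprime_4afc(0.15) < 0


class TestMixedAnova:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        y = rng.normal(0.6, 0.1, size=(6, 3))
        y[3:] += 0.08
        y[:, 2] -= 0.05
        groups = np.array(["younger"] * 3 + ["older"] * 3)
        oracle = bruteforce_mixed_anova(y, groups)
        res = mixed_rm_anova(make_cell_table(y, groups, [1, 2, 3]), dv="p_correct")
        for mine, ref in (("group", "group"), ("level", "within"),
                          ("group:level", "interaction")):
            e = res[mine]
            assert e.F == pytest.approx(oracle[ref]["F"], abs=1e-10)
            assert (e.df_num, e.df_den) == oracle[ref]["df"]
            assert e.epsilon_hat == pytest.approx(oracle[ref]["eps"], abs=1e-10)
            assert e.eta2_g == pytest.approx(oracle[ref]["eta2_g"], abs=1e-10)
        assert res.ss_total == pytest.approx(oracle["ss_total"], abs=1e-10)
        assert oracle["ss_parts"] == pytest.approx(oracle["ss_total"], abs=1e-10)

    def test_matches_pingouin_mixed_design(self):
        """Cross-check F (all effects) and, with no observed factors, the
        generalized eta-squared, on an unbalanced two-group design."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        y = rng.normal(0.5, 0.12, size=(13, 4))
        groups = np.array(["younger"] * 7 + ["older"] * 6)
        y[7:] -= 0.06
        tab = make_cell_table(y, groups, [0, 15, 30, 45], factor="jitter")
        res = mixed_rm_anova(tab, dv="p_correct", observed=())
        long = tab.data
        ref = pingouin.mixed_anova(data=long, dv="p_correct", within="jitter",
                                   subject="subject", between="group",
                                   correction=True, effsize="ng2")
        ref = ref.set_index("Source")
        assert res["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert res["jitter"].F == pytest.approx(ref.loc["jitter", "F"], rel=1e-9)
        assert res["group:jitter"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)
        for mine, theirs in (("group", "group"), ("jitter", "jitter"),
                             ("group:jitter", "Interaction")):
            assert res[mine].eta2_g == pytest.approx(
                ref.loc[theirs, "ng2"], rel=1e-9)

    def test_epsilon_matches_reference_R_implementation(self, tmp_path):
        """The mixed-design Greenhouse-Geisser epsilon (pooled error
        covariance) against R's car::Anova on the same data."""
        rng = np.random.default_rng(2)
        y = rng.normal(0.6, 0.1, size=(10, 5))
        y[5:, :2] += 0.1
        groups = np.array(["younger"] * 5 + ["older"] * 5)
        wide = pd.DataFrame(y, columns=[f"y.{i}" for i in range(5)])
        wide["group"] = groups
        csv = tmp_path / "wide.csv"
        wide.to_csv(csv, index=False)
        script = tmp_path / "gg.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(car))
            wide <- read.csv("{csv}")
            mat <- as.matrix(wide[, 1:5])
            mlm <- lm(mat ~ group, data = wide)
            idata <- data.frame(level = factor(1:5))
            s <- summary(Anova(mlm, idata = idata, idesign = ~level, type = 3),
                         multivariate = FALSE)
            cat(sprintf("%.12f", s$pval.adjustments["level", "GG eps"]))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        gg_r = float(out.stdout.strip())
        res = mixed_rm_anova(make_cell_table(y, groups, list(range(5))),
                             dv="p_correct")
        assert res["level"].epsilon_hat == pytest.approx(gg_r, abs=1e-9)

    def test_within_only_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(3)
        y = rng.normal(0.0, 1.0, size=(8, 4)) + np.array([0, 0.2, 0.4, 0.1])
        tab = make_cell_table(y, ["all"] * 8, list(range(4)))
        res = mixed_rm_anova(tab, dv="p_correct")
        long = tab.data
        ref = AnovaRM(long, depvar="p_correct", subject="subject",
                      within=["level"]).fit()
        assert res["level"].F == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-9)

    def test_two_level_factor_has_unit_epsilon(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, size=(8, 2))
        tab = make_cell_table(y, ["younger"] * 4 + ["older"] * 4, [0, 1])
        assert mixed_rm_anova(tab, dv="p_correct")["level"].epsilon_hat == 1.0

    def test_pure_between_reduces_to_classical_eta_squared(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)])
        df = pd.DataFrame({"subject": [f"s{i}" for i in range(12)],
                           "group": ["younger"] * 6 + ["older"] * 6,
                           "p_correct": vals, "n_trials": 1})
        res = mixed_rm_anova(CellTable(data=df, factors=()), dv="p_correct")
        e = res["group"]
        ss_b = 6 * ((vals[:6].mean() - vals.mean()) ** 2
                    + (vals[6:].mean() - vals.mean()) ** 2)
        ss_e = ((vals[:6] - vals[:6].mean()) ** 2).sum() + \
            ((vals[6:] - vals[6:].mean()) ** 2).sum()
        assert e.eta2_g == pytest.approx(ss_b / (ss_b + ss_e), abs=1e-12)
        assert e.F == pytest.approx((ss_b / 1) / (ss_e / 10), abs=1e-12)

    def test_epsilon_bounds_and_ss_decomposition_full_design(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0.5, 0.1, size=(9, 20))
        rows = []
        for i in range(9):
            c = 0
            for lam in (2, 4, 6, 8):
                for J in (0, 15, 30, 45, 60):
                    rows.append({"subject": f"s{i}",
                                 "group": "younger" if i < 5 else "older",
                                 "lam": lam, "J": J,
                                 "p_correct": y[i, c], "n_trials": 1})
                    c += 1
        tab = CellTable(data=pd.DataFrame(rows), factors=("lam", "J"))
        res = mixed_rm_anova(tab, dv="p_correct")
        total_ss = float(((y - y.mean()) ** 2).sum())
        assert res.ss_total == pytest.approx(total_ss, rel=1e-10)
        for e in res:
            assert 0.0 <= e.eta2_g <= 1.0
            q = e.df_num if not e.effect.startswith("group") else 1
            assert e.epsilon_hat <= 1.0 + 1e-12

    def test_unbalanced_within_design_rejected(self):
        df = pd.DataFrame({"subject": ["a", "a", "b"],
                           "group": ["younger"] * 3,
                           "level": [0, 1, 0],
                           "p_correct": [0.5, 0.6, 0.7], "n_trials": 1})
        with pytest.raises(ValueError, match="balanced"):
            mixed_rm_anova(CellTable(data=df, factors=("level",)),
                           dv="p_correct")


class TestLinearTrend:
    def test_constant_accuracy_gives_zero_scores(self):
        y = np.full((8, 5), 0.7)
        tab = make_cell_table(y, ["younger"] * 4 + ["older"] * 4,
                              [0.04, 0.093, 0.2, 0.4, 0.8],
                              factor="duration_s")
        res = linear_trend_analysis(tab, dv="p_correct")
        assert np.allclose(res.scores["score"], 0.0)

    def test_contrast_is_linear_in_slope(self):
        durs = np.array([0.04, 0.093, 0.2, 0.4, 0.8])
        x = np.log(durs)
        y1 = 0.5 + 0.1 * (x - x.mean())[None, :] + np.zeros((6, 1))
        y2 = 0.5 + 0.2 * (x - x.mean())[None, :] + np.zeros((6, 1))
        g = ["younger"] * 3 + ["older"] * 3
        s1 = linear_trend_analysis(make_cell_table(y1, g, durs,
                                                   factor="duration_s"),
                                   dv="p_correct").scores["score"]
        s2 = linear_trend_analysis(make_cell_table(y2, g, durs,
                                                   factor="duration_s"),
                                   dv="p_correct").scores["score"]
        assert np.allclose(2 * s1, s2)

    def test_weights_centered_unit_norm(self):
        y = np.random.default_rng(0).normal(0.6, 0.05, (6, 5))
        tab = make_cell_table(y, ["younger"] * 3 + ["older"] * 3,
                              [0.04, 0.093, 0.2, 0.4, 0.8],
                              factor="duration_s")
        res = linear_trend_analysis(tab, dv="p_correct")
        assert res.weights.sum() == pytest.approx(0.0, abs=1e-12)
        assert (res.weights ** 2).sum() == pytest.approx(1.0, abs=1e-12)

    def test_null_group_difference_behaves(self):
        """Equal slopes in both groups: the group F should be null-like
        (rejection near the nominal rate over replicates)."""
        rng = np.random.default_rng(7)
        durs = np.array([0.04, 0.093, 0.2, 0.4, 0.8])
        rej = 0
        for _ in range(300):
            y = (0.5 + 0.08 * np.log(durs)[None, :]
                 + rng.normal(0, 0.05, (12, 5)))
            tab = make_cell_table(y, ["younger"] * 6 + ["older"] * 6, durs,
                                  factor="duration_s")
            res = linear_trend_analysis(tab, dv="p_correct")
            rej += res.group_p < 0.05
        lo, hi = sps.binom.ppf([0.005, 0.995], 300, 0.05) / 300
        assert lo <= rej / 300 <= hi

    def test_single_level_rejected(self):
        y = np.full((4, 1), 0.5)
        tab = make_cell_table(y, ["younger"] * 2 + ["older"] * 2, [0.2],
                              factor="duration_s")
        with pytest.raises(ValueError):
            linear_trend_analysis(tab, dv="p_correct")


class TestPipelineCoherence:
    def test_accuracy_and_dprime_effects_agree_in_sign(self):
        """Group and jitter effects point the same way whether measured
        as accuracy or as 4AFC sensitivity."""
        from spiralfield.observer import (OLDER_DEFAULTS, YOUNGER_DEFAULTS,
                                          psychometric_prob)
        from spiralfield.field_fill import Condition
        rng = np.random.default_rng(8)
        rows = []
        for g, params, n in (("younger", YOUNGER_DEFAULTS, 6),
                             ("older", OLDER_DEFAULTS, 6)):
            for i in range(n):
                for J in (0, 30, 60):
                    pc = psychometric_prob(
                        Condition(spacing_deg=1.2, jitter_deg=J), params)
                    k = rng.binomial(60, pc)
                    rows.append({"subject": f"{g}{i}", "group": g,
                                 "J": J, "p_correct": k / 60, "n_trials": 60})
        df = pd.DataFrame(rows)
        df["dprime"] = [dprime_4afc(min(p, 0.999)) for p in df["p_correct"]]
        for dv in ("p_correct", "dprime"):
            by_group = df.groupby("group")[dv].mean()
            assert by_group["younger"] > by_group["older"]
            by_j = df.groupby("J")[dv].mean()
            assert by_j[0] > by_j[60]
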