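import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from pymsp import stats
from pymsp.exceptions import ContractViolation


def hierarchical_data(rng, n_birds=(6, 6), delta=0.0, mean=500.0,
                      bird_sd=1.5, resid_sd=1.0, cells_per_bird=4):
    rows = []
    b = 0
    for pop_i, n in enumerate(n_birds):
        pop = f"pop{'AB'[pop_i]}"
        for _ in range(n):
            eff = rng.normal(0.0, bird_sd)
            k = (cells_per_bird if np.isscalar(cells_per_bird)
                 else rng.integers(*cells_per_bird))
            for _ in range(int(k)):
                rows.append((mean + delta * pop_i + eff
                             + rng.normal(0.0, resid_sd), f"bird{b:02d}", pop))
            b += 1
    return pd.DataFrame(rows, columns=["value", "bird_id", "population"])


class TestFitLMM:
    def test_constant_contrast_recovered_exactly(self):
        rows = []
        for b in range(6):
            pop = "popA" if b < 3 else "popB"
            val = 500.0 if pop == "popA" else 506.0
            rows += [(val, f"bird{b}", pop)] * 4
        df = pd.DataFrame(rows, columns=["value", "bird_id", "population"])
        res = stats.fit_lmm(df)
        assert res.fixed_effect_estimate == pytest.approx(6.0, abs=1e-9)

    def test_zero_bird_variance_limit_matches_anova(self):
        # bird means identical within population -> REML hits the gamma=0
        # boundary and the F statistic must equal one-way ANOVA on cells
        cells = {"popA": [1.0, 2.0, 3.0, 4.0], "popB": [2.0, 3.0, 4.0, 6.0]}
        rows = []
        for b in range(8):
            pop = "popA" if b < 4 else "popB"
            rows += [(v, f"bird{b}", pop) for v in cells[pop]]
        df = pd.DataFrame(rows, columns=["value", "bird_id", "population"])
        res = stats.fit_lmm(df)
        F, _ = sps.f_oneway(df[df.population == "popA"].value,
                            df[df.population == "popB"].value)
        assert res.boundary
        assert res.F == pytest.approx(F, abs=1e-6)

    def test_agrees_with_statsmodels_reml(self, rng):
        import statsmodels.formula.api as smf
        df = hierarchical_data(rng, delta=5.0, cells_per_bird=(2, 7))
        res = stats.fit_lmm(df)
        sm = smf.mixedlm("value ~ population", df,
                         groups=df["bird_id"]).fit(reml=True)
        assert res.fixed_effect_estimate == pytest.approx(
            sm.params["population[T.popB]"], abs=1e-4)
        assert res.var_bird == pytest.approx(float(sm.cov_re.iloc[0, 0]),
                                             abs=1e-3)
        assert res.var_resid == pytest.approx(sm.scale, abs=1e-4)
        assert res.reml_loglik == pytest.approx(sm.llf, abs=1e-4)

    def test_single_population_is_contract_violation(self, rng):
        df = hierarchical_data(rng, n_birds=(6, 0))
        with pytest.raises(ContractViolation):
            stats.fit_lmm(df)

    def test_bird_in_two_populations_rejected(self, rng):
        df = hierarchical_data(rng)
        df.loc[df.index[-1], "bird_id"] = df.loc[df.index[0], "bird_id"]
        with pytest.raises(ContractViolation):
            stats.fit_lmm(df)

    def test_emm_equal_raw_means_in_balanced_design(self, rng):
        df = hierarchical_data(rng, delta=3.0)
        res = stats.fit_lmm(df)
        for pop in ("popA", "popB"):
            raw = df[df.population == pop].value.mean()
            assert res.emm[pop][0] == pytest.approx(raw, abs=1e-9)

    def test_null_estimate_near_zero(self, rng):
        ests = [stats.fit_lmm(hierarchical_data(rng)).fixed_effect_estimate
                for _ in range(40)]
        assert abs(np.mean(ests)) < 0.5

    def test_type_one_error_desk_scale(self):
        rng = np.random.default_rng(123)
        n_rep = 200
        rej = sum(stats.fit_lmm(hierarchical_data(rng)).p < 0.05
                  for _ in range(n_rep))
        # 99% binomial envelope around alpha = 0.05 at n = 200
        assert rej / n_rep <= 0.10

    def test_df_rules_reported(self, rng):
        df = hierarchical_data(rng)
        res = stats.fit_lmm(df)
        assert set(res.df_den_by_method) == {"satterthwaite", "containment",
                                             "residual"}
        assert res.df_den_by_method["containment"] == 10.0  # 12 birds - 2
        res_c = stats.fit_lmm(df, df_method="containment")
        assert res_c.df_den == 10.0

    def test_satterthwaite_df_tracks_bird_level(self, rng):
        # bird variance dominant, balanced: df should be near n_birds - 2
        df = hierarchical_data(rng, bird_sd=3.0, resid_sd=0.5)
        res = stats.fit_lmm(df)
        assert 7.0 < res.df_den < 13.0

    def test_parameter_recovery(self):
        rng = np.random.default_rng(9)
        vb, ve = [], []
        for _ in range(150):
            df = hierarchical_data(rng, n_birds=(6, 6), bird_sd=1.5,
                                   resid_sd=1.0, cells_per_bird=6)
            res = stats.fit_lmm(df)
            vb.append(res.var_bird)
            ve.append(res.var_resid)
        assert np.mean(vb) == pytest.approx(2.25, rel=0.25)
        assert np.mean(ve) == pytest.approx(1.0, rel=0.10)


class TestICC:
    def test_zero_residual_noise_gives_one(self, rng):
        rows = []
        for b in range(5):
            mean = float(rng.normal(500.0, 3.0))
            rows += [(mean, f"bird{b}")] * 4
        df = pd.DataFrame(rows, columns=["value", "bird_id"])
        res = stats.icc(df)
        assert res.icc == pytest.approx(1.0, abs=1e-6)

    def test_zero_bird_variance_boundary_gives_zero(self):
        # identical per-bird samples -> no between-bird spread at all
        rows = []
        for b in range(6):
            rows += [(v, f"bird{b}") for v in (499.0, 500.0, 501.0)]
        df = pd.DataFrame(rows, columns=["value", "bird_id"])
        res = stats.icc(df)
        assert res.icc == pytest.approx(0.0, abs=1e-9)
        assert res.boundary

    def test_balanced_matches_anova_closed_form(self, rng):
        k = 8
        rows = []
        for b in range(12):
            eff = rng.normal(0.0, 2.0)
            rows += [(eff + rng.normal(0.0, 1.0), f"bird{b:02d}")
                     for _ in range(k)]
        df = pd.DataFrame(rows, columns=["value", "bird_id"])
        res = stats.icc(df)
        grp = df.groupby("bird_id").value
        msb = k * grp.mean().var(ddof=1)
        msw = grp.apply(lambda s: s.var(ddof=1)).mean()
        sb = (msb - msw) / k
        assert res.icc == pytest.approx(sb / (sb + msw), abs=1e-6)

    def test_all_singleton_birds_undefined(self):
        df = pd.DataFrame({"value": [1.0, 2.0, 3.0],
                           "bird_id": ["a", "b", "c"]})
        res = stats.icc(df)
        assert res.icc is None
        assert "repeated" in res.reason

    def test_recovery_of_generator_icc(self):
        # generator icc* used as simulation setting (0.3/0.55/0.75)
        rng = np.random.default_rng(17)
        for target in (0.3, 0.55, 0.75):
            bird_sd = np.sqrt(target)
            resid_sd = np.sqrt(1.0 - target)
            vals = []
            for _ in range(40):
                rows = []
                for b in range(12):
                    eff = rng.normal(0.0, bird_sd)
                    rows += [(eff + rng.normal(0.0, resid_sd), f"b{b:02d}")
                             for _ in range(8)]
                df = pd.DataFrame(rows, columns=["value", "bird_id"])
                vals.append(stats.icc(df).icc)
            assert abs(np.mean(vals) - target) < 0.1


class TestComparisonReport:
    def _cells(self, rng):
        frames = []
        for cls, mean, delta in (("LWS", 563.0, 4.0), ("rod", 500.0, 6.0)):
            df = hierarchical_data(rng, n_birds=(7, 5), delta=delta,
                                   mean=mean)
            df["pigment_class"] = cls
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_row_per_type(self, rng):
        rep = stats.comparison_report(self._cells(rng))
        assert list(rep.pigments["type"]) == ["LWS", "rod"]

    def test_missing_population_rows_not_fabricated(self, rng):
        cells = self._cells(rng)
        cells = cells[~((cells.pigment_class == "LWS")
                        & (cells.population == "popB"))]
        rep = stats.comparison_report(cells)
        row = rep.pigments.set_index("type").loc["LWS"]
        assert row["n_popB"] == 0
        assert row["significant"] is None or pd.isna(row["significant"])

    def test_true_contrast_flagged(self, rng):
        rep = stats.comparison_report(self._cells(rng))
        row = rep.pigments.set_index("type").loc["rod"]
        assert row["significant"]
        assert row["estimate"] == pytest.approx(6.0, abs=2.0)
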