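import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aposignal import (
    AbundanceModel,
    AttackRateModel,
    ModelSpec,
    SimConfig,
    attack_analysis_table,
    fit_attack_glmm,
    gen_survey,
    one_way_anova,
    wald_confint,
)
from aposignal.errors import ConvergenceError, SeparationError, ValidationError
from aposignal.stats import GLMMResults, build_design

ATTACK_SPEC = ModelSpec(
    response="attacked",
    fixed_terms=["pp", "ring", "status"],
    interactions=[("ring", "pp")],
)


class TestBuildDesign:
    def test_treatment_coding_with_references(self):
        df = pd.DataFrame(
            {
                "pp": [0.3, 0.5, 0.7],
                "ring": ["Danaus", "Tirumala", "Euploea"],
                "status": ["model", "mimic", "model"],
            }
        )
        X = build_design(df, ATTACK_SPEC)
        assert "Intercept" in X.columns
        assert "ring[Danaus]" not in X.columns  # reference level absorbed
        assert set(["ring[Tirumala]", "ring[Euploea]", "status[mimic]"]) <= set(X.columns)
        assert X["ring[Tirumala]:pp"].tolist() == [0.0, 0.5, 0.0]

    def test_undeclared_interaction_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(response="y", fixed_terms=["a"], interactions=[("a", "b")])


class TestAttackGLMM:
    def test_matches_reference_mixed_model_fit(self):
        """Frozen cross-check against an lme4 glmer fit of the same data.

        The seed-42 synthetic survey (default design) was fitted in R with
        glmer(attacked ~ pp + ring + status + ring:pp + (1|site/transect),
        family = binomial); estimates, SEs and log-likelihood recorded.
        """
        records, *_ = gen_survey(SimConfig(seed=42))
        tab = attack_analysis_table(records)
        res = fit_attack_glmm(tab, ATTACK_SPEC)
        reference = {
            "Intercept": (-3.83324, 0.595245),
            "pp": (6.82773, 1.036864),
            "ring[Euploea]": (5.29173, 0.754967),
            "ring[Tirumala]": (3.66909, 0.744825),
            "status[mimic]": (1.11673, 0.212987),
            "ring[Euploea]:pp": (-9.95125, 1.316094),
            "ring[Tirumala]:pp": (-7.43034, 1.300375),
        }
        for term, (est, se) in reference.items():
            assert res.params[term] == pytest.approx(est, rel=0.02), term
            assert res.bse[term] == pytest.approx(se, rel=0.03), term
        assert res.llf == pytest.approx(-404.5601, abs=0.01)
        assert res.variance_components["site"] == pytest.approx(0.1364893**2, abs=5e-3)

    def test_agrees_with_plain_logistic_when_no_clustering(self):
        # data drawn iid given covariates: the mixed fit should collapse to
        # ordinary logistic regression (statsmodels GLM as oracle)
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 4000
        x = rng.uniform(0, 1, n)
        eta = -1.0 + 2.5 * x
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        df = pd.DataFrame(
            {
                "attacked": y.astype(int),
                "pp": x,
                "site": rng.choice([f"S{i}" for i in range(8)], n),
            }
        )
        df["transect"] = df["site"] + "-T" + rng.choice(["1", "2", "3"], n)
        spec = ModelSpec(response="attacked", fixed_terms=["pp"])
        res = fit_attack_glmm(df, spec)
        glm = sm.GLM(df["attacked"], sm.add_constant(df["pp"]), family=sm.families.Binomial()).fit()
        assert res.params["Intercept"] == pytest.approx(glm.params["const"], rel=0.1)
        assert res.params["pp"] == pytest.approx(glm.params["pp"], rel=0.1)
        assert res.singular  # no true cluster variance

    def test_all_zero_responses_raise_separation(self):
        df = pd.DataFrame(
            {
                "attacked": 0,
                "pp": np.linspace(0.3, 0.8, 40),
                "site": [f"S{i % 4}" for i in range(40)],
                "transect": [f"T{i % 2}" for i in range(40)],
            }
        )
        with pytest.raises(SeparationError):
            fit_attack_glmm(df, ModelSpec(response="attacked", fixed_terms=["pp"]))

    def test_nonbinary_response_rejected(self):
        df = pd.DataFrame(
            {"attacked": [0, 2], "pp": [0.3, 0.4], "site": ["A", "B"], "transect": ["1", "1"]}
        )
        with pytest.raises(ValidationError):
            AttackRateModel.from_dataframe(df, ModelSpec(response="attacked", fixed_terms=["pp"]))


def _count_cells(rng, lam_fn, n_sites=8, n_tr=4):
    rows = []
    for i in range(n_sites):
        pp = 0.3 + 0.5 * i / (n_sites - 1)
        for j in range(n_tr):
            for ring in ("Danaus", "Tirumala", "Euploea"):
                for status in ("model", "mimic"):
                    lam = lam_fn(pp, ring, status)
                    rows.append(
                        {
                            "count": rng.poisson(lam),
                            "pp": pp,
                            "ring": ring,
                            "status": status,
                            "site": f"S{i}",
                            "transect": f"T{j}",
                        }
                    )
    return pd.DataFrame(rows)


class TestAbundanceModel:
    def test_model_mimic_ratio_recovered(self):
        rng = np.random.default_rng(8)
        df = _count_cells(rng, lambda pp, r, s: 40.0 if s == "model" else 4.0)
        spec = ModelSpec(response="count", fixed_terms=["status"], family="negbin-log")
        res = AbundanceModel.from_dataframe(df, spec).fit()
        ci = res.conf_int()
        assert res.params["status[mimic]"] == pytest.approx(np.log(0.1), abs=0.15)
        assert ci.loc["status[mimic]", "upper"] < 0  # significantly fewer mimics

    def test_constant_counts_give_null_pp_effect(self):
        rng = np.random.default_rng(12)
        df = _count_cells(rng, lambda pp, r, s: 20.0)
        spec = ModelSpec(response="count", fixed_terms=["pp"], family="negbin-log")
        ci = AbundanceModel.from_dataframe(df, spec).fit().conf_int()
        assert ci.loc["pp", "lower"] < 0 < ci.loc["pp", "upper"]

    def test_declining_cryptic_ring_interaction_sign(self):
        rng = np.random.default_rng(3)

        def lam(pp, ring, status):
            slope = -3.0 if ring == "Euploea" else 0.0
            return float(np.exp(3.0 + slope * pp))

        df = _count_cells(rng, lam)
        spec = ModelSpec(
            response="count",
            fixed_terms=["pp", "ring"],
            interactions=[("ring", "pp")],
            family="negbin-log",
        )
        res = AbundanceModel.from_dataframe(df, spec).fit()
        ci = res.conf_int()
        assert ci.loc["ring[Euploea]:pp", "upper"] < 0

    def test_gaussian_identity_family(self):
        rng = np.random.default_rng(6)
        df = _count_cells(rng, lambda pp, r, s: 30.0 if s == "model" else 3.0)
        spec = ModelSpec(response="count", fixed_terms=["status"], family="gaussian-identity")
        res = AbundanceModel.from_dataframe(df, spec).fit()
        # identity scale: mimic deficit of ~27 individuals per cell
        assert res.params["status[mimic]"] == pytest.approx(-27.0, abs=3.0)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame(
            {"count": [-1, 2], "pp": [0.3, 0.4], "site": ["A", "B"], "transect": ["1", "1"]}
        )
        with pytest.raises(ValidationError):
            AbundanceModel.from_dataframe(
                df, ModelSpec(response="count", fixed_terms=["pp"], family="negbin-log")
            )


class TestOneWayAnova:
    def test_hand_computed_example(self):
        res = one_way_anova([(1, 2, 3), (2, 3, 4), (3, 4, 5)])
        # SSB = 6, MSB = 3, SSW = 6, MSW = 1 -> F = 3 on (2, 6) df
        assert res.f_stat == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p_value == pytest.approx(float(sps.f.sf(3.0, 2, 6)))

    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(0)
        groups = [rng.integers(0, 20, rng.integers(3, 9)).astype(float) for _ in range(4)]
        res = one_way_anova(groups)
        grand = np.mean(np.concatenate(groups))
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ssb / (len(groups) - 1)) / (ssw / (sum(map(len, groups)) - len(groups)))
        assert res.f_stat == pytest.approx(f_oracle, rel=1e-12)

    def test_huge_shift_is_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        c = rng.normal(10, 1, 50)
        assert one_way_anova([a, b, c]).p_value < 1e-6

    @pytest.mark.parametrize("groups", [[(1, 2)], [(1, 2), (3,)]])
    def test_contract_errors(self, groups):
        with pytest.raises(ValidationError):
            one_way_anova(groups)


class _FakeModel:
    exog_names = ["a", "b"]
    n_site = 2
    n_transect = 4
    family_name = "binomial-logit"


def _results(params, ses, converged=True):
    cov = np.diag(np.asarray(ses, dtype=float) ** 2)
    return GLMMResults(
        _FakeModel(), np.asarray(params, float), cov,
        {"site": 0.1, "transect": 0.05}, llf=-10.0, converged=converged, singular=False,
    )


class TestWaldConfint:
    def test_standard_normal_quantile(self):
        ci = wald_confint(_results([0.0, 1.0], [1.0, 0.5]), level=0.95)
        lo, hi = ci["a"]
        assert lo == pytest.approx(-1.959964, abs=1e-5)
        assert hi == pytest.approx(1.959964, abs=1e-5)

    def test_zero_se_degenerate_interval(self):
        ci = wald_confint(_results([2.0, 1.0], [0.0, 1.0]))
        assert ci["a"] == (2.0, 2.0)

    def test_higher_level_is_wider(self):
        r = _results([0.3, -0.2], [0.7, 1.1])
        ci95 = wald_confint(r, 0.95)
        ci99 = wald_confint(r, 0.99)
        for t in ("a", "b"):
            assert ci99[t][0] < ci95[t][0] < ci95[t][1] < ci99[t][1]

    def test_refuses_unconverged_fit(self):
        with pytest.raises(ConvergenceError):
            wald_confint(_results([0.0, 0.0], [1.0, 1.0], converged=False))


def test_summary_lists_terms_and_variance_components():
    records, *_ = gen_survey(SimConfig(seed=2))
    res = fit_attack_glmm(attack_analysis_table(records), ATTACK_SPEC)
    text = res.summary()
    assert "ring[Euploea]:pp" in text
    assert "site=" in text and "transect=" in text
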