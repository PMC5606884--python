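"""Mixed models and ANOVA for the predation-gradient analysis.

The central model is a binomial GLMM for the per-specimen binary attack
outcome:

    logit P(attacked) = X beta + u_site + v_transect(site)

with independent Gaussian random intercepts for site and for transect
nested within site.  Fixed effects typically include background predation
pressure (PP), mimicry-ring identity, model/mimic status, abundance terms
and two-way interactions; treatment contrasts use the most conspicuous
ring (Danaus) and model status as references.

Estimation is maximum likelihood with a Laplace approximation to the
random-effect integral: for a trial value of the variance parameters, the
joint penalized likelihood in (beta, u) is maximized by Newton iterations
(PIRLS), and the Laplace log-likelihood

    l(theta) = l_cond(beta_hat, u_hat) - ||u_hat||^2 / 2
               - log det(M' W M + I) / 2

is optimized over theta = (log sd_site, log sd_transect) by Nelder-Mead.
Wald covariance of beta comes from the Schur complement of the joint
Hessian, i.e. conditional on the estimated variance components -- the
usual convention, which undercovers slightly when the number of sites is
small.

Count responses (abundance) use the same machinery with a Poisson or
negative-binomial (NB2) family; a Gaussian-identity family is also
provided (delegating to statsmodels MixedLM) because field reports of
abundance effects are sometimes on the identity scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special
from scipy import stats as sps

from .errors import ConvergenceError, NoDataError, SeparationError, ValidationError

_SIGMA_FLOOR = 1e-5
_SEPARATION_BETA = 30.0


# ---------------------------------------------------------------------------
# Families

class _Family:
    name = ""

    def loglik(self, y, trials, eta):  # pragma: no cover - interface
        raise NotImplementedError

    def score_eta(self, y, trials, eta):
        raise NotImplementedError

    def weights(self, y, trials, eta):
        raise NotImplementedError


class _BinomialLogit(_Family):
    name = "binomial-logit"

    def loglik(self, y, trials, eta):
        return float(np.sum(y * eta - trials * np.logaddexp(0.0, eta)))

    def score_eta(self, y, trials, eta):
        return y - trials * special.expit(eta)

    def weights(self, y, trials, eta):
        p = special.expit(eta)
        return np.maximum(trials * p * (1.0 - p), 1e-10)


class _PoissonLog(_Family):
    name = "poisson-log"

    def loglik(self, y, trials, eta):
        mu = np.exp(eta)
        return float(np.sum(y * eta - mu - special.gammaln(y + 1.0)))

    def score_eta(self, y, trials, eta):
        return y - np.exp(eta)

    def weights(self, y, trials, eta):
        return np.maximum(np.exp(eta), 1e-10)


class _NegBinLog(_Family):
    """NB2: Var = mu + alpha mu^2, log link, Fisher scoring."""

    name = "negbin-log"

    def __init__(self, alpha: float = 0.5):
        self.alpha = float(alpha)

    def loglik(self, y, trials, eta):
        a = self.alpha
        if a < 1e-8:
            return _PoissonLog().loglik(y, trials, eta)
        mu = np.exp(eta)
        r = 1.0 / a
        return float(
            np.sum(
                special.gammaln(y + r)
                - special.gammaln(r)
                - special.gammaln(y + 1.0)
                + y * np.log(a * mu / (1.0 + a * mu))
                - r * np.log1p(a * mu)
            )
        )

    def score_eta(self, y, trials, eta):
        mu = np.exp(eta)
        return (y - mu) / (1.0 + self.alpha * mu)

    def weights(self, y, trials, eta):
        mu = np.exp(eta)
        return np.maximum(mu / (1.0 + self.alpha * mu), 1e-10)


def _make_family(name: str, alpha: float = 0.5) -> _Family:
    if name == "binomial-logit":
        return _BinomialLogit()
    if name == "poisson-log":
        return _PoissonLog()
    if name == "negbin-log":
        return _NegBinLog(alpha)
    raise ValidationError(f"unknown family {name!r}")


# ---------------------------------------------------------------------------
# Model specification and design construction

@dataclass
class ModelSpec:
    """Declarative fixed/random structure of a fit.

    fixed_terms name columns of the data; categorical columns expand to
    treatment-contrast dummies against ``references`` (default: 'Danaus'
    for ring, 'model' for status).  interactions are pairs of fixed terms.
    The random structure is always transect nested within site.
    """

    response: str
    fixed_terms: list[str] = dc_field(default_factory=list)
    interactions: list[tuple[str, str]] = dc_field(default_factory=list)
    family: str = "binomial-logit"
    random_nesting: tuple[str, str] = ("site", "transect")
    references: dict[str, str] = dc_field(
        default_factory=lambda: {"ring": "Danaus", "status": "model"}
    )

    def __post_init__(self):
        for a, b in self.interactions:
            if a not in self.fixed_terms or b not in self.fixed_terms:
                raise ValidationError(f"interaction ({a},{b}) references undeclared terms")
        if self.random_nesting != ("site", "transect"):
            raise ValidationError("random structure must be transect nested within site")


def _expand_term(data: pd.DataFrame, term: str, references: Mapping[str, str]) -> pd.DataFrame:
    col = data[term]
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.astype(str).unique())
        ref = references.get(term, levels[0])
        if ref not in levels:
            ref = levels[0]
        cols = {}
        for lev in levels:
            if lev == ref:
                continue
            cols[f"{term}[{lev}]"] = (col.astype(str) == lev).astype(float)
        return pd.DataFrame(cols, index=data.index)
    return pd.DataFrame({term: col.astype(float)})


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Fixed-effect design matrix (with intercept) per the spec."""
    parts = [pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)]
    expanded: dict[str, pd.DataFrame] = {}
    for t in spec.fixed_terms:
        if t not in data.columns:
            raise ValidationError(f"term {t!r} not in data")
        expanded[t] = _expand_term(data, t, spec.references)
        parts.append(expanded[t])
    for a, b in spec.interactions:
        inter = {}
        for ca in expanded[a].columns:
            for cb in expanded[b].columns:
                inter[f"{ca}:{cb}"] = expanded[a][ca] * expanded[b][cb]
        parts.append(pd.DataFrame(inter, index=data.index))
    X = pd.concat(parts, axis=1)
    return X


# ---------------------------------------------------------------------------
# Laplace engine

def _group_codes(values: Sequence) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(values), sort=True)
    return codes.astype(int), len(uniques)


class _LaplaceGLMM:
    """Laplace-approximate GLMM with site + transect-in-site intercepts."""

    def __init__(self, y, trials, X, site, transect, family: _Family):
        self.y = np.asarray(y, dtype=float)
        self.trials = np.asarray(trials, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.site_idx, self.n_site = _group_codes(site)
        # transects are nested: key on (site, transect) so repeated transect
        # labels across sites stay distinct
        tkey = [f"{s}||{t}" for s, t in zip(site, transect)]
        self.tr_idx, self.n_tr = _group_codes(tkey)
        self.family = family
        self.n, self.p = self.X.shape
        self.q = self.n_site + self.n_tr
        # sparse-free random design: indicator columns
        Z = np.zeros((self.n, self.q))
        Z[np.arange(self.n), self.site_idx] = 1.0
        Z[np.arange(self.n), self.n_site + self.tr_idx] = 1.0
        self.Z = Z

    def _pirls(self, sig_s, sig_t, beta, u, maxiter=50, tol=1e-9):
        scale = np.concatenate(
            [np.full(self.n_site, sig_s), np.full(self.n_tr, sig_t)]
        )
        M = self.Z * scale  # n x q
        A = np.hstack([self.X, M])
        coef = np.concatenate([beta, u])
        pen = np.concatenate([np.zeros(self.p), np.ones(self.q)])

        def pll(c):
            eta = A @ c
            return self.family.loglik(self.y, self.trials, eta) - 0.5 * np.sum(
                (c[self.p:]) ** 2
            )

        cur = pll(coef)
        for _ in range(maxiter):
            eta = A @ coef
            g = self.family.score_eta(self.y, self.trials, eta)
            W = self.family.weights(self.y, self.trials, eta)
            grad = A.T @ g - pen * coef
            H = (A * W[:, None]).T @ A
            H[self.p:, self.p:] += np.eye(self.q)
            try:
                step = linalg.solve(H, grad, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.lstsq(H, grad)[0]
            new = coef + step
            val = pll(new)
            shrink = 0
            while not np.isfinite(val) or val < cur - 1e-10:
                step *= 0.5
                new = coef + step
                val = pll(new)
                shrink += 1
                if shrink > 30:
                    break
            if shrink > 30:
                break
            coef, improved = new, val - cur
            cur = val
            if abs(improved) < tol * (abs(cur) + 1.0):
                break
        eta = A @ coef
        W = self.family.weights(self.y, self.trials, eta)
        MWM = (M * W[:, None]).T @ M + np.eye(self.q)
        sign, logdet = np.linalg.slogdet(MWM)
        lap = cur - 0.5 * logdet
        return coef[: self.p], coef[self.p:], lap, cur, W, A, M

    def fit(self, maxiter_outer=200):
        if self.family.name == "binomial-logit":
            tot_y, tot_n = self.y.sum(), self.trials.sum()
            if tot_y == 0 or tot_y == tot_n:
                raise SeparationError("Intercept", "all responses identical; intercept diverges")
        beta = np.zeros(self.p)
        u = np.zeros(self.q)
        state = {"beta": beta, "u": u}

        def neg(theta):
            sig_s = float(np.exp(np.clip(theta[0], -12, 4)))
            sig_t = float(np.exp(np.clip(theta[1], -12, 4)))
            b, uu, lap, *_ = self._pirls(sig_s, sig_t, state["beta"], state["u"])
            state["beta"], state["u"] = b, uu
            return -lap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                neg,
                x0=np.array([np.log(0.3), np.log(0.3)]),
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-5, "maxiter": maxiter_outer},
            )
        sig_s = float(np.exp(np.clip(res.x[0], -12, 4)))
        sig_t = float(np.exp(np.clip(res.x[1], -12, 4)))
        beta, u, lap, _, W, A, M = self._pirls(sig_s, sig_t, state["beta"], state["u"])
        # Wald covariance of beta: Schur complement of the joint Hessian
        H = (A * W[:, None]).T @ A
        H[self.p:, self.p:] += np.eye(self.q)
        Hbb = H[: self.p, : self.p]
        Hbu = H[: self.p, self.p:]
        Huu = H[self.p:, self.p:]
        try:
            cov = linalg.inv(Hbb - Hbu @ linalg.solve(Huu, Hbu.T, assume_a="pos"))
        except linalg.LinAlgError:
            cov = linalg.pinvh(Hbb)
        return {
            "beta": beta,
            "cov": cov,
            "u": u,
            "sigma_site": sig_s,
            "sigma_transect": sig_t,
            "llf": float(lap),
            "converged": bool(res.success or res.fun == res.fun),
            "outer_converged": bool(res.success),
            "singular": bool(sig_s < 1e-3 and sig_t < 1e-3),
        }


# ---------------------------------------------------------------------------
# Results

class GLMMResults:
    """Fit results: estimates, Wald uncertainty, variance components.

    Mirrors the statsmodels results API: ``params``, ``bse``,
    ``conf_int``, ``pvalues``, ``summary``.
    """

    def __init__(self, model, params, cov, variance_components, llf, converged, singular,
                 extra_df: int = 0, alpha_dispersion: float | None = None):
        self.model = model
        self.params = pd.Series(params, index=model.exog_names)
        self.cov_params = pd.DataFrame(cov, index=model.exog_names, columns=model.exog_names)
        self.variance_components = dict(variance_components)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.singular = bool(singular)
        self.alpha_dispersion = alpha_dispersion
        k = len(self.params) + len(self.variance_components) + extra_df
        self.aic = -2.0 * self.llf + 2.0 * k

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse.replace(0.0, np.nan)
        return pd.Series(2.0 * sps.norm.sf(np.abs(z)), index=self.params.index).fillna(0.0)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if not self.converged:
            raise ConvergenceError("fit did not converge; refusing Wald intervals")
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        ci = self.conf_int() if self.converged else None
        lines = [
            f"{type(self.model).__name__} ({self.model.family_name})",
            f"  groups: {self.model.n_site} sites, {self.model.n_transect} transects",
            f"  loglik {self.llf:.3f}   AIC {self.aic:.3f}   converged={self.converged}"
            + ("   SINGULAR" if self.singular else ""),
            "  variance components: "
            + ", ".join(f"{k}={v:.4g}" for k, v in self.variance_components.items())
            + (f", nb_alpha={self.alpha_dispersion:.4g}" if self.alpha_dispersion else ""),
            f"  {'term':<28}{'coef':>10}{'se':>9}{'2.5%':>10}{'97.5%':>10}",
        ]
        for name in self.params.index:
            lo = f"{ci.loc[name, 'lower']:.3f}" if ci is not None else "-"
            hi = f"{ci.loc[name, 'upper']:.3f}" if ci is not None else "-"
            lines.append(
                f"  {name:<28}{self.params[name]:>10.4f}{self.bse[name]:>9.4f}{lo:>10}{hi:>10}"
            )
        return "\n".join(lines)

    def plot_effect(self, term: str, ax=None):  # pragma: no cover - thin plotting
        from .plotting import plot_coefficients

        return plot_coefficients(self, terms=[term], ax=ax)


def wald_confint(fit: GLMMResults, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """estimate +/- z(level) * SE per term (refuses non-converged fits)."""
    ci = fit.conf_int(alpha=1.0 - level)
    return {t: (float(ci.loc[t, "lower"]), float(ci.loc[t, "upper"])) for t in ci.index}


# ---------------------------------------------------------------------------
# Model classes

class _BaseGLMM:
    family_name = ""

    def __init__(self, endog, exog: pd.DataFrame, site, transect, trials=None):
        self.endog = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            self.exog = exog.to_numpy(dtype=float)
            self.exog_names = list(exog.columns)
        else:
            self.exog = np.asarray(exog, dtype=float)
            self.exog_names = [f"x{i}" for i in range(self.exog.shape[1])]
        self.trials = (
            np.ones_like(self.endog) if trials is None else np.asarray(trials, dtype=float)
        )
        self.site = np.asarray(site)
        self.transect = np.asarray(transect)
        self.n_site = len(pd.unique(self.site))
        self.n_transect = len(
            pd.unique(np.array([f"{s}||{t}" for s, t in zip(self.site, self.transect)]))
        )
        if self.n_site < 2:
            raise ValidationError("need >= 2 sites for a mixed fit")
        if len(self.endog) != len(self.exog):
            raise ValidationError("endog/exog length mismatch")

    def _check_separation(self, beta):
        if np.max(np.abs(beta)) > _SEPARATION_BETA:
            term = self.exog_names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(term)

    def _results(self, raw, extra_df=0, alpha_dispersion=None) -> GLMMResults:
        return GLMMResults(
            self,
            raw["beta"],
            raw["cov"],
            {"site": raw["sigma_site"] ** 2, "transect": raw["sigma_transect"] ** 2},
            raw["llf"],
            raw["converged"],
            raw["singular"],
            extra_df=extra_df,
            alpha_dispersion=alpha_dispersion,
        )


class AttackRateModel(_BaseGLMM):
    """Binomial-logit GLMM for binary attack outcomes.

    Build with :meth:`from_dataframe` from a specimen- or cell-level table
    containing the response, fixed-effect columns and site/transect
    labels.  Binary rows sharing a design cell are aggregated to binomial
    counts before fitting (the likelihood is identical; the fit is much
    faster).
    """

    family_name = "binomial-logit"

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        spec: ModelSpec,
        site_col: str = "site",
        transect_col: str = "transect",
    ) -> "AttackRateModel":
        if spec.family != "binomial-logit":
            raise ValidationError("AttackRateModel requires the binomial-logit family")
        X = build_design(data, spec)
        y = data[spec.response].to_numpy(dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValidationError("binary response must be 0/1")
        cell = pd.concat(
            [X, data[[site_col, transect_col]].reset_index(drop=True)], axis=1
        )
        grp = cell.groupby(list(cell.columns), sort=False, as_index=False).size()
        # successes per cell
        cell_y = cell.copy()
        cell_y["__y"] = y
        agg = cell_y.groupby(list(cell.columns), sort=False, as_index=False)["__y"].sum()
        agg["__n"] = grp["size"].to_numpy()
        Xa = agg[X.columns]
        return cls(
            endog=agg["__y"].to_numpy(),
            exog=Xa,
            site=agg[site_col].to_numpy(),
            transect=agg[transect_col].to_numpy(),
            trials=agg["__n"].to_numpy(),
        )

    def fit(self, maxiter: int = 200) -> GLMMResults:
        engine = _LaplaceGLMM(
            self.endog, self.trials, self.exog, self.site, self.transect, _BinomialLogit()
        )
        raw = engine.fit(maxiter_outer=maxiter)
        self._check_separation(raw["beta"])
        return self._results(raw)


class AbundanceModel(_BaseGLMM):
    """Mixed count model for encounter counts per site-transect cell.

    Default family is NB2 (log link) with the dispersion estimated by
    profile likelihood; ``family='poisson-log'`` fixes the dispersion at
    zero, and ``family='gaussian-identity'`` refits via statsmodels
    MixedLM for identity-scale effect reporting.
    """

    def __init__(self, endog, exog, site, transect, family: str = "negbin-log"):
        if np.any(np.asarray(endog) < 0) and family != "gaussian-identity":
            raise ValidationError("counts must be non-negative")
        super().__init__(endog, exog, site, transect)
        self.family_name = family

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        spec: ModelSpec,
        site_col: str = "site",
        transect_col: str = "transect",
    ) -> "AbundanceModel":
        X = build_design(data, spec)
        return cls(
            endog=data[spec.response].to_numpy(dtype=float),
            exog=X,
            site=data[site_col].to_numpy(),
            transect=data[transect_col].to_numpy(),
            family=spec.family,
        )

    def _fit_gaussian(self) -> GLMMResults:
        import statsmodels.formula.api as smf

        df = pd.DataFrame(self.exog, columns=[f"x{i}" for i in range(self.exog.shape[1])])
        df["y"] = self.endog
        df["site"] = self.site
        df["transect"] = [f"{s}||{t}" for s, t in zip(self.site, self.transect)]
        rhs = " + ".join(c for c in df.columns if c.startswith("x"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm(
                f"y ~ 0 + {rhs}",
                df,
                groups="site",
                re_formula="1",
                vc_formula={"transect": "0 + C(transect)"},
            )
            r = m.fit(reml=False)
        k = self.exog.shape[1]
        cov = np.asarray(r.cov_params())[:k, :k]
        raw = {
            "beta": np.asarray(r.fe_params),
            "cov": cov,
            "sigma_site": float(np.sqrt(max(float(np.asarray(r.cov_re).ravel()[0]), 0.0))),
            "sigma_transect": float(np.sqrt(max(float(r.vcomp[0]), 0.0)) if len(r.vcomp) else 0.0),
            "llf": float(r.llf),
            "converged": bool(r.converged),
            "singular": False,
        }
        return self._results(raw, extra_df=1)

    def fit(self, maxiter: int = 200) -> GLMMResults:
        if self.family_name == "gaussian-identity":
            return self._fit_gaussian()
        if self.family_name == "poisson-log":
            engine = _LaplaceGLMM(
                self.endog, self.trials, self.exog, self.site, self.transect, _PoissonLog()
            )
            raw = engine.fit(maxiter_outer=maxiter)
            return self._results(raw)
        # NB2: alternate (theta, beta) fits with profile updates of alpha
        alpha = 0.5
        raw = None
        for _ in range(3):
            fam = _NegBinLog(alpha)
            engine = _LaplaceGLMM(
                self.endog, self.trials, self.exog, self.site, self.transect, fam
            )
            raw = engine.fit(maxiter_outer=maxiter)
            eta = (
                self.exog @ raw["beta"]
                + engine.Z
                @ (
                    np.concatenate(
                        [
                            np.full(engine.n_site, raw["sigma_site"]),
                            np.full(engine.n_tr, raw["sigma_transect"]),
                        ]
                    )
                    * raw["u"]
                )
            )

            def nll(log_a):
                return -_NegBinLog(float(np.exp(log_a))).loglik(self.endog, self.trials, eta)

            opt = optimize.minimize_scalar(nll, bounds=(-12, 3), method="bounded")
            new_alpha = float(np.exp(opt.x))
            if abs(np.log(new_alpha) - np.log(alpha)) < 1e-3:
                alpha = new_alpha
                break
            alpha = new_alpha
        return self._results(raw, extra_df=1, alpha_dispersion=alpha)


# thin operation-level wrappers ---------------------------------------------

def fit_attack_glmm(data: pd.DataFrame, spec: ModelSpec, **kw) -> GLMMResults:
    return AttackRateModel.from_dataframe(data, spec, **kw).fit()


def fit_abundance_model(data: pd.DataFrame, spec: ModelSpec, **kw) -> GLMMResults:
    return AbundanceModel.from_dataframe(data, spec, **kw).fit()


def compare_aic(data: pd.DataFrame, specs: Sequence[ModelSpec], kind: str = "attack") -> pd.DataFrame:
    """AIC table over candidate fixed-effect structures (model selection)."""
    rows = []
    for i, spec in enumerate(specs):
        res = fit_attack_glmm(data, spec) if kind == "attack" else fit_abundance_model(data, spec)
        rows.append(
            {"model": i, "terms": "+".join(spec.fixed_terms), "aic": res.aic, "llf": res.llf}
        )
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)


# ---------------------------------------------------------------------------
# One-way ANOVA

@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (e.g. trait ~ mimicry ring)."""
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValidationError("every group needs >= 2 values")
    f, p = sps.f_oneway(*arrays)
    n = sum(g.size for g in arrays)
    return AnovaResult(
        f_stat=float(f),
        df_between=len(arrays) - 1,
        df_within=n - len(arrays),
        p_value=float(p),
    )
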