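"""Mixed-effects inference with AICc all-subsets model selection.

Two model families, child as the unit of analysis:

* Gaussian models for hemoglobin concentration, with a random intercept for
  household and, in rural fits, a higher-level random intercept for the
  riverine community.  Fitted by maximum likelihood (not REML) through
  statsmodels' linear mixed model so that AICc is comparable across
  fixed-effect subsets.
* Binomial (logistic) models for whether a child eats wildmeat, with the
  same random-intercept structures.  The marginal likelihood is evaluated
  with a Laplace approximation (the per-cluster random-effect integral is
  replaced by a second-order expansion around its mode), maximised with
  L-BFGS-B over fixed effects and log standard deviations.  The
  approximation is named in the fit metadata; AICc comparisons are only
  meaningful within one approximation.

Non-categorical fixed effects are standardized to mean zero and unit
standard deviation before fitting; the stored transform is used to also
report every coefficient per natural unit (e.g. g/dL per monthly meal).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, special
from sklearn.base import BaseEstimator, clone
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "standardize",
    "aicc",
    "vif",
    "ModelFit",
    "MixedEffectsModel",
    "AICcSearch",
    "consumption_curve",
]

MAX_CANDIDATE_TERMS = 20


# ----------------------------------------------------------------------
def standardize(data: pd.DataFrame, columns) -> tuple[pd.DataFrame, dict]:
    """Z-score the given columns; return the new frame and the transform.

    The transform maps column -> (mean, sd) so fitted coefficients can be
    reported per natural unit.  A constant column has no scale and raises
    ``ValueError``.
    """
    out = data.copy()
    transform: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = data[col].astype(float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"column '{col}' has zero standard deviation")
        out[col] = (x - mu) / sd
        transform[col] = (mu, sd)
    return out, transform


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Classical variance inflation factor per (numeric) design column.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the others plus an
    intercept.  Perfectly collinear columns get ``inf``.
    """
    cols = list(design.columns)
    X = design.astype(float).to_numpy()
    n = X.shape[0]
    out: dict[str, float] = {}
    for j, col in enumerate(cols):
        others = np.column_stack([np.ones(n)] + [X[:, i] for i in range(len(cols)) if i != j])
        y = X[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0.0:
            raise ValueError(f"column '{col}' is constant")
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ----------------------------------------------------------------------
@dataclass
class ModelFit:
    """One estimated mixed model."""

    response: str
    family: str
    terms: tuple
    coefficients: pd.DataFrame  # standardized and natural scale, with CIs
    variance_components: dict
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    approximation: str  # 'exact-ml' (gaussian) or 'laplace' (binomial)
    vif: dict = field(default_factory=dict)


def _is_categorical(series: pd.Series) -> bool:
    return (
        series.dtype == object
        or series.dtype == bool
        or isinstance(series.dtype, pd.CategoricalDtype)
    )


class MixedEffectsModel(BaseEstimator):
    """Random-intercept GLMM estimator (scikit-learn style).

    Parameters
    ----------
    response : str
        Outcome column (continuous for gaussian, boolean/0-1 for binomial).
    fixed_effects : sequence of str
        Candidate fixed-effect columns; categorical columns (object, bool or
        categorical dtype) enter as treatment-coded dummies, numeric columns
        are standardized when ``standardize_numeric`` is true.
    family : {'gaussian', 'binomial'}
    group_col : str
        Household identifier — always a random intercept.
    community_col : str or None
        If given, a higher-level random intercept (households nested in
        communities), used for rural fits.
    reml : bool
        Gaussian only; default False (ML) so AICc is comparable across
        fixed-effect sets.

    Fitted attributes end in an underscore: ``result_`` (a
    :class:`ModelFit`), ``coefficients_``, ``loglik_``, ``aicc_``,
    ``converged_``, ``variance_components_``, ``vif_``.
    """

    def __init__(
        self,
        response: str = "hemoglobin_gdl",
        fixed_effects=("child_meals_30d",),
        family: str = "gaussian",
        group_col: str = "household_id",
        community_col: str | None = None,
        standardize_numeric: bool = True,
        reml: bool = False,
    ):
        self.response = response
        self.fixed_effects = fixed_effects
        self.family = family
        self.group_col = group_col
        self.community_col = community_col
        self.standardize_numeric = standardize_numeric
        self.reml = reml

    # -- design helpers -------------------------------------------------
    def _split_terms(self, data: pd.DataFrame):
        numeric, categorical = [], []
        for term in self.fixed_effects:
            if term not in data.columns:
                raise KeyError(f"fixed effect '{term}' not in data")
            (categorical if _is_categorical(data[term]) else numeric).append(term)
        return numeric, categorical

    def _design(self, data: pd.DataFrame, numeric, categorical):
        """Intercept + standardized numerics + treatment-coded dummies."""
        parts = [pd.Series(1.0, index=data.index, name="Intercept")]
        for term in numeric:
            parts.append(data[term].astype(float))
        for term in categorical:
            dummies = pd.get_dummies(data[term], prefix=term, drop_first=True)
            parts.append(dummies.astype(float))
        return pd.concat(parts, axis=1)

    # -- fitting --------------------------------------------------------
    def fit(self, data: pd.DataFrame, y=None) -> "MixedEffectsModel":
        if data[self.group_col].nunique() < 2:
            raise ValueError("need at least 2 households to fit a mixed model")
        numeric, categorical = self._split_terms(data)
        work = data.copy()
        if self.standardize_numeric and numeric:
            work, transform = standardize(work, numeric)
        else:
            transform = {}
        self.transform_ = transform
        self.numeric_terms_ = list(numeric)
        self.categorical_terms_ = list(categorical)

        if self.family == "gaussian":
            self._fit_gaussian(work)
        elif self.family == "binomial":
            self._fit_binomial(work)
        else:
            raise ValueError(f"unknown family {self.family!r}")

        X = self._design(work, numeric, categorical)
        self.vif_ = vif(X[[c for c in X.columns if c in numeric]]) if len(numeric) >= 2 else {
            c: 1.0 for c in numeric
        }
        self.result_ = ModelFit(
            response=self.response,
            family=self.family,
            terms=tuple(self.fixed_effects),
            coefficients=self.coefficients_,
            variance_components=self.variance_components_,
            loglik=self.loglik_,
            k=self.k_,
            n=self.n_,
            aicc=self.aicc_,
            converged=self.converged_,
            approximation=self.approximation_,
            vif=self.vif_,
        )
        return self

    def _finalize(self, names, est, se, loglik, n, n_var_params, converged):
        z = 1.959963984540054
        coef = pd.DataFrame(
            {
                "term": names,
                "estimate": est,
                "se": se,
                "lower": est - z * se,
                "upper": est + z * se,
            }
        )
        nat_scale = np.array(
            [self.transform_.get(t, (0.0, 1.0))[1] for t in names]
        )
        for col in ("estimate", "se", "lower", "upper"):
            coef[f"{col}_natural"] = coef[col] / nat_scale
        self.coefficients_ = coef
        self.loglik_ = float(loglik)
        self.n_ = int(n)
        self.k_ = len(names) + n_var_params
        self.aicc_ = aicc(self.loglik_, self.k_, self.n_)
        self.converged_ = bool(converged)

    def _fit_gaussian(self, work: pd.DataFrame) -> None:
        terms = []
        for t in self.numeric_terms_:
            terms.append(t)
        for t in self.categorical_terms_:
            terms.append(f"C({t})")
        formula = f"{self.response} ~ {' + '.join(terms) if terms else '1'}"
        if self.community_col is not None:
            model = smf.mixedlm(
                formula,
                work,
                groups=work[self.community_col],
                re_formula="1",
                vc_formula={"household": f"0 + C({self.group_col})"},
            )
            n_var = 3  # community, household, residual
        else:
            model = smf.mixedlm(formula, work, groups=work[self.group_col],
                                re_formula="1")
            n_var = 2  # household, residual
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=self.reml, method="lbfgs", maxiter=500)
            fe = res.fe_params
            names = list(fe.index)
            est = fe.to_numpy()
            se = res.bse_fe.to_numpy()
        vc = {"residual": float(res.scale)}
        if self.community_col is not None:
            vc["community"] = float(np.asarray(res.cov_re)[0, 0])
            vc["household"] = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        else:
            vc["household"] = float(np.asarray(res.cov_re)[0, 0])
        self.variance_components_ = vc
        self.approximation_ = "exact-ml" if not self.reml else "reml"
        self._statsmodels_result_ = res
        converged = bool(getattr(res, "converged", True))
        self._finalize(names, est, se, float(res.llf), len(work), n_var, converged)
        # normalise statsmodels' C(col)[T.level] naming to col_level so the
        # natural-scale lookup and curve prediction share one convention
        self.coefficients_["term"] = [
            _clean_term(t) for t in self.coefficients_["term"]
        ]

    # -- binomial family (Laplace) --------------------------------------
    def _clusters(self, work: pd.DataFrame):
        """Partition rows into independent top-level clusters.

        Returns a list of (row_indices, Z, var_index) where Z maps the
        cluster's random-effect vector to observations and var_index gives,
        per random effect, the index into the variance vector (0=community,
        1=household for nested fits; 0=household otherwise).
        """
        clusters = []
        if self.community_col is None:
            for _, idx in work.groupby(self.group_col, sort=True).indices.items():
                Z = np.ones((len(idx), 1))
                clusters.append((np.asarray(idx), Z, np.array([0])))
            self._n_var_params = 1
        else:
            for _, cidx in work.groupby(self.community_col, sort=True).indices.items():
                cidx = np.asarray(cidx)
                hh = work[self.group_col].to_numpy()[cidx]
                hh_levels, hh_codes = np.unique(hh, return_inverse=True)
                q = 1 + len(hh_levels)
                Z = np.zeros((len(cidx), q))
                Z[:, 0] = 1.0
                Z[np.arange(len(cidx)), 1 + hh_codes] = 1.0
                var_index = np.concatenate([[0], np.ones(len(hh_levels), dtype=int)])
                clusters.append((cidx, Z, var_index))
            self._n_var_params = 2
        return clusters

    @staticmethod
    def _laplace_cluster(y, eta0, Z, d, u0):
        """Laplace-approximate log integral over one cluster's random effects."""
        u = u0.copy()
        inv_d = 1.0 / d

        def penalized(u):
            eta = eta0 + Z @ u
            return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (u * inv_d) @ u)

        f = penalized(u)
        for _ in range(100):
            eta = eta0 + Z @ u
            p = special.expit(eta)
            g = Z.T @ (y - p) - u * inv_d
            W = p * (1.0 - p)
            H = Z.T @ (Z * W[:, None]) + np.diag(inv_d)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = g * d
            # step halving keeps the inner Newton monotone
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                f_new = penalized(u_new)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            moved = np.max(np.abs(u_new - u))
            u, f = u_new, f_new
            if moved < 1e-9:
                break
        eta = eta0 + Z @ u
        p = special.expit(eta)
        W = p * (1.0 - p)
        H = Z.T @ (Z * W[:, None]) + np.diag(inv_d)
        sign, logdet_h = np.linalg.slogdet(H)
        ll = f - 0.5 * np.log(d).sum() - 0.5 * logdet_h
        return ll, u

    def _fit_binomial(self, work: pd.DataFrame) -> None:
        X = self._design(work, self.numeric_terms_, self.categorical_terms_)
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
        yv = work[self.response].to_numpy().astype(float)
        if not np.isin(yv, (0.0, 1.0)).all():
            raise ValueError("binomial response must be boolean / 0-1")
        clusters = self._clusters(work)
        n_var = self._n_var_params
        p_fix = Xm.shape[1]
        u_store = [np.zeros(Z.shape[1]) for _, Z, _ in clusters]

        def nll(theta):
            beta = theta[:p_fix]
            sigma = np.exp(theta[p_fix:])
            eta_fixed = Xm @ beta
            total = 0.0
            for ci, (idx, Z, var_index) in enumerate(clusters):
                d = (sigma[var_index]) ** 2
                ll, u_hat = self._laplace_cluster(
                    yv[idx], eta_fixed[idx], Z, d, u_store[ci]
                )
                u_store[ci] = u_hat
                total += ll
            return -total

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start_glm = sm.GLM(yv, Xm, family=sm.families.Binomial()).fit()
        x0 = np.concatenate([start_glm.params, np.full(n_var, np.log(0.5))])
        sigma_cap = 5.0
        bounds = [(None, None)] * p_fix + [(np.log(1e-4), np.log(sigma_cap))] * n_var
        opt = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-10},
        )
        theta = opt.x
        hess = approx_hess1(theta, nll)
        se = np.full(p_fix, np.nan)
        try:
            cov = np.linalg.inv(hess)
            diag = np.diag(cov)[:p_fix]
            se = np.sqrt(np.where(diag > 0, diag, np.nan))
            self._cov_beta_ = cov[:p_fix, :p_fix]
        except np.linalg.LinAlgError:
            self._cov_beta_ = np.full((p_fix, p_fix), np.nan)
        sigma = np.exp(theta[p_fix:])
        if n_var == 2:
            vc = {"community": float(sigma[0] ** 2), "household": float(sigma[1] ** 2)}
        else:
            vc = {"household": float(sigma[0] ** 2)}
        self.variance_components_ = vc
        self.approximation_ = "laplace"
        self._beta_ = theta[:p_fix]
        self._design_columns_ = names
        # an honest convergence flag: a variance estimate escaping to the
        # box bound signals cluster-level separation (the likelihood keeps
        # rising in sigma), and a singular Hessian means no usable SEs
        interior = bool((sigma < 0.9 * sigma_cap).all())
        usable_se = bool(np.isfinite(se).all())
        self._finalize(
            names, theta[:p_fix], se, -float(opt.fun), len(work), n_var,
            opt.success and interior and usable_se,
        )


def _clean_term(term: str) -> str:
    """C(col)[T.level] -> col_level; passthrough otherwise."""
    if term.startswith("C(") and "[T." in term:
        col = term[2 : term.index(")")]
        level = term[term.index("[T.") + 3 : -1]
        return f"{col}_{level}"
    return term


# ----------------------------------------------------------------------
class AICcSearch(BaseEstimator):
    """All-subsets model selection ranked by AICc.

    Fits every subset of ``candidate_terms`` (on top of ``always_terms``)
    with the random structure of the prototype ``model``, ranks converged
    fits by AICc, and flags models within ``plausible_delta`` of the best
    as equally plausible.

    Fitted attributes: ``results_`` (one row per model), ``best_model_``,
    ``best_terms_``, ``fits_`` (terms tuple -> fitted estimator).
    """

    def __init__(
        self,
        model: MixedEffectsModel,
        candidate_terms=(),
        always_terms=(),
        plausible_delta: float = 2.0,
    ):
        self.model = model
        self.candidate_terms = candidate_terms
        self.always_terms = always_terms
        self.plausible_delta = plausible_delta

    def fit(self, data: pd.DataFrame, y=None) -> "AICcSearch":
        candidates = list(self.candidate_terms)
        if len(candidates) > MAX_CANDIDATE_TERMS:
            raise ValueError(
                f"{len(candidates)} candidate terms exceeds the all-subsets "
                f"guard of {MAX_CANDIDATE_TERMS}"
            )
        rows = []
        self.fits_ = {}
        for r in range(len(candidates) + 1):
            for subset in itertools.combinations(candidates, r):
                terms = tuple(self.always_terms) + subset
                est = clone(self.model)
                est.set_params(fixed_effects=terms)
                try:
                    est.fit(data)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                if not est.converged_:
                    continue
                key = tuple(sorted(terms))
                self.fits_[key] = est
                rows.append(
                    {
                        "terms": key,
                        "n_terms": len(terms),
                        "k": est.k_,
                        "loglik": est.loglik_,
                        "aicc": est.aicc_,
                    }
                )
        if not rows:
            raise RuntimeError("no candidate model converged")
        res = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
        res["delta_aicc"] = res["aicc"] - res["aicc"].iloc[0]
        res["plausible"] = res["delta_aicc"] <= self.plausible_delta
        self.results_ = res
        self.best_terms_ = res["terms"].iloc[0]
        self.best_model_ = self.fits_[self.best_terms_]
        return self

    def best_containing(self, term: str) -> MixedEffectsModel | None:
        """Lowest-AICc fitted model whose fixed effects include `term`."""
        for terms in self.results_["terms"]:
            if term in terms:
                return self.fits_[terms]
        return None


# ----------------------------------------------------------------------
def consumption_curve(
    model: MixedEffectsModel,
    ages,
    at: dict | None = None,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Population-level probability of eating wildmeat across an age grid.

    Evaluates the fitted logistic model at reference covariate values
    (defaults: zero for standardized numerics, reference category for
    dummies) with random effects at zero, and builds a delta-method CI band
    on the logit scale from the coefficient covariance.  The band method is
    recorded in the frame attrs.
    """
    if model.family != "binomial":
        raise ValueError("consumption curves require a binomial fit")
    at = dict(at or {})
    names = model._design_columns_
    beta = model._beta_
    cov = model._cov_beta_
    z = float(-special.ndtri((1.0 - conf) / 2.0))
    rows = []
    for age in np.asarray(ages, dtype=float):
        x = np.zeros(len(names))
        for j, name in enumerate(names):
            if name == "Intercept":
                x[j] = 1.0
            elif name in model.transform_:
                mu, sd = model.transform_[name]
                raw = age if name == "age_years" else at.get(name, mu)
                x[j] = (raw - mu) / sd
            else:
                x[j] = float(at.get(name, 0.0))
        eta = float(x @ beta)
        var = float(x @ cov @ x)
        half = z * np.sqrt(max(var, 0.0))
        rows.append(
            {
                "age_years": age,
                "probability": float(special.expit(eta)),
                "lower": float(special.expit(eta - half)),
                "upper": float(special.expit(eta + half)),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["band_method"] = "delta-method on logit scale"
    out.attrs["approximation"] = model.approximation_
    return out
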