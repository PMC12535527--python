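"""Hierarchical (repeated-measures multi-level) modelling of synchrony tables.

The response is the z-scored cross-wavelet power of one dyad; observations are
10-s intervals nested in minutes nested in sessions nested in participants (or
therapists).  Models are fitted by maximum likelihood so that nested models
can be compared with likelihood-ratio ANOVAs at alpha = 0.05, following a
ladder: null model -> design terms (Session, Minute, Interval, Frequency band
and interactions) -> covariates -> substantive predictors (other-dyad
synchrony, favorite horse, CTQ subscales).  Each rung is kept only if it
significantly improves fit.

Fixed-effect inference uses the Wald normal approximation (the within-group n
is large in this design); goodness of fit is summarized by Nakagawa's marginal
and conditional R-squared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger("hrvsync")


@dataclass(frozen=True)
class ModelSpec:
    """One model in a ladder.

    ``fixed`` are patsy formula terms (joined by '+'); ``groups`` is the
    grouping column for random effects; ``re_formula`` describes random
    effects within group ('1' = random intercept, '1 + minute' adds a random
    slope).  ``name`` labels the rung.
    """

    response: str
    fixed: tuple[str, ...] = ()
    groups: str = "participant_id"
    re_formula: str = "1"
    name: str = "model"

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"

    def with_terms(self, *terms: str, name: str | None = None) -> "ModelSpec":
        return ModelSpec(
            response=self.response,
            fixed=self.fixed + tuple(terms),
            groups=self.groups,
            re_formula=self.re_formula,
            name=name or f"{self.name}+{'+'.join(terms)}",
        )


@dataclass
class ModelFit:
    """A fitted mixed model with the quantities the tables report."""

    spec: ModelSpec
    estimates: pd.DataFrame       # term, estimate, ci_low, ci_high, p
    variance_components: dict[str, float]
    resid_var: float
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    n_params: int
    r2_marginal: float
    r2_conditional: float
    converged: bool
    fell_back_to_intercept: bool = False
    result: object = field(default=None, repr=False)  # statsmodels results

    @property
    def table(self) -> pd.DataFrame:
        return self.estimates


@dataclass
class LadderResult:
    """Sequential nested-model comparison at a fixed alpha."""

    fits: list[ModelFit]
    comparisons: pd.DataFrame  # model, df, loglik, aic, chi2, p, kept
    best: ModelFit
    alpha: float = 0.05
    halted: bool = False
    diagnostics: str = ""


# ---------------------------------------------------------------------------
# design assembly


def build_design(
    table: pd.DataFrame,
    response_dyad: str,
    predictor_dyad: str | None = None,
    predictor_name: str = "other_sync",
) -> pd.DataFrame:
    """Model-ready long table for one dyad's response.

    Selects the rows of ``response_dyad``; if ``predictor_dyad`` is given, its
    ``cwp_z`` is aligned row-wise by (session_id, minute, interval, band) and
    attached as ``predictor_name``.  Rows whose predictor key is missing are
    dropped (the count is logged).  Misaligned duplicates raise an error
    naming the offending keys.

    Categorical design variables (minute, interval, band, session) keep
    treatment coding with the first sorted level as reference, which is the
    patsy default applied at fit time.
    """
    keys = ["session_id", "minute", "interval", "band"]
    resp = table[table["dyad"] == response_dyad].copy()
    if resp.empty:
        raise ValueError(f"no rows for response dyad {response_dyad!r}")
    if predictor_dyad is not None:
        pred = table[table["dyad"] == predictor_dyad][keys + ["cwp_z"]]
        dup = pred.duplicated(subset=keys, keep=False)
        if dup.any():
            bad = pred.loc[dup, keys].drop_duplicates().head(5)
            raise ValueError(f"misaligned predictor rows for keys:\n{bad}")
        pred = pred.rename(columns={"cwp_z": predictor_name})
        n_before = len(resp)
        resp = resp.merge(pred, on=keys, how="inner")
        dropped = n_before - len(resp)
        if dropped:
            logger.info("build_design: dropped %d rows missing predictor keys", dropped)
        resp.attrs["n_dropped"] = dropped
    else:
        resp.attrs["n_dropped"] = 0
    return resp.sort_values(keys).reset_index(drop=True)


# ---------------------------------------------------------------------------
# fitting


def _n_params(res) -> int:
    """Total estimated parameters: fixed + random covariance + residual."""
    k_fe = res.k_fe
    k_re = res.k_re * (res.k_re + 1) // 2 + getattr(res, "k_vc", 0)
    return int(k_fe + k_re + 1)


def fit_mlm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Maximum-likelihood fit of one mixed model.

    Wald 95% CIs and normal-approximation p-values for fixed effects.  A
    singular random-slope fit falls back to a random intercept, and the
    fallback is recorded on the returned object; non-convergence is reported
    via ``converged`` (and logged), never silently accepted.
    """
    data = data.dropna(subset=[spec.response]).copy()
    if data[spec.groups].nunique() < 2:
        raise ValueError(f"need >= 2 groups in {spec.groups!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probe = smf.mixedlm(spec.formula, data, groups=data[spec.groups])
    X = np.asarray(probe.exog, dtype=float)
    full_rank = np.linalg.matrix_rank(X)
    if full_rank < X.shape[1]:
        aliased = [
            name
            for j, name in enumerate(probe.exog_names)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == full_rank
        ]
        raise ValueError(f"rank-deficient fixed design; aliased terms: {aliased}")

    def _try(re_formula: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                spec.formula, data, groups=data[spec.groups], re_formula=re_formula
            )
            # near a variance boundary the default optimizer may stop at a
            # worse stationary point (or report llf = inf) while claiming
            # convergence, which zeroes between-group fixed effects; always
            # try Powell as well and keep the best finite likelihood
            res = None
            try:
                res = model.fit(reml=False, maxiter=200)
                if not np.isfinite(res.llf):
                    res = None
            except np.linalg.LinAlgError:
                res = None
            # near a variance boundary the default optimizer may stop at a
            # worse stationary point (or report llf = inf) while claiming
            # convergence, which zeroes between-group fixed effects; re-fit
            # with Powell whenever the fit looks boundary-suspect and keep
            # the better likelihood
            suspect = (
                res is None
                or not res.converged
                or np.min(np.diag(np.atleast_2d(np.asarray(res.cov_re)))) < 1e-4 * res.scale
            )
            if suspect:
                for method in ("powell", "nm"):
                    try:
                        cand = model.fit(reml=False, method=method, maxiter=500)
                    except np.linalg.LinAlgError:
                        continue
                    if not np.isfinite(cand.llf):
                        continue
                    if res is None or cand.llf > res.llf + 1e-10:
                        res = cand
                    break
            if res is None:
                raise np.linalg.LinAlgError("all optimizers failed")
            return res

    fell_back = False
    try:
        res = _try(spec.re_formula)
        singular = np.linalg.eigvalsh(np.atleast_2d(res.cov_re)).min() < 1e-8
    except (np.linalg.LinAlgError, ValueError):
        res, singular = None, True
    if (res is None or singular) and spec.re_formula.strip() != "1":
        logger.info("fit_mlm[%s]: singular random-slope fit, falling back to intercept", spec.name)
        res = _try("1")
        fell_back = True
    if res is None:  # pragma: no cover - defensive
        raise RuntimeError(f"model {spec.name} failed to fit")
    if not res.converged:
        logger.warning("fit_mlm[%s]: did not converge", spec.name)

    fe = res.fe_params
    se = pd.Series(_fe_se_gls(res), index=fe.index)
    z = stats.norm.ppf(0.975)
    est = pd.DataFrame(
        {
            "term": fe.index,
            "estimate": fe.values,
            "ci_low": fe.values - z * se.values,
            "ci_high": fe.values + z * se.values,
            "p": 2 * stats.norm.sf(np.abs(fe.values / se.values)),
        }
    )

    cov_re = np.atleast_2d(res.cov_re)
    vc = {
        name: float(cov_re[i, i])
        for i, name in enumerate(np.atleast_1d(res.cov_re.index) if hasattr(res.cov_re, "index") else [])
    }
    if not vc:
        vc = {"group": float(cov_re[0, 0])}

    r2m, r2c = _nakagawa_from_result(res, data, spec)

    return ModelFit(
        spec=spec,
        estimates=est,
        variance_components=vc,
        resid_var=float(res.scale),
        loglik=float(res.llf),
        aic=float(res.aic),
        n_obs=int(res.nobs),
        n_groups=int(data[spec.groups].nunique()),
        n_params=_n_params(res),
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=bool(res.converged),
        fell_back_to_intercept=fell_back,
        result=res,
    )


def _fe_se_gls(res) -> np.ndarray:
    """Fixed-effect standard errors conditional on the variance estimates.

    ``Var(beta) = (X' V^-1 X)^-1`` with ``V_g = Z_g Sigma Z_g' + s2 I`` per
    group — the same quantity lme4 reports.  Unlike the joint observed
    information, this stays well-defined when a variance component sits on
    the boundary.
    """
    model = res.model
    X = np.asarray(model.exog, dtype=float)
    Sigma = np.atleast_2d(np.asarray(res.cov_re, dtype=float))  # response units
    s2 = float(res.scale)
    XtVinvX = np.zeros((X.shape[1], X.shape[1]))
    for g in range(model.n_groups):
        idx = model.row_indices[model.group_labels[g]]
        Xg = X[idx]
        if model.exog_re is not None and Sigma.size:
            Zg = np.asarray(model.exog_re, dtype=float)[idx]
            Vg = Zg @ Sigma @ Zg.T + s2 * np.eye(len(idx))
            XtVinvX += Xg.T @ np.linalg.solve(Vg, Xg)
        else:  # pragma: no cover - exog_re always present via re_formula
            XtVinvX += Xg.T @ Xg / s2
    return np.sqrt(np.diag(np.linalg.inv(XtVinvX)))


def _nakagawa_from_result(res, data: pd.DataFrame, spec: ModelSpec) -> tuple[float, float]:
    """Marginal/conditional R^2 from variance partition.

    var_fixed is the population variance of the fixed-effect linear predictor
    over the data; var_random averages the random-effect variance
    ``z_i' Sigma z_i`` over observations (equal to the intercept variance for
    intercept-only models); var_resid is the ML residual variance.
    """
    eta = res.model.exog @ res.fe_params.values
    var_f = float(np.var(eta))
    Sigma = np.atleast_2d(np.asarray(res.cov_re, dtype=float)) * 1.0
    Z = res.model.exog_re
    if Z is not None and Sigma.size:
        Zm = np.asarray(Z, dtype=float)
        var_r = float(np.mean(np.einsum("ij,jk,ik->i", Zm, Sigma, Zm)))
    else:  # pragma: no cover
        var_r = 0.0
    var_e = float(res.scale)
    denom = var_f + var_r + var_e
    return var_f / denom, (var_f + var_r) / denom


def r2_nakagawa(fit: ModelFit) -> tuple[float, float]:
    """(marginal, conditional) R^2 of a converged fit."""
    if not fit.converged:
        raise ValueError("r2_nakagawa requires a converged fit")
    return fit.r2_marginal, fit.r2_conditional


# ---------------------------------------------------------------------------
# comparison


def compare_models(fit_reduced: ModelFit, fit_full: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio ANOVA of two nested ML fits.

    Returns ``(chi2, df, p)`` with ``chi2 = 2 * (ll_full - ll_reduced)``
    floored at zero and ``df`` the parameter-count difference.  Both fits must
    use the same rows.
    """
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError(
            f"non-comparable fits: n_obs {fit_reduced.n_obs} != {fit_full.n_obs}"
        )
    chi2 = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    df = fit_full.n_params - fit_reduced.n_params
    if df <= 0:
        p = 1.0 if chi2 == 0 else float(stats.chi2.sf(chi2, max(df, 1)))
    else:
        p = float(stats.chi2.sf(chi2, df))
    if chi2 == 0.0:
        p = 1.0
    return chi2, df, p


def model_ladder(
    data: pd.DataFrame, ladder: list[ModelSpec], alpha: float = 0.05
) -> LadderResult:
    """Fit a strictly nested ladder, keeping each rung iff its LRT p < alpha.

    The comparison at each rung is against the *current best* model (the last
    kept rung), so non-significant rungs do not become the baseline for later
    ones.  A non-convergent rung halts the ladder with partial results and a
    diagnostic message.
    """
    fits: list[ModelFit] = []
    rows = []
    best: ModelFit | None = None
    halted = False
    diag = ""
    for spec in ladder:
        try:
            fit = fit_mlm(spec, data)
        except Exception as exc:  # halt, do not swallow silently
            halted, diag = True, f"rung {spec.name!r} failed: {exc}"
            logger.warning("model_ladder: %s", diag)
            break
        fits.append(fit)
        if not fit.converged:
            halted, diag = True, f"rung {spec.name!r} did not converge"
            rows.append(
                {"model": spec.name, "df": np.nan, "loglik": fit.loglik, "aic": fit.aic,
                 "chi2": np.nan, "p": np.nan, "kept": False}
            )
            break
        if best is None:
            best = fit
            rows.append(
                {"model": spec.name, "df": fit.n_params, "loglik": fit.loglik,
                 "aic": fit.aic, "chi2": np.nan, "p": np.nan, "kept": True}
            )
            continue
        chi2, df, p = compare_models(best, fit)
        kept = p < alpha
        rows.append(
            {"model": spec.name, "df": fit.n_params, "loglik": fit.loglik,
             "aic": fit.aic, "chi2": chi2, "p": p, "kept": kept}
        )
        if kept:
            best = fit
    if best is None:
        raise RuntimeError(f"ladder produced no usable fit: {diag}")
    return LadderResult(
        fits=fits,
        comparisons=pd.DataFrame(rows),
        best=best,
        alpha=alpha,
        halted=halted,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# diagnostics


def assumption_checks(fit: ModelFit, max_shapiro_n: int = 4000) -> dict:
    """Advisory residual diagnostics for a converged fit.

    Reports residual skewness/kurtosis, a Shapiro-Wilk statistic on a capped
    subsample, a Levene statistic across fitted-value quartile bins
    (heteroscedasticity), variance-inflation factors among fixed predictors
    (with aliasing flagged), and the count of |standardized residual| > 4.
    Never blocking: the result is a plain dict.
    """
    if not fit.converged:
        raise ValueError("assumption_checks requires a converged fit")
    res = fit.result
    fitted = np.asarray(res.model.exog @ res.fe_params.values, dtype=float)
    try:
        resid = np.asarray(res.resid, dtype=float)  # conditional on random effects
    except (ValueError, np.linalg.LinAlgError):
        resid = np.asarray(res.model.endog, dtype=float) - fitted  # marginal fallback
    zresid = resid / resid.std()

    sub = resid if resid.size <= max_shapiro_n else np.random.default_rng(0).choice(
        resid, max_shapiro_n, replace=False
    )
    sw_stat, sw_p = stats.shapiro(sub)

    bins = pd.qcut(fitted, 4, duplicates="drop")
    groups = [resid[bins == b] for b in bins.categories if (bins == b).sum() > 1]
    if len(groups) >= 2:
        lev_stat, lev_p = stats.levene(*groups)
    else:  # pragma: no cover - degenerate fitted values
        lev_stat, lev_p = np.nan, np.nan

    X = np.asarray(res.model.exog, dtype=float)
    names = list(res.model.exog_names)
    vifs = {}
    aliased = []
    for j, name in enumerate(names):
        if name.lower() in ("intercept", "const"):
            continue
        others = np.delete(X, j, axis=1)
        beta, _, rank, _ = np.linalg.lstsq(others, X[:, j], rcond=None)
        pred = others @ beta
        ssr = np.sum((X[:, j] - pred) ** 2)
        sst = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        if sst == 0:
            continue
        r2 = 1.0 - ssr / sst
        if r2 > 1 - 1e-10:
            aliased.append(name)
            vifs[name] = np.inf
        else:
            vifs[name] = float(1.0 / (1.0 - r2))

    return {
        "skew": float(stats.skew(resid)),
        "kurtosis": float(stats.kurtosis(resid)),
        "shapiro_stat": float(sw_stat),
        "shapiro_p": float(sw_p),
        "levene_stat": float(lev_stat),
        "levene_p": float(lev_p),
        "vif": vifs,
        "aliased": aliased,
        "n_outliers_z4": int((np.abs(zresid) > 4).sum()),
    }
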