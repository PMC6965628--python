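"""Linear mixed-model recipes for the group-level analyses.

Every model includes a random intercept per subject and is fit by REML
(statsmodels ``MixedLM``).  Fixed effects are tested with Wald F tests
using Satterthwaite denominator degrees of freedom, computed from the
REML variance-component information via the delta method (the lmerTest
construction: per-eigencontrast one-dimensional df combined into an
F-scale df for multi-df terms).  When the information matrix is not
usable (boundary fits), the residual df ``n_obs - rank(X)`` is used as a
fallback.  Type-I behavior is verified by simulation in the test suite.
Where a recipe compares model variants, the adjusted R-squared is
computed from the fixed-effects (marginal) predictions.

Recipes
-------
``ttp_network``         time-to-peak ~ network (DAN / SN / DMN)
``window_accuracy``     window-mean HFB ~ behavioral accuracy, one network
``window_interaction``  error-minus-correct HFB difference ~ network
``dprime_coupling``     run-level d' ~ zero-lag z + lag-minimum z
                        (within-subject standardized; 90/10 runs only)
``task_rest``           condition (task=1, rest=0) ~ coupling, in three
                        variants (lag-only / zero-only / both) compared by
                        adjusted R-squared
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["ModelSpec", "TermTest", "RecipeResult", "fit_lmm",
           "normalize_within_subject", "run_recipe", "RECIPES",
           "compare_band_contributions"]


@dataclass(frozen=True)
class ModelSpec:
    """A mixed-model formula: dependent ~ fixed, random intercept per group."""

    dependent: str
    fixed: tuple[str, ...]
    group: str = "subject"

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.dependent} ~ {rhs}"


@dataclass(frozen=True)
class TermTest:
    term: str
    f_stat: float
    df_num: int
    df_den: float          # Satterthwaite (residual-df fallback)
    p: float


@dataclass
class RecipeResult:
    """Coefficients, Wald F tests, and optional adjusted R-squared values."""

    spec: ModelSpec
    params: pd.Series
    conf_int: pd.DataFrame                  # 95% CIs per coefficient
    tests: dict[str, TermTest]
    n_obs: int
    n_groups: int
    adj_r2: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False                # singular random-effect variance
    extras: dict = field(default_factory=dict)

    def significant(self, term: str, alpha: float = 0.05) -> bool:
        return self.tests[term].p < alpha


# ---------------------------------------------------------------------------
# Satterthwaite machinery for the random-intercept model
#
# V(theta) = sigma2 * I + tau2 * Z Z' is block diagonal per subject, so all
# quantities are computed per block via the Woodbury identity.  The df for a
# contrast c is  nu = 2 f(theta)^2 / (g' A g)  with f = c' (X'V^-1X)^-1 c,
# g its gradient in theta = (sigma2, tau2), and A the inverse observed REML
# information (numerical Hessian of the REML log-likelihood).


def _block_quantities(y, x, blocks, sigma2, tau2):
    """REML log-likelihood pieces and (X'V^-1X)^-1 for given variances."""
    p = x.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet_v = 0.0
    for idx in blocks:
        ni = len(idx)
        xi, yi = x[idx], y[idx]
        # V_i^-1 = (1/s2) (I - (t2 / (s2 + ni t2)) J)
        w = tau2 / (sigma2 + ni * tau2)
        xs, ys = xi.sum(axis=0), yi.sum()
        xtvx += (xi.T @ xi - w * np.outer(xs, xs)) / sigma2
        xtvy += (xi.T @ yi - w * xs * ys) / sigma2
        ytvy += (yi @ yi - w * ys * ys) / sigma2
        logdet_v += (ni - 1) * np.log(sigma2) + np.log(sigma2 + ni * tau2)
    return xtvx, xtvy, ytvy, logdet_v


def _reml_loglik(y, x, blocks, sigma2, tau2):
    if sigma2 <= 0 or tau2 < 0:
        return -np.inf
    xtvx, xtvy, ytvy, logdet_v = _block_quantities(y, x, blocks, sigma2, tau2)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - xtvy @ beta
    return -0.5 * (logdet_v + logdet_xtvx + quad)


def _vbeta(y, x, blocks, sigma2, tau2):
    xtvx = _block_quantities(y, x, blocks, sigma2, tau2)[0]
    return np.linalg.inv(xtvx)


def _satterthwaite_df_1d(y, x, blocks, sigma2, tau2, c,
                         fallback: float) -> float:
    """Satterthwaite df for a single contrast c (delta method)."""
    theta = np.array([sigma2, max(tau2, 0.0)])
    steps = np.maximum(1e-4 * np.maximum(theta, sigma2), 1e-10)

    def f(th):
        return float(c @ _vbeta(y, x, blocks, th[0], th[1]) @ c)

    # gradient of f (forward differences at the tau2 >= 0 boundary)
    grad = np.zeros(2)
    for k in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += steps[k]
        if theta[k] - steps[k] > 0:
            tm[k] -= steps[k]
            grad[k] = (f(tp) - f(tm)) / (2 * steps[k])
        else:
            grad[k] = (f(tp) - f(theta)) / steps[k]
    # observed REML information (negative Hessian)
    def ll(th):
        return _reml_loglik(y, x, blocks, th[0], max(th[1], 0.0))

    hess = np.zeros((2, 2))
    l0 = ll(theta)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = steps[i]
            ej = np.zeros(2); ej[j] = steps[j]
            if i == j:
                hess[i, i] = (ll(theta + ei) - 2 * l0 + ll(theta - ei)) \
                    / steps[i] ** 2 if theta[i] - steps[i] > 0 else \
                    (ll(theta + 2 * ei) - 2 * ll(theta + ei) + l0) \
                    / steps[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    ll(theta + ei + ej) - ll(theta + ei) - ll(theta + ej)
                    + l0) / (steps[i] * steps[j])
    info = -hess
    try:
        a_cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return fallback
    var_f = float(grad @ a_cov @ grad)
    fval = f(theta)
    if not np.isfinite(var_f) or var_f <= 0 or fval <= 0:
        return fallback
    nu = 2.0 * fval ** 2 / var_f
    if not np.isfinite(nu) or nu < 1.0:
        return fallback
    return float(min(nu, fallback))


def _satterthwaite_df_term(y, x, blocks, sigma2, tau2, l_mat, cov,
                           fallback: float) -> float:
    """Multi-df terms: lmerTest's eigencontrast combination."""
    q = l_mat.shape[0]
    if q == 1:
        return _satterthwaite_df_1d(y, x, blocks, sigma2, tau2, l_mat[0],
                                    fallback)
    m = l_mat @ cov @ l_mat.T
    vals, vecs = np.linalg.eigh(m)
    nus = []
    for k in range(q):
        c = vecs[:, k] @ l_mat
        nus.append(_satterthwaite_df_1d(y, x, blocks, sigma2, tau2, c,
                                        fallback))
    nus = np.asarray(nus)
    usable = nus > 2.0
    if not usable.all():
        return fallback
    e_sum = float(np.sum(nus / (nus - 2.0)))
    if e_sum <= q:
        return fallback
    return float(min(2.0 * e_sum / (e_sum - q), fallback))


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> RecipeResult:
    """REML fit of a random-intercept mixed model with Wald F term tests.

    Denominator df follow Satterthwaite's approximation (residual df
    ``n_obs - rank(X)`` as fallback at degenerate fits); two-tailed
    alpha = 0.05 is the decision threshold used throughout.  A singular
    random-effect variance is reported via ``degenerate`` rather than
    raised.
    """
    for col in (spec.dependent, spec.group):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    if table[spec.group].nunique() < 2:
        raise ValueError("need at least 2 subjects for a random intercept")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM.from_formula(spec.formula, groups=table[spec.group],
                                     data=table)
        res = model.fit(reml=True)
    design_info = model.data.design_info
    exog = model.exog
    n, p_rank = exog.shape[0], np.linalg.matrix_rank(exog)
    df_resid = n - p_rank
    fe_names = model.exog_names
    beta = res.fe_params
    cov = res.cov_params().loc[fe_names, fe_names].to_numpy()
    sigma2 = float(res.scale)
    # cov_re is already on the response scale
    tau2 = max(float(np.asarray(res.cov_re).ravel()[0]), 0.0)
    y_vec = model.endog
    groups_arr = np.asarray(table[spec.group])
    blocks = [np.nonzero(groups_arr == g)[0] for g in pd.unique(groups_arr)]
    tests: dict[str, TermTest] = {}
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(*sl.indices(len(fe_names)))
        l_mat = np.zeros((len(idx), len(fe_names)))
        for r, i in enumerate(idx):
            l_mat[r, i] = 1.0
        lb = l_mat @ beta.to_numpy()
        lcl = l_mat @ cov @ l_mat.T
        q = len(idx)
        try:
            w = float(lb @ np.linalg.solve(lcl, lb))
        except np.linalg.LinAlgError:
            w = np.nan
        f = w / q
        df_den = _satterthwaite_df_term(y_vec, exog, blocks, sigma2, tau2,
                                        l_mat, cov, float(df_resid))
        p = float(sps.f.sf(f, q, df_den)) if np.isfinite(f) else np.nan
        tests[term] = TermTest(term=term, f_stat=float(f), df_num=q,
                               df_den=df_den, p=p)
    df_den = min((t.df_den for t in tests.values()), default=float(df_resid))
    # 95% CI from the t reference with the same denominator df
    # boundary (singular) fits can leave tiny negative diagonal entries
    se = pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)), index=fe_names)
    tcrit = sps.t.ppf(0.975, df_den)
    ci = pd.DataFrame({"lower": beta - tcrit * se, "upper": beta + tcrit * se})
    degenerate = bool(np.any(np.diag(res.cov_re) < 1e-10))
    return RecipeResult(spec=spec, params=beta, conf_int=ci, tests=tests,
                        n_obs=n, n_groups=model.n_groups,
                        degenerate=degenerate)


def _adjusted_r2_marginal(table: pd.DataFrame, spec: ModelSpec) -> float:
    """Adjusted R^2 of the fixed-effects (marginal) predictions."""
    res = fit_lmm(table, spec)
    from patsy import dmatrix
    rhs = " + ".join(spec.fixed) if spec.fixed else "1"
    x = np.asarray(dmatrix(rhs, table))
    y = table[spec.dependent].to_numpy(dtype=float)
    yhat = x @ res.params.to_numpy()
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    p_fixed = x.shape[1] - 1
    n = len(y)
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p_fixed - 1))


def normalize_within_subject(table: pd.DataFrame, cols: list[str],
                             group: str = "subject") -> pd.DataFrame:
    """Z-score the given columns within each subject (mean 0, SD 1 per
    subject), as done before pooling run-level coupling and d' values."""
    out = table.copy()
    for col in cols:
        g = out.groupby(group)[col]
        out[col] = (out[col] - g.transform("mean")) / g.transform("std")
    return out


# ---------------------------------------------------------------------------
# named recipes


def _recipe_ttp_network(table: pd.DataFrame) -> RecipeResult:
    res = fit_lmm(table, ModelSpec("ttp_ms", ("C(network)",)))
    med = table.groupby("network")["ttp_ms"].median()
    res.extras["median_ttp_ms"] = med.to_dict()
    order = [n for n in ("DAN", "SN", "DMN") if n in med.index]
    res.extras["ordering_recovered"] = bool(
        all(med[a] < med[b] for a, b in zip(order, order[1:])))
    return res


def _recipe_window_accuracy(table: pd.DataFrame) -> RecipeResult:
    return fit_lmm(table, ModelSpec("value", ("C(accuracy)",)))


def _recipe_window_interaction(table: pd.DataFrame) -> RecipeResult:
    return fit_lmm(table, ModelSpec("diff", ("C(network)",)))


def _recipe_dprime_coupling(table: pd.DataFrame) -> RecipeResult:
    if "mountain_rate" in table.columns:
        table = table[np.isclose(table["mountain_rate"], 0.10)]
    table = normalize_within_subject(
        table, ["d_prime", "zero_lag_z", "lag_min_z"]).dropna()
    return fit_lmm(table, ModelSpec("d_prime", ("zero_lag_z", "lag_min_z")))


def _recipe_task_rest(table: pd.DataFrame) -> RecipeResult:
    t = table.copy()
    if t["condition"].dtype == object:
        t["condition"] = (t["condition"] == "task").astype(float)
    both = ModelSpec("condition", ("lag_min_z", "zero_lag_z"))
    res = fit_lmm(t, both)
    res.adj_r2 = {
        "both": _adjusted_r2_marginal(t, both),
        "lag_min_only": _adjusted_r2_marginal(
            t, ModelSpec("condition", ("lag_min_z",))),
        "zero_lag_only": _adjusted_r2_marginal(
            t, ModelSpec("condition", ("zero_lag_z",))),
    }
    return res


RECIPES = {
    "ttp_network": _recipe_ttp_network,
    "window_accuracy": _recipe_window_accuracy,
    "window_interaction": _recipe_window_interaction,
    "dprime_coupling": _recipe_dprime_coupling,
    "task_rest": _recipe_task_rest,
}


def run_recipe(name: str, table: pd.DataFrame) -> RecipeResult:
    """Run one of the named group-level models on a tidy table."""
    if name not in RECIPES:
        raise ValueError(
            f"unknown recipe {name!r}; valid names: {sorted(RECIPES)}")
    return RECIPES[name](table)


def compare_band_contributions(table: pd.DataFrame,
                               alpha: float = 0.05) -> dict:
    """Do frequency bands differ in their classification contributions?

    ``table`` is tidy with columns ``subject``, ``band``, ``contribution``
    (one MKL contribution per subject and band).  Runs a repeated-measures
    ANOVA over bands, then two-tailed paired t tests of every band against
    every other, FDR-corrected (Benjamini-Hochberg) at ``alpha``.
    """
    from itertools import combinations

    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multitest import multipletests

    required = {"subject", "band", "contribution"}
    if not required.issubset(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    aov = AnovaRM(table, depvar="contribution", subject="subject",
                  within=["band"]).fit()
    row = aov.anova_table.iloc[0]
    wide = table.pivot(index="subject", columns="band",
                       values="contribution")
    pairs, raw_p, t_stats = [], [], []
    for a, b in combinations(wide.columns, 2):
        t, p = sps.ttest_rel(wide[a], wide[b])
        pairs.append((a, b))
        raw_p.append(float(p))
        t_stats.append(float(t))
    reject, p_fdr, _, _ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
    return {
        "anova": {"F": float(row["F Value"]),
                  "df": (float(row["Num DF"]), float(row["Den DF"])),
                  "p": float(row["Pr > F"])},
        "pairwise": [
            {"bands": pair, "t": t, "p": p, "p_fdr": float(pf),
             "significant": bool(r)}
            for pair, t, p, pf, r in zip(pairs, t_stats, raw_p, p_fdr,
                                         reject)],
    }
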