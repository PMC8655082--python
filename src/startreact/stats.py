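"""Proportion and reaction-time inference: arcsine-root transform,
two-way repeated-measures ANOVA with partial eta squared, Tukey post-hocs,
paired t with Cohen's d, and a linear mixed model for premotor RT.

The repeated-measures decomposition tests each within-subject effect
against its own subject-by-effect interaction error term.  The mixed model
is fitted by maximum likelihood (statsmodels MixedLM) with a subject
random intercept and, optionally, an uncorrelated random slope for SCM
presence; singular slope fits are automatically refitted without the
slope.  Wald tests with residual degrees of freedom are reported for the
fixed effects (no Satterthwaite adjustment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as spstats
from scipy.stats import studentized_range
import statsmodels.api as sm


def arcsine_sqrt(p):
    """Variance-stabilising transform for proportions: asin(sqrt(p))."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass
class AnovaTable:
    table: pd.DataFrame  # rows: A, B, A:B
    factors: tuple[str, str]
    grand_mean: float
    ss_total: float
    cell_means: pd.DataFrame = field(repr=False, default=None)
    ms_error: dict = field(default_factory=dict)
    n_subjects: int = 0


def rm_anova2(
    data: pd.DataFrame,
    dv: str = "value",
    within: tuple[str, str] = ("a", "b"),
    subject: str = "subject",
) -> AnovaTable:
    """Two-way fully-within-subject ANOVA on a complete balanced table.

    ``data`` is long-format with one cell mean per subject x A x B.  Each
    effect is tested against its subject-interaction error term; partial
    eta squared is SS_effect / (SS_effect + SS_error).  Missing cells raise.
    """
    fa, fb = within
    piv = data.pivot_table(index=subject, columns=[fa, fb], values=dv, aggfunc="mean")
    if piv.isna().any().any():
        raise ValueError("missing cells: repeated-measures ANOVA needs a complete table")
    a_levels = piv.columns.get_level_values(0).unique()
    b_levels = piv.columns.get_level_values(1).unique()
    a, b, n = len(a_levels), len(b_levels), len(piv)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if piv.shape[1] != a * b:
        raise ValueError("unbalanced design")
    y = piv.to_numpy().reshape(n, a, b)  # subject x A x B

    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)  # subject x A
    m_bs = y.mean(axis=1)  # subject x B

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_subj = a * b * np.sum((m_s - gm) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + gm) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + gm) ** 2)
    ss_total = np.sum((y - gm) ** 2)
    ss_abs = ss_total - (ss_a + ss_b + ss_ab + ss_subj + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    rows = []
    ms_error = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
        (fa, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (fb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{fa}:{fb}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(spstats.f.sf(f, df_eff, df_err)) if ms_err > 0 else 1.0
        pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        ms_error[name] = (ms_err, df_err)
        rows.append(
            dict(
                effect=name,
                ss_effect=ss_eff,
                df_effect=df_eff,
                ss_error=ss_err,
                df_error=df_err,
                F=f,
                p=p,
                partial_eta_sq=pes,
            )
        )
    cell_means = pd.DataFrame(m_ab, index=a_levels, columns=b_levels)
    return AnovaTable(
        pd.DataFrame(rows), within, float(gm), float(ss_total), cell_means, ms_error, n
    )


def posthoc_pairwise(
    data: pd.DataFrame,
    factor: str,
    dv: str = "value",
    within: tuple[str, str] = ("a", "b"),
    subject: str = "subject",
) -> pd.DataFrame:
    """Tukey-HSD comparisons of one factor's marginal means, using that
    effect's within-subject error term from the two-way decomposition."""
    anova = rm_anova2(data, dv=dv, within=within, subject=subject)
    fa, fb = within
    if factor not in within:
        raise ValueError(f"factor {factor!r} not among {within}")
    other = fb if factor == fa else fa
    means = data.groupby(factor)[dv].mean()
    levels = list(means.index)
    if len(levels) < 2:
        raise ValueError("need at least 2 levels")
    ms_err, df_err = anova.ms_error[factor]
    n_per_mean = anova.n_subjects * data[other].nunique()
    se = np.sqrt(ms_err / n_per_mean)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            diff = means[levels[i]] - means[levels[j]]
            q = abs(diff) / se if se > 0 else 0.0
            p = float(studentized_range.sf(q, len(levels), df_err)) if se > 0 else 1.0
            rows.append(
                dict(
                    level_1=levels[i],
                    level_2=levels[j],
                    mean_diff=float(diff),
                    se=float(se),
                    q=float(q),
                    p_tukey=min(p, 1.0),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired t


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    cohen_d: float
    mean_diff: float
    n: int


def cohen_d_from_t(t: float, n: int) -> float:
    """Paired-design identity d = t / sqrt(n)."""
    return t / np.sqrt(n)


def paired_t(x, y) -> TTestResult:
    """Paired-samples t with Cohen's d = mean(diff)/SD(diff) (sample SD)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical samples: degenerate but well-defined
            return TTestResult(0.0, n - 1, 1.0, 0.0, 0.0, n)
        raise ValueError("zero difference variance: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * float(spstats.t.sf(abs(t), n - 1))
    return TTestResult(float(t), n - 1, p, float(d.mean() / sd), float(d.mean()), n)


# ---------------------------------------------------------------------------
# linear mixed model for premotor RT


@dataclass
class LmmResult:
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    vc: dict
    llf: float
    aic: float
    converged: bool
    slope_dropped: bool
    wald: pd.DataFrame
    formula: str
    design_info: object = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    resid_df: int = 0

    def emmeans(self, factor: str, level: float = 0.95) -> pd.DataFrame:
        return emmeans_lmm(self, factor, level)


def _wald_terms(params, cov, design_info, resid_df) -> pd.DataFrame:
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(len(params))[sl]
        beta = params[idx]
        v = cov[np.ix_(idx, idx)]
        try:
            stat = float(beta @ np.linalg.solve(v, beta))
        except np.linalg.LinAlgError:
            stat = np.nan
        q = len(idx)
        f = stat / q
        p = float(spstats.f.sf(f, q, resid_df))
        rows.append(dict(effect=term, F=f, df_num=q, df_den=resid_df, p=p))
    return pd.DataFrame(rows)


def fit_lmm(
    data: pd.DataFrame,
    formula: str = "adjusted_rt_ms ~ C(scm_status) * C(intensity_db) * C(offset_ms)",
    subject: str = "participant_id",
    scm_slope: bool = True,
    scm_column: str = "scm_status",
    reml: bool = False,
    re_var_fixed: float | None = None,
) -> LmmResult:
    """Linear mixed model with subject random intercept (ML by default).

    ``scm_slope`` adds a random slope for SCM presence, uncorrelated with
    the intercept (diagonal covariance).  If the slope fit is singular or
    fails to converge, the model is refitted intercept-only and flagged.
    ``re_var_fixed=0`` pins the intercept variance at zero, in which case
    the ML solution reduces analytically to ordinary least squares (solved
    directly, not delegated).
    """
    data = data.copy()
    if re_var_fixed is not None:
        if re_var_fixed != 0:
            raise NotImplementedError("only re_var_fixed=0 is supported")
        return _fit_lmm_zero_variance(data, formula, subject)
    vc = None
    if scm_slope and scm_column in data:
        data["_scm_num"] = (data[scm_column] == "SCM+").astype(float)
        vc = {"scm_slope": "0 + _scm_num"}

    def _fit(vc_formula):
        model = sm.MixedLM.from_formula(
            formula, data, groups=data[subject], re_formula="1", vc_formula=vc_formula
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=reml, maxiter=200)
        return model, res

    slope_dropped = False
    model, res = _fit(vc)
    if vc is not None:
        singular = (not res.converged) or np.any(
            np.asarray(res.vcomp) < 1e-8 * max(res.scale, 1e-12)
        )
        if singular:
            slope_dropped = True
            model, res = _fit(None)

    k_fe = model.exog.shape[1]
    params = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    names = model.exog_names
    design_info = model.data.design_info
    resid_df = int(data.shape[0] - k_fe)
    vc_out = {"subject_intercept_var": float(np.asarray(res.cov_re)[0, 0])}
    if vc is not None and not slope_dropped:
        vc_out["scm_slope_var"] = float(res.vcomp[0])
    vc_out["residual_var"] = float(res.scale)
    return LmmResult(
        params=pd.Series(params, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        vc=vc_out,
        llf=float(res.llf),
        aic=float(res.aic) if res.aic is not None else np.nan,
        converged=bool(res.converged),
        slope_dropped=slope_dropped,
        wald=_wald_terms(params, cov, design_info, resid_df),
        formula=formula,
        design_info=design_info,
        data=data,
        resid_df=resid_df,
    )


def _fit_lmm_zero_variance(data, formula, subject) -> LmmResult:
    """ML fit with the random-intercept variance pinned at 0: the marginal
    covariance is spherical, so beta solves the least-squares normal
    equations and the likelihood is the iid Gaussian one."""
    y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
    y = np.asarray(y_dm).ravel()
    X = np.asarray(X_dm)
    names = list(X_dm.columns)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, k = X.shape
    sigma2 = float(resid @ resid) / n  # ML variance
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    cov = sigma2 * n / (n - k) * np.linalg.inv(X.T @ X)
    resid_df = n - k
    return LmmResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        vc={"subject_intercept_var": 0.0, "residual_var": sigma2},
        llf=llf,
        aic=2 * (k + 1) - 2 * llf,
        converged=True,
        slope_dropped=False,
        wald=_wald_terms(beta, cov, X_dm.design_info, resid_df),
        formula=formula,
        design_info=X_dm.design_info,
        data=data,
        resid_df=resid_df,
    )


def emmeans_lmm(fit: LmmResult, factor: str, level: float = 0.95) -> pd.DataFrame:
    """Estimated marginal means of one factor: average the fixed-effect
    linear predictor over a balanced grid of the other factors; asymptotic
    normal CIs."""
    di = fit.design_info
    factors = [f for f in di.factor_infos]
    cat_cols = []
    for finfo in di.factor_infos.values():
        name = finfo.factor.name()
        # strip patsy C(...) wrapper to the underlying column
        col = name
        if col.startswith("C(") and col.endswith(")"):
            col = col[2:-1].split(",")[0].strip()
        cat_cols.append(col)
    cat_cols = list(dict.fromkeys(cat_cols))
    if factor not in cat_cols:
        raise ValueError(f"{factor!r} is not a model factor ({cat_cols})")
    grids = {c: sorted(fit.data[c].dropna().unique()) for c in cat_cols}
    z = spstats.norm.ppf(0.5 + level / 2)
    rows = []
    for lev in grids[factor]:
        combos = [{factor: lev}]
        for c in cat_cols:
            if c == factor:
                continue
            combos = [dict(d, **{c: v}) for d in combos for v in grids[c]]
        grid_df = pd.DataFrame(combos)
        (X,) = patsy.build_design_matrices([di], grid_df)
        xbar = np.asarray(X).mean(axis=0)
        est = float(xbar @ fit.params.to_numpy())
        se = float(np.sqrt(xbar @ fit.cov_params.to_numpy() @ xbar))
        rows.append(
            dict(
                level=lev,
                emmean=est,
                se=se,
                ci_low=est - z * se,
                ci_high=est + z * se,
            )
        )
    return pd.DataFrame(rows)
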