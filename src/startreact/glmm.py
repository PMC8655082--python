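"""Binomial mixed logistic regression for response triggering.

A repeated-measures logistic regression: the log odds that an auditory
trial triggers the prepared response is modelled from presentation time,
stimulus intensity, SCM presence and premotor RT, with a Gaussian random
intercept per participant.  The marginal likelihood integrates the random
intercept out by adaptive Gauss-Hermite quadrature (the integrand is
re-centred at its per-subject mode and scaled by its curvature on every
evaluation; one node reduces to the Laplace approximation).  Candidate
models are ranked by AICc, the small-sample-corrected Akaike criterion.

Reference coding throughout: 80 dB, SCM-, early (-1000 ms).  RT enters in
milliseconds, uncentred, so intercepts read as the log odds at RT = 0 for
the reference cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special
from scipy import stats as spstats
from scipy.stats import studentized_range
import statsmodels.api as sm

_REFERENCES = {
    "presentation_time": "early",
    "intensity_db": 80,
    "scm_status": "SCM-",
}


class SeparationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one candidate model.

    ``terms`` use column names, ':' for interactions ('a*b' expands to main
    effects plus interaction via patsy); the random part is always a
    subject intercept.
    """

    name: str
    terms: tuple[str, ...] = ()
    outcome: str = "triggered"
    subject: str = "participant_id"

    def formula(self, data: pd.DataFrame) -> str:
        def wrap(tok: str) -> str:
            tok = tok.strip()
            if tok in _REFERENCES and tok in data.columns:
                ref = _REFERENCES[tok]
                values = set(data[tok].dropna())
                if ref not in values:  # e.g. no 80 dB cell in the 114/120 design
                    ref = sorted(values)[0]
                ref_repr = repr(ref) if isinstance(ref, str) else ref
                return f"C({tok}, Treatment({ref_repr}))"
            return tok

        parts = []
        for term in self.terms:
            for op in ("*", ":"):
                if op in term:
                    parts.append(op.join(wrap(t) for t in term.split(op)))
                    break
            else:
                parts.append(wrap(term))
        rhs = " + ".join(parts) if parts else "1"
        return f"{self.outcome} ~ {rhs}"


def triggering_data(classified: pd.DataFrame) -> pd.DataFrame:
    """Kept auditory trials in modelling form: binary ``triggered`` outcome,
    ``presentation_time`` as early/late labels, RT in ms."""
    d = classified[
        classified["keep"] & (classified["stimulus_kind"] == "auditory")
    ].copy()
    d["triggered"] = (d["response_class"] == "triggered").astype(int)
    d["presentation_time"] = np.where(d["offset_ms"] == -1000, "early", "late")
    d["intensity_db"] = d["intensity_db"].astype(int)
    return d[
        [
            "participant_id",
            "triggered",
            "presentation_time",
            "intensity_db",
            "scm_status",
            "adjusted_rt_ms",
        ]
    ]


def candidate_ladder(
    include_time: bool = True, include_intensity: bool = True
) -> list[ModelSpec]:
    """The candidate set ranked in the analysis: a null model, each single
    predictor, each independent-by-dependent interaction pair, and the full
    model (SCM x RT interacting, intensity and time additive)."""
    specs = [ModelSpec("null", ())]
    singles = []
    if include_time:
        singles.append("presentation_time")
    if include_intensity:
        singles.append("intensity_db")
    singles += ["scm_status", "adjusted_rt_ms"]
    specs += [ModelSpec(t, (t,)) for t in singles]
    for iv in [t for t in ("presentation_time", "intensity_db") if t in singles]:
        for dv in ("scm_status", "adjusted_rt_ms"):
            specs.append(ModelSpec(f"{iv}*{dv}", (f"{iv}*{dv}",)))
    full = ["adjusted_rt_ms*scm_status"]
    if include_intensity:
        full.append("intensity_db")
    if include_time:
        full.append("presentation_time")
    specs.append(ModelSpec("full", tuple(full)))
    return specs


@dataclass
class GlmmFit:
    spec: ModelSpec
    params: pd.Series  # fixed effects, log odds
    se: pd.Series
    z: pd.Series
    pvalues: pd.Series
    re_sd: float  # random-intercept SD
    llf: float
    aic: float
    aicc: float
    n_obs: int
    k_params: int  # fixed coefficients + 1 variance parameter
    n_subjects: int
    converged: bool
    n_nodes: int
    cov_params: pd.DataFrame = field(repr=False, default=None)
    design_info: object = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def re_var(self) -> float:
        return self.re_sd**2


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Sort order + group boundary starts for reduceat-based sums."""
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    starts = np.r_[0, np.nonzero(np.diff(sorted_groups))[0] + 1]
    return order, starts, len(starts)


def _marginal_loglik(
    beta: np.ndarray,
    log_sd: float,
    y: np.ndarray,
    X: np.ndarray,
    starts: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    weights: np.ndarray,
    newton_iter: int = 25,
) -> float:
    """Adaptive Gauss-Hermite marginal log likelihood.

    Data must be sorted by group.  For each subject the integrand
    exp(g(u)), g(u) = Bernoulli log lik + log N(u; 0, sd^2), is maximised
    by Newton steps (vectorised over subjects), then integrated on nodes
    centred at the mode and scaled by the curvature there.
    """
    sd = np.exp(log_sd)
    eta0 = X @ beta
    u = np.zeros(n_groups)
    grp = np.repeat(np.arange(n_groups), np.diff(np.r_[starts, y.size]))
    for _ in range(newton_iter):
        eta = eta0 + u[grp]
        p = special.expit(eta)
        grad = np.add.reduceat(y - p, starts) - u / sd**2
        hess = -np.add.reduceat(p * (1 - p), starts) - 1.0 / sd**2
        step = grad / hess
        u_new = u - step
        if np.max(np.abs(step)) < 1e-10:
            u = u_new
            break
        u = u_new
    tau = 1.0 / np.sqrt(-hess)  # curvature scale at the mode

    # g at transformed nodes u_jk = u_j + sqrt(2) tau_j z_k
    U = u[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    eta = eta0[:, None] + U[grp, :]
    # stable Bernoulli log lik: y*eta - log(1 + exp(eta))
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    g = np.add.reduceat(ll_obs, starts, axis=0)
    g += -0.5 * np.log(2 * np.pi) - log_sd - 0.5 * (U / sd) ** 2
    log_int = special.logsumexp(
        np.log(weights)[None, :] + nodes[None, :] ** 2 + g, axis=1
    )
    return float(np.sum(log_int + 0.5 * np.log(2.0) + np.log(tau)))


def _num_hessian(f, x, h=1e-4):
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    quadrature_nodes: int = 10,
    compute_se: bool = True,
    max_restarts: int = 3,
    re_sd_fixed: float | None = None,
) -> GlmmFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Starts the fixed effects at the plain-logistic (IRLS) solution, then
    maximises the adaptive-quadrature marginal likelihood over
    (beta, log sd) with BFGS, restarting from jittered points on failure.
    Standard errors come from the observed information (central-difference
    Hessian).  Complete separation is detected from runaway coefficients
    and reported as a warning on the (still returned) fit.

    ``re_sd_fixed`` pins the random-intercept SD instead of estimating it
    (0 reduces the model to a plain logistic regression).
    """
    formula = spec.formula(data)
    y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
    y = np.asarray(y_dm).ravel()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = np.asarray(X_dm)
    names = list(X_dm.columns)
    groups_raw = np.asarray(pd.factorize(data[spec.subject])[0])
    if len(np.unique(groups_raw)) < 2:
        raise ValueError("need at least 2 subjects")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    order, starts, n_groups = _group_index(groups_raw)
    y_s, X_s = y[order], X[order]

    nodes, weights = np.polynomial.hermite.hermgauss(quadrature_nodes)

    fixed_log_sd = (
        None if re_sd_fixed is None else float(np.log(max(re_sd_fixed, 1e-8)))
    )

    def nll(theta):
        # sd below exp(-8) is numerically a plain logistic model; clamping
        # keeps the objective finite when the variance collapses
        if fixed_log_sd is None:
            beta_t, log_sd = theta[:-1], float(np.clip(theta[-1], -8.0, 5.0))
        else:
            beta_t, log_sd = theta, max(fixed_log_sd, -8.0)
        val = _marginal_loglik(
            beta_t, log_sd, y_s, X_s, starts, n_groups, nodes, weights
        )
        return -val if np.isfinite(val) else 1e12

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_beta = (
            sm.GLM(y, X, family=sm.families.Binomial())
            .fit(maxiter=50)
            .params
        )
    start_beta = np.clip(start_beta, -10, 10)
    x0 = start_beta if fixed_log_sd is not None else np.r_[start_beta, np.log(0.5)]

    best = None
    rng = np.random.default_rng(0)
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(nll, x0, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        x0 = x0 + rng.normal(0, 0.2, x0.size)
    theta = best.x
    if fixed_log_sd is not None:
        beta, log_sd = theta, max(fixed_log_sd, -8.0)
    else:
        beta, log_sd = theta[:-1], float(np.clip(theta[-1], -8.0, 5.0))
    llf = -best.fun
    k = len(beta) + (1 if fixed_log_sd is None else 0)
    n = y.size
    aic = 2 * k - 2 * llf

    if np.any(np.abs(beta) > 15):
        warnings.warn(
            "coefficients diverging: possible complete separation", SeparationWarning
        )

    se = np.full(len(beta), np.nan)
    cov_df = None
    if compute_se:
        H = _num_hessian(nll, theta)
        p = len(beta)
        cov_beta = None
        try:
            cov = np.linalg.inv(H)
            if np.all(np.isfinite(np.diag(cov)[:p])) and np.all(
                np.diag(cov)[:p] > 0
            ):
                cov_beta = cov[:p, :p]
        except np.linalg.LinAlgError:
            pass
        if cov_beta is None:
            # variance parameter at its boundary flattens the objective in
            # that direction; condition on it and invert the beta block
            try:
                cov_beta = np.linalg.inv(H[:p, :p])
            except np.linalg.LinAlgError:
                cov_beta = None
        if cov_beta is not None:
            d = np.diag(cov_beta).copy()
            d[d < 0] = np.nan
            se = np.sqrt(d)
            cov_df = pd.DataFrame(cov_beta, index=names, columns=names)
    z = beta / se
    pvals = 2 * spstats.norm.sf(np.abs(z))
    return GlmmFit(
        spec=spec,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        z=pd.Series(z, index=names),
        pvalues=pd.Series(pvals, index=names),
        re_sd=float(np.exp(log_sd)),
        llf=llf,
        aic=aic,
        aicc=aicc_value(aic, k, n),
        n_obs=n,
        k_params=k,
        n_subjects=n_groups,
        converged=bool(best.success),
        n_nodes=quadrature_nodes,
        cov_params=cov_df,
        design_info=X_dm.design_info,
        data=data,
    )


def aicc_value(aic: float, k: int, n: int) -> float:
    """AICc = AIC + 2k(k+1)/(n-k-1); n is the number of observations."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def aicc(fit: GlmmFit) -> float:
    if not fit.converged:
        raise ValueError("fit did not converge")
    return aicc_value(fit.aic, fit.k_params, fit.n_obs)


def rank_models(fits: list[GlmmFit]) -> pd.DataFrame:
    """Ascending-AICc model ranking (ties broken by fewer parameters).

    All fits must be on the same observation set.
    """
    if not fits:
        raise ValueError("no fits to rank")
    n0 = fits[0].n_obs
    if any(f.n_obs != n0 for f in fits):
        raise ValueError("fits are not on identical observation sets")
    rows = [
        dict(
            model=f.spec.name,
            k=f.k_params,
            llf=f.llf,
            aic=f.aic,
            aicc=f.aicc,
        )
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values(["aicc", "k"], kind="stable").reset_index(
        drop=True
    )
    out["delta_aicc"] = out["aicc"] - out["aicc"].iloc[0]
    return out


def odds_ratio(beta):
    """Log-odds coefficient to odds ratio: exp(beta)."""
    return np.exp(beta)


def predict_probability(
    fit: GlmmFit, covariates: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Population-level predicted probabilities (random intercept at 0)
    with logistic-transformed Wald CIs on the linear predictor."""
    if fit.cov_params is None:
        raise ValueError("fit lacks a covariance matrix (compute_se=False)")
    (X,) = patsy.build_design_matrices([fit.design_info], covariates)
    X = np.asarray(X)
    eta = X @ fit.params.to_numpy()
    var = np.einsum("ij,jk,ik->i", X, fit.cov_params.to_numpy(), X)
    se = np.sqrt(np.clip(var, 0, None))
    zq = spstats.norm.ppf(0.5 + level / 2)
    out = covariates.copy()
    out["prob"] = special.expit(eta)
    out["ci_low"] = special.expit(eta - zq * se)
    out["ci_high"] = special.expit(eta + zq * se)
    return out


def _emm_rows(fit: GlmmFit, factor: str) -> pd.DataFrame:
    """Linear-predictor EMMs per level of ``factor``: average design rows
    over a balanced grid of the other categorical predictors, continuous
    predictors held at their data mean."""
    data = fit.data
    joined = " ".join(fit.params.index)
    cat_factors = [
        c for c in ("presentation_time", "intensity_db", "scm_status")
        if f"C({c}" in joined
    ]
    if factor not in cat_factors:
        raise ValueError(f"{factor!r} is not a categorical predictor of this model")
    grids = {c: sorted(data[c].dropna().unique()) for c in cat_factors}
    cont = [
        c for c in ("adjusted_rt_ms",) if any(c in t for t in fit.params.index)
    ]
    rows = []
    for lev in grids[factor]:
        combos = [{factor: lev}]
        for c in cat_factors:
            if c != factor:
                combos = [dict(d, **{c: v}) for d in combos for v in grids[c]]
        grid = pd.DataFrame(combos)
        for c in cont:
            grid[c] = data[c].mean()
        (X,) = patsy.build_design_matrices([fit.design_info], grid)
        xbar = np.asarray(X).mean(axis=0)
        est = float(xbar @ fit.params.to_numpy())
        var = float(xbar @ fit.cov_params.to_numpy() @ xbar)
        rows.append((lev, est, var, xbar))
    return rows


def contrast_levels(fit: GlmmFit, factor: str) -> pd.DataFrame:
    """All-pairs contrasts of a categorical predictor on the log-odds
    scale, with single-step Tukey adjustment of the asymptotic z tests."""
    if fit.cov_params is None:
        raise ValueError("fit lacks a covariance matrix (compute_se=False)")
    emms = _emm_rows(fit, factor)
    if len(emms) < 2:
        raise ValueError("factor has fewer than 2 levels")
    kk = len(emms)
    V = fit.cov_params.to_numpy()
    rows = []
    for i in range(kk):
        for j in range(i + 1, kk):
            li, ei, _, xi = emms[i]
            lj, ej, _, xj = emms[j]
            dx = xi - xj
            se = float(np.sqrt(dx @ V @ dx))
            z = (ei - ej) / se if se > 0 else 0.0
            p = float(studentized_range.sf(abs(z) * np.sqrt(2.0), kk, np.inf))
            rows.append(
                dict(
                    level_1=li,
                    level_2=lj,
                    estimate=ei - ej,
                    se=se,
                    z=z,
                    p_tukey=min(p, 1.0),
                )
            )
    return pd.DataFrame(rows)
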