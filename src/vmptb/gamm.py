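"""Longitudinal mixed model of taxon abundance across gestation.

For one taxon the model of the j-th visit of subject i is

    L(abundance)_ij = b0 + b1*PO_i + b2*BMI_ij + b3*pH_ij + b4*I_ethnicity
                      + f_{PO_i}(ga_ij) + gamma_i + eps_ij

where L is the package-wide soft-threshold log10 transform, PO is the
pregnancy outcome (1 = PTB), I_ethnicity is 0 for African ancestry and 1
otherwise, f is a penalized cubic B-spline smoother of gestational age with
a separate curve per outcome level (the smoother-by-outcome interaction),
gamma_i ~ N(0, sigma_subject^2) is a random subject intercept and eps is
residual noise.  The spline's second-difference penalty is recast as a
variance component, so the smoothing parameter lambda = sigma^2/sigma_f^2
and both variances are estimated by restricted maximum likelihood.  Effect
contributions are tested with ANOVA-style Wald F tests; fitted trajectories
carry 98% pointwise confidence bands from the mixed-model posterior
covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .profiles import soft_threshold_log

logger = logging.getLogger(__name__)

BASIS_DIM = 10
CONFIDENCE = 0.98

FIXED_EFFECTS = ("intercept", "outcome_ptb", "bmi", "vaginal_ph",
                 "ethnicity_indicator", "ga", "ga_x_outcome")


def log_abundance_response(abundance):
    """Response transform: the shared soft-threshold log10 (range [0, 3])."""
    return soft_threshold_log(abundance)


def _bspline_basis(x: np.ndarray, lo: float, hi: float, k: int) -> np.ndarray:
    """Cubic B-spline basis with k functions on [lo, hi], evaluated at x."""
    degree = 3
    n_interior = k - degree - 1
    if n_interior < 0:
        raise ValueError("basis_dim must be at least 4 for cubic splines")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    design = np.empty((len(x), k))
    xc = np.clip(x, lo, hi)
    for j in range(k):
        coef = np.zeros(k)
        coef[j] = 1.0
        design[:, j] = BSpline(knots, coef, degree)(xc)
    return design


def _penalty_split(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-split of the second-difference penalty D2'D2.

    Returns ``(T_pen, T_null)``: coefficient-space transforms onto the
    penalized directions (scaled so the implied prior is iid) and the
    penalty null space (constant + linear, handled as fixed effects).
    """
    D2 = np.diff(np.eye(k), n=2, axis=0)
    S = D2.T @ D2
    vals, vecs = np.linalg.eigh(S)
    pos = vals > 1e-8 * vals.max()
    T_pen = vecs[:, pos] / np.sqrt(vals[pos])
    T_null = vecs[:, ~pos]
    return T_pen, T_null


@dataclass
class GammSpec:
    """Fitted model: fixed effects, smoothers, variances, effect tests."""

    beta: pd.Series  # named fixed-effect estimates
    beta_se: pd.Series
    smoother_coefs: dict  # outcome level -> spline random coefficients
    lambda_: float  # penalty parameter sigma^2 / sigma_f^2
    sigma_subject: float
    sigma_resid: float
    sigma_smooth: float
    basis_dim: int
    ga_range: tuple[float, float]
    effect_tests: pd.DataFrame = field(default_factory=pd.DataFrame)
    loglik_reml: float = np.nan
    n_obs: int = 0
    n_subjects: int = 0
    centering: dict = field(default_factory=dict)
    _predict_ctx: dict = field(default_factory=dict, repr=False)

    def fitted_curve(self, outcome: str, ga_grid: np.ndarray,
                     bmi: float | None = None, ph: float | None = None,
                     ethnicity: int = 0) -> pd.DataFrame:
        """Trajectory on the response scale with a 98% pointwise band.

        Covariates default to their training means; outcome is "PTB"/"TB".
        """
        ctx = self._predict_ctx
        ga_grid = np.asarray(ga_grid, dtype=float)
        bmi = self.centering["bmi"] if bmi is None else bmi
        ph = self.centering["vaginal_ph"] if ph is None else ph
        po = 1.0 if outcome == "PTB" else 0.0
        B = _bspline_basis(ga_grid, *self.ga_range, self.basis_dim)
        Z_pen = B @ ctx["T_pen"]
        m = len(ga_grid)
        Xg = np.column_stack([
            np.ones(m), np.full(m, po), np.full(m, bmi), np.full(m, ph),
            np.full(m, float(ethnicity)), ga_grid, ga_grid * po,
        ])
        # design row onto [beta, b_tb, b_ptb] (subject effect at 0)
        k_pen = Z_pen.shape[1]
        Zg = np.zeros((m, 2 * k_pen))
        if po:
            Zg[:, k_pen:] = Z_pen
        else:
            Zg[:, :k_pen] = Z_pen
        C = np.hstack([Xg, Zg])
        coef = np.concatenate([
            self.beta.to_numpy(),
            self.smoother_coefs["TB"], self.smoother_coefs["PTB"],
        ])
        mean = C @ coef
        cov = ctx["coef_cov"]  # posterior covariance of [beta, b_tb, b_ptb]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, cov, C), 0.0))
        zq = stats.norm.ppf(0.5 + CONFIDENCE / 2)
        return pd.DataFrame({
            "gestational_age": ga_grid, "fit": mean,
            "lo": mean - zq * se, "hi": mean + zq * se,
        })


def _design(records: pd.DataFrame, y: np.ndarray, basis_dim: int,
            with_outcome: bool, with_ethnicity: bool):
    ga = records["gestational_age"].to_numpy(dtype=float)
    lo, hi = float(ga.min()), float(ga.max())
    if hi - lo < 60:
        raise ValueError("gestational ages must span at least 60 days")
    po = (records["outcome"] == "PTB").to_numpy(dtype=float)
    cols = {"intercept": np.ones(len(ga))}
    if with_outcome:
        cols["outcome_ptb"] = po
    cols["bmi"] = records["bmi"].to_numpy(dtype=float)
    cols["vaginal_ph"] = records["vaginal_ph"].to_numpy(dtype=float)
    if with_ethnicity:
        cols["ethnicity_indicator"] = records["ethnicity_indicator"].to_numpy(dtype=float)
    cols["ga"] = ga
    if with_outcome:
        cols["ga_x_outcome"] = ga * po
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())

    B = _bspline_basis(ga, lo, hi, basis_dim)
    T_pen, _ = _penalty_split(basis_dim)
    Z_pen_full = B @ T_pen
    k_pen = Z_pen_full.shape[1]
    if with_outcome:
        Z_f = np.zeros((len(ga), 2 * k_pen))
        Z_f[po == 0, :k_pen] = Z_pen_full[po == 0]
        Z_f[po == 1, k_pen:] = Z_pen_full[po == 1]
    else:
        Z_f = Z_pen_full
    subjects = records["subject_id"].to_numpy()
    subj_levels, subj_idx = np.unique(subjects, return_inverse=True)
    Z_s = np.zeros((len(ga), len(subj_levels)))
    Z_s[np.arange(len(ga)), subj_idx] = 1.0
    return X, names, Z_f, Z_s, (lo, hi), T_pen, subj_levels, po


def fit_gamm(
    table,
    records: pd.DataFrame,
    taxon: str,
    basis_dim: int = BASIS_DIM,
    with_outcome: bool = True,
    with_ethnicity: bool = True,
    include_subject: bool = True,
    reml: bool = True,
) -> GammSpec:
    """Fit the penalized-spline mixed model for one taxon by REML.

    ``table`` is an AbundanceTable or a samples-x-taxa DataFrame of
    proportions; ``records`` the per-sample metadata aligned by sample_id.
    One smoother per outcome level shares a single smoothing variance.  With
    ``reml=False`` (and ``include_subject=False``) the model degenerates to
    ordinary least squares on the expanded basis, a cross-check path.
    """
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    rec = (records.set_index("sample_id").loc[frame.index]
           .rename_axis("sample_id").reset_index())
    y = log_abundance_response(frame[taxon].to_numpy(dtype=float))

    if with_outcome and rec.groupby("outcome")["subject_id"].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per outcome group")

    X, names, Z_f, Z_s, ga_range, T_pen, subj_levels, po = _design(
        rec, y, basis_dim, with_outcome, with_ethnicity)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased column: the first whose removal restores full rank
        for j, nm in enumerate(names):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"rank-deficient fixed-effect design: term {nm!r} is aliased")
        raise ValueError("rank-deficient fixed-effect design")

    n, p = X.shape
    k_f = Z_f.shape[1]
    k_s = Z_s.shape[1] if include_subject else 0
    Z = np.hstack([Z_f, Z_s]) if include_subject else Z_f

    if not reml:
        C = np.hstack([X, Z])
        coef, *_ = np.linalg.lstsq(C, y, rcond=None)
        resid = y - C @ coef
        sigma = float(np.sqrt(resid @ resid / max(n - np.linalg.matrix_rank(C), 1)))
        beta = pd.Series(coef[:p], index=names)
        b_f = coef[p:p + k_f]
        return _pack_spec(beta, pd.Series(np.nan, index=names), b_f, np.inf, 0.0,
                          sigma, 0.0, basis_dim, ga_range, T_pen, None,
                          with_outcome, rec, n, subj_levels, fitted_cov=None)

    def reml_crit(log_tau):
        tau_f, tau_s = np.exp(log_tau[0]), (np.exp(log_tau[1]) if include_subject else 0.0)
        M = np.eye(n) + tau_f * (Z_f @ Z_f.T)
        if include_subject:
            M += tau_s * (Z_s @ Z_s.T)
        cf = cho_factor(M, lower=True)
        logdetM = 2 * np.sum(np.log(np.diag(cf[0])))
        Minv_X = cho_solve(cf, X)
        Minv_y = cho_solve(cf, y)
        XtMX = X.T @ Minv_X
        beta = np.linalg.solve(XtMX, X.T @ Minv_y)
        r = y - X @ beta
        quad = float(r @ cho_solve(cf, r))
        sign, logdetXtMX = np.linalg.slogdet(XtMX)
        return (logdetM + logdetXtMX + (n - p) * np.log(max(quad, 1e-300)))

    x0 = np.array([0.0, 0.0]) if include_subject else np.array([0.0])
    res = minimize(reml_crit, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    if not res.success:
        raise RuntimeError(f"REML optimization did not converge: {res.message}")
    tau_f = float(np.exp(res.x[0]))
    tau_s = float(np.exp(res.x[1])) if include_subject else 0.0

    # final solve at the optimum, with coefficient covariances
    M = np.eye(n) + tau_f * (Z_f @ Z_f.T)
    if include_subject:
        M += tau_s * (Z_s @ Z_s.T)
    cf = cho_factor(M, lower=True)
    Minv_X = cho_solve(cf, X)
    XtMX = X.T @ Minv_X
    beta_hat = np.linalg.solve(XtMX, X.T @ cho_solve(cf, y))
    r = y - X @ beta_hat
    quad = float(r @ cho_solve(cf, r))
    sigma2 = quad / (n - p)
    sigma = float(np.sqrt(sigma2))
    sigma_f = float(np.sqrt(tau_f * sigma2))
    sigma_s = float(np.sqrt(tau_s * sigma2))
    lambda_ = 1.0 / tau_f if tau_f > 0 else np.inf

    D = np.concatenate([np.full(k_f, tau_f), np.full(k_s, tau_s)])
    b_hat = (D[:, None] * Z.T) @ cho_solve(cf, r)
    b_f = b_hat[:k_f]

    beta_cov = sigma2 * np.linalg.inv(XtMX)
    beta = pd.Series(beta_hat, index=names)
    beta_se = pd.Series(np.sqrt(np.diag(beta_cov)), index=names)

    # posterior covariance of [beta, b] from the mixed-model equations
    C = np.hstack([X, Z])
    Dinv = np.concatenate([np.full(k_f, 1.0 / tau_f if tau_f > 0 else np.inf),
                           np.full(k_s, 1.0 / tau_s if tau_s > 0 else np.inf)])
    A = C.T @ C + np.diag(np.concatenate([np.zeros(p), Dinv]))
    coef_cov_full = sigma2 * np.linalg.pinv(A)
    keep = list(range(p + k_f))  # beta and smoother coefficients
    coef_cov = coef_cov_full[np.ix_(keep, keep)]

    tests = _effect_tests(beta, beta_cov, names, b_f, coef_cov_full, p, k_f,
                          with_outcome, n)

    return _pack_spec(beta, beta_se, b_f, lambda_, sigma_s, sigma, sigma_f,
                      basis_dim, ga_range, T_pen, tests, with_outcome, rec, n,
                      subj_levels, fitted_cov=coef_cov, loglik=-0.5 * res.fun)


def _effect_tests(beta, beta_cov, names, b_f, coef_cov_full, p, k_f,
                  with_outcome, n):
    rows = []
    for j, nm in enumerate(names):
        if nm == "intercept":
            continue
        se = np.sqrt(beta_cov[j, j])
        F = (beta[nm] / se) ** 2
        rows.append(dict(term=nm, statistic=float(F), df=1,
                         p_value=float(stats.f.sf(F, 1, n - p))))
    # Wald test per smoother: b' Cov(b)^-1 b ~ chi2 (approximate)
    half = k_f // 2 if with_outcome else k_f
    blocks = {"smoother_tb": (0, half), "smoother_ptb": (half, k_f)} if with_outcome \
        else {"smoother": (0, k_f)}
    for nm, (a, b_end) in blocks.items():
        idx = list(range(p + a, p + b_end))
        cov_b = coef_cov_full[np.ix_(idx, idx)]
        bb = b_f[a:b_end]
        try:
            stat = float(bb @ np.linalg.solve(cov_b, bb))
            dfb = b_end - a
            rows.append(dict(term=nm, statistic=stat, df=dfb,
                             p_value=float(stats.chi2.sf(stat, dfb))))
        except np.linalg.LinAlgError:
            rows.append(dict(term=nm, statistic=np.nan, df=b_end - a, p_value=np.nan))
    return pd.DataFrame(rows)


def _pack_spec(beta, beta_se, b_f, lambda_, sigma_s, sigma, sigma_f, basis_dim,
               ga_range, T_pen, tests, with_outcome, rec, n, subj_levels,
               fitted_cov=None, loglik=np.nan):
    k = len(b_f) // 2 if with_outcome else len(b_f)
    coefs = ({"TB": b_f[:k], "PTB": b_f[k:]} if with_outcome
             else {"ALL": b_f})
    return GammSpec(
        beta=beta, beta_se=beta_se, smoother_coefs=coefs, lambda_=lambda_,
        sigma_subject=sigma_s, sigma_resid=sigma, sigma_smooth=sigma_f,
        basis_dim=basis_dim, ga_range=ga_range,
        effect_tests=tests if tests is not None else pd.DataFrame(),
        loglik_reml=loglik, n_obs=n, n_subjects=len(subj_levels),
        centering={"bmi": float(rec["bmi"].mean()),
                   "vaginal_ph": float(rec["vaginal_ph"].mean())},
        _predict_ctx={"T_pen": T_pen, "coef_cov": fitted_cov},
    )


def stratified_fits(
    table,
    records: pd.DataFrame,
    taxon: str,
    basis_dim: int = BASIS_DIM,
    min_subjects: int = 5,
) -> dict[tuple[str, str], GammSpec]:
    """Independent fits per ancestry-by-outcome stratum (AA/EA x PTB/TB).

    The ethnicity and outcome terms drop inside each stratum; strata with
    fewer than ``min_subjects`` subjects are fitted but flagged low-power
    (``spec.centering['low_power']``); empty strata are skipped with a
    warning.
    """
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    rec = (records.set_index("sample_id").loc[frame.index]
           .rename_axis("sample_id").reset_index())
    out: dict[tuple[str, str], GammSpec] = {}
    for eth, eth_name in ((0, "AA"), (1, "EA")):
        for outcome in ("PTB", "TB"):
            sel = rec[(rec["ethnicity_indicator"] == eth) & (rec["outcome"] == outcome)]
            if sel.empty:
                logger.warning("stratum %s %s is empty; skipped", eth_name, outcome)
                continue
            sub_frame = frame.loc[sel["sample_id"]]
            spec = fit_gamm(sub_frame, sel, taxon, basis_dim=basis_dim,
                            with_outcome=False, with_ethnicity=False)
            n_sub = sel["subject_id"].nunique()
            if n_sub < min_subjects:
                logger.warning("stratum %s %s has %d subjects: low power",
                               eth_name, outcome, n_sub)
                spec.centering["low_power"] = True
            out[(eth_name, outcome)] = spec
    return out
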