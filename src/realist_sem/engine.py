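"""Maximum-likelihood covariance-structure estimation.

Minimises the normal-theory discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

by quasi-Newton search (L-BFGS-B with an analytic gradient) followed by a
Newton polish to drive the gradient below tolerance.  Standard errors come
in two flavours: naive (inverse observed information under normality) and
cluster-robust (sandwich A^-1 B A^-1 with cluster-summed casewise scores),
the latter matching the usual "MLR"-style robust standard errors for data
with dependent observations inside practices.

Standardization multiplies each coefficient by sd(predictor)/sd(outcome)
using model-implied variances, so a standardized path is the change in the
outcome per standard-deviation unit of the predictor; delta-method standard
errors are propagated through the standardization map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize
from scipy.stats import norm

from .dataset import ClusteredDataset, sample_covariance
from .model_spec import SemModel

__all__ = [
    "FitOptions",
    "FitResult",
    "model_implied_covariance",
    "fit_ml",
    "fit_ml_cov",
    "naive_vcov",
    "cluster_robust_vcov",
    "casewise_scores",
    "standardize",
    "StandardizedSolution",
]


@dataclass
class FitOptions:
    max_iter: int = 500          # Fisher-scoring iteration cap
    lbfgs_iter: int = 200        # quasi-Newton warm-start iteration cap
    gtol: float = 1e-6           # convergence: max |gradient of F_ML|
    cluster_correction: bool = False  # multiply sandwich meat by G/(G-1)


@dataclass
class FitResult:
    model: SemModel
    theta_hat: np.ndarray
    f_min: float
    sample_cov: np.ndarray
    n: int
    converged: bool
    gradient_norm: float
    n_iter: int
    param_names: list[str]
    vcov_naive: np.ndarray | None = None
    vcov_robust: np.ndarray | None = None
    n_dropped: int = 0
    n_clusters: int | None = None
    warnings: list[str] = field(default_factory=list)
    _hessian: np.ndarray | None = None

    @property
    def naive_se(self) -> np.ndarray:
        if self.vcov_naive is None:
            raise ValueError("naive vcov not computed")
        return np.sqrt(np.clip(np.diag(self.vcov_naive), 0.0, None))

    @property
    def robust_se(self) -> np.ndarray:
        if self.vcov_robust is None:
            raise ValueError("robust vcov not computed")
        return np.sqrt(np.clip(np.diag(self.vcov_robust), 0.0, None))

    @property
    def preferred_vcov(self) -> np.ndarray:
        return self.vcov_robust if self.vcov_robust is not None else self.vcov_naive

    def param_table(self) -> pd.DataFrame:
        d = {"param": self.param_names, "est": self.theta_hat}
        if self.vcov_naive is not None:
            d["naive_se"] = self.naive_se
        if self.vcov_robust is not None:
            d["robust_se"] = self.robust_se
            se = self.robust_se
        elif self.vcov_naive is not None:
            se = self.naive_se
        else:
            se = None
        df = pd.DataFrame(d)
        if se is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                z = self.theta_hat / se
            df["z"] = z
            df["pvalue"] = 2 * norm.sf(np.abs(z))
        return df


# ---------------------------------------------------------------------------
# model-implied covariance and the ML discrepancy
# ---------------------------------------------------------------------------

def model_implied_covariance(theta: np.ndarray, model: SemModel) -> np.ndarray:
    """Sigma(theta) = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta."""
    lam, b, psi, th = model.matrices(theta)
    m = b.shape[0]
    imb = np.eye(m) - b
    try:
        m_inv = sla.solve(imb, np.eye(m))
    except sla.LinAlgError:
        raise ValueError("structural matrix not invertible")
    v = m_inv @ psi @ m_inv.T
    sigma = lam @ v @ lam.T + th
    return 0.5 * (sigma + sigma.T)


def _pieces(theta, model):
    """(lam, M=(I-B)^-1, V=MPsiM', Sigma) or None when (I-B) is singular."""
    lam, b, psi, th = model.matrices(theta)
    m = b.shape[0]
    imb = np.eye(m) - b
    try:
        m_inv = sla.solve(imb, np.eye(m))
    except sla.LinAlgError:
        return None
    v = m_inv @ psi @ m_inv.T
    sigma = lam @ v @ lam.T + th
    return lam, m_inv, v, 0.5 * (sigma + sigma.T)


_BIG = 1e12


def _f_and_grad(theta, model, s, logdet_s):
    """F_ML and its analytic gradient; large value when Sigma is not PD."""
    pieces = _pieces(theta, model)
    q = model.q
    if pieces is None:
        return _BIG, np.zeros(q)
    lam, m_inv, v, sigma = pieces
    try:
        cf = sla.cho_factor(sigma, check_finite=False)
    except sla.LinAlgError:
        return _BIG, np.zeros(q)
    p = sigma.shape[0]
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(cf[0])))
    sigma_inv = sla.cho_solve(cf, np.eye(p), check_finite=False)
    f = logdet_sigma + np.sum(sigma_inv * s) - logdet_s - p
    if not np.isfinite(f):
        return _BIG, np.zeros(q)

    # C = Sigma^-1 (Sigma - S) Sigma^-1 ; dF = tr(C dSigma)
    c = sigma_inv - sigma_inv @ s @ sigma_inv
    g_lam = 2.0 * c @ lam @ v
    lc = lam.T @ c @ lam                       # m x m
    g_b = 2.0 * m_inv.T @ lc @ v
    g_psi = m_inv.T @ lc @ m_inv
    grad = np.empty(q)
    for k, (tag, i, j) in enumerate(model.free_cells):
        if tag == "lam":
            grad[k] = g_lam[i, j]
        elif tag == "b":
            grad[k] = g_b[i, j]
        elif tag == "psi":
            grad[k] = g_psi[i, j] + g_psi[j, i] if i != j else g_psi[i, i]
        else:
            grad[k] = 2.0 * c[i, j] if i != j else c[i, i]
    return f, grad


def default_start(model: SemModel, s: np.ndarray) -> np.ndarray:
    """Documented start values: loadings 1, structural paths 0, residual
    variances half the observed variance, latent variances half the
    reference indicator's variance (full variance for promoted observed
    singletons, whose residual is fixed at zero).  Free covariances between
    two promoted observed singletons start at the corresponding sample
    covariance — their block of the model is saturated, so this is the
    natural moment start; all other covariances start at 0."""
    # variable backing each latent column: the row with a fixed loading of 1
    backing = {}
    for j in range(model.m):
        rows = np.where(model.lam_val[:, j] == 1.0)[0]
        if rows.size:
            backing[j] = rows[0]

    def is_degenerate(i):
        return model.latent_vars[i] in model.degenerate

    theta0 = np.empty(model.q)
    for k, (tag, i, j) in enumerate(model.free_cells):
        if tag == "lam":
            theta0[k] = 1.0
        elif tag == "b":
            theta0[k] = 0.0
        elif tag == "psi":
            if i != j:
                if is_degenerate(i) and is_degenerate(j):
                    theta0[k] = s[backing[i], backing[j]]
                else:
                    theta0[k] = 0.0
            else:
                r = backing.get(i)
                base = s[r, r] if r is not None else 1.0
                theta0[k] = base if is_degenerate(i) else 0.5 * base
        else:
            theta0[k] = 0.5 * s[i, i] if i == j else 0.0
    return theta0


def _hessian(theta, model, s, logdet_s, rel_step=1e-5):
    """Hessian of F_ML by central differences of the analytic gradient."""
    q = theta.size
    h = np.empty((q, q))
    for k in range(q):
        step = rel_step * max(1.0, abs(theta[k]))
        up = theta.copy(); up[k] += step
        dn = theta.copy(); dn[k] -= step
        _, gu = _f_and_grad(up, model, s, logdet_s)
        _, gd = _f_and_grad(dn, model, s, logdet_s)
        h[k] = (gu - gd) / (2.0 * step)
    return 0.5 * (h + h.T)


def _fit_theta(model, s, n, options):
    """Minimise F_ML; returns (theta, f, grad_norm, n_iter, converged)."""
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sample covariance matrix not positive definite")
    theta0 = default_start(model, s)

    res = minimize(
        _f_and_grad, theta0, args=(model, s, logdet_s), jac=True,
        method="L-BFGS-B",
        options={"maxiter": options.lbfgs_iter, "maxfun": 4 * options.lbfgs_iter,
                 "ftol": 1e-14, "gtol": 1e-8},
    )
    theta = res.x
    f, g = _f_and_grad(theta, model, s, logdet_s)
    n_iter = int(res.nit)

    def _try_step(theta, f, g, direction):
        t = 1.0
        for _ in range(40):
            f_new, g_new = _f_and_grad(theta + t * direction, model, s, logdet_s)
            if f_new <= f - 1e-14 or (
                    f_new <= f + 1e-15 and
                    np.max(np.abs(g_new)) < np.max(np.abs(g))):
                return theta + t * direction, f_new, g_new, True
            t *= 0.5
        return theta, f, g, False

    # Fisher-scoring polish: the expected information is cheap and positive
    # semi-definite, so eigenvalue-floored scoring steps descend even where
    # quasi-Newton crawls.  Every tenth step (and whenever scoring stalls)
    # uses the observed Hessian instead — its exact curvature is what makes
    # progress along the occasional quartic-flat ridge of a weakly
    # identified composite.
    def _direction(matrix):
        eigvals, eigvecs = np.linalg.eigh(matrix)
        floor = max(1e-8, 1e-8 * float(eigvals.max(initial=1.0)))
        return -eigvecs @ ((eigvecs.T @ g) / np.maximum(eigvals, floor))

    for it in range(options.max_iter):
        if np.max(np.abs(g)) < options.gtol:
            break
        use_observed = (it % 10 == 9)
        h = _hessian(theta, model, s, logdet_s) if use_observed \
            else expected_information(model, theta)
        theta, f, g, ok = _try_step(theta, f, g, _direction(h))
        n_iter += 1
        if not ok and not use_observed:
            h = _hessian(theta, model, s, logdet_s)
            theta, f, g, ok = _try_step(theta, f, g, _direction(h))
        if not ok:
            break

    grad_norm = float(np.max(np.abs(g)))
    converged = grad_norm < options.gtol and f < _BIG / 2
    return theta, float(f), grad_norm, n_iter, converged


def fit_ml_cov(model: SemModel, s: np.ndarray, n: int,
               options: FitOptions | None = None) -> FitResult:
    """Fit from a sample covariance matrix alone (no robust errors)."""
    options = options or FitOptions()
    s = np.asarray(s, dtype=float)
    if s.shape != (model.p, model.p):
        raise ValueError("sample covariance has wrong dimension for the model")
    theta, f, gnorm, n_iter, converged = _fit_theta(model, s, n, options)
    fit = FitResult(
        model=model, theta_hat=theta, f_min=f, sample_cov=s, n=n,
        converged=converged, gradient_norm=gnorm, n_iter=n_iter,
        param_names=model.param_names(),
    )
    if converged:
        try:
            fit.vcov_naive = naive_vcov(fit, model)
        except ValueError as exc:
            fit.warnings.append(str(exc))
    _flag_heywood(fit)
    return fit


def fit_ml(model: SemModel, data: ClusteredDataset,
           options: FitOptions | None = None) -> FitResult:
    """Fit the model to clustered data: listwise deletion, ML estimation,
    naive and cluster-robust standard errors."""
    options = options or FitOptions()
    bad = [v for v in model.observed_vars if v in data.categorical]
    if bad:
        raise ValueError(
            f"declared-categorical variable(s) {bad} cannot enter the model; "
            "recode ordered scales as numeric codes (ordinal-as-continuous)")
    complete, n_dropped = data.complete_cases(model.observed_vars)
    if complete.n < model.p + 1:
        raise ValueError("fewer complete rows than observed variables + 1")
    s = sample_covariance(complete, model.observed_vars)
    fit = fit_ml_cov(model, s, complete.n, options)
    fit.n_dropped = n_dropped
    fit.n_clusters = complete.n_clusters
    if fit.converged:
        try:
            fit.vcov_robust = cluster_robust_vcov(fit, model, complete,
                                                  options=options)
        except ValueError as exc:
            fit.warnings.append(str(exc))
    return fit


def _flag_heywood(fit: FitResult) -> None:
    lam, b, psi, th = fit.model.matrices(fit.theta_hat)
    if np.any(np.diag(th) < -1e-10) or np.any(np.diag(psi) < -1e-10):
        fit.warnings.append("Heywood case: negative residual variance estimate")


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def _hessian_at_fit(fit: FitResult, model: SemModel) -> np.ndarray:
    if fit._hessian is None:
        _, logdet_s = np.linalg.slogdet(fit.sample_cov)
        fit._hessian = _hessian(fit.theta_hat, model, fit.sample_cov, logdet_s)
    return fit._hessian


def naive_vcov(fit: FitResult, model: SemModel) -> np.ndarray:
    """Inverse observed information: (2/n) * H_F^-1, H_F the Hessian of F_ML."""
    if not fit.converged:
        raise ValueError("naive vcov requires a converged fit")
    h = _hessian_at_fit(fit, model)
    eigvals, eigvecs = np.linalg.eigh(h)
    tol = 1e-10 * max(1.0, float(eigvals.max(initial=1.0)))
    if eigvals.min() < tol:
        k = int(np.argmin(eigvals))
        worst = int(np.argmax(np.abs(eigvecs[:, k])))
        raise ValueError(
            f"parameter not locally identified: {fit.param_names[worst]!r} "
            "(singular information matrix)")
    v = (2.0 / fit.n) * np.linalg.inv(h)
    return 0.5 * (v + v.T)


def _score_vectors(model: SemModel, theta: np.ndarray):
    """Per-parameter rank-2 representation dSigma_k = c (u v' + v u')."""
    pieces = _pieces(theta, model)
    if pieces is None:
        raise ValueError("structural matrix not invertible")
    lam, m_inv, v, sigma = pieces
    lam_m = lam @ m_inv
    lam_v = lam @ v
    p = sigma.shape[0]
    eye = np.eye(p)
    out = []
    for tag, i, j in model.free_cells:
        if tag == "lam":
            out.append((eye[:, i], lam_v[:, j], 1.0))
        elif tag == "b":
            out.append((lam_m[:, i], lam_v[:, j], 1.0))
        elif tag == "psi":
            c = 1.0 if i != j else 0.5
            out.append((lam_m[:, i], lam_m[:, j], c))
        else:
            c = 1.0 if i != j else 0.5
            out.append((eye[:, i], eye[:, j], c))
    return out, sigma


def expected_information(model: SemModel, theta: np.ndarray) -> np.ndarray:
    """Expected (Fisher) information of F_ML per observation unit:

        H_kl = tr(Sigma^-1 dSigma_k Sigma^-1 dSigma_l)

    Positive semi-definite by construction (unlike the observed Hessian,
    whose misfit term can produce tiny or negative curvature along weakly
    identified directions); the score-test modification indices use it.
    """
    vectors, sigma = _score_vectors(model, theta)
    sigma_inv = np.linalg.inv(sigma)
    q = len(vectors)
    # stack u, v through Sigma^-1 once
    us = np.stack([u for u, _, _ in vectors])      # q x p
    vs = np.stack([v for _, v, _ in vectors])
    cs = np.array([c for _, _, c in vectors])
    usi = us @ sigma_inv
    uu = usi @ us.T                                # u_k' S^-1 u_l
    vv = (vs @ sigma_inv) @ vs.T                   # v_k' S^-1 v_l
    uv = usi @ vs.T                                # u_k' S^-1 v_l
    h = 2.0 * np.outer(cs, cs) * (uu * vv + uv * uv.T)
    return 0.5 * (h + h.T)


def casewise_scores(fit: FitResult, model: SemModel,
                    data: ClusteredDataset) -> np.ndarray:
    """n x q matrix of casewise log-likelihood score contributions.

    Row sums over cases equal the total-likelihood score -(n/2) dF/dtheta.
    """
    vectors, sigma = _score_vectors(model, fit.theta_hat)
    x = data.matrix(model.observed_vars)
    z = x - x.mean(axis=0)
    sigma_inv = np.linalg.inv(sigma)
    scores = np.empty((z.shape[0], model.q))
    for k, (u, v, c) in enumerate(vectors):
        zu = z @ (sigma_inv @ u)
        zv = z @ (sigma_inv @ v)
        scores[:, k] = c * (zu * zv - u @ sigma_inv @ v)
    return scores


def cluster_robust_vcov(fit: FitResult, model: SemModel,
                        data: ClusteredDataset,
                        options: FitOptions | None = None) -> np.ndarray:
    """Sandwich A^-1 B A^-1 with B the outer product of cluster-summed
    casewise scores and A the Hessian of the casewise log-likelihood sum.

    With every cluster of size one this is the heteroskedasticity-robust
    (HC0-type) estimator.  An optional G/(G-1) small-sample factor is applied
    when ``options.cluster_correction`` is set.
    """
    options = options or FitOptions()
    if not fit.converged:
        raise ValueError("robust vcov requires a converged fit")
    labels = data.cluster_labels()
    uniq, inverse = np.unique(labels, return_inverse=True)
    n_clusters = uniq.size
    if n_clusters < 2:
        raise ValueError("clustered variance undefined: single cluster")
    scores = casewise_scores(fit, model, data)
    cluster_scores = np.zeros((n_clusters, model.q))
    np.add.at(cluster_scores, inverse, scores)
    meat = cluster_scores.T @ cluster_scores
    if options.cluster_correction:
        meat *= n_clusters / (n_clusters - 1)
    h = _hessian_at_fit(fit, model)          # A = -(n/2) H_F
    # eigenvalue floor keeps the bread PSD when a weakly identified ridge
    # (e.g. composite weights with near-zero outgoing paths) drives a
    # Hessian eigenvalue to numerical zero
    eigvals, eigvecs = np.linalg.eigh(h)
    floor = 1e-12 * float(np.abs(eigvals).max(initial=1.0))
    inv = eigvecs @ np.diag(1.0 / np.maximum(eigvals, floor)) @ eigvecs.T
    bread = inv * (2.0 / fit.n)
    v = bread @ meat @ bread
    return 0.5 * (v + v.T)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizedSolution:
    table: pd.DataFrame          # one row per reported loading / path
    vcov_std: np.ndarray         # delta-method covariance of table["est_std"]
    latent_sd: pd.Series
    observed_sd: pd.Series

    def lookup(self, lhs: str, rhs: str, op: str = "~") -> int:
        t = self.table
        hit = t.index[(t["lhs"] == lhs) & (t["rhs"] == rhs) & (t["op"] == op)]
        if len(hit) != 1:
            raise KeyError(f"no unique standardized entry {lhs!r} {op} {rhs!r}")
        return int(hit[0])


def _report_items(model: SemModel):
    """All loadings and structural paths worth reporting (free or fixed)."""
    items = []
    for i in range(model.p):
        for j in range(model.m):
            if model.lam_free[i, j] or model.lam_val[i, j] != 0:
                items.append(("lam", i, j))
    for i in range(model.m):
        for j in range(model.m):
            if model.b_free[i, j] or model.b_val[i, j] != 0:
                items.append(("b", i, j))
    return items


def _std_vector(theta, model, items):
    lam, b, psi, th = model.matrices(theta)
    m = b.shape[0]
    m_inv = sla.solve(np.eye(m) - b, np.eye(m))
    v = m_inv @ psi @ m_inv.T
    sigma = lam @ v @ lam.T + th
    sd_lat = np.sqrt(np.diag(v))
    sd_obs = np.sqrt(np.diag(sigma))
    if np.any(sd_lat <= 0) or np.any(sd_obs <= 0):
        raise ValueError("zero model-implied variance; cannot standardize")
    out = np.empty(len(items))
    for k, (tag, i, j) in enumerate(items):
        if tag == "lam":
            out[k] = lam[i, j] * sd_lat[j] / sd_obs[i]
        else:
            out[k] = b[i, j] * sd_lat[j] / sd_lat[i]
    return out, sd_lat, sd_obs


def standardize(fit: FitResult, model: SemModel) -> StandardizedSolution:
    """Standardize by both latent and observed model-implied variances.

    Each coefficient is multiplied by sd(predictor)/sd(outcome); the
    delta-method covariance of the standardized estimates is propagated
    through a numerical Jacobian using the robust (or else naive) parameter
    covariance.
    """
    if not fit.converged:
        raise ValueError("standardization requires a converged fit")
    items = _report_items(model)
    est_std, sd_lat, sd_obs = _std_vector(fit.theta_hat, model, items)

    vcov = fit.preferred_vcov
    if vcov is None:
        raise ValueError("no parameter covariance available for delta method")
    jac = np.zeros((len(items), model.q))
    for k in range(model.q):
        step = 1e-6 * max(1.0, abs(fit.theta_hat[k]))
        up = fit.theta_hat.copy(); up[k] += step
        dn = fit.theta_hat.copy(); dn[k] -= step
        s_up, _, _ = _std_vector(up, model, items)
        s_dn, _, _ = _std_vector(dn, model, items)
        jac[:, k] = (s_up - s_dn) / (2.0 * step)
    vcov_std = jac @ vcov @ jac.T

    lam, b, _, _ = model.matrices(fit.theta_hat)
    rows = []
    for k, (tag, i, j) in enumerate(items):
        if tag == "lam":
            lhs, rhs, op = model.latent_vars[j], model.observed_vars[i], "=~"
            raw = lam[i, j]
        else:
            lhs, rhs, op = model.latent_vars[i], model.latent_vars[j], "~"
            raw = b[i, j]
        se = float(np.sqrt(max(vcov_std[k, k], 0.0)))
        est = est_std[k]
        z = est / se if se > 0 else np.nan
        rows.append({
            "lhs": lhs, "op": op, "rhs": rhs, "est": raw, "est_std": est,
            "se_std": se, "z": z,
            "pvalue": 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            "ci_low": est - 1.959963984540054 * se,
            "ci_high": est + 1.959963984540054 * se,
        })
    table = pd.DataFrame(rows)
    return StandardizedSolution(
        table=table, vcov_std=vcov_std,
        latent_sd=pd.Series(sd_lat, index=model.latent_vars),
        observed_sd=pd.Series(sd_obs, index=model.observed_vars),
    )
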