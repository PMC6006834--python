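"""Confirmatory factor analysis for single reflective concepts.

Fits one-factor measurement models through the ML engine, prunes indicators
that do not contribute significantly to the latent variable (backward, one
at a time, refitting after each removal), and computes univariate score-test
modification indices for fixed residual covariances — the only modification
type in scope.

Significance uses cluster-robust standard errors whenever a cluster column
is present, mirroring a practice-clustered analysis; mixed
categorical/continuous CFA is refused by the engine (ordinal Likert codes
must be treated as continuous).
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.stats import norm

from .dataset import ClusteredDataset
from .engine import (FitOptions, FitResult, _f_and_grad, expected_information,
                     fit_ml)
from .model_spec import ConceptBinding, SemModel

__all__ = ["MeasurementFit", "one_factor_model", "fit_cfa",
           "prune_indicators", "modification_indices"]

logger = logging.getLogger(__name__)


@dataclass
class MeasurementFit:
    binding: ConceptBinding
    fit: FitResult
    table: pd.DataFrame          # indicator, loading, se, z, pvalue, retained
    data: ClusteredDataset
    alpha_used: float | None = None

    @property
    def retained(self) -> dict[str, bool]:
        return dict(zip(self.table["indicator"], self.table["retained"]))


def one_factor_model(binding: ConceptBinding,
                     identification: str = "reference") -> SemModel:
    """A single reflective latent with its indicators.

    identification="reference" fixes the reference loading to 1 and frees
    the factor variance; "variance" fixes the factor variance to 1 and frees
    every loading (useful for closed-form cross-checks).
    """
    if binding.mode != "reflective":
        raise ValueError("CFA requires a reflective binding")
    obs = list(binding.indicators)
    p = len(obs)
    lam_val = np.zeros((p, 1)); lam_free = np.zeros((p, 1), dtype=bool)
    if identification == "reference":
        ref = obs.index(binding.reference_indicator)
        lam_val[ref, 0] = 1.0
        lam_free[[i for i in range(p) if i != ref], 0] = True
        psi_free = np.array([[True]])
        psi_val = np.zeros((1, 1))
    elif identification == "variance":
        lam_free[:, 0] = True
        psi_free = np.array([[False]])
        psi_val = np.ones((1, 1))
    else:
        raise ValueError("identification must be 'reference' or 'variance'")
    model = SemModel(
        observed_vars=obs, latent_vars=[binding.concept_name],
        lam_val=lam_val, lam_free=lam_free,
        b_val=np.zeros((1, 1)), b_free=np.zeros((1, 1), dtype=bool),
        psi_val=psi_val, psi_free=psi_free,
        theta_val=np.zeros((p, p)), theta_free=np.eye(p, dtype=bool),
        reference_indicator={binding.concept_name: binding.reference_indicator}
        if identification == "reference" else {},
    )
    model.validate()
    return model


def fit_cfa(binding: ConceptBinding, data: ClusteredDataset,
            options: FitOptions | None = None,
            allow_two_indicators: bool = False) -> MeasurementFit:
    """Fit a one-factor model; loadings with robust z and p-values.

    A standalone one-factor model needs >= 3 indicators to be identified;
    two-indicator bindings are only admissible inside a larger model
    (`allow_two_indicators` is used internally during pruning stops).
    """
    minimum = 2 if allow_two_indicators else 3
    if len(binding.indicators) < minimum:
        raise ValueError(
            f"standalone CFA requires >= {minimum} indicators "
            f"(got {len(binding.indicators)})")
    model = one_factor_model(binding)
    fit = fit_ml(model, data, options)
    if not fit.converged:
        fit.warnings.append("CFA did not converge; estimates are provisional")
    use_robust = fit.vcov_robust is not None
    se = fit.robust_se if use_robust else (
        fit.naive_se if fit.vcov_naive is not None else None)
    names = fit.param_names
    rows = []
    lam, _, _, _ = model.matrices(fit.theta_hat)
    ref = binding.reference_indicator
    for i, ind in enumerate(binding.indicators):
        if ind == ref:
            rows.append({"indicator": ind, "loading": 1.0, "se": np.nan,
                         "z": np.nan, "pvalue": np.nan, "reference": True,
                         "retained": True})
            continue
        pname = f"{binding.concept_name}=~{ind}"
        k = names.index(pname)
        est = fit.theta_hat[k]
        s = se[k] if se is not None else np.nan
        z = est / s if s and np.isfinite(s) and s > 0 else np.nan
        rows.append({"indicator": ind, "loading": est, "se": s, "z": z,
                     "pvalue": 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                     "reference": False, "retained": True})
    return MeasurementFit(binding=binding, fit=fit,
                          table=pd.DataFrame(rows), data=data)


def prune_indicators(mfit: MeasurementFit, alpha: float = 0.05) -> ConceptBinding:
    """Remove indicators that do not significantly contribute to the latent.

    Backward elimination: while any free loading has p >= alpha, drop the
    indicator with the largest p-value and refit.  The reference indicator
    is always retained; pruning stops (with a warning) once only two
    non-reference indicators plus the reference remain, since a smaller
    standalone one-factor model is no longer identified.  Boundary
    convention: p exactly equal to alpha is removed (retention requires
    p < alpha).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    binding = mfit.binding
    current = mfit
    while True:
        t = current.table
        candidates = t[~t["reference"] & (t["pvalue"] >= alpha)]
        if candidates.empty:
            break
        if len(current.binding.indicators) <= 3:
            _warnings.warn(
                f"pruning {binding.concept_name!r} stopped at the minimal "
                "identified binding with non-contributing indicators left",
                stacklevel=2)
            break
        worst = candidates.sort_values("pvalue", ascending=False).iloc[0]
        keep = tuple(i for i in current.binding.indicators
                     if i != worst["indicator"])
        new_binding = current.binding.with_indicators(keep)
        current = fit_cfa(new_binding, mfit.data)
    return current.binding


def modification_indices(fit: FitResult, model: SemModel,
                         data: ClusteredDataset,
                         candidates: list[tuple[str, str]]) -> list[tuple[str, float, float]]:
    """Univariate score-test modification indices for fixed Theta entries.

    For each candidate fixed residual covariance, MI is the 1-df score-test
    statistic for freeing it at the restricted optimum, with the expected
    parameter change (EPC).  Returns (parameter_name, MI, EPC) sorted by MI
    descending; candidates that are already free are skipped with a warning.
    """
    if not fit.converged:
        raise ValueError("modification indices require a converged fit")
    oi = {v: i for i, v in enumerate(model.observed_vars)}
    s = fit.sample_cov
    _, logdet_s = np.linalg.slogdet(s)
    out = []
    for u, v in candidates:
        if u not in oi or v not in oi:
            raise ValueError(f"candidate ({u!r}, {v!r}) names unknown indicators")
        i, j = sorted((oi[u], oi[v]), reverse=True)   # lower-triangle cell
        if model.theta_free[i, j]:
            _warnings.warn(f"candidate {u}~~{v} is already free; skipped",
                           stacklevel=2)
            continue
        aug = SemModel(
            observed_vars=model.observed_vars, latent_vars=model.latent_vars,
            lam_val=model.lam_val, lam_free=model.lam_free,
            b_val=model.b_val, b_free=model.b_free,
            psi_val=model.psi_val, psi_free=model.psi_free,
            theta_val=model.theta_val,
            theta_free=model.theta_free.copy(),
            degenerate=model.degenerate,
            reference_indicator=model.reference_indicator,
            cmo_paths=model.cmo_paths, exogenous=model.exogenous,
        )
        aug.theta_free[i, j] = aug.theta_free[j, i] = True
        # map the restricted estimate into the augmented parameter vector
        old = dict(zip(model.free_cells, fit.theta_hat))
        new_cells = aug.free_cells
        theta_aug = np.array([old.get(c, model.theta_val[c[1], c[2]]
                                      if c[0] == "theta" else 0.0)
                              for c in new_cells])
        k_new = new_cells.index(("theta", i, j))
        _, g = _f_and_grad(theta_aug, aug, s, logdet_s)
        # expected (Fisher) information: PSD, the standard basis for
        # score-test modification indices
        h = expected_information(aug, theta_aug)
        keep = [k for k in range(len(new_cells)) if k != k_new]
        h_oo = h[np.ix_(keep, keep)]
        h_on = h[keep, k_new]
        try:
            solve = sla.solve(h_oo, h_on, assume_a="sym")
        except sla.LinAlgError:
            logger.warning("singular information for candidate %s~~%s", u, v)
            continue
        h_part = h[k_new, k_new] - h_on @ solve
        if h_part <= 0:
            logger.warning("non-positive partial information for %s~~%s", u, v)
            continue
        mi = 0.5 * fit.n * g[k_new] ** 2 / h_part
        epc = -g[k_new] / h_part
        name = f"{model.observed_vars[i]}~~{model.observed_vars[j]}"
        out.append((name, float(mi), float(epc)))
    out.sort(key=lambda t: -t[1])
    return out
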