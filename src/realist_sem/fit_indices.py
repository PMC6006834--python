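"""Covariance-structure fit indices against an independence baseline.

Conventions: the chi-square statistic is T = (n-1) * F_ML and RMSEA's
denominator uses (n-1), a matched pair documented in the methods note.  The
plain (unscaled) ML statistic feeds the indices even when cluster-robust
standard errors are used for inference; scaled-test corrections are out of
scope and this caveat is carried in the index report.

Good-fit verdicts use the strict thresholds RMSEA < 0.06 and CFI/TLI > 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ClusteredDataset, sample_covariance
from .engine import FitResult
from .model_spec import SemModel, degrees_of_freedom

__all__ = ["FitIndices", "baseline_fit", "baseline_fit_cov", "compute_indices",
           "indices_for_fit", "RMSEA_GOOD", "CFI_GOOD", "TLI_GOOD"]

RMSEA_GOOD = 0.06
CFI_GOOD = 0.95
TLI_GOOD = 0.95


@dataclass
class FitIndices:
    T: float
    df: int
    T_baseline: float
    df_baseline: int
    n: int
    rmsea: float | None
    cfi: float | None
    tli: float | None
    verdicts: dict = field(default_factory=dict)
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "chi_square": self.T, "df": self.df,
            "chi_square_baseline": self.T_baseline,
            "df_baseline": self.df_baseline, "n": self.n,
            "rmsea": self.rmsea, "cfi": self.cfi, "tli": self.tli,
            "verdicts": dict(self.verdicts), "note": self.note,
        }


def baseline_fit_cov(s: np.ndarray, n: int) -> tuple[float, int]:
    """Independence-model statistic from a sample covariance matrix.

    The baseline frees every variance and fixes all covariances to zero, so
    its ML optimum is Sigma = diag(S) and F_baseline = -ln|R| with R the
    sample correlation matrix; T_baseline = (n-1) * F_baseline and
    df_baseline = p(p-1)/2.
    """
    s = np.asarray(s, dtype=float)
    p = s.shape[0]
    d = np.sqrt(np.diag(s))
    if np.any(d <= 0):
        raise ValueError("zero-variance variable in baseline model")
    r = s / np.outer(d, d)
    sign, logdet_r = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("sample covariance matrix not positive definite")
    f_baseline = -logdet_r
    return (n - 1) * f_baseline, p * (p - 1) // 2


def baseline_fit(data: ClusteredDataset, variables: list[str]) -> tuple[float, int]:
    """Independence baseline fitted to the data's complete cases."""
    complete, _ = data.complete_cases(variables)
    s = sample_covariance(complete, variables)
    return baseline_fit_cov(s, complete.n)


def compute_indices(T: float, df: int, T_baseline: float, df_baseline: int,
                    n: int, cap_tli: bool = False) -> FitIndices:
    """RMSEA, CFI and TLI from the model and baseline chi-square statistics.

    RMSEA = sqrt(max(T - df, 0) / (df (n-1)));
    CFI   = 1 - max(T - df, 0) / max(T_b - df_b, T - df, 0);
    TLI   = ((T_b/df_b) - (T/df)) / ((T_b/df_b) - 1), uncapped by default.
    """
    if n <= 1:
        raise ValueError("n must exceed 1")
    if df < 1:
        return FitIndices(
            T=T, df=df, T_baseline=T_baseline, df_baseline=df_baseline, n=n,
            rmsea=None, cfi=None, tli=None,
            note="indices undefined: the model has zero degrees of freedom "
                 "(saturated); there is no lack of fit to summarise")
    excess = max(T - df, 0.0)
    rmsea = float(np.sqrt(excess / (df * (n - 1))))
    denom = max(T_baseline - df_baseline, T - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    ratio_b = T_baseline / df_baseline
    tli = None
    if ratio_b != 1.0:
        tli = (ratio_b - T / df) / (ratio_b - 1.0)
        if cap_tli:
            tli = min(tli, 1.0)
    verdicts = {
        "rmsea": "good" if rmsea < RMSEA_GOOD else "not good",
        "cfi": "good" if cfi > CFI_GOOD else "not good",
        "tli": ("good" if tli is not None and tli > TLI_GOOD else "not good"),
    }
    return FitIndices(T=T, df=df, T_baseline=T_baseline,
                      df_baseline=df_baseline, n=n,
                      rmsea=rmsea, cfi=float(cfi),
                      tli=None if tli is None else float(tli),
                      verdicts=verdicts,
                      note="unscaled ML chi-square; robust standard errors do "
                           "not alter the statistic feeding these indices")


def indices_for_fit(fit: FitResult, model: SemModel,
                    cap_tli: bool = False) -> FitIndices:
    """Convenience wrapper: T = (n-1) F_min, baseline from the fitted S."""
    t = (fit.n - 1) * fit.f_min
    df = degrees_of_freedom(model)
    t_b, df_b = baseline_fit_cov(fit.sample_cov, fit.n)
    return compute_indices(t, df, t_b, df_b, fit.n, cap_tli=cap_tli)
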