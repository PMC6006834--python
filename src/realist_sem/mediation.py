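"""Standardized effect decomposition for CMO configurations.

Each CMO is decomposed into the standardized direct effect (context to
outcome not through the mechanism), the indirect effect (product of the
context-to-mechanism coefficient `a` and the mechanism-to-outcome
coefficient `b`), and the total = direct + indirect.  The indirect-effect
standard error uses the delta method

    SE(ab) = sqrt(b^2 var(a) + a^2 var(b) + 2 a b cov(a, b))

with symmetric normal-theory 95% intervals.  The proportion mediated uses
the magnitude convention |indirect| / (|direct| + |indirect|), which handles
opposite-signed direct and indirect components gracefully.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

from .engine import FitResult, StandardizedSolution, standardize
from .model_spec import SemModel

__all__ = ["EffectDecomposition", "indirect_effect", "proportion_mediated",
           "decompose_all"]

logger = logging.getLogger(__name__)

_Z95 = norm.ppf(0.975)


@dataclass
class EffectDecomposition:
    cmo: str                      # CMO label (context concept -> mechanism)
    context: str                  # context node (dummy level for categorical)
    mechanism: str
    outcome: str
    a: float                      # standardized context -> mechanism
    b: float                      # standardized mechanism -> outcome
    direct: float
    direct_se: float
    direct_ci: tuple[float, float]
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    total: float
    proportion_mediated: float | None
    direct_significant: bool
    indirect_significant: bool

    def as_row(self) -> dict:
        row = {
            "cmo": self.cmo, "context": self.context,
            "mechanism": self.mechanism, "outcome": self.outcome,
            "a": self.a, "b": self.b,
            "direct": self.direct, "direct_se": self.direct_se,
            "direct_ci_low": self.direct_ci[0],
            "direct_ci_high": self.direct_ci[1],
            "indirect": self.indirect, "indirect_se": self.indirect_se,
            "indirect_ci_low": self.indirect_ci[0],
            "indirect_ci_high": self.indirect_ci[1],
            "total": self.total,
            "proportion_mediated": self.proportion_mediated,
            "proportion_mediated_pct": (
                None if self.proportion_mediated is None
                else 100.0 * self.proportion_mediated),
            "direct_significant": self.direct_significant,
            "indirect_significant": self.indirect_significant,
        }
        return row


def indirect_effect(a: float, b: float, vcov_ab) -> tuple[float, float, tuple[float, float]]:
    """Product-of-coefficients indirect effect with a delta-method interval.

    `vcov_ab` is the 2x2 covariance of (a, b); pass variances only (cov
    missing) and the cross term is taken as 0 with a logged warning.
    """
    try:
        var_a = float(vcov_ab[0][0])
        var_b = float(vcov_ab[1][1])
        cov_ab = float(vcov_ab[0][1])
    except (TypeError, IndexError):
        var_a, var_b = float(vcov_ab[0]), float(vcov_ab[1])
        cov_ab = 0.0
        logger.warning("covariance of (a, b) unavailable; using cov = 0")
    est = a * b
    var = b * b * var_a + a * a * var_b + 2.0 * a * b * cov_ab
    se = math.sqrt(max(var, 0.0))
    return est, se, (est - _Z95 * se, est + _Z95 * se)


def proportion_mediated(direct: float, indirect: float) -> float | None:
    """|indirect| / (|direct| + |indirect|); None when both are zero."""
    denom = abs(direct) + abs(indirect)
    if denom == 0.0:
        return None
    return abs(indirect) / denom


def decompose_all(fit: FitResult, model: SemModel,
                  std: StandardizedSolution | None = None) -> list[EffectDecomposition]:
    """One decomposition per CMO context node (categorical contexts yield one
    row per dummy level).  Significance = the 95% CI excludes zero, using
    the standardized robust (delta-method) standard errors."""
    if std is None:
        std = standardize(fit, model)
    t = std.table
    out: list[EffectDecomposition] = []
    for cmo in model.cmo_paths:
        mech, outc = cmo["mechanism"], cmo["outcome"]
        try:
            kb = std.lookup(outc, mech)
        except KeyError:
            raise ValueError(f"CMO {cmo['label']!r}: mechanism->outcome path "
                             "missing from the fitted model")
        b = float(t.loc[kb, "est_std"])
        for ctx in cmo["context_nodes"]:
            try:
                ka = std.lookup(mech, ctx)
            except KeyError:
                raise ValueError(f"CMO {cmo['label']!r}: context->mechanism "
                                 f"path for {ctx!r} missing from the model")
            a = float(t.loc[ka, "est_std"])
            vc = [[std.vcov_std[ka, ka], std.vcov_std[ka, kb]],
                  [std.vcov_std[kb, ka], std.vcov_std[kb, kb]]]
            ind, ind_se, ind_ci = indirect_effect(a, b, vc)
            if cmo["direct"]:
                kd = std.lookup(outc, ctx)
                direct = float(t.loc[kd, "est_std"])
                d_se = float(t.loc[kd, "se_std"])
                d_ci = (float(t.loc[kd, "ci_low"]), float(t.loc[kd, "ci_high"]))
            else:
                direct, d_se, d_ci = 0.0, 0.0, (0.0, 0.0)
            out.append(EffectDecomposition(
                cmo=cmo["label"], context=ctx, mechanism=mech, outcome=outc,
                a=a, b=b,
                direct=direct, direct_se=d_se, direct_ci=d_ci,
                indirect=ind, indirect_se=ind_se, indirect_ci=ind_ci,
                total=direct + ind,
                proportion_mediated=proportion_mediated(direct, ind),
                direct_significant=bool(d_ci[0] > 0 or d_ci[1] < 0),
                indirect_significant=bool(ind_ci[0] > 0 or ind_ci[1] < 0),
            ))
    return out


def decomposition_table(decompositions: list[EffectDecomposition]) -> pd.DataFrame:
    return pd.DataFrame([d.as_row() for d in decompositions])
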