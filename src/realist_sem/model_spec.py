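"""Realist CMO configurations compiled into a structural equation model.

A context-mechanism-outcome (CMO) configuration is the realist-evaluation
unit of analysis: a Context triggers a Mechanism which generates an Outcome.
Each concept is bound to data through a :class:`ConceptBinding` — a single
observed variable, a reflective latent with several indicators, a formative
composite, or a categorical context expanded into baseline-contrast dummies.

The compiled :class:`SemModel` uses the standard all-y parameterization:

    Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta

Observed singletons are promoted to degenerate latents (loading 1, zero
residual) so every structural path lives in B.  Reflective latents are
identified by fixing the reference indicator's loading to 1 and freeing the
latent variance.  A formative concept is compiled as a composite: its
indicators (as degenerate latents) regress INTO the composite with the first
weight fixed to 1 and the composite disturbance fixed to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ConceptBinding",
    "CmoConfiguration",
    "SemModel",
    "build_sem_from_cmos",
    "degrees_of_freedom",
    "load_model_config",
    "save_model_config",
    "parse_model_config",
    "model_config_to_dict",
]

_MODES = ("observed", "reflective", "formative", "categorical")


@dataclass(frozen=True)
class ConceptBinding:
    """Bind a realist concept to observed variables.

    modes
    -----
    observed    : exactly one variable, used as-is.
    reflective  : >= 2 indicators caused by the latent concept; `reference`
                  names the indicator whose loading is fixed to 1 (defaults
                  to the first).
    formative   : >= 2 indicators composing the concept (composite).
    categorical : context expanded to one 0/1 dummy column per non-baseline
                  level; `indicators` lists the dummy column names.
    """

    concept_name: str
    mode: str
    indicators: tuple[str, ...]
    reference: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))
        if self.mode not in _MODES:
            raise ValueError(f"unknown binding mode {self.mode!r}")
        if len(set(self.indicators)) != len(self.indicators):
            raise ValueError(f"duplicate indicators in concept {self.concept_name!r}")
        if self.mode == "observed" and len(self.indicators) != 1:
            raise ValueError("observed binding requires exactly 1 indicator")
        if self.mode in ("reflective", "formative") and len(self.indicators) < 2:
            raise ValueError(f"{self.mode} binding requires >= 2 indicators")
        if self.mode == "categorical" and len(self.indicators) < 1:
            raise ValueError("categorical binding requires >= 1 dummy indicator")
        if self.reference is not None:
            if self.mode != "reflective":
                raise ValueError("reference indicator only applies to reflective mode")
            if self.reference not in self.indicators:
                raise ValueError("reference must be one of the indicators")

    @property
    def reference_indicator(self) -> str:
        return self.reference if self.reference is not None else self.indicators[0]

    def with_indicators(self, indicators: tuple[str, ...]) -> "ConceptBinding":
        ref = self.reference if self.reference in indicators else None
        return ConceptBinding(self.concept_name, self.mode, tuple(indicators), ref)


@dataclass(frozen=True)
class CmoConfiguration:
    context: ConceptBinding
    mechanism: ConceptBinding
    outcome: ConceptBinding
    include_direct_path: bool = True

    def __post_init__(self):
        names = {self.context.concept_name, self.mechanism.concept_name,
                 self.outcome.concept_name}
        if len(names) != 3:
            raise ValueError("context, mechanism and outcome must be distinct concepts")
        for role, b in (("mechanism", self.mechanism), ("outcome", self.outcome)):
            if b.mode in ("categorical", "formative"):
                raise ValueError(f"{role} binding cannot be {b.mode}")


@dataclass
class SemModel:
    """All-y pattern matrices with a free/fixed pattern per cell.

    `*_val` holds fixed values (and start hints for free cells); `*_free`
    marks free cells.  Psi and Theta patterns are symmetric: a free
    off-diagonal cell is one parameter controlling both (i, j) and (j, i).
    """

    observed_vars: list[str]
    latent_vars: list[str]
    lam_val: np.ndarray
    lam_free: np.ndarray
    b_val: np.ndarray
    b_free: np.ndarray
    psi_val: np.ndarray
    psi_free: np.ndarray
    theta_val: np.ndarray
    theta_free: np.ndarray
    # latent nodes that are promoted observed singletons (loading 1, Theta 0)
    degenerate: set[str] = field(default_factory=set)
    # reflective latent -> reference indicator name
    reference_indicator: dict[str, str] = field(default_factory=dict)
    # per-CMO path bookkeeping for mediation: label -> dict of node names
    cmo_paths: list[dict] = field(default_factory=list)
    exogenous: list[str] = field(default_factory=list)

    # ---- free-parameter bookkeeping -------------------------------------
    def _free_cells(self):
        """Ordered (matrix_tag, i, j) for every free parameter."""
        cells = []
        p, m = self.lam_val.shape
        for i in range(p):
            for j in range(m):
                if self.lam_free[i, j]:
                    cells.append(("lam", i, j))
        for i in range(m):
            for j in range(m):
                if self.b_free[i, j]:
                    cells.append(("b", i, j))
        for i in range(m):
            for j in range(i + 1):
                if self.psi_free[i, j]:
                    cells.append(("psi", i, j))
        for i in range(p):
            for j in range(i + 1):
                if self.theta_free[i, j]:
                    cells.append(("theta", i, j))
        return cells

    @property
    def free_cells(self):
        return self._free_cells()

    @property
    def q(self) -> int:
        return len(self._free_cells())

    @property
    def p(self) -> int:
        return len(self.observed_vars)

    @property
    def m(self) -> int:
        return len(self.latent_vars)

    def param_names(self) -> list[str]:
        ov, lv = self.observed_vars, self.latent_vars
        names = []
        for tag, i, j in self._free_cells():
            if tag == "lam":
                names.append(f"{lv[j]}=~{ov[i]}")
            elif tag == "b":
                names.append(f"{lv[i]}~{lv[j]}")
            elif tag == "psi":
                names.append(f"{lv[i]}~~{lv[j]}")
            else:
                names.append(f"{ov[i]}~~{ov[j]}")
        return names

    def matrices(self, theta: np.ndarray):
        """Fill the pattern with a free-parameter vector; returns L, B, P, T."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.q,):
            raise ValueError(f"theta must have length {self.q}")
        lam = self.lam_val.copy()
        b = self.b_val.copy()
        psi = self.psi_val.copy()
        theta_m = self.theta_val.copy()
        for val, (tag, i, j) in zip(theta, self._free_cells()):
            if tag == "lam":
                lam[i, j] = val
            elif tag == "b":
                b[i, j] = val
            elif tag == "psi":
                psi[i, j] = psi[j, i] = val
            else:
                theta_m[i, j] = theta_m[j, i] = val
        return lam, b, psi, theta_m

    def validate(self) -> None:
        m = self.m
        if np.any(np.diag(self.b_val) != 0) or np.any(np.diag(self.b_free)):
            raise ValueError("B must have a zero diagonal")
        adj = (self.b_free | (self.b_val != 0)).astype(float)
        power = np.eye(m)
        for _ in range(m):
            power = power @ adj
            if np.trace(power) > 0:
                raise ValueError("non-recursive model unsupported")
        if not (np.array_equal(self.psi_free, self.psi_free.T)
                and np.allclose(self.psi_val, self.psi_val.T)):
            raise ValueError("Psi pattern must be symmetric")
        if not (np.array_equal(self.theta_free, self.theta_free.T)
                and np.allclose(self.theta_val, self.theta_val.T)):
            raise ValueError("Theta pattern must be symmetric")


def degrees_of_freedom(model: SemModel) -> int:
    """Covariance-structure df: p(p+1)/2 distinct moments minus q free params."""
    p_star = model.p * (model.p + 1) // 2
    if model.q > p_star:
        raise ValueError("model not identified by counting rule")
    return p_star - model.q


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def _structural_nodes(binding: ConceptBinding) -> list[str]:
    """Names of the structural (latent) nodes a binding contributes paths to."""
    if binding.mode == "categorical":
        return list(binding.indicators)
    return [binding.concept_name]


def build_sem_from_cmos(
    cmos: list[CmoConfiguration],
    residual_correlations: list[tuple[str, str]] = (),
) -> SemModel:
    """Compile CMO configurations into one identified structural model.

    Shared concepts appear once; every reflective latent is identified by a
    single loading fixed to 1; exogenous nodes receive free variances and
    pairwise covariances; requested residual correlations are freed in Theta.
    """
    if not cmos:
        raise ValueError("at least one CMO configuration is required")

    # concept registry, first-appearance order; consistency across CMOs
    concepts: dict[str, ConceptBinding] = {}
    order: list[str] = []

    def register(b: ConceptBinding):
        if b.concept_name in concepts:
            if concepts[b.concept_name] != b:
                raise ValueError(
                    f"concept {b.concept_name!r} bound inconsistently across CMOs")
        else:
            concepts[b.concept_name] = b
            order.append(b.concept_name)

    outcome_name = cmos[0].outcome.concept_name
    for cmo in cmos:
        if cmo.outcome.concept_name != outcome_name:
            raise ValueError("all CMOs in one model must share the same outcome")
        register(cmo.context)
        register(cmo.mechanism)
        register(cmo.outcome)

    # observed variables, with cross-concept duplication check
    observed: list[str] = []
    owner: dict[str, str] = {}
    for name in order:
        for ind in concepts[name].indicators:
            if ind in owner:
                raise ValueError(
                    f"variable {ind!r} bound to two concepts "
                    f"({owner[ind]!r} and {name!r})")
            owner[ind] = name
            observed.append(ind)

    # structural node list: concept nodes, plus degenerate nodes for
    # categorical dummies and formative indicators
    latent: list[str] = []
    degenerate: set[str] = set()
    reference: dict[str, str] = {}
    for name in order:
        b = concepts[name]
        if b.mode == "observed":
            latent.append(name)
            degenerate.add(name)
        elif b.mode == "reflective":
            latent.append(name)
            reference[name] = b.reference_indicator
        elif b.mode == "categorical":
            for ind in b.indicators:
                latent.append(ind)
                degenerate.add(ind)
        else:  # formative composite: indicator nodes then the composite
            for ind in b.indicators:
                latent.append(ind)
                degenerate.add(ind)
            latent.append(name)

    p, m = len(observed), len(latent)
    li = {v: i for i, v in enumerate(latent)}
    oi = {v: i for i, v in enumerate(observed)}

    lam_val = np.zeros((p, m)); lam_free = np.zeros((p, m), dtype=bool)
    b_val = np.zeros((m, m)); b_free = np.zeros((m, m), dtype=bool)
    psi_val = np.zeros((m, m)); psi_free = np.zeros((m, m), dtype=bool)
    th_val = np.zeros((p, p)); th_free = np.zeros((p, p), dtype=bool)

    # measurement part
    for name in order:
        b = concepts[name]
        if b.mode == "reflective":
            j = li[name]
            for ind in b.indicators:
                i = oi[ind]
                if ind == b.reference_indicator:
                    lam_val[i, j] = 1.0
                else:
                    lam_free[i, j] = True
                th_free[i, i] = True
        else:
            # every non-reflective indicator variable is its own degenerate node
            nodes = b.indicators if b.mode in ("categorical", "formative") \
                else (b.indicators[0],)
            for k, ind in enumerate(b.indicators):
                node = nodes[k] if b.mode in ("categorical", "formative") else name
                lam_val[oi[ind], li[node]] = 1.0  # loading fixed 1, Theta 0

    # formative composite weights: indicators regress into the composite,
    # first weight fixed to 1, composite disturbance fixed to 0
    for name in order:
        b = concepts[name]
        if b.mode == "formative":
            j = li[name]
            for k, ind in enumerate(b.indicators):
                if k == 0:
                    b_val[j, li[ind]] = 1.0
                else:
                    b_free[j, li[ind]] = True

    # structural paths from the CMOs
    cmo_paths: list[dict] = []
    for cmo in cmos:
        ctx_nodes = _structural_nodes(cmo.context)
        mech = cmo.mechanism.concept_name
        out = cmo.outcome.concept_name
        for c in ctx_nodes:
            b_free[li[mech], li[c]] = True
            if cmo.include_direct_path:
                b_free[li[out], li[c]] = True
        b_free[li[out], li[mech]] = True
        cmo_paths.append({
            "label": f"{cmo.context.concept_name}->{mech}",
            "context_concept": cmo.context.concept_name,
            "context_nodes": ctx_nodes,
            "mechanism": mech,
            "outcome": out,
            "direct": cmo.include_direct_path,
        })

    # cycle check on the requested path structure
    adj = b_free | (b_val != 0)
    power = np.eye(m)
    for _ in range(m):
        power = power @ adj.astype(float)
        if np.trace(power) > 0:
            raise ValueError("non-recursive model unsupported")

    # Psi: exogenous nodes (no incoming structural edge) get free variances
    # and pairwise covariances; endogenous nodes get free disturbances,
    # except formative composites whose disturbance is fixed to 0
    incoming = adj.any(axis=1)
    composite = {name for name in order if concepts[name].mode == "formative"}
    exogenous = [latent[i] for i in range(m) if not incoming[i]]
    for i in range(m):
        if latent[i] in composite:
            continue  # psi fixed at 0
        psi_free[i, i] = True
    for a in range(m):
        for b2 in range(a):
            if not incoming[a] and not incoming[b2]:
                psi_free[a, b2] = psi_free[b2, a] = True

    # requested residual correlations
    for pair in residual_correlations:
        if len(pair) != 2:
            raise ValueError("residual correlations must be pairs of indicators")
        u, v = pair
        for w in (u, v):
            if w not in oi:
                raise ValueError(f"residual correlation names unknown indicator {w!r}")
        iu, iv = oi[u], oi[v]
        th_free[iu, iv] = th_free[iv, iu] = True

    model = SemModel(
        observed_vars=observed, latent_vars=latent,
        lam_val=lam_val, lam_free=lam_free,
        b_val=b_val, b_free=b_free,
        psi_val=psi_val, psi_free=psi_free,
        theta_val=th_val, theta_free=th_free,
        degenerate=degenerate, reference_indicator=reference,
        cmo_paths=cmo_paths, exogenous=exogenous,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# model-configuration files (YAML or JSON)
# ---------------------------------------------------------------------------

def _binding_to_dict(b: ConceptBinding) -> dict:
    d = {"name": b.concept_name, "mode": b.mode, "indicators": list(b.indicators)}
    if b.reference is not None:
        d["reference"] = b.reference
    return d


def _binding_from_dict(d: dict) -> ConceptBinding:
    return ConceptBinding(d["name"], d["mode"], tuple(d["indicators"]),
                          d.get("reference"))


def model_config_to_dict(cmos, residual_correlations=(), cluster_column="practice_id",
                         options=None) -> dict:
    return {
        "cmos": [
            {
                "context": _binding_to_dict(c.context),
                "mechanism": _binding_to_dict(c.mechanism),
                "outcome": _binding_to_dict(c.outcome),
                "include_direct_path": c.include_direct_path,
            }
            for c in cmos
        ],
        "residual_correlations": [list(p) for p in residual_correlations],
        "cluster_column": cluster_column,
        "options": dict(options or {}),
    }


def parse_model_config(d: dict):
    """dict -> (cmos, residual_correlations, cluster_column, options)."""
    cmos = [
        CmoConfiguration(
            context=_binding_from_dict(c["context"]),
            mechanism=_binding_from_dict(c["mechanism"]),
            outcome=_binding_from_dict(c["outcome"]),
            include_direct_path=c.get("include_direct_path", True),
        )
        for c in d["cmos"]
    ]
    rc = [tuple(p) for p in d.get("residual_correlations", [])]
    return cmos, rc, d.get("cluster_column", "practice_id"), d.get("options", {})


def save_model_config(path, cmos, residual_correlations=(),
                      cluster_column="practice_id", options=None) -> None:
    d = model_config_to_dict(cmos, residual_correlations, cluster_column, options)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_model_config(path):
    path = str(path)
    with open(path) as fh:
        if path.endswith(".json"):
            d = json.load(fh)
        else:
            d = yaml.safe_load(fh)
    return parse_model_config(d)
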