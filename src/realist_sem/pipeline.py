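"""End-to-end orchestration: data + model config in, structured report out.

Stage order: measurement CFA -> indicator pruning -> model compilation ->
ML fit -> cluster-robust standard errors -> standardization -> CMO effect
decomposition -> fit indices.  The report carries full-precision numbers in
its JSON form and 3-decimal tables in its human-readable form, plus
provenance (seed, config hash, software version, n, cluster count, listwise
deletion count).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cfa import fit_cfa, prune_indicators
from .dataset import ClusteredDataset
from .engine import FitOptions, fit_ml, standardize
from .fit_indices import indices_for_fit
from .mediation import decompose_all, decomposition_table
from .model_spec import (CmoConfiguration, build_sem_from_cmos,
                         degrees_of_freedom, load_model_config,
                         model_config_to_dict)

__all__ = ["RunReport", "run_pipeline", "load_csv_dataset"]


@dataclass
class RunReport:
    measurement: dict
    model: dict
    fit: dict
    standardized: list[dict]
    decompositions: list[dict]
    indices: dict | None
    provenance: dict
    warnings: list[str] = field(default_factory=list)
    converged: bool = True

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2,
                             default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_text(self) -> str:
        lines = []
        lines.append(f"realist-sem {self.provenance['version']} run report")
        lines.append(f"n = {self.fit['n']} individuals in "
                     f"{self.fit['n_clusters']} clusters "
                     f"({self.fit['n_dropped']} rows dropped listwise)")
        lines.append(f"converged: {self.converged}   "
                     f"F_min = {self.fit['f_min']:.6f}   "
                     f"chi2 = {self.fit['chi_square']:.3f} "
                     f"on {self.model['df']} df")
        if self.indices:
            lines.append(
                "fit indices: RMSEA = {rmsea:.3f} ({v[rmsea]}), "
                "CFI = {cfi:.3f} ({v[cfi]}), TLI = {tli:.3f} ({v[tli]})".format(
                    rmsea=self.indices["rmsea"], cfi=self.indices["cfi"],
                    tli=self.indices["tli"], v=self.indices["verdicts"]))
        lines.append("")
        lines.append("standardized effect decomposition per CMO:")
        df = pd.DataFrame(self.decompositions)
        show = df[["cmo", "context", "direct", "direct_ci_low",
                   "direct_ci_high", "indirect", "indirect_ci_low",
                   "indirect_ci_high", "proportion_mediated_pct"]]
        lines.append(show.round(3).to_string(index=False))
        if self.warnings:
            lines.append("")
            lines.append("warnings:")
            lines.extend(f"  - {w}" for w in self.warnings)
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_csv_dataset(data_path, cluster_column: str) -> ClusteredDataset:
    """Read a plain one-row-per-individual CSV; string columns become
    declared-categorical metadata (they cannot enter the model)."""
    frame = pd.read_csv(data_path)
    if cluster_column not in frame.columns:
        raise ValueError(f"data file lacks the cluster column {cluster_column!r}")
    categorical = {c for c in frame.columns
                   if c != cluster_column and frame[c].dtype == object}
    return ClusteredDataset(frame, cluster_column, categorical=categorical)


def _measurement_stage(cmos, data, alpha, prune, options):
    """CFA + pruning for every distinct reflective concept; returns the
    (possibly pruned) CMO list and per-concept summaries."""
    summaries: dict[str, dict] = {}
    pruned: dict[str, object] = {}
    seen = {}
    for cmo in cmos:
        for b in (cmo.context, cmo.mechanism, cmo.outcome):
            if b.mode == "reflective" and b.concept_name not in seen:
                seen[b.concept_name] = b
    for name, binding in seen.items():
        if len(binding.indicators) < 3:
            summaries[name] = {"note": "two-indicator binding; CFA skipped"}
            continue
        mfit = fit_cfa(binding, data, options)
        new_binding = prune_indicators(mfit, alpha) if prune else binding
        removed = [i for i in binding.indicators
                   if i not in new_binding.indicators]
        summaries[name] = {
            "indicators": list(binding.indicators),
            "loadings": mfit.table.drop(columns="retained")
                        .to_dict(orient="records"),
            "converged": bool(mfit.fit.converged),
            "removed": removed,
            "warnings": list(mfit.fit.warnings),
        }
        if removed:
            pruned[name] = new_binding

    if not pruned:
        return cmos, summaries

    def swap(b):
        return pruned.get(b.concept_name, b)

    new_cmos = [CmoConfiguration(swap(c.context), swap(c.mechanism),
                                 swap(c.outcome), c.include_direct_path)
                for c in cmos]
    return new_cmos, summaries


def run_pipeline(data_path, model_config_path, *, alpha: float = 0.05,
                 prune: bool = True, seed: int | None = None,
                 options: FitOptions | None = None) -> RunReport:
    """Run the full analysis described by a model-configuration file.

    Raises ValueError on usage/data errors; a non-converged fit returns a
    report with ``converged=False`` (the CLI maps this to exit code 2).
    """
    options = options or FitOptions()
    cmos, residual_correlations, cluster_column, cfg_options = \
        load_model_config(model_config_path)
    if not cmos:
        raise ValueError("model configuration declares no CMO configurations")
    data = load_csv_dataset(data_path, cluster_column)

    needed = sorted({i for c in cmos
                     for b in (c.context, c.mechanism, c.outcome)
                     for i in b.indicators})
    missing = [v for v in needed if v not in data.frame.columns]
    if missing:
        raise ValueError(f"model variables missing from data: {missing}")

    cmos, measurement = _measurement_stage(cmos, data, alpha, prune, options)

    model = build_sem_from_cmos(cmos, residual_correlations)
    fit = fit_ml(model, data, options)
    warnings = list(fit.warnings)
    df = degrees_of_freedom(model)

    model_desc = {
        "observed_vars": model.observed_vars,
        "latent_vars": model.latent_vars,
        "p": model.p, "m": model.m, "q": model.q, "df": df,
        "free_parameters": model.param_names(),
    }
    fit_desc = {
        "n": fit.n, "n_clusters": fit.n_clusters, "n_dropped": fit.n_dropped,
        "f_min": fit.f_min, "chi_square": (fit.n - 1) * fit.f_min,
        "gradient_norm": fit.gradient_norm, "n_iter": fit.n_iter,
        "converged": fit.converged,
    }

    cfg_dict = model_config_to_dict(cmos, residual_correlations,
                                    cluster_column, cfg_options)
    provenance = {
        "version": __version__,
        "seed": seed,
        "data_path": str(data_path),
        "model_config_path": str(model_config_path),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "n": fit.n, "n_clusters": fit.n_clusters,
        "listwise_deleted": fit.n_dropped,
        "alpha": alpha, "prune": prune,
    }

    if not fit.converged:
        return RunReport(
            measurement=measurement, model=model_desc, fit=fit_desc,
            standardized=[], decompositions=[], indices=None,
            provenance=provenance,
            warnings=warnings + ["model did not converge; no effect "
                                 "decomposition reported"],
            converged=False)

    std = standardize(fit, model)
    decomps = decompose_all(fit, model, std)
    indices = indices_for_fit(fit, model)
    return RunReport(
        measurement=measurement, model=model_desc, fit=fit_desc,
        standardized=std.table.to_dict(orient="records"),
        decompositions=decomposition_table(decomps).to_dict(orient="records"),
        indices=indices.to_dict(), provenance=provenance,
        warnings=warnings, converged=True)
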