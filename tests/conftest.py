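"""Shared fixtures: small hand-built models and datasets.

Everything is generated programmatically; no data files are stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from realist_sem import ClusteredDataset, CmoConfiguration, ConceptBinding
from realist_sem.model_spec import SemModel


def observed(name: str, var: str | None = None) -> ConceptBinding:
    return ConceptBinding(name, "observed", (var or name,))


@pytest.fixture
def simple_cmo() -> CmoConfiguration:
    """One CMO with three observed singletons (c -> m -> o plus direct)."""
    return CmoConfiguration(observed("c"), observed("m"), observed("o"))


@pytest.fixture
def regression_model() -> SemModel:
    """y regressed on x, both observed: the ML == OLS reduction."""
    return SemModel(
        observed_vars=["x", "y"], latent_vars=["xl", "yl"],
        lam_val=np.eye(2), lam_free=np.zeros((2, 2), bool),
        b_val=np.zeros((2, 2)),
        b_free=np.array([[False, False], [True, False]]),
        psi_val=np.zeros((2, 2)),
        psi_free=np.diag([True, True]),
        theta_val=np.zeros((2, 2)), theta_free=np.zeros((2, 2), bool),
        degenerate={"xl", "yl"},
    )


@pytest.fixture
def regression_data() -> ClusteredDataset:
    rng = np.random.default_rng(42)
    n = 400
    x = rng.standard_normal(n)
    y = 0.7 * x + 0.8 * rng.standard_normal(n)
    frame = pd.DataFrame({"x": x, "y": y, "cl": np.arange(n)})
    return ClusteredDataset(frame, "cl")


def make_factor_data(loadings, n, seed, residual_pair=None, rho=0.0,
                     cluster_size=1) -> ClusteredDataset:
    """One-factor continuous data; optionally one residual correlation."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    p = len(loadings)
    y = np.empty((n, p))
    for k, lam in enumerate(loadings):
        y[:, k] = lam * f + np.sqrt(max(1 - lam * lam, 1e-12)) \
            * rng.standard_normal(n)
    if residual_pair is not None:
        shared = rng.standard_normal(n)
        i, j = residual_pair
        y[:, i] += rho * shared
        y[:, j] += rho * shared
    frame = pd.DataFrame(y, columns=[f"x{k + 1}" for k in range(p)])
    frame["cl"] = np.arange(n) // cluster_size
    return ClusteredDataset(frame, "cl")
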