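"""Synthetic linked two-level survey data.

Emulates the statistical structure of an individual-level ageing-cohort
survey joined to practice-level patient-experience percentages: ~276
individuals nested in ~178 GP practices, reflective latents with 3-5 ordinal
indicators, one formative transport composite, practice-level percentage
variables constant within cluster, and a log-normal road-travel-time
variable (median 4.80 min, IQR 2.76-7.88).

The default configuration IS the study fixture: its generating standardized
coefficients reproduce the published direct effects and indirect (a*b)
products for all nine CMO configurations — in particular direct 0.514 and
indirect 0.140 for the ease-of-getting-through CMO, an implied proportion
mediated of 0.21.  Mechanism->outcome coefficients (not printed per path in
the source tables) are fixed once at plausible values and each
context->mechanism coefficient is derived as indirect/b.

Generation notes (see docs/methods.md for the full account):

* Structural equations consume sample-standardized scores, so generating
  coefficients are standardized coefficients by construction.
* Exogenous practice-level percentages are constant within cluster;
  endogenous percentages (convenience, obtaining an appointment) carry
  individual variation plus an independent practice random effect, keeping
  the fitted individual-level model correctly specified while inducing
  within-practice dependence.
* Ordinal indicators are produced by thresholding continuous scores
  (`discretize_to_likert`); marginal category frequencies follow the
  published baseline table.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import ClusteredDataset
from .model_spec import CmoConfiguration, ConceptBinding

__all__ = ["SyntheticConfig", "paper_fixture", "null_fixture",
           "generate_linked_dataset", "discretize_to_likert",
           "paper_model_cmos", "MECHANISMS", "CONTEXT_NODES"]


# ---------------------------------------------------------------------------
# the study schema
# ---------------------------------------------------------------------------

MECHANISMS = ("health_literacy", "assertiveness", "convenience")

#: structural context nodes (education expanded to baseline-contrast dummies)
CONTEXT_NODES = (
    "clear_info", "edu_alevel", "edu_olevel", "edu_cse", "edu_noqual",
    "self_esteem", "technology", "healthcare_experience",
    "ease_getting_through", "transport",
)

EDUCATION_LEVELS = {          # label -> (dummy column, sampling probability)
    "no_qualification": ("edu_noqual", 0.385),
    "cse_or_equivalent": ("edu_cse", 0.093),
    "gce_o_level": ("edu_olevel", 0.245),
    "gce_a_level": ("edu_alevel", 0.086),
    "higher_education": (None, 0.191),      # baseline, no dummy
}

SELF_ESTEEM_INDICATORS = ("se_ideal", "se_conditions", "se_satisfied",
                          "se_important", "se_no_regrets")
ASSERT_INDICATORS = ("ast_determined", "ast_outgoing", "ast_proud")
HCE_INDICATORS = ("hce_not_overheard", "hce_gp_time", "hce_gp_explain",
                  "hce_gp_involve")
TRANSPORT_INDICATORS = ("lifts_freq", "travel_time_min",
                        "public_transport_freq")

ORDINAL_VARS = (
    "internet_use", "lifts_freq", "public_transport_freq",
    "health_literacy_score",
) + SELF_ESTEEM_INDICATORS + ASSERT_INDICATORS


def _thr(cum):
    return tuple(float(norm.ppf(c)) for c in cum)


def _default_likert_thresholds() -> dict[str, tuple[float, ...]]:
    """Thresholds on the N(0,1) scale from published category frequencies
    (internet use, lifts, public transport, health-literacy score) and
    plausible satisfaction/affect distributions for the Likert indicators."""
    t = {
        # codes 1 (never) .. 6 (every day)
        "internet_use": _thr([0.4389, 0.4627, 0.4789, 0.5222, 0.6865]),
        "lifts_freq": _thr([0.7016, 0.7924, 0.8543, 0.9341, 0.9960]),
        "public_transport_freq": _thr([0.409, 0.710, 0.797, 0.866, 0.960]),
        # codes 1..5 for 0..4 correct answers
        "health_literacy_score": _thr([0.00397, 0.03968, 0.10714, 0.28571]),
        "ast_determined": _thr([0.05, 0.15, 0.40, 0.70]),
        "ast_outgoing": _thr([0.10, 0.40, 0.75]),
        "ast_proud": _thr([0.05, 0.15, 0.40, 0.70]),
    }
    for v in SELF_ESTEEM_INDICATORS:
        t[v] = _thr([0.03, 0.08, 0.15, 0.30, 0.55, 0.80])
    return t


def _default_loadings() -> dict[str, tuple[float, ...]]:
    return {
        "self_esteem": (0.80, 0.78, 0.82, 0.60, 0.75),
        "assertiveness": (0.75, 0.65, 0.70),
        "healthcare_experience": (0.85, 0.80, 0.82, 0.78),
    }


def _default_practice_percent() -> dict[str, tuple[float, float]]:
    """(mean, sd) on the percent scale for GPPS-style variables."""
    return {
        "pct_know_ooh": (72.0, 8.0),
        "pct_easy_get_through": (70.0, 9.0),
        "hce_not_overheard": (85.0, 6.0),
        "hce_gp_time": (82.0, 6.0),
        "hce_gp_explain": (80.0, 6.0),
        "hce_gp_involve": (78.0, 6.0),
        "pct_convenient": (75.0, 8.0),
        "pct_get_appointment": (84.0, 5.5),
    }


# generating standardized coefficients: published direct effects; each a is
# indirect/b with b fixed per mechanism (see module docstring)
_B = {"health_literacy": 0.10, "assertiveness": 0.10, "convenience": 0.35}

_INDIRECT = {
    ("clear_info", "health_literacy"): 0.000,
    ("edu_alevel", "health_literacy"): 0.007,
    ("edu_olevel", "health_literacy"): 0.005,
    ("edu_cse", "health_literacy"): 0.004,
    ("edu_noqual", "health_literacy"): 0.011,
    ("self_esteem", "assertiveness"): 0.035,
    ("clear_info", "assertiveness"): -0.002,
    ("technology", "convenience"): 0.029,
    ("healthcare_experience", "convenience"): 0.088,
    ("ease_getting_through", "convenience"): 0.140,
    ("transport", "convenience"): 0.018,
    ("clear_info", "convenience"): 0.037,
}

_DIRECT = {
    "clear_info": 0.084,
    "edu_alevel": -0.028, "edu_olevel": -0.026,
    "edu_cse": 0.006, "edu_noqual": 0.009,
    "self_esteem": -0.095,
    "technology": 0.080,
    "healthcare_experience": -0.078,
    "ease_getting_through": 0.514,
    "transport": 0.011,
}


def _default_a() -> dict[str, dict[str, float]]:
    a: dict[str, dict[str, float]] = {}
    for (ctx, mech), ind in _INDIRECT.items():
        a.setdefault(ctx, {})[mech] = ind / _B[mech]
    return a


@dataclass
class SyntheticConfig:
    """Generating truth for a linked two-level dataset.

    All path coefficients are standardized.  `a[context][mechanism]` are the
    context->mechanism coefficients, `b[mechanism]` the mechanism->outcome
    coefficients, `direct[context]` the context->outcome direct effects.
    """

    n_individuals: int = 276
    n_practices: int = 178
    a: dict = field(default_factory=_default_a)
    b: dict = field(default_factory=lambda: dict(_B))
    direct: dict = field(default_factory=lambda: dict(_DIRECT))
    loadings: dict = field(default_factory=_default_loadings)
    likert_thresholds: dict = field(default_factory=_default_likert_thresholds)
    practice_percent: dict = field(default_factory=_default_practice_percent)
    travel_time_median: float = 4.80
    travel_time_iqr: tuple = (2.76, 7.88)
    icc_individual: float = 0.05   # practice share of individual-level scores
    icc_gpps: float = 0.30         # practice share of endogenous percent vars
    missing_rate: float = 0.0
    demographics: bool = True
    seed: int | None = None

    # -- derived quantities -------------------------------------------------
    @property
    def travel_lognormal(self) -> tuple[float, float]:
        """(mu, sigma) solved from the printed median and IQR."""
        mu = math.log(self.travel_time_median)
        q1, q3 = self.travel_time_iqr
        sigma = math.log(q3 / q1) / (2 * norm.ppf(0.75))
        return mu, sigma

    def implied_effects(self) -> dict[str, dict[str, float]]:
        """Generating direct/indirect/total/proportion-mediated per context
        node and mechanism pairing."""
        out = {}
        for ctx, mechs in self.a.items():
            for mech, a in mechs.items():
                ind = a * self.b[mech]
                d = self.direct.get(ctx, 0.0)
                denom = abs(d) + abs(ind)
                out[f"{ctx}->{mech}"] = {
                    "a": a, "b": self.b[mech], "direct": d, "indirect": ind,
                    "total": d + ind,
                    "proportion_mediated": abs(ind) / denom if denom else None,
                }
        return out

    def validate(self) -> None:
        """Check the generating coefficients leave positive disturbance
        variances (positive-definite implied covariance)."""
        bad = []
        for mech in MECHANISMS:
            var_sys = sum(self.a.get(c, {}).get(mech, 0.0) ** 2
                          for c in CONTEXT_NODES)
            if var_sys >= 0.98:
                bad.append(f"mechanism {mech!r} explained variance {var_sys:.3f}")
        # outcome: generous bound ignoring (small) cross-covariances
        var_out = sum(v ** 2 for v in self.direct.values()) + \
            sum(v ** 2 for v in self.b.values()) + \
            2 * sum(abs(self.direct.get(c, 0.0)) *
                    abs(self.a.get(c, {}).get(m, 0.0)) * abs(self.b[m])
                    for c in CONTEXT_NODES for m in MECHANISMS)
        if var_out >= 0.98:
            bad.append(f"outcome explained variance {var_out:.3f}")
        if bad:
            raise ValueError(
                "generating coefficients imply a non-positive-definite "
                "covariance: " + "; ".join(bad))

    def scaled(self, n_individuals: int) -> "SyntheticConfig":
        """Same generating truth at a different sample size, keeping the
        fixture's mean cluster size (~276/178 individuals per practice)."""
        g = max(2, round(n_individuals * self.n_practices / self.n_individuals))
        return dataclasses.replace(self, n_individuals=n_individuals,
                                   n_practices=g)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["travel_time_iqr"] = list(self.travel_time_iqr)
        d["likert_thresholds"] = {k: list(v)
                                  for k, v in self.likert_thresholds.items()}
        d["loadings"] = {k: list(v) for k, v in self.loadings.items()}
        d["practice_percent"] = {k: list(v)
                                 for k, v in self.practice_percent.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["travel_time_iqr"] = tuple(d["travel_time_iqr"])
        d["likert_thresholds"] = {k: tuple(v)
                                  for k, v in d["likert_thresholds"].items()}
        d["loadings"] = {k: tuple(v) for k, v in d["loadings"].items()}
        d["practice_percent"] = {k: tuple(v)
                                 for k, v in d["practice_percent"].items()}
        return cls(**d)


def paper_fixture() -> SyntheticConfig:
    """The fixture parameterized to the published model: 178 practices, 276
    individuals, generating standardized direct effect 0.514 and indirect
    0.140 for the ease-of-getting-through CMO (proportion mediated 0.21)."""
    cfg = SyntheticConfig()
    cfg.validate()
    return cfg


def null_fixture() -> SyntheticConfig:
    """The fixture with every structural path set to zero (calibration)."""
    cfg = paper_fixture()
    zero_a = {c: {m: 0.0 for m in mechs} for c, mechs in cfg.a.items()}
    return dataclasses.replace(
        cfg, a=zero_a, b={m: 0.0 for m in cfg.b},
        direct={c: 0.0 for c in cfg.direct})


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def discretize_to_likert(values, thresholds) -> np.ndarray:
    """Map continuous values to ordinal codes 1..k via k-1 strictly
    increasing thresholds; code i iff value in (t_{i-1}, t_i] (right-closed:
    a value exactly at a threshold takes the lower category)."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    values = np.asarray(values, dtype=float)
    return np.searchsorted(thresholds, values, side="left") + 1


def _std(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def _clustered_noise(rng, assign, n_practices, icc) -> np.ndarray:
    """Unit-variance noise with a practice random-effect share `icc`."""
    u = rng.standard_normal(n_practices)[assign]
    e = rng.standard_normal(assign.size)
    return math.sqrt(icc) * u + math.sqrt(1.0 - icc) * e


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_linked_dataset(config: SyntheticConfig,
                            seed: int | None = None) -> ClusteredDataset:
    """Draw one linked dataset from the generating model.

    Reproducible: the same (config, seed) yields a bit-identical dataset.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n, g = config.n_individuals, config.n_practices
    if n < g:
        raise ValueError("need at least one individual per practice")

    # deterministic near-equal cluster sizes; every practice non-empty
    base, rem = divmod(n, g)
    sizes = np.full(g, base); sizes[:rem] += 1
    assign = np.repeat(np.arange(g), sizes)
    practice_id = np.array([f"p{k + 1:05d}" for k in assign])

    cols: dict[str, np.ndarray] = {"practice_id": practice_id}
    pp = config.practice_percent

    def to_percent(var, z):
        mean, sd = pp[var]
        return np.clip(mean + sd * z, 0.0, 100.0)

    # ---- exogenous contexts ------------------------------------------------
    x: dict[str, np.ndarray] = {}     # standardized structural scores

    # practice-level percents, constant within cluster
    clear_z = rng.standard_normal(g)[assign]
    ease_z = rng.standard_normal(g)[assign]
    cols["pct_know_ooh"] = to_percent("pct_know_ooh", clear_z)
    cols["pct_easy_get_through"] = to_percent("pct_easy_get_through", ease_z)
    x["clear_info"] = _std(cols["pct_know_ooh"])
    x["ease_getting_through"] = _std(cols["pct_easy_get_through"])

    # healthcare experience: practice-level reflective latent
    f_hce_p = rng.standard_normal(g)
    for lam, var in zip(config.loadings["healthcare_experience"], HCE_INDICATORS):
        eps = rng.standard_normal(g)
        y = lam * f_hce_p + math.sqrt(1 - lam ** 2) * eps
        cols[var] = to_percent(var, y[assign])
    x["healthcare_experience"] = _std(f_hce_p[assign])

    # education: multinomial category -> baseline-contrast dummies
    labels = list(EDUCATION_LEVELS)
    probs = np.array([EDUCATION_LEVELS[k][1] for k in labels])
    probs = probs / probs.sum()
    edu = rng.choice(len(labels), size=n, p=probs)
    cols["education"] = np.array([labels[k] for k in edu])
    for k, label in enumerate(labels):
        dummy = EDUCATION_LEVELS[label][0]
        if dummy is not None:
            d = (edu == k).astype(float)
            cols[dummy] = d
            x[dummy] = _std(d)

    # self-esteem: individual reflective latent with a practice effect
    f_se = _clustered_noise(rng, assign, g, config.icc_individual)
    for lam, var in zip(config.loadings["self_esteem"], SELF_ESTEEM_INDICATORS):
        y = lam * f_se + math.sqrt(1 - lam ** 2) * rng.standard_normal(n)
        cols[var] = discretize_to_likert(y, config.likert_thresholds[var]).astype(float)
    x["self_esteem"] = _std(f_se)

    # technology: ordinal internet-use code, used as the context score itself
    tech_z = _clustered_noise(rng, assign, g, config.icc_individual)
    cols["internet_use"] = discretize_to_likert(
        tech_z, config.likert_thresholds["internet_use"]).astype(float)
    x["technology"] = _std(cols["internet_use"])

    # transport: formative composite of lifts, travel time, public transport
    t0 = _clustered_noise(rng, assign, g, config.icc_individual)
    lifts_z = 0.6 * t0 + math.sqrt(1 - 0.36) * rng.standard_normal(n)
    pub_z = 0.5 * t0 + math.sqrt(1 - 0.25) * rng.standard_normal(n)
    trav_z = -0.4 * t0 + math.sqrt(1 - 0.16) * rng.standard_normal(n)
    mu, sigma = config.travel_lognormal
    cols["lifts_freq"] = discretize_to_likert(
        lifts_z, config.likert_thresholds["lifts_freq"]).astype(float)
    cols["public_transport_freq"] = discretize_to_likert(
        pub_z, config.likert_thresholds["public_transport_freq"]).astype(float)
    cols["travel_time_min"] = np.exp(mu + sigma * trav_z)
    composite = (0.45 * _std(cols["lifts_freq"])
                 + 0.45 * _std(cols["public_transport_freq"])
                 - 0.45 * _std(cols["travel_time_min"]))
    x["transport"] = _std(composite)

    # ---- mechanisms --------------------------------------------------------
    def systematic(coeffs: dict[str, float], scores: dict[str, np.ndarray]):
        s = np.zeros(n)
        for node, coef in coeffs.items():
            if coef != 0.0:
                s = s + coef * scores[node]
        return s

    m_scores: dict[str, np.ndarray] = {}

    def disturb(sys_part, icc, what):
        var_sys = sys_part.var()
        if var_sys >= 1.0:
            raise ValueError(
                f"generating coefficients for {what!r} explain >= 100% of "
                "variance; implied covariance not positive definite")
        d = _clustered_noise(rng, assign, g, icc)
        return sys_part + math.sqrt(1.0 - var_sys) * d

    a_of = {m: {c: config.a.get(c, {}).get(m, 0.0) for c in CONTEXT_NODES}
            for m in MECHANISMS}

    # health literacy: ordinal score; the observed code is the mechanism
    hl_star = disturb(systematic(a_of["health_literacy"], x),
                      config.icc_individual, "health_literacy")
    cols["health_literacy_score"] = discretize_to_likert(
        hl_star, config.likert_thresholds["health_literacy_score"]).astype(float)
    m_scores["health_literacy"] = _std(cols["health_literacy_score"])

    # assertiveness: individual latent, ordinal indicators
    ast_star = disturb(systematic(a_of["assertiveness"], x),
                       config.icc_individual, "assertiveness")
    sd_ast = ast_star.std()
    for lam, var in zip(config.loadings["assertiveness"], ASSERT_INDICATORS):
        y = lam * ast_star / sd_ast \
            + math.sqrt(1 - lam ** 2) * rng.standard_normal(n)
        cols[var] = discretize_to_likert(
            y, config.likert_thresholds[var]).astype(float)
    m_scores["assertiveness"] = _std(ast_star)

    # convenience: GPPS-style percent (individual variation + practice effect)
    conv_star = disturb(systematic(a_of["convenience"], x),
                        config.icc_gpps, "convenience")
    cols["pct_convenient"] = to_percent("pct_convenient", conv_star)
    m_scores["convenience"] = _std(cols["pct_convenient"])

    # ---- outcome -----------------------------------------------------------
    out_sys = systematic(config.direct, x) + systematic(config.b, m_scores)
    out_star = disturb(out_sys, config.icc_gpps, "outcome")
    cols["pct_get_appointment"] = to_percent("pct_get_appointment", out_star)

    # ---- cosmetic demographics (excluded from the model) -------------------
    categorical = {"education"}
    if config.demographics:
        cols["sex"] = np.where(rng.random(n) < 0.612, "female", "male")
        age_bands = ["50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80+"]
        age_p = np.array([11, 27, 57, 33, 65, 47, 35], dtype=float)
        cols["age_band"] = rng.choice(age_bands, size=n, p=age_p / age_p.sum())
        occ = ["routine", "semi_routine", "lower_supervisory", "small_employer"]
        occ_p = np.array([74, 134, 63, 3], dtype=float)
        cols["occupation"] = rng.choice(occ, size=n, p=occ_p / occ_p.sum())
        categorical |= {"sex", "age_band", "occupation"}

    frame = pd.DataFrame(cols)

    # MCAR missingness on the modelled numeric columns, per cell
    if config.missing_rate > 0:
        model_cols = [c for c in frame.columns
                      if c not in categorical and c != "practice_id"]
        mask = rng.random((n, len(model_cols))) < config.missing_rate
        block = frame[model_cols].to_numpy(dtype=float)
        block[mask] = np.nan
        frame[model_cols] = block

    return ClusteredDataset(frame, "practice_id",
                            ordinal=set(ORDINAL_VARS), categorical=categorical)


# ---------------------------------------------------------------------------
# the study's model configuration
# ---------------------------------------------------------------------------

def paper_model_cmos() -> list[CmoConfiguration]:
    """The nine CMO configurations of the study, bound to the generated
    variable names: three mechanisms (health literacy, assertiveness,
    convenience), seven distinct contexts, one outcome (obtaining an
    appointment)."""
    clear_info = ConceptBinding("clear_info", "observed", ("pct_know_ooh",))
    education = ConceptBinding(
        "education", "categorical",
        ("edu_alevel", "edu_olevel", "edu_cse", "edu_noqual"))
    self_esteem = ConceptBinding("self_esteem", "reflective",
                                 SELF_ESTEEM_INDICATORS)
    technology = ConceptBinding("technology", "observed", ("internet_use",))
    hce = ConceptBinding("healthcare_experience", "reflective", HCE_INDICATORS)
    ease = ConceptBinding("ease_getting_through", "observed",
                          ("pct_easy_get_through",))
    transport = ConceptBinding("transport", "formative", TRANSPORT_INDICATORS)
    hl = ConceptBinding("health_literacy", "observed",
                        ("health_literacy_score",))
    assertiveness = ConceptBinding("assertiveness", "reflective",
                                   ASSERT_INDICATORS)
    outcome = ConceptBinding("obtain_appointment", "observed",
                             ("pct_get_appointment",))
    convenience = ConceptBinding("convenience", "observed",
                                 ("pct_convenient",))
    pairs = [
        (clear_info, hl), (education, hl),
        (self_esteem, assertiveness), (clear_info, assertiveness),
        (technology, convenience), (hce, convenience),
        (ease, convenience), (transport, convenience),
        (clear_info, convenience),
    ]
    return [CmoConfiguration(context=c, mechanism=m, outcome=outcome)
            for c, m in pairs]
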