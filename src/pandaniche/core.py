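"""Household resource-use decisions and ecological-niche evaluation of giant
panda habitat under labor-force aging.

The pipeline models how rural households around giant panda nature reserves
decide on two habitat-disturbing resource-utilization patterns — cultivated
land use and fuelwood cutting — and maps those micro decisions onto a
village-level ecological-niche evaluation of habitat condition:

1.  **simulate** — draw a synthetic household survey (labor structure,
    resource-use quantities and revenues, perceptions, constraints), a
    community attribute table at two time points, a per-reserve panda-survey
    table and a community adjacency list, calibrated to the published
    summary statistics of the Sichuan reserve household survey the model was
    developed against.
2.  **decide** — a belief–aspiration–decision model per household: belief
    update from regulation perceptions, per-pattern importance from the
    value shares of the two utilization patterns, and a final intensity
    modulated by four factors (ecological value identity, social pressure,
    environmental constraints, labor literacy); aggregated per community and
    per age group (OAG = primary laborer >= 55 years, YAG otherwise).
3.  **evaluate** — a 4-dimension, 14-index evaluation matrix per
    community x age group with a *state* layer (baseline level) and a
    *potential* layer (five-year increment), coefficient-of-variation index
    weights, relative and comprehensive ecological niche widths (shares of
    the weighted resource/condition space) and pairwise Pianka niche
    overlaps between neighboring communities.
4.  **compare** — old-age-group vs young-adult-group width differences and
    overlap ratios, with the ratio classified as a positive difference
    (ratio in (0, 1): aging reduces ecological competition) or a negative
    difference (ratio > 1).

Everything is deterministic under a single root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

__all__ = [
    # errors
    "PandaNicheError", "InvalidSpecError", "InvalidParameterError",
    "DataError", "DegenerateColumnError",
    # config
    "VariableSpec", "ScenarioConfig", "DecisionConfig", "EvaluationConfig",
    "PipelineConfig", "DEFAULT_VARIABLE_SPECS",
    # calibration
    "calibrate_truncated_normal", "truncated_normal_max_sd",
    "calibrate_ordinal3", "max_sd_two_point",
    # synthetic data
    "generate_households", "generate_communities", "generate_panda_survey",
    "generate_adjacency", "generate_centroids_geojson", "simulate",
    # household decision model
    "classify_age_group", "update_belief", "pattern_importance",
    "factor_scores", "salience_weights", "factor_modulations",
    "final_decision", "household_decision_table", "aggregate_to_community",
    "decide",
    # niche evaluation
    "INDEX_COLUMNS", "INDEX_DIMENSIONS", "INDEX_DIRECTIONS", "IndexMatrix",
    "IndexWeights", "build_index_matrix", "standardize", "compute_weights",
    "adjusted_values", "relative_niche_width", "comprehensive_niche",
    "pianka_overlap", "niche_overlap", "overlap_table", "overlap_ratio",
    "evaluate",
    # pipeline
    "ComparisonReport", "compare_groups", "RunManifest", "run_all",
]

logger = logging.getLogger("pandaniche")

OAG = "OAG"
YAG = "YAG"
AGE_THRESHOLD = 55  # primary laborer age (years) separating OAG from YAG


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------

class PandaNicheError(Exception):
    """Base class for all pipeline errors."""


class InvalidSpecError(PandaNicheError):
    """A variable or scenario specification is inconsistent or infeasible."""


class InvalidParameterError(PandaNicheError):
    """A model parameter is outside its admissible range."""


class DataError(PandaNicheError):
    """Input data violate a structural requirement (missing key, zero
    denominator, empty table)."""


class DegenerateColumnError(DataError):
    """An index column is constant where variation is required."""


# --------------------------------------------------------------------------
# variable specifications and configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """Marginal distribution of one survey variable.

    kind is one of ``truncated_normal`` (moment-matched on [lower, upper]),
    ``bernoulli`` (success probability ``p``) or ``categorical`` (``values``
    with either explicit ``probs`` or, for 3-level ordinals, a target
    ``mean``/``sd`` matched in closed form).
    """

    kind: str
    mean: float | None = None
    sd: float | None = None
    lower: float | None = None
    upper: float | None = None
    p: float | None = None
    values: tuple | None = None
    probs: tuple | None = None
    integer: bool = False

    def validate(self, name: str = "?") -> None:
        if self.kind == "truncated_normal":
            if self.mean is None or self.sd is None or self.lower is None \
                    or self.upper is None:
                raise InvalidSpecError(f"{name}: truncated_normal needs "
                                       "mean, sd, lower, upper")
            if not self.lower < self.upper:
                raise InvalidSpecError(f"{name}: lower must be < upper")
            if not self.lower <= self.mean <= self.upper:
                raise InvalidSpecError(
                    f"{name}: mean {self.mean} outside "
                    f"[{self.lower}, {self.upper}]")
            if self.sd <= 0:
                raise InvalidSpecError(f"{name}: sd must be > 0")
        elif self.kind == "bernoulli":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise InvalidSpecError(f"{name}: bernoulli needs p in [0,1]")
        elif self.kind == "categorical":
            if self.values is None:
                raise InvalidSpecError(f"{name}: categorical needs values")
            if self.probs is not None:
                pr = np.asarray(self.probs, dtype=float)
                if len(pr) != len(self.values) or np.any(pr < 0) \
                        or abs(pr.sum() - 1.0) > 1e-9:
                    raise InvalidSpecError(f"{name}: invalid probs")
            elif self.mean is None or self.sd is None:
                raise InvalidSpecError(
                    f"{name}: categorical needs probs or mean+sd")
            elif tuple(self.values) != (1, 2, 3):
                raise InvalidSpecError(
                    f"{name}: mean/sd calibration implemented for the "
                    "3-level ordinal {1,2,3} only")
        else:
            raise InvalidSpecError(f"{name}: unknown kind {self.kind!r}")


def _tn(mean, sd, lower, upper, integer=False):
    return VariableSpec("truncated_normal", mean=mean, sd=sd, lower=lower,
                        upper=upper, integer=integer)


def _ord3(mean, sd):
    return VariableSpec("categorical", values=(1, 2, 3), mean=mean, sd=sd,
                        integer=True)


#: Default marginals. The aging-ratio, aging-share, ordinal, restriction and
#: distance rows reproduce the printed summary statistics (mean/SD/min/max)
#: of the 538-household Sichuan reserve survey; perception and quantity /
#: revenue variables, which the survey summary does not tabulate, use
#: realistic magnitudes for smallholder mountain agriculture (cropland in mu,
#: fuelwood in kg, revenues in CNY/yr) documented in docs/methods.md.
DEFAULT_VARIABLE_SPECS: dict[str, VariableSpec] = {
    "primary_laborer_age": _tn(50.0, 13.0, 18.0, 85.0, integer=True),
    "aging_ratio": _tn(0.289, 0.327, 0.0, 1.0),
    "aging_planting_share": _tn(0.478, 0.287, 0.0, 1.0),
    "aging_fuelwood_share": _tn(0.455, 0.281, 0.0, 1.0),
    "education_level": _ord3(1.271, 0.887),
    "health_level": _ord3(2.385, 1.439),
    "livelihood_type": _ord3(2.017, 0.620),
    "soil_quality": _ord3(1.704, 1.120),
    "land_fragmentation": _tn(0.733, 1.507, 0.0, 1.0),
    "fuel_slope": _ord3(2.617, 1.241),
    "fuel_restriction": VariableSpec("bernoulli", p=0.684),
    "fuel_distance_km": _tn(4.891, 4.247, 0.0, 16.0),
    "perception_planting_regulation": VariableSpec(
        "categorical", values=(1, 2, 3, 4, 5),
        probs=(0.05, 0.10, 0.20, 0.35, 0.30), integer=True),
    "perception_fuelwood_regulation": VariableSpec(
        "categorical", values=(1, 2, 3, 4, 5),
        probs=(0.04, 0.08, 0.18, 0.35, 0.35), integer=True),
    "UA_cropland": _tn(5.0, 3.0, 0.0, 15.0),
    "I_cropland": _tn(3000.0, 2000.0, 0.0, 20000.0),
    "UA_fuelwood": _tn(1500.0, 1000.0, 0.0, 6000.0),
    "I_fuelwood": _tn(800.0, 600.0, 0.0, 5000.0),
}


@dataclass
class ScenarioConfig:
    """Synthetic-survey scenario: sample sizes, seed and the aging effect.

    ``aging_effect`` multiplies the resource-use quantities (and hence the
    proportional revenues) of OAG households by ``1 - aging_effect``.
    """

    n_households: int = 538
    n_communities: int = 35
    n_reserves: int = 9
    households_per_community: int | None = None
    seed: int = 0
    aging_effect: float = 0.3
    period_years: int = 5
    age_threshold: int = AGE_THRESHOLD
    variable_specs: Mapping[str, VariableSpec] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLE_SPECS))

    def validate(self) -> None:
        if min(self.n_households, self.n_communities, self.n_reserves) < 1:
            raise InvalidSpecError("all counts must be >= 1")
        if self.n_communities < self.n_reserves:
            raise InvalidSpecError("need at least one community per reserve")
        if not 0.0 <= self.aging_effect <= 1.0:
            raise InvalidSpecError("aging_effect must be in [0, 1]")
        if self.period_years < 1:
            raise InvalidSpecError("period_years must be >= 1")
        if self.households_per_community is not None and (
                self.n_households
                != self.n_communities * self.households_per_community):
            raise InvalidSpecError(
                "n_households must equal n_communities * "
                "households_per_community when the latter is given")
        for name, spec in self.variable_specs.items():
            spec.validate(name)


@dataclass
class DecisionConfig:
    """Parameters of the household decision model.

    ``salience`` holds the non-negative factor saliences a_x for
    (ecological value identity, social pressure, environmental constraints,
    labor literacy); weights are a_x / sum(a_x).  ``modulation_signs`` maps
    each factor to -1 (modulation = 1 - score: the factor suppresses
    utilization) or +1 (modulation = score: the factor enables it).
    """

    smoothing: float = 0.5
    belief_prior: float = 0.5
    salience: tuple = (1.0, 1.0, 1.0, 1.0)
    modulation_signs: Mapping[str, int] = field(default_factory=lambda: {
        "ecological_value_identity": -1,
        "social_pressure": -1,
        "environmental_constraints": -1,
        "labor_literacy": +1,
    })
    scale_by_quantity: bool = True
    weighted_aggregation: bool = False
    age_threshold: int = AGE_THRESHOLD


@dataclass
class EvaluationConfig:
    """Parameters of the niche evaluation."""

    A: float = 1.0                 # state/potential conversion coefficient
    period_years: int = 5          # potential increments span this period
    eps: float = 1e-6              # lower bound of the rescaled columns
    standardization: str = "minmax"  # or "zscore_shifted"
    all_pairs: bool = False


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    write_geojson: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a JSON or YAML config with sections per stage."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text) or {}
        else:
            raw = json.loads(text) if text.strip() else {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        cfg = cls()
        scen = dict(raw.get("scenario", {}))
        vspecs = scen.pop("variable_specs", None)
        if vspecs is not None:
            merged = dict(DEFAULT_VARIABLE_SPECS)
            for name, d in vspecs.items():
                merged[name] = VariableSpec(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d.items()})
            scen["variable_specs"] = merged
        cfg.scenario = dataclasses.replace(cfg.scenario, **scen)
        dec = dict(raw.get("decision", {}))
        if "salience" in dec:
            dec["salience"] = tuple(dec["salience"])
        cfg.decision = dataclasses.replace(cfg.decision, **dec)
        cfg.evaluation = dataclasses.replace(
            cfg.evaluation, **raw.get("evaluation", {}))
        cfg.write_geojson = raw.get("write_geojson", cfg.write_geojson)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["variable_specs"] = {
            k: dataclasses.asdict(v)
            for k, v in self.scenario.variable_specs.items()}
        return d


def _substream(seed: int, *tokens) -> np.random.Generator:
    """Independent, order-insensitive RNG substream keyed by string tokens,
    so adding a variable never perturbs the draws of the others."""
    key = [zlib.crc32(str(t).encode("utf-8")) for t in tokens]
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


# --------------------------------------------------------------------------
# distribution calibration
# --------------------------------------------------------------------------

def max_sd_two_point(mean: float, lower: float, upper: float) -> float:
    """Largest standard deviation of *any* distribution on [lower, upper]
    with the given mean (attained by the two-point mass on the endpoints)."""
    return float(np.sqrt((mean - lower) * (upper - mean)))


def _trunc_moments(mu: float, sigma: float, lower: float, upper: float):
    a, b = (lower - mu) / sigma, (upper - mu) / sigma
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(max(float(v), 0.0)))


def _mu_for_mean(mean, sigma, lower, upper):
    # In the large-sigma limit the truncated density is log-linear with
    # slope mu/sigma^2, so the bracket for mu must widen like sigma^2.
    w = 10.0 * max(sigma, upper - lower) + 40.0 * sigma**2 / (upper - lower)
    return brentq(lambda mu: _trunc_moments(mu, sigma, lower, upper)[0] - mean,
                  lower - w, upper + w, xtol=1e-13, maxiter=200)


_SIGMA_CAP_FACTOR = 10.0  # sd(sigma) has converged to its supremum here


def truncated_normal_max_sd(mean: float, lower: float, upper: float) -> float:
    """Supremum of the sd attainable by a truncated normal on
    [lower, upper] with the given post-truncation mean (log-linear limit)."""
    cap = _SIGMA_CAP_FACTOR * (upper - lower)
    mu = _mu_for_mean(mean, cap, lower, upper)
    return _trunc_moments(mu, cap, lower, upper)[1]


def calibrate_truncated_normal(mean: float, sd: float, lower: float,
                               upper: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose truncation to [lower, upper] has the
    requested post-truncation mean and sd.

    The mean is always matched (to ~1e-9).  If the requested sd exceeds the
    supremum attainable by the truncated-normal family at that mean, sigma
    is set to the supremum's limit and a warning is emitted; the realized sd
    is then the largest feasible one.
    """
    _tn(mean, sd, lower, upper).validate("truncated_normal")
    span = upper - lower
    if mean <= lower or mean >= upper:
        # boundary mean: only the degenerate spike is compatible
        warnings.warn("mean on the support boundary: using a degenerate "
                      "near-spike distribution", stacklevel=2)
        return float(mean), 1e-9 * span
    if sd <= 1e-7 * span:
        return float(mean), max(float(sd), 1e-12 * span)
    sig_hi = _SIGMA_CAP_FACTOR * span
    sd_hi = _trunc_moments(_mu_for_mean(mean, sig_hi, lower, upper),
                           sig_hi, lower, upper)[1]
    if sd >= sd_hi:
        if sd > sd_hi * (1 + 1e-9):
            warnings.warn(
                f"requested sd {sd:g} infeasible for a truncated normal on "
                f"[{lower:g}, {upper:g}] with mean {mean:g}; clipped to the "
                f"feasible maximum {sd_hi:g}", stacklevel=2)
        mu = _mu_for_mean(mean, sig_hi, lower, upper)
        return float(mu), float(sig_hi)

    def sd_err(log_sigma):
        sigma = float(np.exp(log_sigma))
        mu = _mu_for_mean(mean, sigma, lower, upper)
        return _trunc_moments(mu, sigma, lower, upper)[1] - sd

    lo = np.log(max(sd * 1e-2, 1e-9 * span))
    log_sigma = brentq(sd_err, lo, np.log(sig_hi), xtol=1e-12, maxiter=200)
    sigma = float(np.exp(log_sigma))
    return float(_mu_for_mean(mean, sigma, lower, upper)), sigma


def calibrate_ordinal3(mean: float, sd: float) -> tuple[float, float, float]:
    """Probabilities (p1, p2, p3) on {1, 2, 3} with the exact target mean
    and the closest feasible sd.

    With the mean fixed, Var = (4*mean - 3 - mean^2) - p2, so p2 is solved
    in closed form and clipped to its feasible interval; clipping (an
    infeasible printed sd) emits a warning.
    """
    if not 1.0 <= mean <= 3.0:
        raise InvalidSpecError(f"ordinal mean {mean} outside [1, 3]")
    if sd < 0:
        raise InvalidSpecError("sd must be >= 0")
    var_max = 4.0 * mean - 3.0 - mean**2          # p2 = 0 (mass on {1, 3})
    p2_hi = min(mean - 1.0, 3.0 - mean)           # largest admissible p2
    p2 = var_max - sd**2
    if p2 < 0.0 or p2 > p2_hi:
        clipped = float(np.clip(p2, 0.0, p2_hi))
        realized = float(np.sqrt(max(var_max - clipped, 0.0)))
        warnings.warn(
            f"ordinal sd {sd:g} infeasible on {{1,2,3}} at mean {mean:g}; "
            f"using closest feasible sd {realized:g}", stacklevel=2)
        p2 = clipped
    p3 = (mean - 1.0 - p2) / 2.0
    p1 = 1.0 - p2 - p3
    return float(p1), float(p2), float(p3)


_CALIBRATION_CACHE: dict[tuple, tuple] = {}


def _calibrated(spec: VariableSpec, name: str):
    key = (name, spec.kind, spec.mean, spec.sd, spec.lower, spec.upper,
           spec.p, spec.values, spec.probs)
    if key not in _CALIBRATION_CACHE:
        if spec.kind == "truncated_normal":
            _CALIBRATION_CACHE[key] = calibrate_truncated_normal(
                spec.mean, spec.sd, spec.lower, spec.upper)
        elif spec.kind == "categorical" and spec.probs is None:
            _CALIBRATION_CACHE[key] = calibrate_ordinal3(spec.mean, spec.sd)
        else:
            _CALIBRATION_CACHE[key] = ()
    return _CALIBRATION_CACHE[key]


def _draw(spec: VariableSpec, n: int, rng: np.random.Generator,
          name: str = "?") -> np.ndarray:
    spec.validate(name)
    if spec.kind == "truncated_normal":
        mu, sigma = _calibrated(spec, name)
        a = (spec.lower - mu) / sigma
        b = (spec.upper - mu) / sigma
        x = sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n,
                              random_state=rng)
        x = np.clip(x, spec.lower, spec.upper)
        return np.rint(x).astype(int) if spec.integer else x
    if spec.kind == "bernoulli":
        return (rng.random(n) < spec.p).astype(int)
    probs = spec.probs if spec.probs is not None else _calibrated(spec, name)
    vals = np.asarray(spec.values)
    out = rng.choice(vals, size=n, p=np.asarray(probs, dtype=float))
    return out.astype(int) if spec.integer else out


# --------------------------------------------------------------------------
# synthetic survey generation
# --------------------------------------------------------------------------

def _even_split(total: int, groups: int) -> np.ndarray:
    """Deterministic near-even group sizes summing to total."""
    base, extra = divmod(total, groups)
    return np.array([base + (1 if g < extra else 0) for g in range(groups)])


def _community_ids(n: int) -> list[str]:
    return [f"C{i + 1:02d}" for i in range(n)]


def _reserve_ids(n: int) -> list[str]:
    return [f"R{i + 1}" for i in range(n)]


def _community_reserve_map(config: ScenarioConfig) -> pd.DataFrame:
    sizes = _even_split(config.n_communities, config.n_reserves)
    rid = np.repeat(_reserve_ids(config.n_reserves), sizes)
    return pd.DataFrame({"community_id": _community_ids(config.n_communities),
                         "reserve_id": rid})


def generate_households(config: ScenarioConfig) -> pd.DataFrame:
    """Synthetic household questionnaire table.

    Every variable is drawn from its (calibrated) marginal in an
    independent seeded substream.  Non-agricultural households (livelihood
    type 3) have zero resource-use quantities; OAG households (primary
    laborer age >= ``age_threshold``) have quantities and proportional
    revenues scaled by ``1 - aging_effect``.
    """
    config.validate()
    n = config.n_households
    sizes = (_even_split(n, config.n_communities)
             if config.households_per_community is None
             else np.full(config.n_communities,
                          config.households_per_community))
    cols: dict[str, np.ndarray] = {
        "household_id": np.array([f"H{i + 1:04d}" for i in range(n)]),
        "community_id": np.repeat(_community_ids(config.n_communities),
                                  sizes),
    }
    for name, spec in config.variable_specs.items():
        rng = _substream(config.seed, "households", name)
        cols[name] = _draw(spec, n, rng, name)
    df = pd.DataFrame(cols)

    nonfarm = df["livelihood_type"] == 3
    for c in ("UA_cropland", "UA_fuelwood", "I_cropland", "I_fuelwood"):
        df.loc[nonfarm, c] = 0.0
    oag = df["primary_laborer_age"] >= config.age_threshold
    shrink = 1.0 - config.aging_effect
    for c in ("UA_cropland", "UA_fuelwood", "I_cropland", "I_fuelwood"):
        df.loc[oag, c] = df.loc[oag, c] * shrink
    return df


def generate_communities(config: ScenarioConfig) -> pd.DataFrame:
    """Community attribute table with 2013 and 2018 layers.

    Land, labor and population magnitudes are plausible for mountain
    villages (areas in hm^2, people counts); the 2018 layer applies small
    drifts consistent with cropland abandonment, forest recovery and labor
    out-migration.  Structural ratios (available <= total, labor <=
    population) hold in both layers.
    """
    config.validate()
    nc = config.n_communities
    base = _community_reserve_map(config)

    def tn(name, mean, sd, lo, hi):
        return _draw(_tn(mean, sd, lo, hi), nc,
                     _substream(config.seed, "communities", name), name)

    tacl = tn("TACL", 300.0, 100.0, 50.0, 800.0)
    aacl = tacl * tn("AACL_frac", 0.60, 0.15, 0.20, 0.95)
    tafl = tn("TAFL", 1200.0, 400.0, 200.0, 3000.0)
    aafl = tafl * tn("AAFL_frac", 0.35, 0.10, 0.05, 0.80)
    tpr = np.rint(tn("TPR", 900.0, 300.0, 200.0, 2000.0)).astype(int)
    lfqh = np.rint(tpr * tn("LFQH_frac", 0.45, 0.10, 0.15, 0.80)).astype(int)

    def drift(name, mean, sd):
        rng = _substream(config.seed, "communities", "drift", name)
        return rng.normal(mean, sd, nc)

    out = base.copy()
    out["inside_reserve"] = (np.arange(nc) % 2 == 0).astype(int)
    out["TACL_2013"] = tacl
    out["TACL_2018"] = tacl * (1.0 + np.clip(drift("TACL", -0.06, 0.03),
                                             -0.5, 0.5))
    out["AACL_2013"] = aacl
    out["AACL_2018"] = np.minimum(
        aacl * (1.0 + np.clip(drift("AACL", -0.10, 0.04), -0.6, 0.5)),
        out["TACL_2018"])
    out["TAFL_2013"] = tafl
    out["TAFL_2018"] = tafl * (1.0 + np.clip(drift("TAFL", 0.02, 0.02),
                                             -0.3, 0.3))
    out["AAFL_2013"] = aafl
    out["AAFL_2018"] = np.minimum(
        aafl * (1.0 + np.clip(drift("AAFL", -0.05, 0.03), -0.5, 0.5)),
        out["TAFL_2018"])
    out["TPR_2013"] = tpr
    out["TPR_2018"] = np.rint(tpr * (1.0 + np.clip(
        drift("TPR", -0.03, 0.02), -0.3, 0.3))).astype(int)
    out["LFQH_2013"] = np.minimum(lfqh, tpr)
    out["LFQH_2018"] = np.minimum(
        np.rint(lfqh * (1.0 + np.clip(drift("LFQH", -0.08, 0.04),
                                      -0.5, 0.3))).astype(int),
        out["TPR_2018"])
    # constraint-dimension change rates (fractions of the five-year change)
    for name, mean, sd in (("x8", 0.25, 0.12), ("x9", 0.30, 0.15),
                           ("x10", 0.35, 0.15)):
        v13 = tn(name, mean, sd, 0.0, 1.0)
        out[f"{name}_2013"] = v13
        out[f"{name}_2018"] = np.clip(
            v13 + drift(name, 0.05, 0.05), 0.0, 1.0)
    return out


def generate_panda_survey(config: ScenarioConfig) -> pd.DataFrame:
    """Per-reserve panda survey table: habitat area and wild population at
    the 3rd and 4th national surveys, staple-food bamboo and reserve area."""
    config.validate()
    nr = config.n_reserves

    def tn(name, mean, sd, lo, hi):
        return _draw(_tn(mean, sd, lo, hi), nr,
                     _substream(config.seed, "panda_survey", name), name)

    agph3 = tn("AGPH3rd", 30000.0, 12000.0, 5000.0, 80000.0)
    habitat_rate = tn("habitat_rate", 0.12, 0.08, -0.20, 0.50)
    pgph3 = np.rint(tn("PGPH3rd", 30.0, 12.0, 5.0, 80.0)).astype(int)
    pop_rate = tn("pop_rate", 0.15, 0.10, -0.30, 0.60)
    anr = tn("ANR", 40000.0, 15000.0, 8000.0, 100000.0)
    asfb = anr * tn("ASFB_frac", 0.35, 0.10, 0.05, 0.80)
    return pd.DataFrame({
        "reserve_id": _reserve_ids(nr),
        "AGPH3rd": agph3,
        "AGPH4th": agph3 * (1.0 + habitat_rate),
        "PGPH3rd": pgph3,
        "PGPH4th": np.maximum(np.rint(pgph3 * (1.0 + pop_rate)), 1.0
                              ).astype(int),
        "ASFB": asfb,
        "ANR": anr,
    })


def generate_adjacency(config: ScenarioConfig) -> pd.DataFrame:
    """Undirected neighbor pairs: a ring over the communities of each
    reserve (every community borders its neighbors within the reserve)."""
    config.validate()
    cmap = _community_reserve_map(config)
    pairs = []
    for _, grp in cmap.groupby("reserve_id", sort=False):
        ids = list(grp["community_id"])
        if len(ids) < 2:
            continue
        edges = [(ids[i], ids[i + 1]) for i in range(len(ids) - 1)]
        if len(ids) > 2:
            edges.append((ids[0], ids[-1]))
        pairs.extend(tuple(sorted(e)) for e in edges)
    pairs = sorted(set(pairs))
    return pd.DataFrame(pairs, columns=["community_a", "community_b"])


def generate_centroids_geojson(config: ScenarioConfig) -> dict:
    """Point centroids per community (synthetic coordinates in Sichuan's
    lon/lat range), clustered around a per-reserve center."""
    config.validate()
    cmap = _community_reserve_map(config)
    rng = _substream(config.seed, "centroids")
    centers = {rid: (102.0 + rng.uniform(-1.5, 1.5),
                     30.5 + rng.uniform(-1.5, 1.5))
               for rid in _reserve_ids(config.n_reserves)}
    features = []
    for _, row in cmap.iterrows():
        cx, cy = centers[row["reserve_id"]]
        lon = cx + rng.uniform(-0.15, 0.15)
        lat = cy + rng.uniform(-0.15, 0.15)
        features.append({
            "type": "Feature",
            "properties": {"community_id": row["community_id"],
                           "reserve_id": row["reserve_id"]},
            "geometry": {"type": "Point",
                         "coordinates": [round(lon, 6), round(lat, 6)]},
        })
    return {"type": "FeatureCollection", "features": features}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def simulate(config: ScenarioConfig, out_dir: str | Path,
             write_geojson: bool = True) -> dict[str, Path]:
    """Generate and write all survey tables; returns the file map."""
    # fresh calibration so emitted warnings do not depend on process history
    _CALIBRATION_CACHE.clear()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in (("households", generate_households(config)),
                     ("communities", generate_communities(config)),
                     ("panda_survey", generate_panda_survey(config)),
                     ("adjacency", generate_adjacency(config))):
        path = out / f"{name}.csv"
        _write_csv(df, path)
        files[name] = path
    if write_geojson:
        path = out / "communities.geojson"
        path.write_text(json.dumps(generate_centroids_geojson(config),
                                   indent=1) + "\n", encoding="utf-8")
        files["centroids"] = path
    return files


# --------------------------------------------------------------------------
# household decision model
# --------------------------------------------------------------------------

FACTORS = ("ecological_value_identity", "social_pressure",
           "environmental_constraints", "labor_literacy")
PATTERNS = ("cropland", "fuelwood")


def classify_age_group(age, threshold: int = AGE_THRESHOLD):
    """OAG if the primary laborer is ``threshold`` years or older, else YAG."""
    arr = np.asarray(age, dtype=float)
    if np.any(np.isnan(arr)):
        raise DataError("primary laborer age missing")
    out = np.where(arr >= threshold, OAG, YAG)
    return out.item() if np.isscalar(age) or arr.ndim == 0 else out


def update_belief(belief, perception, smoothing: float = 0.5):
    """One exponential-smoothing step of the household belief: the cognition
    of the resource-use state under reserve regulation is pulled toward the
    current regulation perception."""
    if not 0.0 <= smoothing <= 1.0:
        raise InvalidParameterError("smoothing must be in [0, 1]")
    b = np.asarray(belief, dtype=float)
    p = np.asarray(perception, dtype=float)
    if np.any((b < 0) | (b > 1)) or np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("belief and perception must be in [0, 1]")
    out = smoothing * p + (1.0 - smoothing) * b
    return float(out) if out.ndim == 0 else out


def pattern_importance(ua, revenue):
    """Within-household importance share of each utilization pattern:
    value share UA_k * I_k / sum_k UA_k * I_k.

    Returns ``(importance, no_utilization)``; a household with zero total
    value (a valid non-utilizing observation) gets zero shares and the flag.
    """
    ua = np.asarray(ua, dtype=float)
    rev = np.asarray(revenue, dtype=float)
    if np.any(ua < 0) or np.any(rev < 0):
        raise InvalidParameterError("quantities and revenues must be >= 0")
    value = ua * rev
    total = value.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        imp = np.where(total > 0, value / np.where(total > 0, total, 1.0),
                       0.0)
    flag = np.squeeze(total, axis=-1) == 0
    return imp, (bool(flag) if flag.ndim == 0 else flag)


def factor_scores(households: pd.DataFrame, belief) -> pd.DataFrame:
    """Four decision-factor scores in [0, 1] per household.

    * ecological value identity — the (updated) belief itself;
    * social pressure — mean of the two regulation perceptions rescaled
      from [1, 5] to [0, 1];
    * environmental constraints — mean of inverted soil quality,
      fragmentation, slope, the restriction flag and relative distance;
    * labor literacy — mean of rescaled education and health.
    """
    h = households
    belief = np.broadcast_to(np.asarray(belief, dtype=float), (len(h),))
    pressure = ((h["perception_planting_regulation"].to_numpy() - 1.0) / 4.0
                + (h["perception_fuelwood_regulation"].to_numpy() - 1.0)
                / 4.0) / 2.0
    constraints = (
        (3.0 - h["soil_quality"].to_numpy()) / 2.0
        + np.clip(h["land_fragmentation"].to_numpy(), 0.0, 1.0)
        + (h["fuel_slope"].to_numpy() - 1.0) / 2.0
        + h["fuel_restriction"].to_numpy().astype(float)
        + h["fuel_distance_km"].to_numpy() / 16.0) / 5.0
    literacy = ((h["education_level"].to_numpy() - 1.0) / 2.0
                + (h["health_level"].to_numpy() - 1.0) / 2.0) / 2.0
    out = pd.DataFrame({
        "ecological_value_identity": belief,
        "social_pressure": pressure,
        "environmental_constraints": constraints,
        "labor_literacy": literacy,
    }, index=h.index)
    bad = [c for c in out if ((out[c] < -1e-12) | (out[c] > 1 + 1e-12)).any()]
    if bad:
        raise DataError(f"factor scores outside [0, 1]: {bad}")
    return out.clip(0.0, 1.0)


def salience_weights(salience) -> np.ndarray:
    """Normalized factor weights w_x = a_x / sum(a_x)."""
    a = np.asarray(salience, dtype=float)
    if a.shape != (4,) or np.any(a < 0):
        raise InvalidParameterError("salience must be four values >= 0")
    total = a.sum()
    if total == 0:
        raise InvalidParameterError("invalid salience: all a_x are zero")
    return a / total


def factor_modulations(scores: pd.DataFrame,
                       signs: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Per-factor modulation m_x: ``1 - score`` for suppressing factors
    (sign -1), ``score`` for enabling factors (sign +1), 1 for sign 0."""
    signs = dict(signs) if signs is not None else \
        dict(DecisionConfig().modulation_signs)
    out = {}
    for f in FACTORS:
        s = signs.get(f, 0)
        col = scores[f].to_numpy(dtype=float)
        out[f] = 1.0 - col if s < 0 else (col if s > 0
                                          else np.ones_like(col))
    return pd.DataFrame(out, index=scores.index)


def final_decision(importance, modulations, salience=(1.0, 1.0, 1.0, 1.0)):
    """Final per-pattern intensity: the importance share damped by the
    salience-weighted mean of the factor modulations,
    ``final_k = (sum_x w_x m_x) * importance_k``.

    With all modulations equal to 1 the output equals the importance (the
    degenerate weighted-sum reading with weights summing to one).
    """
    w = salience_weights(salience)
    m = np.asarray(modulations, dtype=float)
    if np.any((m < -1e-12) | (m > 1 + 1e-12)):
        raise InvalidParameterError("modulations must be in [0, 1]")
    damp = np.clip(m, 0.0, 1.0) @ w
    return np.asarray(importance, dtype=float) * damp[..., None]


def household_decision_table(households: pd.DataFrame,
                             cfg: DecisionConfig | None = None
                             ) -> pd.DataFrame:
    """Per-household decision table at the current step (state) and after
    one belief update (next).

    The aggregation-ready intensity is the final modulated share scaled by
    the household's relative physical utilization (quantity / sample
    maximum), so that an aging-induced quantity reduction propagates to the
    community level.
    """
    cfg = cfg or DecisionConfig()
    h = households.reset_index(drop=True)
    if len(h) == 0:
        raise DataError("empty household table")
    perception = ((h["perception_planting_regulation"].to_numpy() - 1.0)
                  / 4.0 / 2.0
                  + (h["perception_fuelwood_regulation"].to_numpy() - 1.0)
                  / 4.0 / 2.0)
    belief_state = np.full(len(h), float(cfg.belief_prior))
    belief_next = update_belief(belief_state, perception, cfg.smoothing)

    ua = h[["UA_cropland", "UA_fuelwood"]].to_numpy(dtype=float)
    rev = h[["I_cropland", "I_fuelwood"]].to_numpy(dtype=float)
    importance, no_util = pattern_importance(ua, rev)

    out = pd.DataFrame({
        "household_id": h["household_id"],
        "community_id": h["community_id"],
        "age_group": classify_age_group(
            h["primary_laborer_age"].to_numpy(), cfg.age_threshold),
        "no_utilization": no_util,
    })
    ua_max = ua.max(axis=0)
    scale = (ua / np.where(ua_max > 0, ua_max, 1.0)
             if cfg.scale_by_quantity else np.ones_like(ua))
    for step, belief in (("state", belief_state), ("next", belief_next)):
        scores = factor_scores(h, belief)
        final = final_decision(importance,
                               factor_modulations(scores,
                                                  cfg.modulation_signs),
                               cfg.salience)
        intensity = final * scale
        for k, pat in enumerate(PATTERNS):
            out[f"importance_{pat}"] = importance[:, k]
            out[f"final_{pat}_{step}"] = final[:, k]
            out[f"intensity_{pat}_{step}"] = intensity[:, k]
    out["ua_total_value"] = (ua * rev).sum(axis=1)
    return out


def aggregate_to_community(decisions: pd.DataFrame, group: str,
                           value_cols: Sequence[str],
                           weight_col: str | None = None) -> pd.DataFrame:
    """Community-level mean of per-household intensities for one age group.

    Communities present in the table but without members of the group get
    missing values.  With ``weight_col`` the mean is weighted (zero total
    weight falls back to the unweighted mean).
    """
    if len(decisions) == 0:
        raise DataError("empty decision table")
    sub = decisions[decisions["age_group"] == group]
    all_comm = pd.Index(decisions["community_id"].unique(),
                        name="community_id")
    if weight_col is None:
        agg = sub.groupby("community_id")[list(value_cols)].mean()
    else:
        def wmean(g):
            w = g[weight_col].to_numpy(dtype=float)
            vals = g[list(value_cols)].to_numpy(dtype=float)
            if w.sum() <= 0:
                return pd.Series(vals.mean(axis=0), index=list(value_cols))
            return pd.Series((vals * w[:, None]).sum(axis=0) / w.sum(),
                             index=list(value_cols))
        agg = sub.groupby("community_id").apply(wmean, include_groups=False)
    agg["n_households"] = sub.groupby("community_id").size()
    agg = agg.reindex(all_comm)
    agg["n_households"] = agg["n_households"].fillna(0).astype(int)
    agg.insert(0, "age_group", group)
    return agg.reset_index()


def decide(households: pd.DataFrame, cfg: DecisionConfig | None = None
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the decision model; returns the household-level table and the
    community x age-group decision table with x1 (cropland) and x2
    (fuelwood) state values and five-year potentials."""
    cfg = cfg or DecisionConfig()
    decisions = household_decision_table(households, cfg)
    value_cols = [f"intensity_{p}_{s}" for p in PATTERNS
                  for s in ("state", "next")]
    weight = "ua_total_value" if cfg.weighted_aggregation else None
    parts = [aggregate_to_community(decisions, g, value_cols, weight)
             for g in (OAG, YAG)]
    comm = pd.concat(parts, ignore_index=True)
    for xi, pat in (("x1", "cropland"), ("x2", "fuelwood")):
        comm[f"{xi}_state"] = comm[f"intensity_{pat}_state"]
        comm[f"{xi}_potential"] = (comm[f"intensity_{pat}_next"]
                                   - comm[f"intensity_{pat}_state"])
    keep = ["community_id", "age_group", "n_households",
            "x1_state", "x1_potential", "x2_state", "x2_potential"]
    return decisions, comm[keep]


# --------------------------------------------------------------------------
# niche evaluation: index system
# --------------------------------------------------------------------------

INDEX_COLUMNS = tuple(f"x{i}" for i in range(1, 15))

#: Dimensions of the evaluation space: resource-utilization strength (X1),
#: support (X2), constraint (X3) and panda sustainable-habitat level (X4).
INDEX_DIMENSIONS: dict[str, tuple[str, ...]] = {
    "X1": ("x1", "x2"),
    "X2": ("x3", "x4", "x5"),
    "X3": ("x6", "x7", "x8", "x9", "x10"),
    "X4": ("x11", "x12", "x13", "x14"),
}

#: Orientation toward habitat level: -1 for cost-type indexes (more
#: utilization = lower habitat level), +1 for benefit-type indexes.
INDEX_DIRECTIONS: dict[str, int] = {
    **{x: 1 for x in INDEX_COLUMNS}, "x1": -1, "x2": -1}


@dataclass
class IndexMatrix:
    """State and potential layers of the 14-index evaluation matrix.

    Rows are (community_id, age_group) evaluation units; the two layers
    share the same index and columns x1..x14.
    """

    state: pd.DataFrame
    potential: pd.DataFrame
    dimensions: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(INDEX_DIMENSIONS))
    directions: Mapping[str, int] = field(
        default_factory=lambda: dict(INDEX_DIRECTIONS))

    def validate(self) -> None:
        for layer in (self.state, self.potential):
            if list(layer.columns) != list(INDEX_COLUMNS):
                raise DataError("index matrix must have columns x1..x14")
        if not self.state.index.equals(self.potential.index):
            raise DataError("state and potential layers must share rows")
        if self.state.isna().any().any() or self.potential.isna().any().any():
            raise DataError("index matrix contains missing values")


@dataclass
class IndexWeights:
    """Coefficient-of-variation index weights and dimension weights."""

    V: pd.Series        # per-index coefficient of variation
    W: pd.Series        # normalized index weights, sum to 1
    w_d: pd.Series      # dimension weights (sums of member W), sum to 1


def _require_nonzero(values: pd.Series, what: str) -> None:
    bad = values.index[np.asarray(values, dtype=float) == 0]
    if len(bad):
        raise DataError(f"zero denominator {what} for {list(bad)[:5]}")


def build_index_matrix(community_decisions: pd.DataFrame,
                       communities: pd.DataFrame,
                       panda_survey: pd.DataFrame,
                       households: pd.DataFrame) -> IndexMatrix:
    """Assemble the community x age-group evaluation matrix.

    x1/x2 come from the decision model per group; x3-x5 and x8-x10 from the
    community table (ratios and change-rate fields at 2013 and 2018);
    x6/x7 are community mean regulation perceptions; x11-x14 broadcast the
    reserve-level panda-survey ratios to member communities.  Cross-sectional
    indexes (x6, x7, x11-x14) have zero potential.
    """
    comm = communities.set_index("community_id")
    for col in ("TACL_2013", "TACL_2018", "TAFL_2013", "TAFL_2018",
                "TPR_2013", "TPR_2018"):
        _require_nonzero(comm[col], col)
    ps = panda_survey.set_index("reserve_id")
    for col in ("AGPH3rd", "PGPH3rd", "ANR", "PGPH4th"):
        _require_nonzero(ps[col], col)

    cd = community_decisions.dropna(subset=["x1_state", "x2_state"])
    dropped = len(community_decisions) - len(cd)
    if dropped:
        logger.warning("dropped %d community x group rows without members",
                       dropped)
    if len(cd) == 0:
        raise DataError("no community decisions available")
    units = pd.MultiIndex.from_frame(cd[["community_id", "age_group"]])

    state = pd.DataFrame(index=units, columns=list(INDEX_COLUMNS),
                         dtype=float)
    pot = state.copy()
    cids = units.get_level_values("community_id")

    state["x1"] = cd["x1_state"].to_numpy()
    pot["x1"] = cd["x1_potential"].to_numpy()
    state["x2"] = cd["x2_state"].to_numpy()
    pot["x2"] = cd["x2_potential"].to_numpy()

    ratios = {
        "x3": ("AACL", "TACL"), "x4": ("AAFL", "TAFL"), "x5": ("LFQH", "TPR"),
    }
    for xi, (num, den) in ratios.items():
        r13 = comm[f"{num}_2013"] / comm[f"{den}_2013"]
        r18 = comm[f"{num}_2018"] / comm[f"{den}_2018"]
        state[xi] = r13.reindex(cids).to_numpy()
        pot[xi] = (r18 - r13).reindex(cids).to_numpy()

    perc = households.groupby("community_id")[
        ["perception_planting_regulation",
         "perception_fuelwood_regulation"]].mean()
    state["x6"] = perc["perception_planting_regulation"].reindex(
        cids).to_numpy()
    state["x7"] = perc["perception_fuelwood_regulation"].reindex(
        cids).to_numpy()
    pot[["x6", "x7"]] = 0.0

    for xi in ("x8", "x9", "x10"):
        state[xi] = comm[f"{xi}_2013"].reindex(cids).to_numpy()
        pot[xi] = (comm[f"{xi}_2018"]
                   - comm[f"{xi}_2013"]).reindex(cids).to_numpy()

    reserve_of = comm["reserve_id"].reindex(cids).to_numpy()
    x4vals = pd.DataFrame({
        "x11": (ps["AGPH4th"] - ps["AGPH3rd"]) / ps["AGPH3rd"],
        "x12": (ps["PGPH4th"] - ps["PGPH3rd"]) / ps["PGPH3rd"],
        "x13": ps["ASFB"] / ps["ANR"],
        "x14": ps["ASFB"] / ps["PGPH4th"],
    })
    for xi in ("x11", "x12", "x13", "x14"):
        state[xi] = x4vals[xi].reindex(reserve_of).to_numpy()
        pot[xi] = 0.0

    matrix = IndexMatrix(state=state, potential=pot)
    matrix.validate()
    return matrix


# --------------------------------------------------------------------------
# niche evaluation: standardization, weights, widths, overlaps
# --------------------------------------------------------------------------

def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores (sample SD, n-1 denominator)."""
    if len(df) < 2:
        raise DataError("standardization needs at least two rows")
    if df.isna().any().any():
        raise DataError("missing values in index matrix")
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    bad = sd.index[sd.to_numpy() <= 1e-12]
    if len(bad):
        raise DegenerateColumnError(
            f"zero-variance column(s): {list(bad)}")
    return (df - mean) / sd


def compute_weights(raw_adjusted: pd.DataFrame,
                    dimensions: Mapping[str, tuple[str, ...]] | None = None
                    ) -> IndexWeights:
    """Coefficient-of-variation weights on the raw adjusted columns:
    V_j = sd_j / |mean_j|, W_j = V_j / sum(V), dimension weights are the
    sums of their member index weights."""
    dimensions = dimensions or INDEX_DIMENSIONS
    mean = raw_adjusted.mean(axis=0)
    bad = mean.index[np.abs(mean.to_numpy()) < 1e-9]
    if len(bad):
        raise DataError(f"weight undefined: near-zero column mean for "
                        f"{list(bad)}")
    V = raw_adjusted.std(axis=0, ddof=1) / mean.abs()
    W = V / V.sum()
    w_d = pd.Series({d: float(W[list(cols)].sum())
                     for d, cols in dimensions.items()})
    return IndexWeights(V=V, W=W, w_d=w_d)


def adjusted_values(matrix: IndexMatrix, A: float = 1.0,
                    period_years: int = 5, orientation: str = "habitat",
                    eps: float = 1e-6, standardization: str = "minmax",
                    on_constant: str = "error"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute niche values R = S + A * (P / period_years) and their
    strictly positive per-column rescaling.

    ``orientation='habitat'`` inverts cost-type columns (direction -1) so
    that higher always means a higher habitat level; ``'utilization'``
    keeps the raw orientation (for resource-use overlap profiles).
    ``standardization`` selects min-max rescaling to [eps, 1] or z-scores
    shifted to be positive.  A constant column raises a degenerate-column
    error, or, with ``on_constant='neutral'``, maps to all ones with a
    warning (such columns carry zero coefficient-of-variation weight).
    Returns ``(raw, rescaled)``.
    """
    matrix.validate()
    if orientation not in ("habitat", "utilization"):
        raise InvalidParameterError(f"unknown orientation {orientation!r}")
    if period_years < 1:
        raise InvalidParameterError("period_years must be >= 1")
    raw = matrix.state + A * (matrix.potential / float(period_years))
    scaled = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        x = raw[col].to_numpy(dtype=float)
        invert = orientation == "habitat" and \
            matrix.directions.get(col, 1) < 0
        constant = (x.max() - x.min() <= 0 if standardization == "minmax"
                    else x.std(ddof=1) <= 1e-12)
        if constant:
            if on_constant != "neutral":
                raise DegenerateColumnError(
                    f"index {col}: constant adjusted column")
            warnings.warn(f"index {col}: constant adjusted column mapped "
                          "to 1 (zero evaluation weight)", stacklevel=2)
            scaled[col] = 1.0
            continue
        if standardization == "minmax":
            v = (x - x.min()) / (x.max() - x.min())
            if invert:
                v = 1.0 - v
            scaled[col] = eps + (1.0 - eps) * v
        elif standardization == "zscore_shifted":
            z = (x - x.mean()) / x.std(ddof=1)
            if invert:
                z = -z
            scaled[col] = z - z.min() + eps
        else:
            raise InvalidParameterError(
                f"unknown standardization {standardization!r}")
    return raw, scaled


def relative_niche_width(scaled: pd.DataFrame, weights: IndexWeights,
                         dimension: str,
                         dimensions: Mapping[str, tuple[str, ...]] | None
                         = None) -> pd.Series:
    """Relative niche width of one dimension per evaluation unit: the
    weighted mean (weights W_k / w_d) of the unit's share of each member
    index across all units.  Sums to 1 across units."""
    cols = (dimensions or INDEX_DIMENSIONS).get(dimension)
    if not cols:
        raise InvalidSpecError(f"unknown or empty dimension {dimension!r}")
    if (scaled[list(cols)] <= 0).any().any():
        raise DataError("adjusted values must be strictly positive")
    shares = scaled[list(cols)] / scaled[list(cols)].sum(axis=0)
    if weights.w_d[dimension] > 0:
        wk = weights.W[list(cols)] / weights.w_d[dimension]
    else:  # all member indexes constant: fall back to equal index weights
        wk = pd.Series(1.0 / len(cols), index=list(cols))
    return (shares * wk).sum(axis=1).rename(f"N_{dimension}")


def comprehensive_niche(widths: pd.DataFrame,
                        weights: IndexWeights) -> pd.Series:
    """Comprehensive niche width M = sum_d w_d * N_d per unit."""
    missing = [d for d in INDEX_DIMENSIONS if f"N_{d}" not in widths]
    if missing:
        raise DataError(f"missing dimension widths: {missing}")
    M = sum(widths[f"N_{d}"] * weights.w_d[d] for d in INDEX_DIMENSIONS)
    return M.rename("M")


def pianka_overlap(u, v) -> float:
    """Pianka niche overlap of two resource-share profiles: the cosine
    similarity of the percentage-ownership vectors.  NaN for zero profiles."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    su, sv = u.sum(), v.sum()
    if su <= 0 or sv <= 0:
        return float("nan")
    pu, pv = u / su, v / sv
    denom = np.sqrt((pu * pu).sum() * (pv * pv).sum())
    return float(np.clip((pu * pv).sum() / denom, 0.0, 1.0))


def niche_overlap(scaled: pd.DataFrame, pair: tuple, group: str | None = None
                  ) -> float:
    """Overlap between two communities' 14-index utilization profiles.

    Rows of ``scaled`` are either (community, group) units (pass ``group``)
    or plain community rows.
    """
    j, k = pair
    if group is not None:
        u = scaled.loc[(j, group)]
        v = scaled.loc[(k, group)]
    else:
        u = scaled.loc[j]
        v = scaled.loc[k]
    return pianka_overlap(np.asarray(u, dtype=float),
                          np.asarray(v, dtype=float))


def overlap_ratio(o_oag: float, o_yag: float) -> tuple[float, str]:
    """OAG/YAG overlap ratio and its sign classification: ratio in (0, 1)
    is a positive difference (aging reduces competition), ratio > 1 a
    negative difference; a zero or undefined YAG overlap, or exact
    equality, is 'undefined'."""
    if not np.isfinite(o_oag) or not np.isfinite(o_yag) or o_yag == 0:
        return float("nan"), "undefined"
    ratio = float(o_oag / o_yag)
    if ratio == 1.0:
        return ratio, "undefined"
    return ratio, "positive" if ratio < 1.0 else "negative"


def overlap_table(scaled: pd.DataFrame, pairs: Iterable[tuple]
                  ) -> pd.DataFrame:
    """Per-pair OAG and YAG overlaps with the ratio classification."""
    rows = []
    have = set(scaled.index)
    for j, k in pairs:
        rec = {"community_a": j, "community_b": k}
        for g in (OAG, YAG):
            rec[f"O_{g}"] = (niche_overlap(scaled, (j, k), g)
                             if (j, g) in have and (k, g) in have
                             else float("nan"))
        rec["ratio"], rec["classification"] = overlap_ratio(
            rec[f"O_{OAG}"], rec[f"O_{YAG}"])
        rows.append(rec)
    return pd.DataFrame(
        rows, columns=["community_a", "community_b", f"O_{OAG}", f"O_{YAG}",
                       "ratio", "classification"])


def evaluate(community_decisions: pd.DataFrame, communities: pd.DataFrame,
             panda_survey: pd.DataFrame, adjacency: pd.DataFrame,
             households: pd.DataFrame,
             cfg: EvaluationConfig | None = None) -> dict[str, pd.DataFrame]:
    """Full niche evaluation.

    Widths use habitat-oriented adjusted values (utilization indexes
    inverted); overlaps use utilization-oriented profiles.  Evaluation
    units are community x age-group rows, and widths sum to 1 across all
    units, so OAG and YAG widths are directly comparable.
    """
    cfg = cfg or EvaluationConfig()
    matrix = build_index_matrix(community_decisions, communities,
                                panda_survey, households)
    raw, scaled_hab = adjusted_values(
        matrix, A=cfg.A, period_years=cfg.period_years,
        orientation="habitat", eps=cfg.eps,
        standardization=cfg.standardization, on_constant="neutral")
    _, scaled_util = adjusted_values(
        matrix, A=cfg.A, period_years=cfg.period_years,
        orientation="utilization", eps=cfg.eps,
        standardization=cfg.standardization, on_constant="neutral")
    weights = compute_weights(raw)
    varying = raw.columns[raw.std(axis=0, ddof=1) > 1e-12]
    zscores = raw * np.nan
    if len(varying):
        zscores[varying] = standardize(raw[varying])

    widths = pd.DataFrame(index=raw.index)
    for d in INDEX_DIMENSIONS:
        widths[f"N_{d}"] = relative_niche_width(scaled_hab, weights, d)
    widths["M"] = comprehensive_niche(widths, weights)

    if cfg.all_pairs:
        comms = sorted(raw.index.get_level_values("community_id").unique())
        pairs = [(a, b) for i, a in enumerate(comms)
                 for b in comms[i + 1:]]
    else:
        pairs = list(adjacency[["community_a",
                                "community_b"]].itertuples(index=False,
                                                           name=None))
    overlaps = overlap_table(scaled_util, pairs)

    weights_df = pd.DataFrame({"index": list(weights.V.index),
                               "V": weights.V.to_numpy(),
                               "W": weights.W.to_numpy()})
    weights_df["dimension"] = [next(d for d, cols in INDEX_DIMENSIONS.items()
                                    if x in cols)
                               for x in weights_df["index"]]
    weights_df["w_d"] = weights_df["dimension"].map(weights.w_d)
    return {
        "index_state": matrix.state.reset_index(),
        "index_potential": matrix.potential.reset_index(),
        "adjusted_raw": raw.reset_index(),
        "standardized": zscores.reset_index(),
        "weights": weights_df,
        "widths": widths.reset_index(),
        "overlaps": overlaps,
    }


# --------------------------------------------------------------------------
# pipeline orchestration
# --------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """OAG vs YAG comparison: per-community width differences, per-pair
    overlap ratios and the summary counts."""

    communities: pd.DataFrame
    pairs: pd.DataFrame
    summary: dict


def compare_groups(widths: pd.DataFrame,
                   overlaps: pd.DataFrame) -> ComparisonReport:
    """Build the group-comparison report from the width and overlap tables."""
    wide = widths.pivot(index="community_id", columns="age_group",
                        values="M")
    for g in (OAG, YAG):
        if g not in wide:
            wide[g] = np.nan
    incomplete = wide.index[wide[[OAG, YAG]].isna().any(axis=1)]
    if len(incomplete):
        logger.warning("communities excluded from width comparison "
                       "(missing group): %s", list(incomplete))
    comm = wide.dropna(subset=[OAG, YAG]).reset_index()
    comm = comm.rename(columns={OAG: "M_OAG", YAG: "M_YAG"})
    comm["difference"] = comm["M_OAG"] - comm["M_YAG"]

    pairs = overlaps.copy()
    counts = (pairs["classification"].value_counts()
              if len(pairs) else pd.Series(dtype=int))
    summary = {
        "n_communities": int(len(comm)),
        "n_width_oag_higher": int((comm["difference"] > 0).sum()),
        "n_width_yag_higher": int((comm["difference"] < 0).sum()),
        "n_pairs": int(len(pairs)),
        "n_pairs_positive": int(counts.get("positive", 0)),
        "n_pairs_negative": int(counts.get("negative", 0)),
        "n_pairs_undefined": int(counts.get("undefined", 0)),
        "median_overlap_ratio": (float(pairs["ratio"].median())
                                 if len(pairs) and
                                 pairs["ratio"].notna().any()
                                 else float("nan")),
    }
    return ComparisonReport(communities=comm, pairs=pairs, summary=summary)


@dataclass
class RunManifest:
    """Reproducibility record of a pipeline run."""

    config_hash: str
    seed: int
    version: str
    checksums: dict[str, str]
    warnings: list[str]
    timestamp: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig | None = None, seed: int | None = None,
            out_dir: str | Path = "out") -> RunManifest:
    """simulate -> decide -> evaluate -> compare, writing every table, a
    summary and a manifest with per-file checksums."""
    from . import __version__

    config = config or PipelineConfig()
    if seed is not None:
        config.scenario = dataclasses.replace(config.scenario,
                                              seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = fn(*args, **kwargs)
            collected.extend(f"{name}: {w.message}" for w in caught)
            return result
        except PandaNicheError as exc:
            raise type(exc)(f"stage {name}: {exc}") from exc

    files = stage("simulate", simulate, config.scenario, out,
                  config.write_geojson)
    households = pd.read_csv(files["households"])
    communities = pd.read_csv(files["communities"])
    panda = pd.read_csv(files["panda_survey"])
    adjacency = pd.read_csv(files["adjacency"])

    decisions, comm_dec = stage("decide", decide, households,
                                config.decision)
    _write_csv(decisions, out / "decisions.csv")
    _write_csv(comm_dec, out / "community_decisions.csv")

    tables = stage("evaluate", evaluate, comm_dec, communities, panda,
                   adjacency, households, config.evaluation)
    name_map = {"index_state": "index_matrix_state.csv",
                "index_potential": "index_matrix_potential.csv",
                "adjusted_raw": "adjusted_values.csv",
                "standardized": "standardized.csv",
                "weights": "weights.csv",
                "widths": "widths.csv",
                "overlaps": "overlaps.csv"}
    for key, fname in name_map.items():
        _write_csv(tables[key], out / fname)

    report = stage("compare", compare_groups, tables["widths"],
                   tables["overlaps"])
    _write_csv(report.communities, out / "comparison_communities.csv")
    _write_csv(report.pairs, out / "comparison_pairs.csv")
    (out / "summary.json").write_text(
        json.dumps(report.summary, indent=1, sort_keys=True) + "\n",
        encoding="utf-8")

    cfg_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    table_files = sorted(p for p in out.iterdir()
                         if p.suffix in (".csv", ".json", ".geojson")
                         and p.name != "manifest.json")
    manifest = RunManifest(
        config_hash=config_hash,
        seed=int(config.scenario.seed),
        version=__version__,
        checksums={p.name: _sha256(p) for p in table_files},
        warnings=collected,
        timestamp=pd.Timestamp.now(tz="UTC").isoformat(),
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=1, sort_keys=True) + "\n",
        encoding="utf-8")
    return manifest
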