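"""Seeded synthetic multi-ethnic cohort generator.

Generates per-subject cohort tables with the statistical structure the
downstream analyses assume, so every stage can be tested against known
ground truth:

* genotype dosage ``G in {0,1,2}`` sampled under Hardy-Weinberg
  equilibrium, ``G ~ Binomial(2, f)`` with a per-population effect-allele
  frequency ``f``;
* a linear structural mediator/outcome pair

      M = alpha_M + a*G + gamma'X + eps,
      Y = alpha_Y + c*G + b*M + delta'X + eta,

  so the total per-allele effect on Y is ``c + a*b`` and the indirect
  (mediated) effect is ``a*b`` — the ground truth the mediation stage
  must recover;
* a binary event with logistic mean;
* trial-style survival: exponential proportional-hazards event times
  with a randomized treatment arm and uniform administrative censoring.

Per-stratum random streams are derived from the master seed and a CRC32
of the stratum label, so neither stratum order nor the presence of other
strata changes a stratum's rows.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate column: name, distribution family and parameters.

    Families: ``normal(mu, sd)``, ``bernoulli(p)``, ``uniform(lo, hi)``,
    ``lognormal(mu, sigma)`` (of the underlying normal).
    """

    name: str
    dist: str
    params: Tuple[float, ...]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "normal":
            return rng.normal(self.params[0], self.params[1], n)
        if self.dist == "bernoulli":
            return rng.binomial(1, self.params[0], n).astype(float)
        if self.dist == "uniform":
            return rng.uniform(self.params[0], self.params[1], n)
        if self.dist == "lognormal":
            return rng.lognormal(self.params[0], self.params[1], n)
        raise ValueError(f"unknown covariate distribution {self.dist!r}")


@dataclass(frozen=True)
class LinearModel:
    """Gaussian linear structural equation for the mediator.

    ``noise="lognormal"`` swaps the Gaussian residual for a standardized
    log-normal one (shape 0.5) rescaled to ``noise_sd`` — a hook for
    right-skewed biomarkers; the mean-zero rescaling keeps the stated
    first two moments.
    """

    name: str
    intercept: float
    snp_effect: float  # a: per-allele effect on the mediator
    covariate_effects: Dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    noise: str = "normal"  # "normal" | "lognormal"

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")
        if self.noise not in ("normal", "lognormal"):
            raise ValueError(f"unknown noise family {self.noise!r}")


@dataclass(frozen=True)
class OutcomeModel:
    """Linear structural equation for the continuous outcome."""

    name: str
    intercept: float
    snp_effect: float  # c: direct per-allele effect
    mediator_effect: float  # b: effect of the mediator
    covariate_effects: Dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")


@dataclass(frozen=True)
class EventModel:
    """Bernoulli event with logistic mean.

    With all slopes at 0 the prevalence is ``expit(intercept)`` exactly.
    """

    name: str
    intercept: float
    snp_effect: float = 0.0
    covariate_effects: Dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential proportional-hazards event times.

    hazard_i = baseline_hazard * exp(snp_loghr*G + treatment_loghr*T
               + interaction_loghr*G*T + sum coef*X); censoring is
    administrative, ``C ~ Uniform(0, 2*censor_horizon)`` (staggered entry
    with a fixed study end), so median follow-up is about the horizon.
    """

    baseline_hazard: float
    snp_loghr: float = 0.0
    treatment_loghr: float = 0.0
    interaction_loghr: float = 0.0
    covariate_loghr: Dict[str, float] = field(default_factory=dict)
    censor_horizon: float = 3.7  # years
    treatment_allocation: float = 0.5
    time_name: str = "time"
    event_name: str = "event"
    treatment_name: str = "treatment"

    def __post_init__(self):
        if self.baseline_hazard <= 0 or self.censor_horizon <= 0:
            raise ValueError("hazard and censoring horizon must be positive")
        if not 0.0 <= self.treatment_allocation <= 1.0:
            raise ValueError("treatment allocation must be in [0, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    """One population stratum: size, allele frequency and trait models."""

    label: str
    n: int
    effect_allele_freq: float
    covariates: Tuple[CovariateSpec, ...] = ()
    mediator: Optional[LinearModel] = None
    outcome: Optional[OutcomeModel] = None
    event: Optional[EventModel] = None
    survival: Optional[SurvivalModel] = None
    missing_rate: float = 0.0  # MCAR, applied to mediator/outcome columns

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.effect_allele_freq <= 1.0:
            raise ValueError("effect-allele frequency must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")
        declared = {c.name for c in self.covariates}
        for model in (self.mediator, self.outcome, self.event):
            if model is None:
                continue
            undeclared = set(model.covariate_effects) - declared
            if undeclared:
                raise ValueError(
                    f"{model.name!r} references undeclared covariates: {sorted(undeclared)}"
                )
        if self.survival is not None:
            undeclared = set(self.survival.covariate_loghr) - declared
            if undeclared:
                raise ValueError(
                    f"survival model references undeclared covariates: {sorted(undeclared)}"
                )


# ---------------------------------------------------------------------------
# generators


def _stratum_rng(label: str, seed: int) -> np.random.Generator:
    # label-keyed sub-stream: stratum order and co-simulated strata never
    # change a stratum's draws
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def gen_genotypes(n: int, freq: float, seed) -> np.ndarray:
    """i.i.d. Hardy-Weinberg dosages, ``Binomial(2, freq)``.

    ``seed`` may be an int or an already-constructed Generator.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError("effect-allele frequency must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, freq, size=int(n))


def _noise(rng, model: LinearModel, n: int) -> np.ndarray:
    if model.noise == "normal":
        return rng.normal(0.0, model.noise_sd, n)
    # standardized lognormal(0, 0.5), rescaled to mean 0 / sd noise_sd
    raw = rng.lognormal(0.0, 0.5, n)
    mu = np.exp(0.5**2 / 2)
    sd = np.sqrt((np.exp(0.5**2) - 1) * np.exp(0.5**2))
    return (raw - mu) / sd * model.noise_sd


def gen_stratum(spec: PopulationSpec, seed: int) -> pd.DataFrame:
    """One stratum of ``spec.n`` subjects obeying the structural equations.

    All randomness derives from ``(seed, spec.label)``, so two calls with
    the same arguments return byte-identical tables.
    """
    rng = _stratum_rng(spec.label, seed)
    n = spec.n
    g = gen_genotypes(n, spec.effect_allele_freq, rng)

    cols: Dict[str, np.ndarray] = {}
    cols["subject_id"] = np.array([f"{spec.label}-{i:06d}" for i in range(n)])
    cols["stratum"] = np.full(n, spec.label)
    cols["dosage"] = g

    x = {c.name: c.sample(rng, n) for c in spec.covariates}
    cols.update(x)

    def lin_pred(intercept, snp_eff, cov_eff, extra=0.0):
        eta = intercept + snp_eff * g + extra
        for name, coef in cov_eff.items():
            eta = eta + coef * x[name]
        return eta

    m = None
    if spec.mediator is not None:
        m = lin_pred(spec.mediator.intercept, spec.mediator.snp_effect,
                     spec.mediator.covariate_effects) + _noise(rng, spec.mediator, n)
        cols[spec.mediator.name] = m

    if spec.outcome is not None:
        if spec.outcome.mediator_effect != 0.0 and m is None:
            raise ValueError("outcome model uses a mediator but none is specified")
        extra = spec.outcome.mediator_effect * m if m is not None else 0.0
        y = lin_pred(spec.outcome.intercept, spec.outcome.snp_effect,
                     spec.outcome.covariate_effects, extra)
        y = y + rng.normal(0.0, spec.outcome.noise_sd, n)
        cols[spec.outcome.name] = y

    if spec.event is not None:
        eta = lin_pred(spec.event.intercept, spec.event.snp_effect,
                       spec.event.covariate_effects)
        p = 1.0 / (1.0 + np.exp(-eta))
        cols[spec.event.name] = rng.binomial(1, p, n)

    if spec.survival is not None:
        sv = spec.survival
        t_arm = rng.binomial(1, sv.treatment_allocation, n).astype(float)
        loghr = sv.snp_loghr * g + sv.treatment_loghr * t_arm + sv.interaction_loghr * g * t_arm
        for name, coef in sv.covariate_loghr.items():
            loghr = loghr + coef * x[name]
        rate = sv.baseline_hazard * np.exp(loghr)
        event_time = rng.exponential(1.0 / rate)
        censor_time = rng.uniform(0.0, 2.0 * sv.censor_horizon, n)
        cols[sv.treatment_name] = t_arm.astype(int)
        cols[sv.time_name] = np.minimum(event_time, censor_time)
        cols[sv.event_name] = (event_time <= censor_time).astype(int)

    df = pd.DataFrame(cols)

    if spec.missing_rate > 0.0:
        targets = [m.name for m in (spec.mediator, spec.outcome) if m is not None]
        for name in targets:
            mask = rng.uniform(size=n) < spec.missing_rate
            df.loc[mask, name] = np.nan
    return df


def gen_multiethnic(specs: Sequence[PopulationSpec], seed: int) -> pd.DataFrame:
    """Concatenated strata with label-derived sub-seeds.

    With a single spec the output is identical to :func:`gen_stratum`.
    """
    if len(specs) < 1:
        raise ValueError("need at least one population spec")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate stratum labels: {sorted(labels)}")
    parts = [gen_stratum(s, seed) for s in specs]
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# study-condition presets

#: (label, n, effect-allele frequency, event prevalence) for the four
#: population strata of the multi-ethnic cohort the generator emulates.
MESA_STRATA_PARAMS = (
    ("Caucasian", 2470, 0.18, 0.127),
    ("African-American", 2507, 0.62, 0.110),
    ("Hispanic", 2071, 0.35, 0.121),
    ("Chinese-American", 758, 0.57, 0.084),
)

_BASE_COVARIATES = (
    CovariateSpec("age", "normal", (62.0, 9.5)),
    CovariateSpec("sex", "bernoulli", (0.47,)),
    CovariateSpec("pc1", "normal", (0.0, 1.0)),
    CovariateSpec("pc2", "normal", (0.0, 1.0)),
)

#: Structural ground truth of the default cohort preset: per-allele
#: mediator effect a, mediator->outcome effect b, direct effect c.
DEFAULT_A = 2.4
DEFAULT_B = 5.0e-4
DEFAULT_C = 0.0098

_MEDIATOR_INTERCEPTS = {
    "Caucasian": 153.0, "African-American": 134.0,
    "Hispanic": 150.0, "Chinese-American": 154.0,
}


def mesa_like_specs(
    n_override: Optional[int] = None,
    a: float = DEFAULT_A,
    b: float = DEFAULT_B,
    c: float = DEFAULT_C,
    missing_rate: float = 0.0,
) -> Tuple[PopulationSpec, ...]:
    """Default four-stratum cohort preset.

    Emulates the observational cohort: stratum sizes 2470/2507/2071/758,
    effect-allele frequencies 0.18/0.62/0.35/0.57, an Lp-PLA2-activity-like
    mediator (residual SD 37 nmol/min/ml), a cIMT-like outcome (residual
    SD 0.17 mm) and a binary CV event with prevalences 12.7/11.0/12.1/8.4%.
    """
    specs = []
    for label, n, freq, prev in MESA_STRATA_PARAMS:
        logit = float(np.log(prev / (1.0 - prev)))
        specs.append(PopulationSpec(
            label=label,
            n=int(n_override or n),
            effect_allele_freq=freq,
            covariates=_BASE_COVARIATES,
            mediator=LinearModel(
                name="lppla2_activity",
                intercept=_MEDIATOR_INTERCEPTS[label],
                snp_effect=a,
                covariate_effects={"age": 0.2, "sex": -4.0},
                noise_sd=37.0,
            ),
            outcome=OutcomeModel(
                name="cimt",
                intercept=0.55,
                snp_effect=c,
                mediator_effect=b,
                covariate_effects={"age": 0.004, "sex": 0.01},
                noise_sd=0.17,
            ),
            event=EventModel(name="cv_event", intercept=logit),
            missing_rate=missing_rate,
        ))
    return tuple(specs)


#: (label, n, effect-allele frequency) for the two trial presets.
TRIAL_STRATA_PARAMS = {
    "stability": (
        ("Caucasian", 9448, 0.17), ("African-American", 254, 0.53),
        ("Asian", 1257, 0.64), ("Other", 1637, 0.25),
    ),
    "solid": (
        ("Caucasian", 7503, 0.16), ("African-American", 185, 0.59),
        ("Asian", 408, 0.62), ("Other", 1303, 0.27),
    ),
}


def trial_like_specs(
    trial: str = "stability",
    n_override: Optional[int] = None,
    biomarker_effect: float = 3.8,
    snp_loghr: float = 0.1,
    treatment_loghr: float = 0.0,
    interaction_loghr: float = 0.0,
) -> Tuple[PopulationSpec, ...]:
    """Randomized-trial preset: baseline biomarker plus survival outcome.

    Stratum sizes and allele frequencies follow the named trial; the
    default event rate (~0.028/y baseline hazard against a 3.7 y or 2.5 y
    administrative-censoring horizon) gives roughly the trials' ~9-14%
    event proportions.  Treatment is randomized 1:1 with a null effect by
    default (the trials' darapladib arm showed none).
    """
    if trial not in TRIAL_STRATA_PARAMS:
        raise ValueError(f"unknown trial preset {trial!r}")
    horizon = 3.7 if trial == "stability" else 2.5
    specs = []
    for label, n, freq in TRIAL_STRATA_PARAMS[trial]:
        specs.append(PopulationSpec(
            label=label,
            n=int(n_override or n),
            effect_allele_freq=freq,
            covariates=_BASE_COVARIATES,
            mediator=LinearModel(
                name="lppla2_activity",
                intercept=150.0,
                snp_effect=biomarker_effect,
                covariate_effects={"age": 0.2},
                noise_sd=40.0,
            ),
            survival=SurvivalModel(
                baseline_hazard=0.028,
                snp_loghr=snp_loghr,
                treatment_loghr=treatment_loghr,
                interaction_loghr=interaction_loghr,
                censor_horizon=horizon,
            ),
        ))
    return tuple(specs)
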