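"""Synthetic two-trial datasets with the structure the MAIC assumes.

Generates patient-level myeloma-trial data — baseline covariates, nested
ordinal responses (ORR ⊃ ≥VGPR ⊃ ≥CR by construction, via a single latent
uniform against nested logistic thresholds), Weibull proportional-hazards
survival with administrative-uniform censoring, and rare binary safety
events.  Two default configurations emulate the published baseline summaries
of the pooled modified-dosing population and the label-dosing population
(median age 58/57, 58% male, ECOG>=1 52/56%, IgG 61/66%, ISS I 41/34%,
ISS II 43/44%, median creatinine clearance 95.2/82.5 mL/min).

Outcome models depend on covariates only through the indicator basis that the
default matching specification balances; because covariates are generated
independently, an exponential tilt on that basis transports the entire
outcome-relevant distribution, so MAIC weighting can fully correct the
covariate shift between the two default trials.  An optional unmatched
confounder demonstrates the residual confounding that weighting cannot fix.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64), so
tables are bit-reproducible for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .trial_data import (
    AggregateProfile,
    IPDTable,
    MatchSpec,
    MatchTarget,
    ValidationError,
    default_match_spec,
)

__all__ = [
    "CovariateModel",
    "ResponseModel",
    "SurvivalModel",
    "SimConfig",
    "simulate_trial",
    "profile_from_ipd",
    "default_paperlike_config",
    "AGE_CUT",
    "CRCL_CUT",
    "OUTCOME_BASIS",
]

#: Cutpoints defining the indicator basis (the target medians being matched).
AGE_CUT = 58.0
CRCL_CUT = 95.2

OUTCOME_BASIS = (
    "age_le_cut",
    "male",
    "ecog_ge1",
    "igg",
    "iss_i",
    "iss_ii",
    "crcl_le_cut",
)

AGE_RANGE = (18.0, 80.0)


@dataclass(frozen=True)
class CovariateModel:
    """Marginal baseline covariate generators (drawn independently)."""

    age_mean: float = 58.0
    age_sd: float = 9.0
    male: float = 0.58
    ecog_ge1: float = 0.52
    igg: float = 0.61
    iss: tuple[float, float, float] = (0.41, 0.43, 0.16)
    crcl_median: float = 95.2
    crcl_sigma: float = 0.35
    hemoglobin_mean: float = 11.5
    hemoglobin_sd: float = 1.6
    platelets_mean: float = 230.0
    platelets_sd: float = 65.0


@dataclass(frozen=True)
class ResponseModel:
    """Nested-threshold ordinal response model.

    ``intercepts`` maps each timepoint to logit intercepts (ORR, >=VGPR, >=CR)
    — strictly decreasing so the response levels nest.  ``coefs`` act on the
    indicator basis; ``arm_log_or`` shifts all thresholds for the trial's arm.
    """

    coefs: dict = field(
        default_factory=lambda: {
            "age_le_cut": 0.25,
            "ecog_ge1": -0.35,
            "igg": -0.15,
            "iss_i": 0.45,
            "iss_ii": 0.15,
            "crcl_le_cut": -0.20,
        }
    )
    intercepts: dict = field(
        default_factory=lambda: {
            "postinduction": (1.8, 0.0, -2.2),
            "posttransplant": (2.3, 0.8, -1.6),
        }
    )
    arm_log_or: float = 0.0


@dataclass(frozen=True)
class SurvivalModel:
    """Weibull proportional-hazards model: S(t) = exp(-(t/scale)^shape * e^lp)."""

    shape: float
    scale: float
    coefs: dict = field(default_factory=dict)
    arm_log_hr: float = 0.0


def _default_os() -> SurvivalModel:
    return SurvivalModel(
        shape=1.2,
        scale=180.0,
        coefs={"ecog_ge1": 0.45, "iss_i": -0.40, "iss_ii": -0.10,
               "crcl_le_cut": 0.25, "age_le_cut": -0.20},
    )


def _default_pfs() -> SurvivalModel:
    return SurvivalModel(
        shape=1.1,
        scale=60.0,
        coefs={"ecog_ge1": 0.40, "iss_i": -0.35, "iss_ii": -0.10,
               "crcl_le_cut": 0.20, "age_le_cut": -0.15},
    )


@dataclass(frozen=True)
class SimConfig:
    """Full generating configuration for one synthetic trial arm."""

    trial_id: str
    arm: str
    n: int
    covariates: CovariateModel = field(default_factory=CovariateModel)
    response: ResponseModel = field(default_factory=ResponseModel)
    survival_os: SurvivalModel = field(default_factory=_default_os)
    survival_pfs: SurvivalModel = field(default_factory=_default_pfs)
    censor_window: tuple[float, float] = (3.0, 40.0)  # months
    safety_rates: dict = field(
        default_factory=lambda: {
            "discontinued_ae": 0.055,
            "thrombosis_g34": 0.02,
            "neuropathy_g34": 0.066,
        }
    )
    confounder_prob: float = 0.0  # optional unmatched binary confounder
    confounder_log_or: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        cov = self.covariates
        if self.n <= 0:
            bad.append("n")
        for name in ("male", "ecog_ge1", "igg"):
            if not 0.0 <= getattr(cov, name) <= 1.0:
                bad.append(f"covariates.{name}")
        if abs(sum(cov.iss) - 1.0) > 1e-9 or any(p < 0 for p in cov.iss):
            bad.append("covariates.iss")
        if cov.age_sd <= 0 or cov.crcl_sigma <= 0 or cov.crcl_median <= 0:
            bad.append("covariates.age_sd/crcl")
        for label, sm in (("os", self.survival_os), ("pfs", self.survival_pfs)):
            if sm.shape <= 0 or sm.scale <= 0:
                bad.append(f"survival_{label}.shape/scale")
        if not 0 <= self.censor_window[0] < self.censor_window[1]:
            bad.append("censor_window")
        for key, rate in self.safety_rates.items():
            if not 0.0 <= rate <= 1.0:
                bad.append(f"safety_rates.{key}")
        if not 0.0 <= self.confounder_prob <= 1.0:
            bad.append("confounder_prob")
        if bad:
            raise ValidationError(f"invalid SimConfig fields: {bad}")


def _basis(frame: pd.DataFrame) -> pd.DataFrame:
    """Indicator basis through which all outcome models act."""
    return pd.DataFrame(
        {
            "age_le_cut": (frame["age"] <= AGE_CUT).astype(float),
            "male": (frame["sex"] == "male").astype(float),
            "ecog_ge1": frame["ecog_ge1"].astype(float),
            "igg": (frame["myeloma_type"] == "IgG").astype(float),
            "iss_i": (frame["iss"] == "I").astype(float),
            "iss_ii": (frame["iss"] == "II").astype(float),
            "crcl_le_cut": (frame["creatinine_clearance"] <= CRCL_CUT).astype(float),
        }
    )


def _linear_predictor(z: pd.DataFrame, coefs: dict, extra: np.ndarray | None = None):
    lp = np.zeros(len(z))
    for name, c in coefs.items():
        lp += c * z[name].to_numpy()
    if extra is not None:
        lp += extra
    return lp


def simulate_trial(config: SimConfig) -> IPDTable:
    """Draw one synthetic trial arm; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    cov = config.covariates

    a, b = (
        (AGE_RANGE[0] - cov.age_mean) / cov.age_sd,
        (AGE_RANGE[1] - cov.age_mean) / cov.age_sd,
    )
    age = truncnorm.rvs(a, b, loc=cov.age_mean, scale=cov.age_sd,
                        size=n, random_state=rng)
    frame = pd.DataFrame(
        {
            "patient_id": [f"{config.trial_id}-{i + 1:05d}" for i in range(n)],
            "trial_id": config.trial_id,
            "arm": config.arm,
            "age": np.round(age, 1),
            "sex": np.where(rng.random(n) < cov.male, "male", "female"),
            "ecog_ge1": (rng.random(n) < cov.ecog_ge1).astype(int),
            "myeloma_type": np.where(rng.random(n) < cov.igg, "IgG", "non-IgG"),
            "iss": rng.choice(["I", "II", "III"], size=n, p=list(cov.iss)),
            "creatinine_clearance": np.round(
                np.exp(rng.normal(np.log(cov.crcl_median), cov.crcl_sigma, n)), 1
            ),
            "hemoglobin": np.round(
                rng.normal(cov.hemoglobin_mean, cov.hemoglobin_sd, n), 1
            ),
            "platelets": np.round(
                np.clip(rng.normal(cov.platelets_mean, cov.platelets_sd, n), 20, None)
            ),
        }
    )
    z = _basis(frame)
    conf = None
    if config.confounder_prob > 0:
        conf = (rng.random(n) < config.confounder_prob).astype(float)

    # nested ordinal responses: one latent uniform per timepoint
    rm = config.response
    extra = rm.arm_log_or + (
        config.confounder_log_or * conf if conf is not None else 0.0
    )
    eta = _linear_predictor(z, rm.coefs, extra if np.ndim(extra) else None)
    if np.ndim(extra) == 0:
        eta = eta + extra
    for timepoint, (a_orr, a_vgpr, a_cr) in rm.intercepts.items():
        if not a_orr > a_vgpr > a_cr:
            raise ValidationError(
                f"response intercepts for {timepoint} must nest (ORR > VGPR > CR)"
            )
        u = rng.random(n)
        level = np.select(
            [u < expit(a_cr + eta), u < expit(a_vgpr + eta), u < expit(a_orr + eta)],
            ["CR", "VGPR", "PR"],
            default="none",
        )
        frame[f"response_{timepoint}"] = level

    # Weibull PH survival by inverse transform; administrative censoring
    c_lo, c_hi = config.censor_window
    for label, sm in (("os", config.survival_os), ("pfs", config.survival_pfs)):
        lp = _linear_predictor(z, sm.coefs)
        lp += sm.arm_log_hr
        if conf is not None:
            lp = lp + config.confounder_log_or * conf
        u = rng.random(n)
        t_event = sm.scale * (-np.log(u) * np.exp(-lp)) ** (1.0 / sm.shape)
        t_cens = rng.uniform(c_lo, c_hi, n)
        frame[f"{label}_time"] = np.round(np.minimum(t_event, t_cens), 3)
        frame[f"{label}_event"] = (t_event <= t_cens).astype(int)

    for col, rate in config.safety_rates.items():
        frame[col] = (rng.random(n) < rate).astype(int)

    return IPDTable(
        frame,
        provenance={config.trial_id: f"synthetic (seed={config.seed})"},
    )


def profile_from_ipd(
    ipd: IPDTable, spec: MatchSpec | None = None, source_n: int | None = None
) -> AggregateProfile:
    """Summarise an IPD table into the aggregate profile its matcher targets.

    Produces the comparator side of an unanchored MAIC: one target per
    encoding rule, computed as the sample median / proportion / mean.
    """
    spec = spec or default_match_spec()
    frame = ipd.frame
    targets = []
    for rule in spec.rules:
        col = frame[rule.variable]
        if rule.statistic == "median":
            value = float(np.median(pd.to_numeric(col).dropna()))
        elif rule.statistic == "proportion":
            if pd.api.types.is_numeric_dtype(col):
                value = float((col == float(rule.level)).mean())
            else:
                value = float((col.astype(str) == str(rule.level)).mean())
        else:  # mean
            value = float(pd.to_numeric(col).mean())
        targets.append(
            MatchTarget(rule.variable, rule.statistic, value, rule.level)
        )
    return AggregateProfile(tuple(targets), source_n or len(frame))


def default_paperlike_config(
    n_mod: int = 591, n_label: int = 130, seed: int = 20200825
) -> tuple[SimConfig, SimConfig]:
    """Two trial configurations emulating the published baseline columns.

    The first approximates the pooled modified-dosing population (the
    aggregate side of the matching); the second the label-dosing population
    whose IPD gets weighted.  Outcome models are shared — the trials differ
    only in matched covariate distributions and follow-up — so weighting the
    second to the first's profile recovers the first population's outcomes.
    """
    mod = SimConfig(
        trial_id="MOD-POOLED",
        arm="VTd-mod",
        n=n_mod,
        covariates=CovariateModel(
            age_mean=58.0, male=0.58, ecog_ge1=0.52, igg=0.61,
            iss=(0.41, 0.43, 0.16), crcl_median=95.2,
        ),
        censor_window=(3.0, 40.0),
        seed=seed,
    )
    label = SimConfig(
        trial_id="LABEL",
        arm="VTd-label",
        n=n_label,
        covariates=CovariateModel(
            age_mean=57.0, male=0.58, ecog_ge1=0.56, igg=0.66,
            iss=(0.34, 0.44, 0.22), crcl_median=82.5,
        ),
        safety_rates={
            "discontinued_ae": 0.062,
            "thrombosis_g34": 0.008,
            "neuropathy_g34": 0.054,
        },
        censor_window=(6.0, 72.0),
        seed=seed + 1,
    )
    return mod, label


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of a configuration with a different seed."""
    return replace(config, seed=seed)
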