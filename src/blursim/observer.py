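"""Synthetic observers: Weibull detection plus shifted-lognormal RT.

A simulated subject holds one parameter set per condition of the
location x blur x cue factorial.  Detection follows a Weibull
psychometric function

    p(x) = gamma + (1 - gamma - lapse) * (1 - exp(-(x / alpha)**beta))

on the dot diameter ``x`` (arcmin), with threshold ``alpha``, slope
``beta``, guess rate ``gamma`` and lapse rate ``lapse``.  Response time
is a shifted lognormal whose median is the condition's ``rt_mu``;
congruent cueing lowers the median by a fixed benefit, and blur leaves
RT untouched by construction.

Cohorts are generated from population-level effects that act
multiplicatively on ``alpha`` (log-additive, matching the multiplicative
staircase steps and the ratio definition of refractive gain):
a location factor (worst in the inferior quadrant), a per-quadrant
blur-inflation factor (largest on the horizontal meridian), and a small
threshold penalty for incongruent cues.  Between-subject variability is
lognormal noise on each factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .conditions import BLUR_LEVELS, CUE_LEVELS, Condition, LOCATIONS

__all__ = [
    "ConditionParams",
    "ObserverModel",
    "ObserverEffects",
    "psychometric_p",
    "simulate_response",
    "make_cohort",
    "cohort_to_frame",
]


@dataclass(frozen=True)
class ConditionParams:
    """Psychometric and RT parameters for one condition."""

    alpha: float
    beta: float = 3.0
    gamma: float = 0.02
    lapse: float = 0.01
    rt_mu: float = 400.0
    rt_sigma: float = 0.2
    rt_shift: float = 150.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if not (0 <= self.gamma and 0 <= self.lapse and self.gamma + self.lapse < 1):
            raise ValueError("need 0 <= gamma, lapse and gamma + lapse < 1")
        if not 0 < self.rt_shift < self.rt_mu or self.rt_sigma <= 0:
            raise ValueError("RT parameters must satisfy 0 < rt_shift < rt_mu, rt_sigma > 0")


@dataclass
class ObserverModel:
    """One simulated subject: a parameter set per factorial condition."""

    subject_id: str
    params: dict[Condition, ConditionParams]


def psychometric_p(params: ConditionParams, level: float) -> float:
    """Probability of a correct detection at a dot diameter (arcmin)."""
    if level <= 0:
        raise ValueError("level must be > 0")
    core = 1.0 - np.exp(-((level / params.alpha) ** params.beta))
    return float(params.gamma + (1.0 - params.gamma - params.lapse) * core)


def simulate_response(
    model: ObserverModel,
    condition: Condition,
    level: float,
    rng: np.random.Generator,
) -> tuple[bool, float]:
    """Draw one (correct, rt_ms) response.

    RT is measured from target offset, as a shifted lognormal with
    median ``rt_mu``; it does not depend on the stimulus level or on
    blur, only on the cue condition baked into ``rt_mu``.
    """
    p = model.params[condition]
    correct = bool(rng.random() < psychometric_p(p, level))
    rt = p.rt_shift + float(
        np.exp(rng.normal(np.log(p.rt_mu - p.rt_shift), p.rt_sigma))
    )
    return correct, rt


def _default_location_factors() -> dict[str, float]:
    return {"inferior": 1.35, "superior": 1.15, "nasal": 1.0, "temporal": 1.0}


def _default_blur_factors() -> dict[str, float]:
    return {"temporal": 1.34, "nasal": 1.23, "superior": 1.07, "inferior": 1.03}


@dataclass
class ObserverEffects:
    """Population-level generating effects for a simulated cohort.

    ``base_alpha`` is the clear, horizontal-meridian detection threshold
    in arcmin.  ``blur_factors`` are the per-quadrant threshold
    inflations under defocus; with zero subject noise they equal the
    population refractive gain (MAD_blur / MAD_clear) of each quadrant.
    """

    base_alpha: float = 3.0
    location_factors: dict[str, float] = field(default_factory=_default_location_factors)
    blur_factors: dict[str, float] = field(default_factory=_default_blur_factors)
    cue_factor_incongruent: float = 1.05
    rt_base: float = 400.0
    rt_congruency_benefit: float = 30.0
    between_subject_sd: float = 0.08
    beta: float = 3.0
    gamma: float = 0.02
    lapse: float = 0.01
    rt_sigma: float = 0.2
    rt_shift: float = 150.0

    def __post_init__(self) -> None:
        factors = [
            self.base_alpha,
            self.cue_factor_incongruent,
            *self.location_factors.values(),
            *self.blur_factors.values(),
        ]
        if any(f <= 0 for f in factors):
            raise ValueError("all effect multipliers must be > 0")
        if self.between_subject_sd < 0:
            raise ValueError("between_subject_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ObserverEffects":
        return cls(**data)


def make_cohort(
    effects: ObserverEffects,
    n_subjects: int = 5,
    rng: np.random.Generator | None = None,
) -> list[ObserverModel]:
    """Draw a cohort of simulated subjects.

    Each subject perturbs the base threshold and every location/blur/cue
    factor by independent lognormal noise (sd ``between_subject_sd`` in
    log units), then builds its 16 per-condition parameter sets.
    Deterministic given the generator state.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    sd = effects.between_subject_sd

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0

    cohort = []
    for s in range(n_subjects):
        base = effects.base_alpha * noise()
        loc_noise = {q: noise() for q in LOCATIONS}
        blur_noise = {q: noise() for q in LOCATIONS}
        cue_noise = noise()
        rt_noise = noise()
        benefit_noise = noise()
        params: dict[Condition, ConditionParams] = {}
        for q in LOCATIONS:
            for blur in BLUR_LEVELS:
                for cue in CUE_LEVELS:
                    alpha = base * effects.location_factors[q] * loc_noise[q]
                    if blur == "blurred":
                        alpha *= effects.blur_factors[q] * blur_noise[q]
                    if cue == "incongruent":
                        alpha *= effects.cue_factor_incongruent * cue_noise
                    rt_mu = effects.rt_base * rt_noise
                    if cue == "congruent":
                        rt_mu -= effects.rt_congruency_benefit * benefit_noise
                    params[Condition(q, blur, cue)] = ConditionParams(
                        alpha=alpha,
                        beta=effects.beta,
                        gamma=effects.gamma,
                        lapse=effects.lapse,
                        rt_mu=rt_mu,
                        rt_sigma=effects.rt_sigma,
                        rt_shift=effects.rt_shift,
                    )
        cohort.append(ObserverModel(subject_id=f"S{s + 1}", params=params))
    return cohort


def cohort_to_frame(cohort: list[ObserverModel]) -> pd.DataFrame:
    """Per-condition parameter dump, one row per subject x condition."""
    rows = []
    for model in cohort:
        for cond, p in model.params.items():
            rows.append(
                {
                    "subject": model.subject_id,
                    "location": cond.location,
                    "blur": cond.blur,
                    "cue": cond.cue,
                    **asdict(p),
                }
            )
    return pd.DataFrame(rows)
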