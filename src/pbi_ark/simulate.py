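"""Synthetic validation-study cohorts.

Generates respondent-level data with the statistical structure the
analysis pipeline assumes, so every stage is testable without patient
data:

* needs (PNQ) items follow a latent factor model: per population a
  simple-structure loading pattern over the bundled subscale map (salient
  loading 0.7 by default), unit-variance latents discretised to the 0-4
  ordinal scale by fixed thresholds;
* benefit (PBQ) items load on a single latent treatment response theta,
  discretised the same way; a goal that "did not apply" before treatment
  cannot be achieved, so PBQ not-apply is forced wherever PNQ was
  not-apply, with additional independent contamination;
* visit-1 clinical variables derive from a latent baseline burden b; the
  visit-2 values derive from b minus ``clinical_coupling * theta``, which
  couples clinical improvement to the same treatment response that drives
  the benefit ratings;
* not-apply and missing responses are generated completely at random with
  configurable probabilities.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .instrument import (
    Cohort,
    DURATION_LEVELS,
    FREQUENCY_LEVELS,
    IMPAIRMENT_LEVELS,
    JUDGEMENT_LEVELS,
    MISSING,
    N_ITEMS,
    NOT_APPLICABLE,
    Population,
    Respondent,
    ResponseValue,
    SEVERITY_LEVELS,
    Sex,
    SubscaleMap,
    builtin_instrument,
    builtin_subscale_map,
)

__all__ = ["SimulationConfig", "simulate_cohort", "population_targets", "loading_pattern_from_map"]

_DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)


def loading_pattern_from_map(subscale_map: SubscaleMap, salient: float = 0.7) -> np.ndarray:
    """Simple-structure (19 x n_subscales) pattern: ``salient`` on the item's
    own subscale factor, 0 elsewhere."""
    names = subscale_map.names
    pattern = np.zeros((N_ITEMS, len(names)))
    for j, name in enumerate(names):
        for item_id in subscale_map.items_of(name):
            pattern[item_id - 1, j] = salient
    return pattern


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Sample sizes default to the validation study's 223 children and 122
    adolescents.  ``loading_pattern_*`` defaults to the simple structure
    over the bundled subscale maps with ``salient_loading`` on the item's
    own factor.  ``thresholds`` are the latent cut-points mapping the
    unit-variance latents to ordinal levels 0-4.  ``theta_*`` parameterise
    the latent treatment response; ``benefit_loading`` couples benefit
    items to it and ``clinical_coupling`` couples visit-1 to visit-2
    clinical improvement to it.  ``need_mean_*`` shift the latent need
    level of a population (0 = thresholds' reference scale).
    """

    n_children: int = 223
    n_adolescents: int = 122
    salient_loading: float = 0.7
    loading_pattern_children: Optional[Sequence[Sequence[float]]] = None
    loading_pattern_adolescents: Optional[Sequence[Sequence[float]]] = None
    thresholds: tuple[float, float, float, float] = _DEFAULT_THRESHOLDS
    p_not_apply_pnq: float = 0.05
    p_not_apply_pbq: float = 0.05
    p_missing: float = 0.02
    theta_mean: float = 0.5
    theta_sd: float = 1.0
    benefit_loading: float = 0.7
    clinical_coupling: float = 0.8
    need_mean_children: float = 0.0
    need_mean_adolescents: float = 0.0
    male_fraction: float = 0.609
    asthma_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_not_apply_pnq", "p_not_apply_pbq", "p_missing",
                     "male_fraction", "asthma_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_not_apply_pnq + self.p_missing > 1 or self.p_not_apply_pbq + self.p_missing > 1:
            raise ValueError("not-apply and missing probabilities sum above 1")
        t = tuple(self.thresholds)
        if len(t) != 4 or any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError(f"thresholds must be 4 strictly ascending values, got {t}")
        self.thresholds = t
        if self.n_children < 0 or self.n_adolescents < 0:
            raise ValueError("sample sizes must be non-negative")
        if self.theta_sd <= 0:
            raise ValueError("theta_sd must be positive")
        if not -1.0 <= self.benefit_loading <= 1.0:
            raise ValueError("benefit_loading must be in [-1, 1]")
        for pop in Population:
            pat = self.pattern(pop)
            if pat.shape[0] != N_ITEMS:
                raise ValueError(f"loading pattern must have {N_ITEMS} rows")
            if np.any((pat ** 2).sum(axis=1) > 1.0 + 1e-12):
                raise ValueError("loading rows must have communality <= 1")

    def pattern(self, population: Population) -> np.ndarray:
        explicit = (
            self.loading_pattern_children
            if population is Population.CHILDREN
            else self.loading_pattern_adolescents
        )
        if explicit is not None:
            return np.asarray(explicit, dtype=float)
        return loading_pattern_from_map(builtin_subscale_map(population), self.salient_loading)

    def need_mean(self, population: Population) -> float:
        return (
            self.need_mean_children
            if population is Population.CHILDREN
            else self.need_mean_adolescents
        )

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("loading_pattern_children", "loading_pattern_adolescents"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        d["thresholds"] = list(d["thresholds"])
        return json.dumps(d, indent=2, sort_keys=True)

    @staticmethod
    def from_json(text_or_path: Union[str, Path]) -> "SimulationConfig":
        if isinstance(text_or_path, Path):
            text_or_path = text_or_path.read_text("utf-8")
        raw = json.loads(text_or_path)
        raw["thresholds"] = tuple(raw.get("thresholds", _DEFAULT_THRESHOLDS))
        return SimulationConfig(**raw)


def _discretize(latent: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    return np.searchsorted(np.asarray(thresholds), latent).astype(float)


def _contaminate(
    levels: np.ndarray, rng: np.random.Generator, p_na: float, p_missing: float
) -> np.ndarray:
    """Overwrite levels with the not-apply code (-1) w.p. p_na and NaN w.p.
    p_missing, mutually exclusively."""
    u = rng.random(levels.shape)
    out = levels.copy()
    out[u < p_na] = -1.0
    out[(u >= p_na) & (u < p_na + p_missing)] = np.nan
    return out


_SEVERITY_CUTS = (-1.5, -0.5, 0.5)   # none | mild | moderate | strong
_DICHOTOMY_CUT = -0.5                # frequency/duration high vs low
_IMPAIRED_CUT = 0.0                  # normal vs impaired
_JUDGEMENT_CUTS = (-0.5, 0.2, 1.0)   # worse | unchanged | somewhat | much better
_CLINICAL_NOISE_SD = 0.5


def _codes_to_responses(mat: np.ndarray) -> list[tuple[ResponseValue, ...]]:
    out = []
    for row in mat:
        out.append(
            tuple(
                MISSING if np.isnan(c) else (NOT_APPLICABLE if c == -1.0 else ResponseValue.ordinal(int(c)))
                for c in row
            )
        )
    return out


def _maybe_missing(rng: np.random.Generator, value, p: float):
    return None if rng.random() < p else value


def _simulate_population(
    config: SimulationConfig, population: Population, n: int, rng: np.random.Generator
) -> list[Respondent]:
    if n == 0:
        return []
    pattern = config.pattern(population)
    k = pattern.shape[1]
    uniq = np.sqrt(np.clip(1.0 - (pattern ** 2).sum(axis=1), 0.0, None))

    ages = rng.integers(5, 13, n) if population is Population.CHILDREN else rng.integers(13, 18, n)
    male = rng.random(n) < config.male_fraction
    asthma = rng.random(n) < config.asthma_fraction

    factors = rng.standard_normal((n, k))
    pnq_latent = factors @ pattern.T + rng.standard_normal((n, N_ITEMS)) * uniq + config.need_mean(population)
    pnq = _contaminate(
        _discretize(pnq_latent, config.thresholds), rng, config.p_not_apply_pnq, config.p_missing
    )

    theta = config.theta_mean + config.theta_sd * rng.standard_normal(n)
    b_uniq = np.sqrt(max(0.0, 1.0 - config.benefit_loading ** 2))
    pbq_latent = config.benefit_loading * theta[:, None] + b_uniq * rng.standard_normal((n, N_ITEMS))
    pbq = _contaminate(
        _discretize(pbq_latent, config.thresholds), rng, config.p_not_apply_pbq, config.p_missing
    )
    pbq[pnq == -1.0] = -1.0  # a goal that did not apply cannot be achieved

    # Clinical variables: latent baseline burden, improved by theta at visit 2.
    burden = rng.standard_normal(n)
    improved = burden - config.clinical_coupling * theta

    def noisy(base):
        return base + _CLINICAL_NOISE_SD * rng.standard_normal(n)

    clinical: dict[str, np.ndarray] = {}
    for field_name in ("rhinitis_severity", "conjunctivitis_severity"):
        clinical[f"v1_{field_name}"] = np.searchsorted(_SEVERITY_CUTS, noisy(burden))
        clinical[f"v2_{field_name}"] = np.searchsorted(_SEVERITY_CUTS, noisy(improved))
    for field_name, _levels in (("rhinitis_frequency", FREQUENCY_LEVELS),
                                ("rhinitis_duration", DURATION_LEVELS)):
        clinical[f"v1_{field_name}"] = (noisy(burden) > _DICHOTOMY_CUT).astype(int)
        clinical[f"v2_{field_name}"] = (noisy(improved) > _DICHOTOMY_CUT).astype(int)
    for field_name in ("sleep", "activities", "performance"):
        clinical[f"v1_{field_name}"] = (noisy(burden) > _IMPAIRED_CUT).astype(int)
        clinical[f"v2_{field_name}"] = (noisy(improved) > _IMPAIRED_CUT).astype(int)
    for field_name in ("vas_avg", "vas_peak"):
        clinical[f"v1_{field_name}"] = np.clip(np.round(5.0 + 2.0 * noisy(burden)), 0, 10).astype(int)
        clinical[f"v2_{field_name}"] = np.clip(np.round(5.0 + 2.0 * noisy(improved)), 0, 10).astype(int)
    for who in ("physician", "patient"):
        j = theta + _CLINICAL_NOISE_SD * rng.standard_normal(n)
        # JUDGEMENT_LEVELS runs best-to-worst; index 3 - searchsorted position.
        clinical[f"v2_global_judgement_{who}"] = 3 - np.searchsorted(_JUDGEMENT_CUTS, j)

    level_maps = {
        "rhinitis_severity": SEVERITY_LEVELS,
        "conjunctivitis_severity": SEVERITY_LEVELS,
        "rhinitis_frequency": FREQUENCY_LEVELS,
        "rhinitis_duration": DURATION_LEVELS,
        "sleep": IMPAIRMENT_LEVELS,
        "activities": IMPAIRMENT_LEVELS,
        "performance": IMPAIRMENT_LEVELS,
        "global_judgement_physician": JUDGEMENT_LEVELS,
        "global_judgement_patient": JUDGEMENT_LEVELS,
    }

    prefix = "c" if population is Population.CHILDREN else "a"
    pnq_resp = _codes_to_responses(pnq)
    pbq_resp = _codes_to_responses(pbq)
    respondents = []
    for i in range(n):
        convergent: dict[str, Optional[object]] = {}
        for col, arr in clinical.items():
            base = col[3:]
            if base in ("vas_avg", "vas_peak"):
                value: object = int(arr[i])
            else:
                value = level_maps[base][int(arr[i])]
            convergent[col] = _maybe_missing(rng, value, config.p_missing)
        respondents.append(
            Respondent(
                id=f"{prefix}{i + 1:05d}",
                age_years=float(ages[i]),
                sex=Sex.MALE if male[i] else Sex.FEMALE,
                asthma=bool(asthma[i]),
                pnq=pnq_resp[i],
                pbq=pbq_resp[i],
                convergent=convergent,
            )
        )
    return respondents


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full two-population cohort, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    respondents = _simulate_population(config, Population.CHILDREN, config.n_children, rng)
    respondents += _simulate_population(config, Population.ADOLESCENTS, config.n_adolescents, rng)
    return Cohort(builtin_instrument(), tuple(respondents))


def population_targets(config: SimulationConfig, population: Union[Population, str] = Population.CHILDREN) -> dict:
    """Analytic expectations implied by the generator, used as test oracles.

    Latent inter-item correlation within a subscale is the squared salient
    loading; the compound-symmetry (Spearman-Brown) form gives the alpha
    each subscale would attain on the latent scale -- an upper bound for the
    discretised items, since ordinal coarsening attenuates correlations.
    """
    population = Population(population) if isinstance(population, str) else population
    subscale_map = builtin_subscale_map(population)
    pattern = config.pattern(population)
    targets: dict[str, object] = {"congruence_target": 1.0}
    alpha_bounds = {}
    for name in subscale_map.names:
        items = sorted(subscale_map.items_of(name))
        lam = pattern[[i - 1 for i in items]].max(axis=1)
        rho = float(np.mean(lam) ** 2)
        k = len(items)
        alpha_bounds[name] = k * rho / (1.0 + (k - 1) * rho)
    targets["alpha_latent_bound"] = alpha_bounds
    if config.clinical_coupling > 0 and config.benefit_loading > 0:
        sign = -1
    elif config.clinical_coupling == 0 or config.benefit_loading == 0:
        sign = 0
    else:
        sign = 1
    targets["expected_sign_pbi_vs_vas_change"] = sign
    return targets
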