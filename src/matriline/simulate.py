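"""Forward-time pedigree simulator with matriline-inherited sex-ratio effects.

The generator reads the hierarchical model generatively. Each founding
female receives a maternally inherited logit-scale effect
``m ~ Normal(0, sigma2_m)`` that is copied unchanged to every daughter in
her matriline (strict maternal transmission, no segregation or mutation).
Each breeding dam additionally receives her own residual effect
``e ~ Normal(0, sigma2_e)``. Offspring are male independently with
probability ``expit(mu + m + e)`` — the primary sex ratio — before any
endosymbiont mechanism acts.

Endosymbiont infection is transmitted maternally with a configurable
efficiency. Two manipulative mechanisms are available for infected dams:

* male killing: each male embryo dies with probability ``strength``,
  shrinking the brood (the hatched count reflects the removals);
* feminization: each genetic male is relabelled phenotypically female with
  probability ``rate``, leaving brood size untouched.

Reproducibility: one master seed; per-dam substreams are derived
deterministically from (generation, dam index), so identical params and
seed give byte-identical pedigrees and partial re-simulation is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.special import expit, logit

from .errors import ConfigurationError, DomainError
from .model import ParameterState
from .pedigree import Clutch, Individual, InfectionStatus, Pedigree, Sex

__all__ = [
    "Mechanism",
    "SimulationParams",
    "SimulationTruth",
    "simulate_pedigree",
    "apply_mechanism",
    "simulate_transmission",
    "expected_sexratio_male_killing",
]


@dataclass(frozen=True)
class Mechanism:
    """Endosymbiont manipulation applied to broods of infected dams."""

    kind: str = "none"  # none | male_killing | feminization
    strength: float = 0.0  # per-male probability of dying (male killing)
    rate: float = 0.0  # per-male probability of relabelling (feminization)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "male_killing", "feminization"):
            raise ConfigurationError(f"unknown mechanism kind {self.kind!r}")
        for name in ("strength", "rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"mechanism {name} must be in [0,1]")

    @classmethod
    def none(cls) -> "Mechanism":
        return cls("none")

    @classmethod
    def male_killing(cls, strength: float) -> "Mechanism":
        return cls("male_killing", strength=strength)

    @classmethod
    def feminization(cls, rate: float) -> "Mechanism":
        return cls("feminization", rate=rate)


@dataclass
class SimulationParams:
    """Generator controls.

    Defaults mirror the breeding-study conditions: a mean clutch size of 17
    eggs (Poisson), a female-biased mean sex ratio of 0.34, and matriline /
    dam variances at the posterior means estimated from the real pedigree
    (0.64 and 0.27 logit^2). ``daughters_bred_per_dam`` may be an int or
    ``("poisson", mean)``.
    """

    n_founders: int = 200
    n_generations: int = 2
    daughters_bred_per_dam: Union[int, tuple] = 2
    mu: float = float(logit(0.34))
    sigma2_m: float = 0.64
    sigma2_e: float = 0.27
    clutch_size_distribution: tuple = ("poisson", 17.0)
    clutches_per_dam: int = 1
    founder_infection_prevalence: float = 0.0
    transmission_efficiency: float = 1.0
    mechanism: Mechanism = field(default_factory=Mechanism.none)
    infection_coupled_effects: bool = False
    endosymbiont: str = "wolbachia"
    population: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1 or self.n_generations < 1:
            raise ConfigurationError(
                "n_founders and n_generations must both be >= 1"
            )
        if self.clutches_per_dam < 1:
            raise ConfigurationError("clutches_per_dam must be >= 1")
        for name in ("founder_infection_prevalence", "transmission_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1]")
        for name in ("sigma2_m", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class SimulationTruth:
    """Every latent value behind a simulated pedigree.

    ``state`` stores the generating parameters in model form: ``m`` per
    matriline (founder id), ``e`` per breeding dam. Zero variances would be
    infinite precisions, so the variances themselves are kept here.
    """

    state: ParameterState
    sigma2_m: float
    sigma2_e: float
    infected: dict[str, bool]
    params: SimulationParams

    def to_dict(self) -> dict:
        return {
            "mu": self.state.mu,
            "sigma2_m": self.sigma2_m,
            "sigma2_e": self.sigma2_e,
            "m": dict(self.state.m),
            "e": dict(self.state.e),
            "infected": dict(self.infected),
            "params": {
                "n_founders": self.params.n_founders,
                "n_generations": self.params.n_generations,
                "daughters_bred_per_dam": list(self.params.daughters_bred_per_dam)
                if isinstance(self.params.daughters_bred_per_dam, tuple)
                else self.params.daughters_bred_per_dam,
                "mu": self.params.mu,
                "sigma2_m": self.params.sigma2_m,
                "sigma2_e": self.params.sigma2_e,
                "clutch_size_distribution": list(self.params.clutch_size_distribution),
                "clutches_per_dam": self.params.clutches_per_dam,
                "founder_infection_prevalence": self.params.founder_infection_prevalence,
                "transmission_efficiency": self.params.transmission_efficiency,
                "mechanism": {
                    "kind": self.params.mechanism.kind,
                    "strength": self.params.mechanism.strength,
                    "rate": self.params.mechanism.rate,
                },
                "infection_coupled_effects": self.params.infection_coupled_effects,
                "endosymbiont": self.params.endosymbiont,
                "population": self.params.population,
                "seed": self.params.seed,
            },
        }


def apply_mechanism(
    sexes: np.ndarray,
    infected: bool,
    mechanism: Mechanism,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Apply an endosymbiont mechanism to a brood's primary sexes.

    ``sexes`` is an int array with male = 1, female = 0. Returns the
    surviving phenotypic sexes and the number of embryos killed. Uninfected
    dams (and mechanism "none") pass through unchanged.
    """
    sexes = np.asarray(sexes, dtype=np.int64)
    if not infected or mechanism.kind == "none":
        return sexes, 0
    males = sexes == 1
    if mechanism.kind == "male_killing":
        killed = males & (rng.random(sexes.size) < mechanism.strength)
        return sexes[~killed], int(killed.sum())
    # feminization: relabel, brood size unchanged
    flipped = males & (rng.random(sexes.size) < mechanism.rate)
    out = sexes.copy()
    out[flipped] = 0
    return out, 0


def simulate_transmission(
    dam_infected: bool,
    n_offspring: int,
    efficiency: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-offspring infection flags under strictly maternal transmission."""
    if not 0.0 <= efficiency <= 1.0:
        raise ConfigurationError("transmission efficiency must be in [0,1]")
    if not dam_infected:
        return np.zeros(n_offspring, dtype=bool)
    return rng.random(n_offspring) < efficiency


def expected_sexratio_male_killing(
    prevalence: float, strength: float, primary: float = 0.5
) -> float:
    """Population tertiary sex ratio under male killing, analytically.

    With founder prevalence ``p``, killing strength ``s`` and primary male
    probability ``r``: infected broods keep males with probability
    ``r (1 - s)`` per egg, so the surviving male fraction is
    ``[(1-p) r + p r (1-s)] / [(1-p) + p (1 - r s)]``.
    """
    p, s, r = prevalence, strength, primary
    males = (1 - p) * r + p * r * (1 - s)
    total = (1 - p) + p * (1 - r * s)
    if total == 0:
        raise DomainError("no surviving offspring under these parameters")
    return males / total


def _draw_clutch_size(dist: tuple, rng: np.random.Generator) -> int:
    name = dist[0]
    if name == "poisson":
        return int(rng.poisson(dist[1]))
    if name == "fixed":
        return int(dist[1])
    if name == "negative_binomial":
        # (name, n, p) in numpy's convention; allows over-dispersion
        return int(rng.negative_binomial(dist[1], dist[2]))
    raise ConfigurationError(f"unknown clutch size distribution {name!r}")


def _n_daughters_bred(spec: Union[int, tuple], rng: np.random.Generator) -> int:
    if isinstance(spec, tuple):
        if spec[0] != "poisson":
            raise ConfigurationError(
                f"unknown daughters_bred_per_dam distribution {spec[0]!r}"
            )
        return int(rng.poisson(spec[1]))
    return int(spec)


def _dam_rng(seed: int, generation: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(generation, index))
    )


def simulate_pedigree(
    params: SimulationParams,
) -> tuple[Pedigree, SimulationTruth]:
    """Simulate a multi-generation maternal pedigree with clutches.

    Founders breed in generation 1; in each later generation,
    ``daughters_bred_per_dam`` adult daughters of every current dam are
    mated and breed in turn. Every bred dam contributes
    ``clutches_per_dam`` clutches. Returns the pedigree together with a
    truth object recording all latent effects and infection flags.
    """
    master = _dam_rng(params.seed, 0, 0)

    # founders: matriline effects and infection status
    founder_ids = [f"F{i + 1:04d}" for i in range(params.n_founders)]
    infected_flags = master.random(params.n_founders) < params.founder_infection_prevalence
    m_draws = master.normal(0.0, np.sqrt(params.sigma2_m), params.n_founders)
    if params.infection_coupled_effects:
        m_draws = np.where(infected_flags, m_draws, 0.0)

    individuals: list[Individual] = []
    clutches: list[Clutch] = []
    m_by_matriline: dict[str, float] = {}
    e_by_dam: dict[str, float] = {}
    infected: dict[str, bool] = {}

    def _status(flag: bool) -> dict:
        return {
            params.endosymbiont: InfectionStatus.POSITIVE
            if flag
            else InfectionStatus.NEGATIVE
        }

    # (dam_id, matriline_id, m, infected)
    current: list[tuple[str, str, float, bool]] = []
    for fid, inf, m in zip(founder_ids, infected_flags, m_draws):
        individuals.append(
            Individual(
                id=fid,
                dam_id=None,
                sex=Sex.FEMALE,
                population=params.population,
                infections=_status(bool(inf)),
            )
        )
        infected[fid] = bool(inf)
        m_by_matriline[fid] = float(m)
        current.append((fid, fid, float(m), bool(inf)))

    next_id = 1
    for gen in range(1, params.n_generations + 1):
        next_gen: list[tuple[str, str, float, bool]] = []
        for idx, (dam_id, mat_id, m, dam_inf) in enumerate(current):
            rng = _dam_rng(params.seed, gen, idx)
            e = rng.normal(0.0, np.sqrt(params.sigma2_e))
            e_by_dam[dam_id] = float(e)
            p_male = expit(params.mu + m + e)
            daughters: list[str] = []
            for clutch_idx in range(1, params.clutches_per_dam + 1):
                size = _draw_clutch_size(params.clutch_size_distribution, rng)
                primary = (rng.random(size) < p_male).astype(np.int64)
                surviving, _n_killed = apply_mechanism(
                    primary, dam_inf, params.mechanism, rng
                )
                off_inf = simulate_transmission(
                    dam_inf, surviving.size, params.transmission_efficiency, rng
                )
                n_male = int(surviving.sum())
                n_female = int(surviving.size - n_male)
                clutches.append(
                    Clutch(
                        dam_id=dam_id,
                        clutch_index=clutch_idx,
                        n_adult_male=n_male,
                        n_adult_female=n_female,
                        n_hatched=int(surviving.size),
                    )
                )
                for sex, oinf in zip(surviving, off_inf):
                    oid = f"X{next_id:06d}"
                    next_id += 1
                    individuals.append(
                        Individual(
                            id=oid,
                            dam_id=dam_id,
                            sex=Sex.MALE if sex == 1 else Sex.FEMALE,
                            population=params.population,
                            infections=_status(bool(oinf)),
                        )
                    )
                    infected[oid] = bool(oinf)
                    if sex == 0:
                        daughters.append(oid)
            if gen < params.n_generations:
                n_bred = min(
                    _n_daughters_bred(params.daughters_bred_per_dam, rng),
                    len(daughters),
                )
                for did in daughters[:n_bred]:
                    next_gen.append((did, mat_id, m, infected[did]))
        current = next_gen

    state = ParameterState(
        mu=params.mu,
        beta={},
        m=m_by_matriline,
        e=e_by_dam,
        tau_m=1.0 / params.sigma2_m if params.sigma2_m > 0 else np.inf,
        tau_e=1.0 / params.sigma2_e if params.sigma2_e > 0 else np.inf,
    )
    truth = SimulationTruth(
        state=state,
        sigma2_m=params.sigma2_m,
        sigma2_e=params.sigma2_e,
        infected=infected,
        params=params,
    )
    return Pedigree(individuals, clutches), truth
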