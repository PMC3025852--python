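"""Pedigree domain types: individuals, clutches, maternal lineages.

A matriline is the chain of mother--daughter links back to a founding
female. Under strict maternal transmission, an endosymbiont (and the
maternally inherited sex-ratio effect in the hierarchical model) is
constant within a matriline, so the pedigree collapses to a partition of
individuals by founding female. This module provides that resolution plus
the dam-level aggregation into binomial records that the model consumes.

Sex is coded male = 1, female = 0 throughout the package: a "sex ratio"
always means the proportion of males. Only adult offspring are sexed, so
counts refer to the tertiary sex ratio (proportion of males among
offspring surviving to adulthood).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import (
    DomainError,
    PedigreeReferenceError,
    PedigreeStructureError,
    UndefinedValueError,
)

__all__ = [
    "Sex",
    "InfectionStatus",
    "Individual",
    "Clutch",
    "Pedigree",
    "DamRecord",
    "resolve_matrilines",
    "aggregate_dams",
    "tertiary_sex_ratio",
]


class Sex(str, enum.Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "U"


class InfectionStatus(str, enum.Enum):
    POSITIVE = "pos"
    NEGATIVE = "neg"
    UNTESTED = "NA"


@dataclass(frozen=True)
class Individual:
    """One spider in the pedigree.

    ``dam_id`` is ``None`` for founders (wild-caught females or individuals
    of unknown maternity). ``infections`` maps an endosymbiont name
    (e.g. ``"wolbachia"``) to its PCR status.
    """

    id: str
    dam_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    population: str = ""
    infections: Mapping[str, InfectionStatus] = field(default_factory=dict)
    treatment: Optional[str] = None
    sire_id: Optional[str] = None  # pass-through only; never used in the model

    def __post_init__(self) -> None:
        if not self.id:
            raise DomainError("individual id must be non-empty")


@dataclass(frozen=True)
class Clutch:
    """Counts for one cocoon: adults sexed at maturity, eggs hatched."""

    dam_id: str
    n_adult_male: int
    n_adult_female: int
    n_hatched: int
    clutch_index: int = 1

    def __post_init__(self) -> None:
        for name in ("n_adult_male", "n_adult_female", "n_hatched"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0 (dam {self.dam_id})")
        if self.n_adult_male + self.n_adult_female > self.n_hatched:
            raise DomainError(
                f"clutch of dam {self.dam_id} (index {self.clutch_index}): "
                f"adults {self.n_adult_male + self.n_adult_female} exceed "
                f"hatched {self.n_hatched}"
            )

    @property
    def n_adult(self) -> int:
        return self.n_adult_male + self.n_adult_female


class Pedigree:
    """A validated collection of individuals and their clutches.

    Validation enforces: unique non-empty ids, dam links that point at
    existing females, clutch dams that exist, and an acyclic dam-link graph.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        clutches: Iterable[Clutch] = (),
        validate: bool = True,
    ) -> None:
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise DomainError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self.clutches: list[Clutch] = list(clutches)
        if validate:
            self.validate()

    def validate(self) -> None:
        for ind in self.individuals.values():
            if ind.dam_id is not None:
                dam = self.individuals.get(ind.dam_id)
                if dam is None:
                    raise PedigreeReferenceError(
                        f"individual {ind.id!r}: dam_id {ind.dam_id!r} does "
                        "not exist in the pedigree"
                    )
                if dam.sex is not Sex.FEMALE:
                    raise DomainError(
                        f"individual {ind.id!r}: dam {dam.id!r} is not female "
                        f"(sex={dam.sex.value})"
                    )
        for clutch in self.clutches:
            if clutch.dam_id not in self.individuals:
                raise PedigreeReferenceError(
                    f"clutch {clutch.clutch_index} references unknown dam "
                    f"{clutch.dam_id!r}"
                )
            dam = self.individuals[clutch.dam_id]
            if dam.sex is not Sex.FEMALE:
                raise DomainError(
                    f"clutch {clutch.clutch_index}: dam {clutch.dam_id!r} is "
                    f"not female (sex={dam.sex.value})"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        resolved: set[str] = set()
        for start in self.individuals:
            if start in resolved:
                continue
            path: list[str] = []
            on_path: set[str] = set()
            cur: Optional[str] = start
            while cur is not None and cur not in resolved:
                if cur in on_path:
                    cycle = path[path.index(cur):] + [cur]
                    raise PedigreeStructureError(
                        "cyclic dam links: " + " -> ".join(cycle)
                    )
                path.append(cur)
                on_path.add(cur)
                cur = self.individuals[cur].dam_id
            resolved.update(path)

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.dam_id is None]

    def __len__(self) -> int:
        return len(self.individuals)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Pedigree({len(self.individuals)} individuals, "
            f"{len(self.clutches)} clutches)"
        )


@dataclass
class DamRecord:
    """The binomial observation unit of the hierarchical model.

    One record per dam, pooling her clutches: ``total_male`` successes out
    of ``total_male + total_female`` sexed adults, tagged with the founding
    female of her maternal lineage. ``excluded`` marks dams with zero sexed
    adult offspring; these never enter a model fit.
    """

    dam_id: str
    matriline_id: str
    total_male: int
    total_female: int
    covariates: dict = field(default_factory=dict)
    n_hatched: int = 0
    n_clutches: int = 1
    excluded: bool = False

    @property
    def total(self) -> int:
        return self.total_male + self.total_female


def resolve_matrilines(pedigree: Pedigree) -> dict[str, str]:
    """Map every individual to the founding female of its maternal lineage.

    Founders map to themselves. Males inherit their dam's matriline id;
    it is bookkeeping only and never enters the likelihood. Raises
    :class:`PedigreeStructureError` on cyclic dam links (naming the cycle)
    and :class:`PedigreeReferenceError` on a dangling dam_id.
    """
    individuals = pedigree.individuals
    result: dict[str, str] = {}
    # iterate in sorted order so the walk (and any error) is input-order
    # invariant; path compression keeps this linear overall
    for start in sorted(individuals):
        if start in result:
            continue
        path: list[str] = []
        on_path: set[str] = set()
        cur = start
        while True:
            if cur in result:
                root = result[cur]
                break
            if cur in on_path:
                cycle = path[path.index(cur):] + [cur]
                raise PedigreeStructureError(
                    "cyclic dam links: " + " -> ".join(cycle)
                )
            path.append(cur)
            on_path.add(cur)
            dam_id = individuals[cur].dam_id
            if dam_id is None:
                root = cur
                break
            if dam_id not in individuals:
                raise PedigreeReferenceError(
                    f"individual {cur!r}: dam_id {dam_id!r} does not exist"
                )
            cur = dam_id
        for node in path:
            result[node] = root
    return result


def aggregate_dams(pedigree: Pedigree, per_clutch: bool = False) -> list[DamRecord]:
    """Pool each dam's clutches into one binomial record.

    Covariates (population, infection statuses, treatment) are copied from
    the dam's Individual entry. Dams with zero sexed adult offspring are
    returned with ``excluded=True`` so callers can report them; model fits
    drop them. With ``per_clutch=True`` one record per clutch is emitted
    instead (used for the clutch-size/sex-ratio correlation, never for the
    pooled model fit).
    """
    matrilines = resolve_matrilines(pedigree)
    records: list[DamRecord] = []

    def _covariates(dam: Individual) -> dict:
        cov: dict = {"population": dam.population}
        for name, status in dam.infections.items():
            cov[name] = status.value
        if dam.treatment is not None:
            cov["treatment"] = dam.treatment
        return cov

    if per_clutch:
        for clutch in pedigree.clutches:
            dam = pedigree.individuals[clutch.dam_id]
            records.append(
                DamRecord(
                    dam_id=clutch.dam_id,
                    matriline_id=matrilines[clutch.dam_id],
                    total_male=clutch.n_adult_male,
                    total_female=clutch.n_adult_female,
                    covariates=_covariates(dam),
                    n_hatched=clutch.n_hatched,
                    n_clutches=1,
                    excluded=clutch.n_adult == 0,
                )
            )
        return records

    by_dam: dict[str, list[Clutch]] = {}
    for clutch in pedigree.clutches:
        by_dam.setdefault(clutch.dam_id, []).append(clutch)
    for dam_id in sorted(by_dam):
        clutches = by_dam[dam_id]
        dam = pedigree.individuals[dam_id]
        if dam.sex is not Sex.FEMALE:
            raise DomainError(
                f"dam {dam_id!r} has sex {dam.sex.value}; clutches must "
                "belong to females"
            )
        total_male = sum(c.n_adult_male for c in clutches)
        total_female = sum(c.n_adult_female for c in clutches)
        records.append(
            DamRecord(
                dam_id=dam_id,
                matriline_id=matrilines[dam_id],
                total_male=total_male,
                total_female=total_female,
                covariates=_covariates(dam),
                n_hatched=sum(c.n_hatched for c in clutches),
                n_clutches=len(clutches),
                excluded=(total_male + total_female) == 0,
            )
        )
    return records


def tertiary_sex_ratio(record: DamRecord) -> float:
    """Proportion of males among a dam's sexed adult offspring."""
    total = record.total_male + record.total_female
    if total == 0:
        raise UndefinedValueError(
            f"dam {record.dam_id!r}: sex ratio undefined with zero sexed "
            "adult offspring"
        )
    return record.total_male / total
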