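"""CSV / JSON / YAML interchange.

Pedigree CSV columns: ``individual_id, dam_id, sex, population, wolbachia,
rickettsia, cardinium, treatment`` (optional ``sire_id`` pass-through).
An empty ``dam_id`` marks a founder; sexes are ``M/F/U``; infection
statuses are ``pos/neg/NA``. Clutch CSV columns: ``dam_id, clutch_index,
n_adult_male, n_adult_female, n_hatched``. Comma-separated, UTF-8, header
mandatory, empty string = missing, no index column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .errors import SchemaError
from .model import McmcConfig, MaternalModelSpec
from .pedigree import Clutch, Individual, InfectionStatus, Pedigree, Sex
from .simulate import Mechanism, SimulationParams

__all__ = [
    "ENDOSYMBIONTS",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_clutch_csv",
    "write_clutch_csv",
    "write_truth_json",
    "load_config",
    "simulation_params_from_config",
    "mcmc_config_from_config",
    "model_spec_from_config",
]

ENDOSYMBIONTS = ("wolbachia", "rickettsia", "cardinium")

_PEDIGREE_COLUMNS = ["individual_id", "dam_id", "sex", "population",
                     *ENDOSYMBIONTS, "treatment"]
_CLUTCH_COLUMNS = ["dam_id", "clutch_index", "n_adult_male",
                   "n_adult_female", "n_hatched"]


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or value == ""


def read_pedigree_csv(
    path: Union[str, Path],
    clutch_path: Union[str, Path, None] = None,
) -> Pedigree:
    """Read and validate a pedigree CSV (and optionally its clutch CSV)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing pedigree columns {missing}")
    individuals = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sex = Sex(row.sex)
        except ValueError:
            raise SchemaError(
                f"{path}:{row_number}: invalid sex {row.sex!r} (use M/F/U)"
            ) from None
        infections = {}
        for name in ENDOSYMBIONTS:
            raw = getattr(row, name)
            if _is_missing(raw):
                raw = "NA"
            try:
                status = InfectionStatus(raw)
            except ValueError:
                raise SchemaError(
                    f"{path}:{row_number}: invalid {name} status {raw!r} "
                    "(use pos/neg/NA)"
                ) from None
            if status is not InfectionStatus.UNTESTED:
                infections[name] = status
        individuals.append(
            Individual(
                id=row.individual_id,
                dam_id=None if _is_missing(row.dam_id) else row.dam_id,
                sex=sex,
                population=row.population,
                infections=infections,
                treatment=None if _is_missing(row.treatment) else row.treatment,
                sire_id=getattr(row, "sire_id", None) or None,
            )
        )
    clutches = read_clutch_csv(clutch_path) if clutch_path is not None else ()
    return Pedigree(individuals, clutches)


def write_pedigree_csv(pedigree: Pedigree, path: Union[str, Path]) -> None:
    rows = []
    for ind in pedigree.individuals.values():
        row = {
            "individual_id": ind.id,
            "dam_id": ind.dam_id or "",
            "sex": ind.sex.value,
            "population": ind.population,
            "treatment": ind.treatment or "",
        }
        for name in ENDOSYMBIONTS:
            status = ind.infections.get(name, InfectionStatus.UNTESTED)
            row[name] = status.value
        rows.append(row)
    pd.DataFrame(rows, columns=_PEDIGREE_COLUMNS).to_csv(path, index=False)


def read_clutch_csv(path: Union[str, Path]) -> list[Clutch]:
    df = pd.read_csv(path, dtype={"dam_id": str})
    missing = [c for c in _CLUTCH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing clutch columns {missing}")
    clutches = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        counts = {}
        for name in ("clutch_index", "n_adult_male", "n_adult_female", "n_hatched"):
            value = getattr(row, name)
            if pd.isna(value) or int(value) != value or int(value) < 0:
                raise SchemaError(
                    f"{path}:{row_number}: {name}={value!r} is not a "
                    "non-negative integer"
                )
            counts[name] = int(value)
        try:
            clutches.append(Clutch(dam_id=row.dam_id, **counts))
        except Exception as exc:
            raise SchemaError(f"{path}:{row_number}: {exc}") from exc
    return clutches


def write_clutch_csv(clutches, path: Union[str, Path]) -> None:
    rows = [
        {
            "dam_id": c.dam_id,
            "clutch_index": c.clutch_index,
            "n_adult_male": c.n_adult_male,
            "n_adult_female": c.n_adult_female,
            "n_hatched": c.n_hatched,
        }
        for c in clutches
    ]
    pd.DataFrame(rows, columns=_CLUTCH_COLUMNS).to_csv(path, index=False)


def write_truth_json(truth, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


# --------------------------------------------------------------------------
# YAML / JSON configuration


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML (or JSON, a YAML subset) run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return config


def simulation_params_from_config(config: dict, seed=None) -> SimulationParams:
    section = dict(config.get("simulation", config))
    mech = section.pop("mechanism", None)
    if isinstance(mech, dict):
        section["mechanism"] = Mechanism(
            kind=mech.get("kind", "none"),
            strength=float(mech.get("strength", 0.0)),
            rate=float(mech.get("rate", 0.0)),
        )
    elif isinstance(mech, str):
        section["mechanism"] = Mechanism(kind=mech)
    for key in ("clutch_size_distribution", "daughters_bred_per_dam"):
        if key in section and isinstance(section[key], list):
            section[key] = tuple(section[key])
    if seed is not None:
        section["seed"] = int(seed)
    return SimulationParams(**section)


def mcmc_config_from_config(config: dict, seed=None) -> McmcConfig:
    section = dict(config.get("mcmc", {}))
    if seed is not None:
        section["seed"] = int(seed)
    return McmcConfig(**section)


def model_spec_from_config(config: dict) -> MaternalModelSpec:
    section = dict(config.get("model", {}))
    if "covariates" in section:
        section["covariates"] = tuple(section["covariates"])
    return MaternalModelSpec(**section)
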