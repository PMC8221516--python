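"""Parameter-file loading and packaged fixtures.

Species and chemical parameters live in small YAML files (packaged
fixtures under ``avirisk/data``: the California Gnatcatcher life
history and two unnamed insecticides, a chronic "reproductive stressor"
and an acute "survival stressor", with registration-study toxicity
endpoints and label constraints).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .demography import HabitatCoefficients, VitalRates
from .exposure import Chemical, ForagerProfile
from .nest import BreedingParams

__all__ = [
    "SpeciesParams",
    "load_species",
    "load_chemical",
    "packaged_species",
    "packaged_chemical",
    "PACKAGED_CHEMICALS",
]

PACKAGED_CHEMICALS = ("reproductive_stressor", "survival_stressor")


@dataclass(frozen=True)
class SpeciesParams:
    """Bundle of species parameters used across the pipeline."""

    name: str
    vitals: VitalRates
    coeffs: HabitatCoefficients
    breeding: BreedingParams
    forager: ForagerProfile


def _species_from_dict(doc: dict) -> SpeciesParams:
    return SpeciesParams(
        name=doc.get("name", "species"),
        vitals=VitalRates(s_j=doc["s_j"], s_a=doc["s_a"], f=doc["f"]),
        coeffs=HabitatCoefficients(
            alpha_f=doc.get("alpha_f", 3.0), alpha_s=doc.get("alpha_s", 5.0)
        ),
        breeding=BreedingParams(**doc.get("breeding", {})),
        forager=ForagerProfile(**doc.get("forager", {})),
    )


def load_species(path: str | Path) -> SpeciesParams:
    """Read a species parameter file (YAML)."""
    with open(path) as fh:
        return _species_from_dict(yaml.safe_load(fh))


def load_chemical(path: str | Path) -> Chemical:
    """Read a chemical parameter file (YAML)."""
    with open(path) as fh:
        return Chemical(**yaml.safe_load(fh))


def _packaged(name: str) -> dict:
    text = resources.files("avirisk").joinpath(f"data/{name}.yaml").read_text()
    return yaml.safe_load(text)


def packaged_species(name: str = "cagn") -> SpeciesParams:
    """Packaged species fixture (default: California Gnatcatcher)."""
    return _species_from_dict(_packaged(f"species_{name}"))


def packaged_chemical(name: str) -> Chemical:
    """Packaged chemical fixture: 'reproductive_stressor' or 'survival_stressor'."""
    if name not in PACKAGED_CHEMICALS:
        raise ValueError(f"unknown packaged chemical {name!r}; have {PACKAGED_CHEMICALS}")
    return Chemical(**_packaged(name))
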