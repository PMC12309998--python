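"""Trait registry for the winter-barley drought phenotyping design.

The study records five morphological and thirteen yield-related traits per
plant at full maturity.  Fourteen are measured directly; four (MTKW, ATKW,
ASN, ASW) are computed from the measured grain weights, grain numbers and
the reproductive tiller count.  The formulas used here are a documented
reconstruction (the trait names alone leave the denominators ambiguous)
and can be overridden when deriving, see
:func:`barleystress.tables.derive_traits`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

#: Closed set of treatment labels: well-watered control, single drought at
#: booting (Z49), and double drought at first node appearance + booting
#: (Z31 + Z49).
TREATMENTS = ("C", "Ds", "Dd")

#: Aliases accepted by the readers (resolved after whitespace stripping;
#: matching is otherwise case-sensitive).
TREATMENT_ALIASES = {
    "C": "C",
    "Ds": "Ds",
    "Dd": "Dd",
    "control": "C",
    "single": "Ds",
    "double": "Dd",
}

ROW_TYPES = ("2R", "6R")


@dataclass(frozen=True)
class TraitDefinition:
    """One entry of the trait registry."""

    code: str
    name: str
    category: str  # "morphological" or "yield"
    units: str
    derived_from: Optional[str] = None  # formula string over registered codes


_DEFS = [
    TraitDefinition("LIN", "length of the last internode", "morphological", "cm"),
    TraitDefinition("EaL", "length of the main ear", "morphological", "cm"),
    TraitDefinition("SPS", "number of spikelets in the main ear", "morphological", "count"),
    TraitDefinition("DENS", "main ear density", "morphological", "count/cm"),
    TraitDefinition("BIOM", "aboveground dry weight of plant without the ears", "morphological", "g"),
    TraitDefinition("RT", "number of reproductive tillers", "yield", "count"),
    TraitDefinition("MSSN", "grain number per spikelet of the main ear", "yield", "count"),
    TraitDefinition("MEaW", "main ear weight", "yield", "g"),
    TraitDefinition("MSW", "weight of grains in the main ear", "yield", "g"),
    TraitDefinition("MSN", "number of grains in the main ear", "yield", "count"),
    TraitDefinition("SEaW", "total side ears weight", "yield", "g"),
    TraitDefinition("SSW", "total grain weight in the side ears", "yield", "g"),
    TraitDefinition("SSN", "total grain number in the side ears", "yield", "count"),
    TraitDefinition("GY", "grain yield per plant", "yield", "g"),
    TraitDefinition("MTKW", "thousand kernel weight in the main ear", "yield",
                    "g/1000 kernels", derived_from="1000 * MSW / MSN"),
    TraitDefinition("ATKW", "average thousand kernel weight", "yield",
                    "g/1000 kernels", derived_from="1000 * (MSW + SSW) / (MSN + SSN)"),
    TraitDefinition("ASN", "average number of grains per spike harvested", "yield",
                    "count", derived_from="(MSN + SSN) / RT"),
    TraitDefinition("ASW", "average weight of grains per spike harvested", "yield",
                    "g", derived_from="(MSW + SSW) / RT"),
]

#: The 18 pre-registered study traits, keyed by code.
REGISTRY: dict[str, TraitDefinition] = {d.code: d for d in _DEFS}

MEASURED_TRAITS = tuple(d.code for d in _DEFS if d.derived_from is None)
DERIVED_TRAITS = tuple(d.code for d in _DEFS if d.derived_from is not None)


@dataclass(frozen=True)
class GenotypeMeta:
    """Cultivar metadata: name, spike row type (2R two-rowed / 6R six-rowed)."""

    name: str
    row_type: str
    origin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.row_type not in ROW_TYPES:
            raise ValueError(
                f"row_type must be one of {ROW_TYPES}, got {self.row_type!r}"
            )


def is_registered(code: str) -> bool:
    return code in REGISTRY
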