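"""Species registry for the two-loop mammalian circadian clock model.

The network couples two interlocked feedback loops around the CLOCK/BMAL
transcriptional activator:

* the **PC loop** — *Per* and *Cry* transcripts are translated in the
  cytoplasm, PER is reversibly phosphorylated, PER/CRY and PER*/CRY
  complexes form, shuttle into the nucleus and inhibit CLOCK/BMAL-mediated
  transcription;
* the **RBR loop** — *Rev-Erb* and *Ror* transcripts produce nuclear
  REV-ERB and ROR proteins which compete for RORE sites on the *Bmal*
  promoter (REV-ERB represses, ROR activates); nuclear BMAL binds CLOCK
  to regenerate the activator.

There are 19 dynamic state variables: 5 mRNAs, 8 cytoplasmic
proteins/complexes and 6 nuclear proteins/complexes.  Free nuclear CLOCK
is treated as a constant reservoir and absorbed into the CLOCK/BMAL
association rate, so it is not a state variable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Compartment(enum.Enum):
    NUCLEUS = "nucleus"
    CYTOPLASM = "cytoplasm"


class Role(enum.Enum):
    MRNA = "mRNA"
    PROTEIN = "protein"
    COMPLEX = "complex"


@dataclass(frozen=True)
class SpeciesId:
    """One dynamic state variable of the clock network."""

    name: str
    compartment: Compartment
    role: Role
    index: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


_N, _C = Compartment.NUCLEUS, Compartment.CYTOPLASM
_M, _P, _X = Role.MRNA, Role.PROTEIN, Role.COMPLEX

#: Canonical state ordering used by every array in the package.
SPECIES: tuple[SpeciesId, ...] = (
    SpeciesId("CLOCK/BMAL", _N, _X, 0),
    SpeciesId("PERp/CRY_N", _N, _X, 1),
    SpeciesId("PER/CRY_N", _N, _X, 2),
    SpeciesId("BMAL_N", _N, _P, 3),
    SpeciesId("REV-ERB_N", _N, _P, 4),
    SpeciesId("ROR_N", _N, _P, 5),
    SpeciesId("Per", _C, _M, 6),
    SpeciesId("Cry", _C, _M, 7),
    SpeciesId("Rev-Erb", _C, _M, 8),
    SpeciesId("Ror", _C, _M, 9),
    SpeciesId("Bmal", _C, _M, 10),
    SpeciesId("PER_C", _C, _P, 11),
    SpeciesId("PERp_C", _C, _P, 12),
    SpeciesId("CRY_C", _C, _P, 13),
    SpeciesId("PERp/CRY_C", _C, _X, 14),
    SpeciesId("PER/CRY_C", _C, _X, 15),
    SpeciesId("REV-ERB_C", _C, _P, 16),
    SpeciesId("ROR_C", _C, _P, 17),
    SpeciesId("BMAL_C", _C, _P, 18),
)

N_SPECIES = len(SPECIES)

#: Conventional short symbols (x: nuclear, y: mRNA, z: cytoplasmic), kept
#: as aliases because the modelling literature on this network uses them.
ALIASES: dict[str, str] = {
    "x1": "CLOCK/BMAL",
    "x2": "PERp/CRY_N",
    "x3": "PER/CRY_N",
    "x4": "BMAL_N",
    "x5": "REV-ERB_N",
    "x6": "ROR_N",
    "y1": "Per",
    "y2": "Cry",
    "y3": "Rev-Erb",
    "y4": "Ror",
    "y5": "Bmal",
    "z1": "PER_C",
    "z2": "PERp_C",
    "z3": "CRY_C",
    "z4": "PERp/CRY_C",
    "z5": "PER/CRY_C",
    "z6": "REV-ERB_C",
    "z7": "ROR_C",
    "z8": "BMAL_C",
}

#: Virtual readout: the pooled nuclear inhibitor PER/CRY_N + PERp/CRY_N.
PERCRY_POOL = "percry_pool"

_BY_NAME = {s.name: s for s in SPECIES}
# tolerant lookups: aliases, slash/star-free spellings, case-insensitive
_LOOKUP: dict[str, SpeciesId] = {}
for _s in SPECIES:
    for key in (_s.name, _s.name.replace("/", "_"), _s.name.replace("/", "")):
        _LOOKUP[key.lower()] = _s
for _a, _n in ALIASES.items():
    _LOOKUP[_a.lower()] = _BY_NAME[_n]


def species_by_name(name: str) -> SpeciesId:
    """Resolve a species by canonical name, alias (x1..z8) or loose spelling."""
    try:
        return _LOOKUP[name.strip().lower()]
    except KeyError:
        raise KeyError(
            f"unknown species {name!r}; known names: "
            + ", ".join(s.name for s in SPECIES)
        ) from None


def species_index(name: str) -> int:
    return species_by_name(name).index


#: The five gene entities of the model (gene families, not paralogs).
GENES: tuple[str, ...] = ("Per", "Cry", "Rev-Erb", "Ror", "Bmal")

#: gene -> (mRNA index, translated cytoplasmic protein index)
GENE_TO_MRNA: dict[str, int] = {
    "Per": 6,
    "Cry": 7,
    "Rev-Erb": 8,
    "Ror": 9,
    "Bmal": 10,
}
GENE_TO_PROTEIN: dict[str, int] = {
    "Per": 11,
    "Cry": 13,
    "Rev-Erb": 16,
    "Ror": 17,
    "Bmal": 18,
}


def gene_by_name(name: str) -> str:
    """Normalize a gene-entity name (``per``, ``rev-erb``, ``reverb`` ...)."""
    key = name.strip().lower().replace("-", "").replace("_", "")
    for g in GENES:
        if g.lower().replace("-", "") == key:
            return g
    raise KeyError(f"unknown gene entity {name!r}; choose from {GENES}")
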