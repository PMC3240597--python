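"""The 71 kinetic parameters of the clock model.

Naming scheme (conventional for this model family):

* ``V1max..V5max`` — maximal/basal transcription rates for the five gene
  entities in the fixed order Per, Cry, Rev-Erb, Ror, Bmal (the same 1..5
  order is used for every per-gene parameter group);
* ``ka*``/``b*``/``f*`` — activation constant, Hill coefficient and fold
  activation of the promoter's activator (CLOCK/BMAL for Per, Cry,
  Rev-Erb, Ror; nuclear ROR for Bmal);
* ``ki1..ki4``/``c1..c4`` — inhibition constant and Hill coefficient of
  the nuclear PER/CRY pool on the four E-box promoters;
* ``ki5``/``c5`` — REV-ERB_N repression of Bmal (RORE competition);
* ``ki6``/``c6`` — REV-ERB_N repression of Cry (loop cross-talk);
* ``kp1..kp5`` — translation rates;
* ``kphos``/``kdphos`` — cytoplasmic PER phosphorylation cycle;
* ``kfz4/kdz4``, ``kfz5/kdz5`` — association/dissociation of the
  cytoplasmic PER*/CRY and PER/CRY complexes;
* ``kfx1/kdx1`` — CLOCK/BMAL formation from nuclear BMAL (free CLOCK is
  constant and absorbed into ``kfx1``) and its dissociation;
* ``kiz4..kiz8`` — nuclear import; ``kex1``/``kex2`` — nuclear export of
  PER/CRY_N and PERp/CRY_N;
* ``dy1..dy5``, ``dz1..dz8``, ``dx1..dx6`` — linear degradation, one rate
  per species (dy: mRNA, dz: cytoplasmic, dx: nuclear).

Concentrations are in the model's normalized arbitrary units; first-order
rates are h^-1 and bimolecular association rates (a.u.·h)^-1.

The default values shipped in ``data/parameters.tsv`` are a calibrated
set: the wiring and rate laws are fixed by the network design, and the
values were calibrated once so that the wild-type limit cycle has a
23.5 h period with the documented cycle means and perturbation
phenotypes (see docs/methods.md).
"""

from __future__ import annotations

import importlib.resources
from collections.abc import Iterator, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "N_PARAMS",
    "ClockParameters",
    "ConfigurationError",
]

# (name, unit, description) in canonical vector order
_PARAM_TABLE: tuple[tuple[str, str, str], ...] = (
    # transcription
    ("V1max", "a.u./h", "Per basal transcription rate"),
    ("V2max", "a.u./h", "Cry basal transcription rate"),
    ("V3max", "a.u./h", "Rev-Erb basal transcription rate"),
    ("V4max", "a.u./h", "Ror basal transcription rate"),
    ("V5max", "a.u./h", "Bmal basal transcription rate"),
    ("ka1", "a.u.", "CLOCK/BMAL activation constant, Per promoter"),
    ("ka2", "a.u.", "CLOCK/BMAL activation constant, Cry promoter"),
    ("ka3", "a.u.", "CLOCK/BMAL activation constant, Rev-Erb promoter"),
    ("ka4", "a.u.", "CLOCK/BMAL activation constant, Ror promoter"),
    ("ka5", "a.u.", "ROR_N activation constant, Bmal RORE"),
    ("b1", "1", "activation Hill coefficient, Per"),
    ("b2", "1", "activation Hill coefficient, Cry"),
    ("b3", "1", "activation Hill coefficient, Rev-Erb"),
    ("b4", "1", "activation Hill coefficient, Ror"),
    ("b5", "1", "activation Hill coefficient, Bmal"),
    ("f1", "1", "fold activation, Per"),
    ("f2", "1", "fold activation, Cry"),
    ("f3", "1", "fold activation, Rev-Erb"),
    ("f4", "1", "fold activation, Ror"),
    ("f5", "1", "fold activation, Bmal"),
    ("ki1", "a.u.", "PER/CRY pool inhibition constant, Per"),
    ("ki2", "a.u.", "PER/CRY pool inhibition constant, Cry"),
    ("ki3", "a.u.", "PER/CRY pool inhibition constant, Rev-Erb"),
    ("ki4", "a.u.", "PER/CRY pool inhibition constant, Ror"),
    ("ki5", "a.u.", "REV-ERB_N inhibition constant, Bmal RORE"),
    ("ki6", "a.u.", "REV-ERB_N inhibition constant, Cry"),
    ("c1", "1", "inhibition Hill coefficient, Per"),
    ("c2", "1", "inhibition Hill coefficient, Cry"),
    ("c3", "1", "inhibition Hill coefficient, Rev-Erb"),
    ("c4", "1", "inhibition Hill coefficient, Ror"),
    ("c5", "1", "inhibition Hill coefficient, Bmal RORE"),
    ("c6", "1", "inhibition Hill coefficient, Cry by REV-ERB_N"),
    # translation
    ("kp1", "1/h", "Per translation rate"),
    ("kp2", "1/h", "Cry translation rate"),
    ("kp3", "1/h", "Rev-Erb translation rate"),
    ("kp4", "1/h", "Ror translation rate"),
    ("kp5", "1/h", "Bmal translation rate"),
    # phosphorylation
    ("kphos", "1/h", "PER_C phosphorylation"),
    ("kdphos", "1/h", "PERp_C dephosphorylation"),
    # complex formation
    ("kfz4", "1/(a.u. h)", "PERp_C + CRY_C association"),
    ("kdz4", "1/h", "PERp/CRY_C dissociation"),
    ("kfz5", "1/(a.u. h)", "PER_C + CRY_C association"),
    ("kdz5", "1/h", "PER/CRY_C dissociation"),
    ("kfx1", "1/h", "CLOCK/BMAL formation from BMAL_N (CLOCK absorbed)"),
    ("kdx1", "1/h", "CLOCK/BMAL dissociation"),
    # transport
    ("kiz4", "1/h", "PERp/CRY_C nuclear import"),
    ("kiz5", "1/h", "PER/CRY_C nuclear import"),
    ("kiz6", "1/h", "REV-ERB_C nuclear import"),
    ("kiz7", "1/h", "ROR_C nuclear import"),
    ("kiz8", "1/h", "BMAL_C nuclear import"),
    ("kex1", "1/h", "PER/CRY_N nuclear export"),
    ("kex2", "1/h", "PERp/CRY_N nuclear export"),
    # degradation: mRNA
    ("dy1", "1/h", "Per mRNA degradation"),
    ("dy2", "1/h", "Cry mRNA degradation"),
    ("dy3", "1/h", "Rev-Erb mRNA degradation"),
    ("dy4", "1/h", "Ror mRNA degradation"),
    ("dy5", "1/h", "Bmal mRNA degradation"),
    # degradation: cytoplasm
    ("dz1", "1/h", "PER_C degradation"),
    ("dz2", "1/h", "PERp_C degradation"),
    ("dz3", "1/h", "CRY_C degradation"),
    ("dz4", "1/h", "PERp/CRY_C degradation"),
    ("dz5", "1/h", "PER/CRY_C degradation"),
    ("dz6", "1/h", "REV-ERB_C degradation"),
    ("dz7", "1/h", "ROR_C degradation"),
    ("dz8", "1/h", "BMAL_C degradation"),
    # degradation: nucleus
    ("dx1", "1/h", "CLOCK/BMAL degradation"),
    ("dx2", "1/h", "PERp/CRY_N degradation"),
    ("dx3", "1/h", "PER/CRY_N degradation"),
    ("dx4", "1/h", "BMAL_N degradation"),
    ("dx5", "1/h", "REV-ERB_N degradation"),
    ("dx6", "1/h", "ROR_N degradation"),
)

PARAM_NAMES: tuple[str, ...] = tuple(name for name, _, _ in _PARAM_TABLE)
PARAM_UNITS: dict[str, str] = {n: u for n, u, _ in _PARAM_TABLE}
PARAM_DESCRIPTIONS: dict[str, str] = {n: d for n, _, d in _PARAM_TABLE}
N_PARAMS = len(PARAM_NAMES)
_INDEX = {n: i for i, n in enumerate(PARAM_NAMES)}

_HILL_COEFFS = frozenset(
    ("b1", "b2", "b3", "b4", "b5", "c1", "c2", "c3", "c4", "c5", "c6")
)


class ConfigurationError(ValueError):
    """Raised when a parameter set is missing entries or violates bounds."""


class ClockParameters(Mapping[str, float]):
    """Immutable, validated set of the 71 model rate constants.

    Behaves as a read-only mapping ``name -> value``; :meth:`as_array`
    gives the canonical vector used by the numerical kernel.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        missing = [n for n in PARAM_NAMES if n not in values]
        if missing:
            raise ConfigurationError(f"missing parameter(s): {', '.join(missing)}")
        unknown = [n for n in values if n not in _INDEX]
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {', '.join(unknown)}")
        vec = np.array([float(values[n]) for n in PARAM_NAMES], dtype=float)
        for name, v in zip(PARAM_NAMES, vec):
            if not np.isfinite(v):
                raise ConfigurationError(f"parameter {name} is not finite: {v}")
            if v < 0:
                raise ConfigurationError(f"parameter {name} is negative: {v}")
            if name in _HILL_COEFFS and v < 1:
                raise ConfigurationError(
                    f"Hill coefficient {name} must be >= 1, got {v}"
                )
        vec.flags.writeable = False
        object.__setattr__(self, "_values", vec)

    # Mapping interface -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        try:
            return float(self._values[_INDEX[name]])
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(PARAM_NAMES)

    def __len__(self) -> int:
        return N_PARAMS

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("ClockParameters is immutable")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ClockParameters({N_PARAMS} rates, dy1={self['dy1']:g})"

    # ------------------------------------------------------------------
    def as_array(self) -> np.ndarray:
        """Parameter vector in canonical :data:`PARAM_NAMES` order."""
        return self._values

    def replace(self, **changes: float) -> "ClockParameters":
        """New set with named values replaced."""
        d = dict(zip(PARAM_NAMES, self._values))
        d.update(changes)
        return ClockParameters(d)

    def scaled(self, name: str, factor: float) -> "ClockParameters":
        """New set with one parameter multiplied by ``factor``."""
        return self.replace(**{name: self[name] * factor})

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "ClockParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_PARAMS,):
            raise ConfigurationError(f"expected shape ({N_PARAMS},), got {vec.shape}")
        return cls(dict(zip(PARAM_NAMES, vec)))

    @classmethod
    def default(cls) -> "ClockParameters":
        """The calibrated wild-type parameter set shipped with the package."""
        return cls(_load_default_table())


def _load_default_table() -> dict[str, float]:
    text = (
        importlib.resources.files("circlock")
        .joinpath("data/parameters.tsv")
        .read_text()
    )
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        fields = line.split("\t")
        name, raw = fields[0], fields[1]
        try:
            values[name] = float(raw)
        except ValueError:
            raise ConfigurationError(
                f"unparsable value for parameter {name!r}: {raw!r}"
            ) from None
    return values


def write_parameter_table(values: Mapping[str, float], path) -> None:
    """Write a parameter table in the package's flat TSV format."""
    lines = ["name\tvalue\tunit\tdescription"]
    for n in PARAM_NAMES:
        lines.append(f"{n}\t{values[n]:.10g}\t{PARAM_UNITS[n]}\t{PARAM_DESCRIPTIONS[n]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
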