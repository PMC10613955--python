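"""Domain model for a computed-NMR assignment study.

A *study* pairs an experimental assignment table — equivalence groups of
nuclei sharing one observed chemical shift — with one or more conformer
records carrying per-atom isotropic shieldings and a relative energy.
Equivalent nuclei (e.g. the three protons of a freely rotating methyl)
give a single NMR signal, so computed values are averaged over each
group before comparison with experiment.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import (
    AssignmentInconsistencyError,
    DuplicateGroupError,
    EmptyStudyError,
    IncompleteConformerError,
)

#: kJ/mol per hartree (CODATA), applied before any energy windowing.
HARTREE_TO_KJMOL = 2625.49964

ENERGY_UNITS = ("hartree", "kJ/mol")


class Nucleus(str, enum.Enum):
    """NMR-active nucleus observed in the study: ``1H`` or ``13C``."""

    H1 = "1H"
    C13 = "13C"

    @property
    def element(self) -> str:
        return "H" if self is Nucleus.H1 else "C"

    @classmethod
    def parse(cls, label: str) -> "Nucleus":
        label = str(label).strip()
        for nuc in cls:
            if label in (nuc.value, nuc.name):
                return nuc
        raise ValueError(f"unknown nucleus label {label!r}; expected one of "
                         f"{[n.value for n in cls]}")


@dataclass(frozen=True)
class AtomRecord:
    """One atom in engine output order: 1-based index plus element symbol."""

    atom_index: int
    element: str

    def __post_init__(self) -> None:
        if self.atom_index < 1:
            raise ValueError("atom_index must be >= 1 (1-based engine order)")
        if not self.element:
            raise ValueError("element symbol must be nonempty")


@dataclass(frozen=True)
class EquivalenceGroup:
    """A set of symmetry/exchange-equivalent atoms sharing one experimental shift.

    Parameters
    ----------
    group_id : str
        Label, e.g. ``"C14"`` or ``"Me-29"``.
    nucleus : Nucleus
        Which nucleus the group's shift belongs to.
    atom_indices : tuple of int
        1-based atom indices in engine output order.
    delta_exp : float
        Experimental chemical shift in ppm.
    """

    group_id: str
    nucleus: Nucleus
    atom_indices: tuple[int, ...]
    delta_exp: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_indices", tuple(int(i) for i in self.atom_indices))
        if not self.atom_indices:
            raise ValueError(f"group {self.group_id!r}: atom_indices must be nonempty")
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError(f"group {self.group_id!r}: atom_indices must be distinct")
        if any(i < 1 for i in self.atom_indices):
            raise ValueError(f"group {self.group_id!r}: atom indices are 1-based")
        if not math.isfinite(self.delta_exp):
            raise ValueError(f"group {self.group_id!r}: delta_exp must be finite")


@dataclass(frozen=True)
class ConformerRecord:
    """One optimized geometry: identity, energy, and per-atom isotropic shieldings.

    ``energy`` carries its declared unit (``"hartree"`` or ``"kJ/mol"``);
    relative energies are computed downstream, so absolute offsets never
    matter. ``shieldings`` maps 1-based atom index to isotropic shielding
    in ppm.
    """

    conformer_id: str
    energy: float
    energy_unit: str
    shieldings: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.energy_unit not in ENERGY_UNITS:
            raise ValueError(f"unsupported energy unit {self.energy_unit!r}; "
                             f"expected one of {ENERGY_UNITS}")
        if not math.isfinite(self.energy):
            raise ValueError(f"conformer {self.conformer_id!r}: energy must be finite")
        object.__setattr__(self, "shieldings",
                           {int(k): float(v) for k, v in self.shieldings.items()})

    def energy_kJmol(self) -> float:
        """Energy expressed in kJ/mol (hartree converted, offsets untouched)."""
        if self.energy_unit == "hartree":
            return self.energy * HARTREE_TO_KJMOL
        return self.energy


@dataclass(frozen=True)
class EnsembleConfig:
    """Thermodynamic settings for Boltzmann conformer weighting.

    Defaults: T = 298 K, R = 8.3145 J K⁻¹ mol⁻¹, 10 kJ/mol energy window.
    """

    temperature_K: float = 298.0
    gas_constant: float = 8.3145
    window_kJmol: float = 10.0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("invalid temperature: temperature_K must be > 0")
        if self.window_kJmol < 0:
            raise ValueError("window_kJmol must be >= 0")


@dataclass(frozen=True, order=True)
class MethodKey:
    """One DFT method combination: exchange-correlation functional × basis set."""

    functional: str
    basis_set: str

    def __post_init__(self) -> None:
        if not self.functional or not self.basis_set:
            raise ValueError("functional and basis_set must be nonempty")

    def __str__(self) -> str:
        return f"{self.functional}/{self.basis_set}"


@dataclass(frozen=True)
class StudyBundle:
    """Validated pairing of equivalence groups with conformer records.

    ``elements`` optionally maps atom index to element symbol (as reported
    by the engine), enabling nucleus/element consistency checks.
    """

    groups: tuple[EquivalenceGroup, ...]
    conformers: tuple[ConformerRecord, ...]
    elements: Mapping[int, str] = field(default_factory=dict)

    def groups_for(self, nucleus: Nucleus) -> tuple[EquivalenceGroup, ...]:
        return tuple(g for g in self.groups if g.nucleus is nucleus)

    def relative_energies_kJmol(self) -> dict[str, float]:
        """Per-conformer energies in kJ/mol relative to the ensemble minimum."""
        absolute = {c.conformer_id: c.energy_kJmol() for c in self.conformers}
        floor = min(absolute.values())
        return {cid: e - floor for cid, e in absolute.items()}


def validate_study(
    groups: Sequence[EquivalenceGroup],
    conformers: Sequence[ConformerRecord],
    elements: Mapping[int, str] | None = None,
) -> StudyBundle:
    """Check group/conformer cross-consistency and return a :class:`StudyBundle`.

    Every atom referenced by any group must be present in every conformer's
    shielding map, group ids must be unique, and — when ``elements`` is
    supplied — each group's atoms must carry the element implied by its
    nucleus.

    Raises
    ------
    EmptyStudyError, DuplicateGroupError, IncompleteConformerError,
    AssignmentInconsistencyError
    """
    if not groups or not conformers:
        raise EmptyStudyError("empty study: need at least one group and one conformer")

    seen: set[str] = set()
    for g in groups:
        if g.group_id in seen:
            raise DuplicateGroupError(f"duplicate group: {g.group_id!r}")
        seen.add(g.group_id)

    elements = dict(elements or {})
    for g in groups:
        for idx in g.atom_indices:
            if idx in elements and elements[idx] != g.nucleus.element:
                raise AssignmentInconsistencyError(
                    f"assignment inconsistency: group {g.group_id!r} is "
                    f"{g.nucleus.value} but atom {idx} is element "
                    f"{elements[idx]!r}")
            for c in conformers:
                if idx not in c.shieldings:
                    raise IncompleteConformerError(
                        f"incomplete conformer: {c.conformer_id!r} lacks atom "
                        f"{idx} required by group {g.group_id!r}")

    return StudyBundle(tuple(groups), tuple(conformers), elements)


def group_average(per_atom_values: Mapping[int, float],
                  group: EquivalenceGroup) -> float:
    """Arithmetic mean of a quantity over a group's equivalent atoms.

    Equivalent nuclei exchange fast on the NMR timescale, so the observed
    signal corresponds to the plain average of the per-atom values.
    """
    try:
        vals = [per_atom_values[i] for i in group.atom_indices]
    except KeyError as exc:
        raise IncompleteConformerError(
            f"incomplete conformer: atom {exc.args[0]} required by group "
            f"{group.group_id!r} is missing") from exc
    # fsum: correctly rounded, hence invariant under atom-order permutation
    return math.fsum(vals) / len(vals)
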