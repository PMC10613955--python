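"""Readers and writers bridging engine output and tidy interchange tables.

Two entry points exist for getting shieldings into the pipeline:

* :func:`parse_engine_log` extracts per-atom isotropic shieldings (from
  ``Magnetic shielding tensor (ppm)`` sections with ``Isotropic =`` atom
  lines) and the final self-consistent-field energy (last ``SCF Done:``
  line wins, in hartree) from the common quantum-chemistry log dialect.
* tidy delimited tables, the engine-agnostic interchange format:

  - shieldings: ``conformer_id,atom_index,element,isotropic_shielding_ppm``
  - energies:   ``conformer_id,energy,unit`` with unit hartree or kJ/mol
  - assignments: ``group_id,nucleus,atom_indices,delta_exp_ppm`` with
    semicolon-separated 1-based atom indices and nucleus in {1H, 13C}

On reading, hartree energies are converted (1 hartree = 2625.49964
kJ/mol) and immediately re-expressed relative to the ensemble minimum,
so absolute electronic-energy offsets never propagate downstream.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .errors import EmptyStudyError, FormatError, MalformedLogError
from .study import (HARTREE_TO_KJMOL, ConformerRecord, EquivalenceGroup,
                    Nucleus, StudyBundle, validate_study)

__all__ = ["parse_engine_log", "parse_logs", "read_tables", "write_tables",
           "read_assignments", "write_assignments"]

SHIELDING_COLUMNS = ["conformer_id", "atom_index", "element",
                     "isotropic_shielding_ppm"]
ENERGY_COLUMNS = ["conformer_id", "energy", "unit"]
ASSIGNMENT_COLUMNS = ["group_id", "nucleus", "atom_indices", "delta_exp_ppm"]

_SHIELDING_SECTION = re.compile(r"Magnetic shielding tensor \(ppm\)")
_ISOTROPIC_LINE = re.compile(
    r"^\s*(\d+)\s+([A-Za-z]{1,2})\s+Isotropic\s*=\s*(-?\d+(?:\.\d+)?)")
_SCF_LINE = re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*(-?\d+(?:\.\d+)?(?:[DEde][+-]?\d+)?)")


def parse_engine_log(
    source: str | Path | TextIO,
    conformer_id: str | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Extract shieldings and the final SCF energy from one engine log.

    Parameters
    ----------
    source : path or text stream
        The log text. Line-ending dialect and leading whitespace are
        irrelevant.
    conformer_id : str, optional
        Identity recorded in the returned table; defaults to the file
        stem, or ``"conformer"`` for anonymous streams.

    Returns
    -------
    (shieldings, energy_hartree)
        ``shieldings`` is a tidy fragment with the interchange columns;
        ``energy_hartree`` is the last SCF energy seen, or None (with a
        warning) when the log has no energy line. A log with no
        shielding section yields an empty fragment and a warning rather
        than an error.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        path = Path(source)
        text = path.read_text()
        conformer_id = conformer_id or path.stem
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    conformer_id = conformer_id or "conformer"

    energy: float | None = None
    rows: list[tuple[str, int, str, float]] = []
    in_section = False
    seen: set[int] = set()
    for line in io.StringIO(text):
        if _SHIELDING_SECTION.search(line):
            in_section = True
            continue
        m = _SCF_LINE.search(line)
        if m:
            energy = float(m.group(1).replace("D", "E").replace("d", "e"))
            continue
        if in_section:
            m = _ISOTROPIC_LINE.match(line)
            if m:
                idx = int(m.group(1))
                if idx in seen:
                    raise MalformedLogError(
                        f"malformed log: duplicate atom index {idx} in "
                        f"shielding block")
                seen.add(idx)
                rows.append((conformer_id, idx, m.group(2), float(m.group(3))))

    if not rows:
        warnings.warn(f"no shielding block found in log for {conformer_id!r}",
                      stacklevel=2)
    if energy is None:
        warnings.warn(f"no SCF energy line found in log for {conformer_id!r}",
                      stacklevel=2)
    frag = pd.DataFrame(rows, columns=SHIELDING_COLUMNS)
    return frag, energy


def parse_logs(paths: Sequence[str | Path]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse several logs (one conformer each) into interchange tables."""
    shield_frames, energy_rows = [], []
    for p in paths:
        frag, energy = parse_engine_log(p)
        shield_frames.append(frag)
        if energy is not None:
            energy_rows.append((Path(p).stem, energy, "hartree"))
    shieldings = (pd.concat(shield_frames, ignore_index=True)
                  if shield_frames else pd.DataFrame(columns=SHIELDING_COLUMNS))
    energies = pd.DataFrame(energy_rows, columns=ENERGY_COLUMNS)
    return shieldings, energies


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"format error: {what} table missing column(s) "
                          f"{missing}")


def read_assignments(path: str | Path) -> list[EquivalenceGroup]:
    """Read an assignment table into equivalence groups."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ASSIGNMENT_COLUMNS, "assignments")
    groups = []
    for i, row in df.iterrows():
        try:
            nucleus = Nucleus.parse(row["nucleus"])
        except ValueError as exc:
            raise FormatError(f"format error: assignments row {i}, column "
                              f"'nucleus': {exc}") from exc
        try:
            indices = tuple(int(tok) for tok in str(row["atom_indices"]).split(";"))
            groups.append(EquivalenceGroup(
                group_id=str(row["group_id"]), nucleus=nucleus,
                atom_indices=indices, delta_exp=float(row["delta_exp_ppm"])))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"format error: assignments row {i}: {exc}") from exc
    return groups


def write_assignments(groups: Sequence[EquivalenceGroup], path: str | Path) -> None:
    rows = [(g.group_id, g.nucleus.value,
             ";".join(str(i) for i in g.atom_indices), repr(g.delta_exp))
            for g in groups]
    pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(path, index=False)


def read_tables(
    shieldings_path: str | Path,
    energies_path: str | Path,
    assignments_path: str | Path,
) -> StudyBundle:
    """Read interchange tables into a validated study bundle.

    Energies are converted to kJ/mol (hartree × 2625.49964) and
    re-expressed relative to the ensemble minimum before the bundle is
    built.
    """
    shieldings = pd.read_csv(shieldings_path, float_precision="round_trip")
    energies = pd.read_csv(energies_path, float_precision="round_trip")
    _require_columns(shieldings, SHIELDING_COLUMNS, "shieldings")
    _require_columns(energies, ENERGY_COLUMNS, "energies")

    dup = shieldings.duplicated(subset=["conformer_id", "atom_index"])
    if dup.any():
        raise FormatError(f"format error: shieldings rows "
                          f"{list(shieldings.index[dup])} duplicate "
                          f"(conformer_id, atom_index)")
    if not np.isfinite(shieldings["isotropic_shielding_ppm"]).all():
        bad = int(shieldings.index[~np.isfinite(
            shieldings["isotropic_shielding_ppm"])][0])
        raise FormatError(f"format error: shieldings row {bad}, column "
                          f"'isotropic_shielding_ppm' is not finite")
    if energies["conformer_id"].duplicated().any():
        raise FormatError("format error: energies column 'conformer_id' has "
                          "duplicates")
    bad_units = set(energies["unit"]) - {"hartree", "kJ/mol"}
    if bad_units:
        raise FormatError(f"format error: unsupported unit {sorted(bad_units)} "
                          f"in energies column 'unit'")

    shield_ids = set(shieldings["conformer_id"].astype(str))
    energy_ids = set(energies["conformer_id"].astype(str))
    if shield_ids != energy_ids:
        raise FormatError(
            f"format error: column 'conformer_id' differs between tables "
            f"(only in shieldings: {sorted(shield_ids - energy_ids)}, "
            f"only in energies: {sorted(energy_ids - shield_ids)})")

    kj = {
        str(row["conformer_id"]):
            float(row["energy"]) * (HARTREE_TO_KJMOL
                                    if row["unit"] == "hartree" else 1.0)
        for _, row in energies.iterrows()
    }
    floor = min(kj.values())

    elements: dict[int, str] = {}
    conformers = []
    for cid in energies["conformer_id"].astype(str):
        sub = shieldings[shieldings["conformer_id"].astype(str) == cid]
        shield_map = dict(zip(sub["atom_index"].astype(int),
                              sub["isotropic_shielding_ppm"].astype(float)))
        elements.update(dict(zip(sub["atom_index"].astype(int),
                                 sub["element"].astype(str))))
        conformers.append(ConformerRecord(
            conformer_id=cid, energy=kj[cid] - floor, energy_unit="kJ/mol",
            shieldings=shield_map))

    groups = read_assignments(assignments_path)
    return validate_study(groups, conformers, elements)


def write_tables(
    bundle: StudyBundle,
    shieldings_path: str | Path,
    energies_path: str | Path,
    assignments_path: str | Path,
) -> None:
    """Write a bundle back to the three interchange tables.

    Inverse of :func:`read_tables`: reading the written files reproduces
    the bundle exactly (energies in a bundle are already relative, so
    the re-relativization on read is the identity).
    """
    if not bundle.conformers or not bundle.groups:
        raise EmptyStudyError("empty study: nothing to write")
    # floats serialized via repr: shortest exact round-trip representation
    srows = []
    for c in bundle.conformers:
        for idx in sorted(c.shieldings):
            srows.append((c.conformer_id, idx,
                          bundle.elements.get(idx, "X"),
                          repr(c.shieldings[idx])))
    pd.DataFrame(srows, columns=SHIELDING_COLUMNS).to_csv(
        shieldings_path, index=False)
    erows = [(c.conformer_id, repr(c.energy), c.energy_unit)
             for c in bundle.conformers]
    pd.DataFrame(erows, columns=ENERGY_COLUMNS).to_csv(energies_path, index=False)
    write_assignments(bundle.groups, assignments_path)
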