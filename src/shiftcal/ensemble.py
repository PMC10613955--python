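"""Energy-window filtering and Boltzmann-weighted conformer averaging.

Shieldings computed for individual conformers are combined into a
population-weighted ensemble average

    sigma_cal = sum_i sigma_i * exp(-dE_i / RT) / sum_i exp(-dE_i / RT)

with relative energies dE_i (kJ/mol, minimum 0), R = 8.3145 J/K/mol and
T = 298 K by default. Conformers outside an energy window (default
10 kJ/mol, inclusive) are discarded first and the weights renormalized
over the retained subset. Window 0 is the single-conformer (global
minimum) mode used during method screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import EmptyEnsembleError, IncompleteConformerError, InvalidTemperatureError
from .study import EnsembleConfig

__all__ = ["WeightedEnsemble", "filter_window", "boltzmann_weights", "ensemble_average"]


@dataclass(frozen=True)
class WeightedEnsemble:
    """Boltzmann populations over a set of conformers.

    Invariants: relative energies have minimum exactly 0, weights are
    strictly positive and sum to 1.
    """

    conformer_ids: tuple[str, ...]
    relative_energies_kJmol: np.ndarray
    weights: np.ndarray

    def as_mapping(self) -> dict[str, float]:
        return {cid: float(w) for cid, w in zip(self.conformer_ids, self.weights)}


def filter_window(energies_kJmol: Mapping[str, float],
                  window_kJmol: float) -> list[str]:
    """Retain conformers within ``window_kJmol`` of the minimum (inclusive).

    Input energies may be absolute or already relative; they are
    re-expressed relative to their own minimum, so the global minimum is
    always retained — in particular with window 0 only the minimum-energy
    conformer(s) survive. Input order is preserved.
    """
    if not energies_kJmol:
        raise EmptyEnsembleError("empty ensemble: no conformer energies supplied")
    if window_kJmol < 0:
        raise ValueError("window_kJmol must be >= 0")
    floor = min(energies_kJmol.values())
    return [cid for cid, e in energies_kJmol.items() if e - floor <= window_kJmol]


def boltzmann_weights(
    relative_energies_kJmol: Mapping[str, float] | Sequence[float],
    config: EnsembleConfig = EnsembleConfig(),
) -> WeightedEnsemble:
    """Boltzmann populations w_i = exp(-dE_i/RT) / sum_j exp(-dE_j/RT).

    Energies are taken in kJ/mol and converted to J/mol before dividing
    by RT. The minimum is subtracted before exponentiation; this leaves
    the weights unchanged (the offset cancels in the ratio) while
    preventing overflow for large energy spreads.
    """
    if config.temperature_K <= 0:
        raise InvalidTemperatureError("invalid temperature: T must be > 0 K")
    if isinstance(relative_energies_kJmol, Mapping):
        ids = tuple(str(k) for k in relative_energies_kJmol)
        energies = np.asarray([relative_energies_kJmol[k] for k in relative_energies_kJmol],
                              dtype=float)
    else:
        energies = np.asarray(relative_energies_kJmol, dtype=float)
        ids = tuple(str(i) for i in range(energies.size))
    if energies.size == 0:
        raise EmptyEnsembleError("empty ensemble: no energies to weight")
    if not np.all(np.isfinite(energies)):
        raise ValueError("conformer energies must be finite")

    rel = energies - energies.min()
    rt = config.gas_constant * config.temperature_K  # J/mol
    logw = -(rel * 1000.0) / rt
    w = np.exp(logw)
    w /= w.sum()
    return WeightedEnsemble(ids, rel, w)


def ensemble_average(
    shieldings: Mapping[str, Mapping[int, float]],
    ensemble: WeightedEnsemble,
) -> dict[int, float]:
    """Per-atom weighted mean shielding over the retained conformers.

    ``shieldings`` maps conformer_id -> (atom_index -> sigma_i, ppm).
    Every conformer in the ensemble must supply every atom that any
    retained conformer reports.
    """
    missing = [cid for cid in ensemble.conformer_ids if cid not in shieldings]
    if missing:
        raise IncompleteConformerError(
            f"incomplete conformer: no shieldings for {missing[0]!r}")

    atoms: set[int] = set()
    for cid in ensemble.conformer_ids:
        atoms.update(shieldings[cid])

    out: dict[int, float] = {}
    for atom in sorted(atoms):
        acc = 0.0
        for cid, w in zip(ensemble.conformer_ids, ensemble.weights):
            try:
                acc += float(w) * shieldings[cid][atom]
            except KeyError:
                raise IncompleteConformerError(
                    f"incomplete conformer: {cid!r} lacks atom {atom}") from None
        out[atom] = acc
    return out
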