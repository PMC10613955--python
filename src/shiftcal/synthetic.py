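"""Synthetic multi-conformer shielding studies with known ground truth.

The generator emulates the statistical structure of a real computed-NMR
study of a mid-sized natural product — by default the dipterocarpol
oxime layout: 30 carbon groups spanning ~15-167 ppm, 13 proton groups
(29 protons) spanning 0.86-5.12 ppm, and a 15-conformer ensemble with
relative energies inside a 10 kJ/mol window (a wider pre-filter pool
may span up to 21 kJ/mol). Shieldings follow an exact linear law

    sigma = a * delta_exp + b + conformer_effect + atom_noise

where the conformer effect is drawn once per (conformer, group) —
shared by equivalent atoms, mimicking a geometry change shifting a
whole methyl — and atom_noise independently per atom. The true slope,
intercept, per-conformer effects and Boltzmann weights are returned so
recovery can be checked end to end.

The default slopes/intercepts (a = -1.05, b = 186 ppm for 13C;
a = -1.02, b = 31.6 ppm for 1H) are plausible round numbers of the
right magnitude for linear shielding-shift scaling; they are arbitrary
generator settings, not fitted constants from any particular study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import oxime_elements, oxime_fixture
from .errors import InvalidGeneratorSpecError
from .study import (ConformerRecord, EnsembleConfig, EquivalenceGroup, Nucleus,
                    StudyBundle, validate_study)

__all__ = ["NucleusModel", "GeneratorSpec", "GroundTruth", "generate_study"]


@dataclass(frozen=True)
class NucleusModel:
    """True linear law and noise scales for one nucleus type (all ppm)."""

    true_slope: float
    true_intercept: float
    conformer_sd: float
    atom_sd: float


@dataclass(frozen=True)
class GeneratorSpec:
    """Study-generation settings.

    By default experimental shifts are taken verbatim from the bundled
    oxime assignment tables; set ``use_fixture_shifts=False`` to draw
    them uniformly over each nucleus's range instead (group sizes are
    kept). Energies are uniform over [0, ``energy_span_kJmol``] with the
    global minimum forced to exactly 0.
    """

    seed: int
    n_conformers: int = 15
    energy_span_kJmol: float = 10.0
    temperature_K: float = 298.0
    carbon: NucleusModel = field(default_factory=lambda: NucleusModel(
        true_slope=-1.05, true_intercept=186.0, conformer_sd=1.0, atom_sd=0.5))
    proton: NucleusModel = field(default_factory=lambda: NucleusModel(
        true_slope=-1.02, true_intercept=31.6, conformer_sd=0.06, atom_sd=0.03))
    use_fixture_shifts: bool = True
    carbon_range_ppm: tuple[float, float] = (15.40, 167.21)
    proton_range_ppm: tuple[float, float] = (0.86, 5.12)

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise InvalidGeneratorSpecError("invalid generator spec: n_conformers >= 1")
        if self.energy_span_kJmol < 0:
            raise InvalidGeneratorSpecError("invalid generator spec: negative energy span")
        if self.temperature_K <= 0:
            raise InvalidGeneratorSpecError("invalid generator spec: temperature <= 0")
        for m in (self.carbon, self.proton):
            if m.conformer_sd < 0 or m.atom_sd < 0:
                raise InvalidGeneratorSpecError("invalid generator spec: negative noise sd")
            if m.true_slope == 0:
                raise InvalidGeneratorSpecError("invalid generator spec: zero true slope")

    def model_for(self, nucleus: Nucleus) -> NucleusModel:
        return self.carbon if nucleus is Nucleus.C13 else self.proton


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    spec: GeneratorSpec
    relative_energies_kJmol: np.ndarray
    weights: np.ndarray
    #: nucleus -> array of shape (n_conformers, n_groups): the conformer
    #: effects added to each group's mean shielding.
    conformer_effects: dict[Nucleus, np.ndarray]
    #: nucleus -> group_id order used in the effect arrays.
    group_order: dict[Nucleus, tuple[str, ...]]

    def true_params(self, nucleus: Nucleus) -> tuple[float, float]:
        m = self.spec.model_for(nucleus)
        return m.true_slope, m.true_intercept


def _fixture_groups(spec: GeneratorSpec, rng: np.random.Generator,
                    ) -> tuple[list[EquivalenceGroup], dict[int, str]]:
    carbons, protons = oxime_fixture()
    groups = carbons + protons
    if not spec.use_fixture_shifts:
        lo_c, hi_c = spec.carbon_range_ppm
        lo_h, hi_h = spec.proton_range_ppm
        redrawn = []
        for g in groups:
            lo, hi = (lo_c, hi_c) if g.nucleus is Nucleus.C13 else (lo_h, hi_h)
            redrawn.append(replace(g, delta_exp=float(rng.uniform(lo, hi))))
        groups = redrawn
    return groups, oxime_elements()


def generate_study(spec: GeneratorSpec) -> tuple[StudyBundle, GroundTruth]:
    """Generate a full validated study bundle plus its ground truth.

    Deterministic in ``spec.seed``: identical specs give bit-identical
    bundles.
    """
    rng = np.random.default_rng(spec.seed)
    groups, elements = _fixture_groups(spec, rng)

    # Relative energies: global minimum exactly 0, rest uniform in the span.
    n = spec.n_conformers
    rel = np.zeros(n)
    if n > 1:
        rel[1:] = np.sort(rng.uniform(0.0, spec.energy_span_kJmol, size=n - 1))

    config = EnsembleConfig(temperature_K=spec.temperature_K,
                            window_kJmol=spec.energy_span_kJmol)
    logw = -(rel * 1000.0) / (config.gas_constant * config.temperature_K)
    w = np.exp(logw - logw.max())
    w /= w.sum()

    by_nuc = {nuc: [g for g in groups if g.nucleus is nuc] for nuc in Nucleus}
    effects: dict[Nucleus, np.ndarray] = {}
    order: dict[Nucleus, tuple[str, ...]] = {}
    # Per-conformer per-atom shieldings, built group-wise.
    sigma: list[dict[int, float]] = [dict() for _ in range(n)]
    for nuc in (Nucleus.H1, Nucleus.C13):
        model = spec.model_for(nuc)
        gs = by_nuc[nuc]
        order[nuc] = tuple(g.group_id for g in gs)
        eff = rng.normal(0.0, model.conformer_sd, size=(n, len(gs)))
        effects[nuc] = eff
        for j, g in enumerate(gs):
            mean = model.true_slope * g.delta_exp + model.true_intercept
            noise = rng.normal(0.0, model.atom_sd,
                               size=(n, len(g.atom_indices)))
            for i in range(n):
                for k, atom in enumerate(g.atom_indices):
                    sigma[i][atom] = mean + eff[i, j] + noise[i, k]

    conformers = [
        ConformerRecord(conformer_id=f"conf{i + 1:03d}", energy=float(rel[i]),
                        energy_unit="kJ/mol", shieldings=sigma[i])
        for i in range(n)
    ]
    bundle = validate_study(groups, conformers, elements)
    truth = GroundTruth(spec=spec, relative_energies_kJmol=rel, weights=w,
                        conformer_effects=effects, group_order=order)
    return bundle, truth
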