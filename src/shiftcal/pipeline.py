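"""End-to-end shift prediction for one validated study.

Chains the pipeline stages: energy-window filtering -> Boltzmann
weighting -> ensemble averaging of shieldings -> equivalence-group
averaging -> linear scaling fit -> predicted shifts -> error metrics,
performed independently per nucleus type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .ensemble import WeightedEnsemble, boltzmann_weights, ensemble_average, filter_window
from .metrics import MetricsReport, abs_deviations, summarize
from .scaling import ScalingFit, apply_scaling, fit_scaling
from .study import EnsembleConfig, MethodKey, Nucleus, StudyBundle, group_average

__all__ = ["StudyResult", "run_study", "ensemble_group_shieldings"]


@dataclass(frozen=True)
class StudyResult:
    """Everything computed for one nucleus of one study."""

    nucleus: Nucleus
    ensemble: WeightedEnsemble
    sigma_by_group: Mapping[str, float]
    fit: ScalingFit
    predictions: Mapping[str, float]
    report: MetricsReport


def ensemble_group_shieldings(
    bundle: StudyBundle,
    config: EnsembleConfig = EnsembleConfig(),
) -> tuple[WeightedEnsemble, dict[str, float]]:
    """Window-filter, Boltzmann-average and group-average a bundle.

    Returns the weighted ensemble and one sigma_cal per equivalence
    group (all nuclei together; split downstream). With window 0 this
    is single-conformer (global-minimum) mode.
    """
    rel = bundle.relative_energies_kJmol()
    retained = filter_window(rel, config.window_kJmol)
    ensemble = boltzmann_weights({cid: rel[cid] for cid in retained}, config)
    shieldings = {c.conformer_id: c.shieldings for c in bundle.conformers
                  if c.conformer_id in set(retained)}
    per_atom = ensemble_average(shieldings, ensemble)
    sigma = {g.group_id: group_average(per_atom, g) for g in bundle.groups}
    return ensemble, sigma


def run_study(
    bundle: StudyBundle,
    config: EnsembleConfig = EnsembleConfig(),
    method: MethodKey | None = None,
) -> dict[Nucleus, StudyResult]:
    """Predict shifts and score them against experiment, per nucleus."""
    ensemble, sigma = ensemble_group_shieldings(bundle, config)
    out: dict[Nucleus, StudyResult] = {}
    for nucleus in Nucleus:
        groups = bundle.groups_for(nucleus)
        if not groups:
            continue
        exp = {g.group_id: g.delta_exp for g in groups}
        fit = fit_scaling([(g.delta_exp, sigma[g.group_id]) for g in groups],
                          nucleus)
        pred = {g.group_id: apply_scaling(fit, sigma[g.group_id]) for g in groups}
        devs = abs_deviations(pred, exp)
        report = summarize(devs, exp, fit.r_squared, nucleus, method=method)
        out[nucleus] = StudyResult(nucleus=nucleus, ensemble=ensemble,
                                   sigma_by_group={g.group_id: sigma[g.group_id]
                                                   for g in groups},
                                   fit=fit, predictions=pred, report=report)
    return out
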