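"""Energy-window filtering and Boltzmann weighting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shiftcal import (EnsembleConfig, EquivalenceGroup, Nucleus,
                      boltzmann_weights, ensemble_average, filter_window,
                      group_average)
from shiftcal.errors import (EmptyEnsembleError, IncompleteConformerError,
                             InvalidTemperatureError)

R = 8.3145
T = 298.0


def reference_weights(energies_kJmol):
    """Independent direct evaluation of the Boltzmann ratio."""
    factors = [math.exp(-(e * 1000.0) / (R * T)) for e in energies_kJmol]
    total = sum(factors)
    return [f / total for f in factors]


class TestFilterWindow:
    def test_inclusive_boundary(self):
        rel = {"a": 0.0, "b": 5.0, "c": 9.99, "d": 10.01}
        assert filter_window(rel, 10.0) == ["a", "b", "c"]

    def test_zero_window_keeps_global_minimum(self):
        rel = {"a": 0.0, "b": 5.0, "c": 9.99, "d": 10.01}
        assert filter_window(rel, 0.0) == ["a"]

    def test_degenerate_all_at_minimum(self):
        rel = {k: 0.0 for k in "abcd"}
        assert filter_window(rel, 0.0) == list("abcd")

    def test_absolute_energies_are_relativized(self):
        assert filter_window({"a": 1000.0, "b": 1011.0}, 10.0) == ["a"]

    def test_empty_rejected(self):
        with pytest.raises(EmptyEnsembleError, match="empty ensemble"):
            filter_window({}, 10.0)


class TestBoltzmannWeights:
    def test_degenerate_pair_is_uniform(self):
        ens = boltzmann_weights([0.0, 0.0])
        assert np.allclose(ens.weights, [0.5, 0.5])

    def test_single_conformer(self):
        assert boltzmann_weights([0.0]).weights == pytest.approx([1.0])

    def test_ten_kJmol_pair_at_298K(self):
        """dE = [0, 10] kJ/mol at 298 K gives ~[0.9826, 0.0174]."""
        ens = boltzmann_weights([0.0, 10.0], EnsembleConfig())
        expected = reference_weights([0.0, 10.0])
        assert np.allclose(ens.weights, expected, atol=1e-15)
        assert np.round(ens.weights, 4).tolist() == [0.9826, 0.0174]

    def test_negative_temperature_rejected(self):
        with pytest.raises((InvalidTemperatureError, ValueError)):
            boltzmann_weights([0.0, 1.0], EnsembleConfig(temperature_K=-5))

    @given(st.lists(st.floats(0, 200), min_size=1, max_size=1000))
    def test_normalization_to_1e12(self, energies):
        ens = boltzmann_weights(energies)
        assert abs(ens.weights.sum() - 1.0) < 1e-12
        assert (ens.weights > 0).all()
        assert ens.relative_energies_kJmol.min() == 0.0

    @given(st.lists(st.floats(0, 50), min_size=2, max_size=50),
           st.floats(-1e6, 1e6))
    def test_offset_invariance(self, energies, offset):
        base = boltzmann_weights(energies).weights
        shifted = boltzmann_weights([e + offset for e in energies]).weights
        assert np.allclose(base, shifted, atol=1e-12)

    def test_monotone_in_energy(self):
        ens = boltzmann_weights([0.0, 1.0, 2.0, 5.0, 9.0])
        assert (np.diff(ens.weights) < 0).all()

    def test_temperature_limits(self):
        energies = [0.0, 2.0, 7.0]
        cold = boltzmann_weights(energies, EnsembleConfig(temperature_K=1e-3))
        assert np.allclose(cold.weights, [1.0, 0.0, 0.0], atol=1e-9)
        hot = boltzmann_weights(energies, EnsembleConfig(temperature_K=1e9))
        assert np.allclose(hot.weights, 1 / 3, atol=1e-9)


class TestEnsembleAverage:
    def test_constant_shielding_is_fixed_point(self):
        ens = boltzmann_weights([0.0, 3.0])
        avg = ensemble_average({"0": {1: 30.0}, "1": {1: 30.0}}, ens)
        assert avg[1] == pytest.approx(30.0)

    def test_uniform_weights_give_midpoint(self):
        ens = boltzmann_weights([0.0, 0.0])
        avg = ensemble_average({"0": {1: 20.0}, "1": {1: 40.0}}, ens)
        assert avg[1] == pytest.approx(30.0)

    def test_weighted_mean_against_hand_value(self):
        """sigma [20, 40] at dE [0, 10] kJ/mol: 0.9826*20 + 0.0174*40."""
        ens = boltzmann_weights([0.0, 10.0])
        avg = ensemble_average({"0": {1: 20.0}, "1": {1: 40.0}}, ens)
        w = reference_weights([0.0, 10.0])
        assert avg[1] == pytest.approx(20.0 * w[0] + 40.0 * w[1], abs=1e-12)
        # hand value from 4-dp-rounded weights: 0.9826*20 + 0.0174*40 = 20.348
        assert avg[1] == pytest.approx(20.348, abs=1e-3)

    def test_missing_atom_raises(self):
        ens = boltzmann_weights([0.0, 1.0])
        with pytest.raises(IncompleteConformerError):
            ensemble_average({"0": {1: 20.0}, "1": {2: 40.0}}, ens)


@given(st.integers(0, 2**31 - 1))
def test_ensemble_and_group_averaging_commute(seed):
    """Both averages are linear, so their order cannot matter."""
    rng = np.random.default_rng(seed)
    n_conf, atoms = 4, (1, 2, 3)
    group = EquivalenceGroup(group_id="Me", nucleus=Nucleus.H1,
                             atom_indices=atoms, delta_exp=1.0)
    shieldings = {str(i): {a: rng.normal(30, 2) for a in atoms}
                  for i in range(n_conf)}
    ens = boltzmann_weights(rng.uniform(0, 10, n_conf).tolist())
    ens = boltzmann_weights(dict(zip(shieldings, ens.relative_energies_kJmol)))

    # ensemble first, then equivalence average
    route1 = group_average(ensemble_average(shieldings, ens), group)
    # equivalence average per conformer, then ensemble average
    per_conf = {cid: {0: group_average(vals, group)}
                for cid, vals in shieldings.items()}
    route2 = ensemble_average(per_conf, ens)[0]
    assert route1 == pytest.approx(route2, abs=1e-12)
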