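"""Window-filter a conformer ensemble and compute Boltzmann populations.

A flexible molecule's NMR observables are population averages over its
low-energy conformers. Here a small ensemble is filtered to a 10 kJ/mol
window and weighted at 298 K.
"""

from shiftcal import EnsembleConfig, boltzmann_weights, filter_window

# relative energies (kJ/mol) from a conformer search, minimum at zero
energies = {"conf1": 0.0, "conf2": 1.8, "conf3": 5.2, "conf4": 9.9,
            "conf5": 14.6}

retained = filter_window(energies, window_kJmol=10.0)
print(f"retained within 10 kJ/mol: {retained}")

ensemble = boltzmann_weights({c: energies[c] for c in retained},
                             EnsembleConfig(temperature_K=298.0))
for cid, w in ensemble.as_mapping().items():
    print(f"  {cid}: dE = {energies[cid]:5.1f} kJ/mol  weight = {w:.4f}")
print(f"weight sum = {sum(ensemble.weights):.12f}")

# The weights fall off exponentially with relative energy: conf1 carries
# roughly two thirds of the population, conf5 (outside the window)
# contributes nothing. Weighted shielding averages use exactly these
# populations.
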