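"""Bundled reference data for the dipterocarpol oxime study.

The package ships the experimental assignment data of dipterocarpol
oxime (a dammarane triterpenoid oxime, MW 457.74, CDCl3, 400/101 MHz):
the 30 experimental 13C shifts and the 29 assignable protons grouped
into 13 equivalence groups — 8 methyl groups of three protons each
(single signals due to fast rotation), the olefinic proton H24, the
diastereotopic alpha-protons H2a/H2b, and the two allylic H23 protons.
Overlapping or unassignable ring protons are excluded, as is standard
when only confidently assigned signals enter a calibration.

Also bundled are the published single-conformer screening statistics
(r-squared and RMSE per functional x basis-set cell) for the same
compound, usable with :func:`shiftcal.screen.screen_from_metrics` to
exercise ranking and best-per-functional selection on real benchmark
numbers.

Atom indices are a synthetic 1-based numbering (carbons 1-30, protons
31-59); real studies supply their own engine-order numbering in the
assignment table.
"""

from __future__ import annotations

from .study import EquivalenceGroup, MethodKey, Nucleus

__all__ = [
    "OXIME1_C13_SHIFTS", "OXIME1_PROTON_GROUPS", "oxime_fixture",
    "oxime_elements", "OXIME1_C13_SCREEN", "OXIME1_H1_SCREEN",
    "OXIME1_C13_ENSEMBLE_STATS", "OXIME1_H1_ENSEMBLE_STATS",
]

#: The 30 experimental 13C shifts (ppm, CDCl3) of dipterocarpol oxime,
#: in the conventional descending order.
OXIME1_C13_SHIFTS: tuple[float, ...] = (
    167.21, 131.68, 124.69, 75.46, 56.04, 50.29, 50.25, 49.77, 42.31,
    40.48, 40.46, 40.38, 39.10, 37.18, 34.82, 31.14, 27.53, 27.29,
    25.79, 25.42, 24.80, 22.86, 22.56, 21.80, 19.03, 17.75, 17.13,
    16.34, 15.92, 15.40,
)

#: Considered protons: (group_id, delta_exp ppm, n_protons). Methyls are
#: 3-proton groups; the two 1.14 ppm methyls are distinct groups that
#: happen to overlap (a 6H singlet); H23a/H23b share the 2.05 ppm
#: multiplet; H2a/H2b are the assigned diastereotopic alpha-protons.
OXIME1_PROTON_GROUPS: tuple[tuple[str, float, int], ...] = (
    ("Me-26", 1.68, 3),
    ("Me-27", 1.62, 3),
    ("Me-21", 1.14, 3),
    ("Me-28", 1.14, 3),
    ("Me-19", 1.05, 3),
    ("Me-29", 0.98, 3),
    ("Me-30", 0.94, 3),
    ("Me-18", 0.86, 3),
    ("H24", 5.12, 1),
    ("H2a", 2.96, 1),
    ("H2b", 2.27, 1),
    ("H23a", 2.05, 1),
    ("H23b", 2.05, 1),
)


def oxime_fixture() -> tuple[list[EquivalenceGroup], list[EquivalenceGroup]]:
    """Assignment tables of the oxime study: (carbon_groups, proton_groups).

    Returns 30 singleton carbon groups (labels ``C01``..``C30`` in
    printed order; the skeletal position mapping lives with the original
    study) and the 13 proton groups covering 29 protons.
    """
    carbons = [
        EquivalenceGroup(group_id=f"C{i + 1:02d}", nucleus=Nucleus.C13,
                         atom_indices=(i + 1,), delta_exp=shift)
        for i, shift in enumerate(OXIME1_C13_SHIFTS)
    ]
    protons = []
    next_atom = len(OXIME1_C13_SHIFTS) + 1
    for gid, shift, n in OXIME1_PROTON_GROUPS:
        idx = tuple(range(next_atom, next_atom + n))
        next_atom += n
        protons.append(EquivalenceGroup(group_id=gid, nucleus=Nucleus.H1,
                                        atom_indices=idx, delta_exp=shift))
    return carbons, protons


def oxime_elements() -> dict[int, str]:
    """Element symbol per fixture atom index (carbons then protons)."""
    n_c = len(OXIME1_C13_SHIFTS)
    n_h = sum(n for _, _, n in OXIME1_PROTON_GROUPS)
    out = {i + 1: "C" for i in range(n_c)}
    out.update({n_c + i + 1: "H" for i in range(n_h)})
    return out


def _grid(functionals, basis_sets, rows):
    out: dict[MethodKey, tuple[float, float]] = {}
    for basis, cells in zip(basis_sets, rows):
        for func, (r2, rmse) in zip(functionals, cells):
            out[MethodKey(func, basis)] = (r2, rmse)
    return out


_BASIS_SETS = (
    "6-31G", "6-31G(d,p)", "6-31+G(d,p)", "6-31++G(d,p)", "6-311G(d,p)",
    "6-31G(d,3p)", "6-31G(3d,p)", "6-31G(3d,3p)", "cc-pVDZ", "DGDZVP",
    "DGDZVP2",
)

#: Published single-conformer 13C screening statistics for the oxime:
#: MethodKey -> (r_squared, rmse_ppm), six best-performing functionals.
OXIME1_C13_SCREEN: dict[MethodKey, tuple[float, float]] = _grid(
    ("B3LYP", "HSEH1PBE", "B3PW91", "CAM-B3LYP", "mPW1PW91", "wB97XD"),
    _BASIS_SETS,
    [
        [(0.9981, 1.54), (0.9988, 1.24), (0.9985, 1.37), (0.9990, 1.16), (0.9988, 1.24), (0.9989, 1.20)],
        [(0.9983, 1.50), (0.9988, 1.24), (0.9985, 1.37), (0.9992, 1.03), (0.9989, 1.20), (0.9991, 1.08)],
        [(0.9987, 1.31), (0.9990, 1.12), (0.9989, 1.17), (0.9991, 1.06), (0.9991, 1.08), (0.9987, 1.27)],
        [(0.9988, 1.25), (0.9991, 1.10), (0.9990, 1.13), (0.9991, 1.09), (0.9990, 1.13), (0.9988, 1.26)],
        [(0.9983, 1.49), (0.9986, 1.36), (0.9984, 1.43), (0.9989, 1.18), (0.9987, 1.30), (0.9988, 1.24)],
        [(0.9977, 1.72), (0.9985, 1.37), (0.9982, 1.51), (0.9989, 1.20), (0.9986, 1.32), (0.9988, 1.21)],
        [(0.9930, 3.01), (0.9951, 2.51), (0.9939, 7.72), (0.9963, 2.19), (0.9950, 2.54), (0.9976, 1.76)],
        [(0.9899, 3.61), (0.9934, 2.91), (0.9915, 3.31), (0.9944, 2.68), (0.9930, 3.00), (0.9970, 1.96)],
        [(0.9975, 1.79), (0.9983, 1.48), (0.9980, 1.60), (0.9989, 1.20), (0.9985, 1.40), (0.9989, 1.19)],
        [(0.9989, 1.19), (0.9990, 1.12), (0.9990, 1.13), (0.9992, 1.03), (0.9990, 1.14), (0.9990, 1.11)],
        [(0.9981, 1.57), (0.9987, 1.31), (0.9984, 1.43), (0.9992, 1.03), (0.9988, 1.26), (0.9990, 1.12)],
    ],
)

#: Published single-conformer 1H screening statistics for the oxime:
#: MethodKey -> (r_squared, rmse_ppm), six best-performing functionals.
OXIME1_H1_SCREEN: dict[MethodKey, tuple[float, float]] = _grid(
    ("B3LYP", "LSDA", "HSEH1PBE", "HCTH", "BPV86", "PBEPBE"),
    _BASIS_SETS,
    [
        [(0.9915, 0.108), (0.9931, 0.098), (0.9915, 0.108), (0.9930, 0.098), (0.9926, 0.101), (0.9926, 0.101)],
        [(0.9881, 0.129), (0.9897, 0.120), (0.9874, 0.132), (0.9886, 0.126), (0.9892, 0.122), (0.9889, 0.124)],
        [(0.9882, 0.128), (0.9895, 0.120), (0.9881, 0.128), (0.9879, 0.130), (0.9892, 0.122), (0.9890, 0.123)],
        [(0.9838, 0.219), (0.9855, 0.142), (0.9848, 0.146), (0.9813, 0.161), (0.9843, 0.148), (0.9841, 0.149)],
        [(0.9865, 0.137), (0.9882, 0.128), (0.9866, 0.136), (0.9875, 0.132), (0.9880, 0.129), (0.9875, 0.132)],
        [(0.9864, 0.137), (0.9878, 0.130), (0.9863, 0.138), (0.9875, 0.132), (0.9879, 0.130), (0.9876, 0.131)],
        [(0.9791, 0.171), (0.9786, 0.173), (0.9804, 0.166), (0.9796, 0.169), (0.9782, 0.175), (0.9782, 0.175)],
        [(0.9782, 0.175), (0.9775, 0.178), (0.9790, 0.171), (0.9756, 0.185), (0.9770, 0.180), (0.9769, 0.180)],
        [(0.9856, 0.141), (0.9875, 0.132), (0.9851, 0.144), (0.9870, 0.134), (0.9876, 0.131), (0.9871, 0.134)],
        [(0.9866, 0.136), (0.9890, 0.124), (0.9847, 0.146), (0.9871, 0.134), (0.9881, 0.128), (0.9877, 0.130)],
        [(0.9886, 0.125), (0.9907, 0.113), (0.9879, 0.129), (0.9901, 0.117), (0.9903, 0.116), (0.9900, 0.118)],
    ],
)

#: Published Boltzmann-ensemble (15 conformers, 10 kJ/mol window)
#: 13C statistics: MethodKey -> (r2, mae, rmse, maxdev), all ppm.
OXIME1_C13_ENSEMBLE_STATS: dict[MethodKey, tuple[float, float, float, float]] = {
    MethodKey("B3LYP", "DGDZVP"): (0.9993, 0.75, 0.95, 2.09),
    MethodKey("B3PW91", "DGDZVP"): (0.9993, 0.71, 0.93, 2.21),
    MethodKey("CAM-B3LYP", "DGDZVP"): (0.9994, 0.62, 0.84, 2.15),
    MethodKey("HSEH1PBE", "6-31++G(d,p)"): (0.9991, 0.89, 1.09, 3.17),
    MethodKey("mPW1PW91", "6-31+G(d,p)"): (0.9990, 0.89, 1.14, 2.73),
    MethodKey("wB97XD", "6-31G(d,p)"): (0.9994, 0.72, 0.90, 2.08),
}

#: Published Boltzmann-ensemble 1H statistics, same layout.
OXIME1_H1_ENSEMBLE_STATS: dict[MethodKey, tuple[float, float, float, float]] = {
    MethodKey("B3LYP", "6-31G"): (0.9969, 0.0594, 0.0647, 0.107),
    MethodKey("LSDA", "6-31G"): (0.9965, 0.0614, 0.0691, 0.115),
    MethodKey("HSEH1PBE", "6-31G"): (0.9972, 0.0554, 0.0617, 0.109),
    MethodKey("HCTH", "6-31G"): (0.9966, 0.0646, 0.0681, 0.0940),
    MethodKey("BPV86", "6-31G"): (0.9970, 0.0606, 0.0643, 0.0940),
    MethodKey("PBEPBE", "6-31G"): (0.9945, 0.0765, 0.0870, 0.161),
}
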