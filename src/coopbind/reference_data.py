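"""Published benchmark values used as bookkeeping-identity fixtures.

A literature MM-PB/SA + MM-GB/SA study of one- and two-ligand binding to a
cytochrome P450 reported component tables (frame-averaged mean +/- std,
kcal/mol) for two receptor structures ("t" and "w") in two binding modes
(normal: one ligand; cooperative: two ligands), plus per-residue
decomposition tables.  The underlying trajectories were never deposited, so
these printed values serve purely as inputs for validating the aggregation
identities and ratio formatting of this package - they are not recomputed
quantities.
"""

from __future__ import annotations

#: Table of binding energy components: structure -> arm -> term -> (mean, std)
ENERGY_COMPONENTS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "t": {
        "normal": {
            "dE_ele": (-20.80, 2.71),
            "dE_vdw": (-65.33, 2.46),
            "dE_gas": (-86.13, 3.34),
            "dG_nonpolar_PB": (-8.37, 0.21),
            "dG_sol_PB": (47.27, 3.84),
            "dG_ele_PB": (34.84, 3.64),
            "dG_bind_PB": (-38.86, 4.00),
            "dG_nonpolar_GB": (-8.37, 0.21),
            "dG_sol_GB": (31.72, 2.50),
            "dG_ele_GB": (19.29, 2.23),
            "dG_bind_GB": (-54.41, 2.64),
        },
        "cooperative": {
            "dE_ele": (-25.68, 3.08),
            "dE_vdw": (-74.99, 2.57),
            "dE_gas": (-100.67, 3.68),
            "dG_nonpolar_PB": (-8.44, 0.14),
            "dG_sol_PB": (53.11, 3.15),
            "dG_ele_PB": (35.87, 4.17),
            "dG_bind_PB": (-47.56, 4.36),
            "dG_nonpolar_GB": (-8.44, 0.14),
            "dG_sol_GB": (33.72, 2.21),
            "dG_ele_GB": (16.48, 2.44),
            "dG_bind_GB": (-66.95, 3.12),
        },
    },
    "w": {
        "normal": {
            "dE_ele": (-31.63, 3.45),
            "dE_vdw": (-57.44, 2.37),
            "dE_gas": (-89.06, 3.17),
            "dG_nonpolar_PB": (-7.79, 0.06),
            "dG_sol_PB": (59.24, 2.46),
            "dG_ele_PB": (35.40, 4.15),
            "dG_bind_PB": (-29.83, 4.26),
            "dG_nonpolar_GB": (-7.79, 0.16),
            "dG_sol_GB": (38.10, 2.85),
            "dG_ele_GB": (14.26, 2.44),
            "dG_bind_GB": (-50.97, 3.22),
        },
        "cooperative": {
            "dE_ele": (-25.29, 3.57),
            "dE_vdw": (-75.63, 3.42),
            "dE_gas": (-100.92, 4.35),
            "dG_nonpolar_PB": (-7.84, 0.15),
            "dG_sol_PB": (56.43, 2.67),
            "dG_ele_PB": (38.97, 3.86),
            "dG_bind_PB": (-44.50, 4.45),
            "dG_nonpolar_GB": (-7.84, 0.15),
            "dG_sol_GB": (34.11, 2.04),
            "dG_ele_GB": (16.65, 2.82),
            "dG_bind_GB": (-66.81, 3.74),
        },
    },
}

#: Per-residue decomposition tables: structure -> residue number ->
#: (residue name, normal (mean, std), cooperative (mean, std)), kcal/mol
RESIDUE_CONTRIBUTIONS: dict[str, dict[int, tuple[str, tuple[float, float], tuple[float, float]]]] = {
    "t": {
        57: ("Phenylalanine", (-0.79, 0.38), (-0.96, 0.33)),
        106: ("Arginine", (-0.89, 0.33), (-2.79, 0.76)),
        108: ("Phenylalanine", (-0.86, 0.27), (0.04, 0.05)),
        212: ("Arginine", (-1.75, 0.37), (-1.71, 0.29)),
        215: ("Phenylalanine", (-2.03, 0.35), (-1.76, 0.30)),
        301: ("Isoleucine", (-0.80, 0.20), (-0.71, 0.18)),
        304: ("Phenylalanine", (-1.56, 0.34), (-2.14, 0.31)),
        305: ("Alanine", (-0.94, 0.25), (-1.30, 0.26)),
        308: ("Glutamic acid", (-0.92, 0.37), (-0.62, 0.34)),
        309: ("Threonine", (-1.34, 0.29), (-1.19, 0.47)),
        369: ("Isoleucine", (-1.39, 0.32), (-1.63, 0.33)),
        370: ("Alanine", (-1.59, 0.37), (-1.04, 0.41)),
        371: ("Methionine", (-0.26, 0.07), (-1.24, 0.36)),
        372: ("Arginine", (-4.31, 0.69), (-4.25, 0.79)),
        373: ("Leucine", (-0.83, 0.17), (-0.38, 0.11)),
        374: ("Glutamic acid", (-1.09, 0.70), (-1.35, 0.45)),
        482: ("Leucine", (-1.03, 0.22), (-0.60, 0.15)),
    },
    "w": {
        57: ("Phenylalanine", (-0.83, 0.25), (-0.24, 0.22)),
        105: ("Arginine", (-0.19, 0.13), (-2.41, 0.58)),
        106: ("Arginine", (-0.80, 0.33), (-0.70, 0.20)),
        108: ("Phenylalanine", (-0.73, 0.24), (0.06, 0.03)),
        119: ("Serine", (-0.42, 0.28), (-0.78, 0.46)),
        212: ("Arginine", (-3.10, 0.66), (-3.83, 1.00)),
        215: ("Phenylalanine", (-1.89, 0.39), (-0.43, 0.22)),
        301: ("Isoleucine", (-0.64, 0.26), (-0.46, 0.14)),
        304: ("Phenylalanine", (-1.56, 0.42), (-1.07, 0.33)),
        305: ("Alanine", (-1.42, 0.17), (-1.30, 0.26)),
        309: ("Threonine", (-0.77, 0.21), (-0.37, 0.36)),
        369: ("Isoleucine", (-1.12, 0.43), (-0.95, 0.28)),
        370: ("Alanine", (-0.73, 0.17), (-1.19, 0.46)),
        371: ("Methionine", (-1.75, 0.29), (-0.30, 0.07)),
        372: ("Arginine", (-4.49, 0.58), (-1.86, 0.59)),
        373: ("Leucine", (-0.78, 0.17), (-1.56, 0.41)),
        374: ("Glutamic acid", (2.48, 0.79), (0.44, 0.56)),
        482: ("Leucine", (-1.24, 0.49), (-2.26, 0.36)),
    },
}
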