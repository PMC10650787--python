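"""Published group-level study values used as generator defaults and checks.

These are the printed group means (SDs in parentheses in the source tables)
for α4β2-receptor radioligand kinetics in mice: two-tissue-model rate
constants per ligand/group/region, the in-house-solver binding-potential
estimates, the DVR-vs-BP_ND+1 comparison, and left-ventricle SUV summaries.
They parameterize the synthetic cohort generator and anchor arithmetic
cross-checks; they are inputs, not outputs, of this package.

Groups: WT (wild type), KO (β2-subunit knockout, no specific binding),
AN (acute nicotine pretreatment, binding blocked).
Ligands: "2-FA" (slow kinetics, 180-min scan), "Nifene" (fast, 60-min scan).
"""

from __future__ import annotations

# (count, frame duration in seconds) blocks; 2-FA ends at 180 min, Nifene at 60 min
FRAME_SCHEDULE_SPECS: dict[str, list[tuple[int, int]]] = {
    "2-FA": [(10, 60), (17, 600)],
    "Nifene": [(12, 10), (18, 60), (8, 300)],
}

SCAN_DURATION_MIN = {"2-FA": 180.0, "Nifene": 60.0}

# Group sizes (animals imaged per ligand and group)
GROUP_SIZES = {
    "2-FA": {"WT": 10, "KO": 11, "AN": 6},
    "Nifene": {"WT": 12, "KO": 7, "AN": 4},
}

# Two-tissue-model rate constants, mean (sd), 1/min, per ligand/group/region.
RATE_CONSTANTS: dict[str, dict[str, dict[str, dict[str, tuple[float, float]]]]] = {
    "2-FA": {
        "WT": {
            "thalamus": {"K1": (0.098, 0.013), "k2": (0.075, 0.015),
                         "k3": (0.029, 0.0064), "k4": (0.0077, 0.0013)},
            "midbrain": {"K1": (0.11, 0.017), "k2": (0.076, 0.020),
                         "k3": (0.024, 0.0062), "k4": (0.0084, 0.0016)},
            "cerebellum": {"K1": (0.10, 0.016), "k2": (0.080, 0.016),
                           "k3": (0.011, 0.0025), "k4": (0.0081, 0.0017)},
        },
        "KO": {
            "thalamus": {"K1": (0.066, 0.0061), "k2": (0.055, 0.0066),
                         "k3": (0.0049, 0.0016), "k4": (0.020, 0.0037)},
            "midbrain": {"K1": (0.076, 0.0087), "k2": (0.066, 0.0087),
                         "k3": (0.0060, 0.0012), "k4": (0.026, 0.0037)},
            "cerebellum": {"K1": (0.077, 0.0072), "k2": (0.068, 0.0069),
                           "k3": (0.0056, 0.00083), "k4": (0.017, 0.0040)},
        },
        "AN": {
            "thalamus": {"K1": (0.060, 0.0036), "k2": (0.050, 0.0046),
                         "k3": (0.0054, 0.00080), "k4": (0.016, 0.0017)},
            "midbrain": {"K1": (0.062, 0.0051), "k2": (0.051, 0.0055),
                         "k3": (0.0031, 0.00070), "k4": (0.0093, 0.0022)},
            "cerebellum": {"K1": (0.063, 0.0053), "k2": (0.058, 0.0057),
                           "k3": (0.0036, 0.0010), "k4": (0.015, 0.0059)},
        },
    },
    "Nifene": {
        "WT": {
            "thalamus": {"K1": (1.66, 0.24), "k2": (1.23, 0.26),
                         "k3": (0.43, 0.11), "k4": (0.50, 0.12)},
            "midbrain": {"K1": (1.94, 0.31), "k2": (1.52, 0.35),
                         "k3": (0.50, 0.13), "k4": (0.60, 0.14)},
            "cerebellum": {"K1": (1.56, 0.33), "k2": (1.19, 0.32),
                           "k3": (0.10, 0.055), "k4": (0.62, 0.18)},
        },
        "KO": {
            "thalamus": {"K1": (0.55, 0.089), "k2": (0.51, 0.074),
                         "k3": (0.047, 0.011), "k4": (0.27, 0.034)},
            "midbrain": {"K1": (0.50, 0.080), "k2": (0.47, 0.069),
                         "k3": (0.029, 0.0085), "k4": (0.26, 0.046)},
            "cerebellum": {"K1": (0.33, 0.061), "k2": (0.31, 0.053),
                           "k3": (0.010, 0.0052), "k4": (0.19, 0.046)},
        },
        "AN": {
            "thalamus": {"K1": (1.25, 0.072), "k2": (1.09, 0.068),
                         "k3": (0.14, 0.024), "k4": (0.51, 0.12)},
            "midbrain": {"K1": (1.28, 0.099), "k2": (1.14, 0.061),
                         "k3": (0.12, 0.026), "k4": (0.60, 0.077)},
            "cerebellum": {"K1": (0.91, 0.10), "k2": (0.83, 0.072),
                           "k3": (0.033, 0.013), "k4": (0.34, 0.14)},
        },
    },
}

# In-house-solver BP_ND group estimates, mean (sd), per ligand/group/region.
SOLVER_BP_ND: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "2-FA": {
        "WT": {"thalamus": (3.84, 0.70), "midbrain": (2.66, 0.41)},
        "KO": {"thalamus": (0.34, 0.14), "midbrain": (0.29, 0.064)},
        "AN": {"thalamus": (0.33, 0.037), "midbrain": (0.52, 0.17)},
    },
    "Nifene": {
        "WT": {"thalamus": (0.90, 0.14), "midbrain": (0.88, 0.17)},
        "KO": {"thalamus": (0.18, 0.038), "midbrain": (0.12, 0.034)},
        "AN": {"thalamus": (0.29, 0.056), "midbrain": (0.23, 0.056)},
    },
}

# Published pairwise comparison: BP_ND+1 (compartment fit, LV input) vs
# Logan DVR (cerebellum reference), mean (sd).
BP_PLUS_ONE_VS_DVR: dict[str, dict[str, dict[str, dict[str, tuple[float, float]]]]] = {
    "2-FA": {
        "WT": {"thalamus": {"bp_plus_one": (4.84, 0.70), "dvr": (2.35, 0.15)},
               "midbrain": {"bp_plus_one": (3.66, 0.41), "dvr": (1.96, 0.080)}},
        "KO": {"thalamus": {"bp_plus_one": (1.34, 0.14), "dvr": (0.97, 0.019)},
               "midbrain": {"bp_plus_one": (1.29, 0.064), "dvr": (0.97, 0.011)}},
        "AN": {"thalamus": {"bp_plus_one": (1.33, 0.037), "dvr": (1.15, 0.051)},
               "midbrain": {"bp_plus_one": (1.52, 0.17), "dvr": (1.05, 0.023)}},
    },
    "Nifene": {
        "WT": {"thalamus": {"bp_plus_one": (1.90, 0.14), "dvr": (1.79, 0.079)},
               "midbrain": {"bp_plus_one": (1.88, 0.17), "dvr": (1.54, 0.092)}},
        "KO": {"thalamus": {"bp_plus_one": (1.18, 0.038), "dvr": (0.94, 0.039)},
               "midbrain": {"bp_plus_one": (1.12, 0.034), "dvr": (0.98, 0.015)}},
        "AN": {"thalamus": {"bp_plus_one": (1.29, 0.056), "dvr": (0.93, 0.016)},
               "midbrain": {"bp_plus_one": (1.23, 0.056), "dvr": (0.99, 0.0049)}},
    },
}

# Left-ventricle SUV summaries per ligand and group: peak over the scan and
# mean over the final 30 min, mean (sd). Groups showed no significant
# differences, so the WT values serve as generator targets for all groups.
LV_SUV_SUMMARY: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "2-FA": {
        "peak": {"WT": (0.55, 0.17), "KO": (0.47, 0.22), "AN": (0.569, 0.12)},
        "late_mean": {"WT": (0.077, 0.029), "KO": (0.081, 0.049), "AN": (0.074, 0.014)},
    },
    "Nifene": {
        "peak": {"WT": (0.98, 0.21), "KO": (1.4, 0.95), "AN": (1.2, 0.15)},
        "late_mean": {"WT": (0.41, 0.14), "KO": (0.45, 0.14), "AN": (0.50, 0.12)},
    },
}

# Package defaults for the input-function time-to-peak (min); IP injection
# peaks late relative to an IV bolus. Not printed in the source study.
DEFAULT_T_PEAK_MIN = {"2-FA": 10.0, "Nifene": 5.0}

LATE_WINDOW_MIN = 30.0
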