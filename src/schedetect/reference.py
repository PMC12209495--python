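"""Published reference outcomes from the original 12-rat experiment.

The pipeline re-implements an analysis originally run on real open-field
recordings of 12 water-restricted rats, three per schedule condition.  The
per-rat signal-detection outcomes (sensitivity, specificity, d', criterion c)
for the schedule-vs-no-schedule task, and the Wilcoxon signed-rank statistics
per model, were published as summary tables.  They are embedded here so the
signal-detection arithmetic can be validated against the published grid, and
so downstream consumers can compare synthetic-pipeline output with the real
experiment's numbers.

Each rat was tested on 25 schedule-phase and 5 extinction-phase sessions, so
``N_SIGNAL = 25`` and ``N_NOISE = 5`` throughout.
"""

from __future__ import annotations

ALGORITHMS = ("LR", "SVC", "RF", "ANN")
SUBJECTS = tuple(f"S{i}" for i in range(1, 13))

N_SIGNAL = 25
N_NOISE = 5

#: Published per-rat sensitivity for the schedule-vs-none task,
#: {rat: {algorithm: hit rate}}.
SENSITIVITY: dict[str, dict[str, float]] = {
    "S1": {"LR": 0.84, "SVC": 0.92, "RF": 1.00, "ANN": 0.88},
    "S2": {"LR": 0.76, "SVC": 0.80, "RF": 0.96, "ANN": 0.80},
    "S3": {"LR": 0.88, "SVC": 0.88, "RF": 0.96, "ANN": 0.88},
    "S4": {"LR": 1.00, "SVC": 1.00, "RF": 1.00, "ANN": 1.00},
    "S5": {"LR": 0.52, "SVC": 0.80, "RF": 0.96, "ANN": 0.60},
    "S6": {"LR": 1.00, "SVC": 0.92, "RF": 1.00, "ANN": 1.00},
    "S7": {"LR": 0.84, "SVC": 0.68, "RF": 0.96, "ANN": 0.64},
    "S8": {"LR": 0.56, "SVC": 0.56, "RF": 0.76, "ANN": 0.56},
    "S9": {"LR": 0.72, "SVC": 0.76, "RF": 1.00, "ANN": 0.84},
    "S10": {"LR": 0.72, "SVC": 0.96, "RF": 0.96, "ANN": 0.92},
    "S11": {"LR": 0.76, "SVC": 0.80, "RF": 1.00, "ANN": 0.76},
    "S12": {"LR": 0.28, "SVC": 0.56, "RF": 0.80, "ANN": 0.56},
}

#: Published per-rat specificity (true-negative rate), same layout.
SPECIFICITY: dict[str, dict[str, float]] = {
    "S1": {"LR": 1.00, "SVC": 1.00, "RF": 0.80, "ANN": 1.00},
    "S2": {"LR": 0.60, "SVC": 0.60, "RF": 0.20, "ANN": 0.60},
    "S3": {"LR": 1.00, "SVC": 1.00, "RF": 0.60, "ANN": 1.00},
    "S4": {"LR": 0.20, "SVC": 0.00, "RF": 0.00, "ANN": 0.20},
    "S5": {"LR": 1.00, "SVC": 1.00, "RF": 1.00, "ANN": 1.00},
    "S6": {"LR": 0.80, "SVC": 0.40, "RF": 0.20, "ANN": 0.60},
    "S7": {"LR": 1.00, "SVC": 0.60, "RF": 0.40, "ANN": 1.00},
    "S8": {"LR": 1.00, "SVC": 1.00, "RF": 0.80, "ANN": 1.00},
    "S9": {"LR": 1.00, "SVC": 1.00, "RF": 0.80, "ANN": 0.80},
    "S10": {"LR": 0.60, "SVC": 0.20, "RF": 0.20, "ANN": 0.40},
    "S11": {"LR": 1.00, "SVC": 0.80, "RF": 0.20, "ANN": 0.80},
    "S12": {"LR": 0.80, "SVC": 0.80, "RF": 0.80, "ANN": 0.80},
}

#: Published per-rat d' for the same task, as printed (two decimals).
DPRIME_PUBLISHED: dict[str, dict[str, float]] = {
    "S1": {"LR": 2.28, "SVC": 2.69, "RF": 2.90, "ANN": 2.46},
    "S2": {"LR": 0.96, "SVC": 1.10, "RF": 0.91, "ANN": 1.09},
    "S3": {"LR": 2.46, "SVC": 2.46, "RF": 2.00, "ANN": 2.46},
    "S4": {"LR": 1.21, "SVC": 0.77, "RF": 0.77, "ANN": 1.21},
    "S5": {"LR": 1.33, "SVC": 2.12, "RF": 3.03, "ANN": 1.53},
    "S6": {"LR": 2.90, "SVC": 1.15, "RF": 1.21, "ANN": 2.31},
    "S7": {"LR": 2.28, "SVC": 0.72, "RF": 1.50, "ANN": 1.64},
    "S8": {"LR": 1.43, "SVC": 1.43, "RF": 1.55, "ANN": 1.43},
    "S9": {"LR": 1.86, "SVC": 1.99, "RF": 2.90, "ANN": 1.84},
    "S10": {"LR": 0.84, "SVC": 0.91, "RF": 0.91, "ANN": 1.15},
    "S11": {"LR": 1.99, "SVC": 1.68, "RF": 1.21, "ANN": 1.55},
    "S12": {"LR": 0.26, "SVC": 0.99, "RF": 1.68, "ANN": 0.99},
}

#: Published per-rat criterion c, as printed (two decimals).
CRITERION_PUBLISHED: dict[str, dict[str, float]] = {
    "S1": {"LR": 0.14, "SVC": -0.06, "RF": -0.61, "ANN": 0.05},
    "S2": {"LR": -0.23, "SVC": -0.29, "RF": -1.29, "ANN": -0.29},
    "S3": {"LR": 0.05, "SVC": -0.74, "RF": 0.05, "ANN": 0.05},
    "S4": {"LR": -1.45, "SVC": -1.67, "RF": -1.67, "ANN": -1.45},
    "S5": {"LR": 0.62, "SVC": 0.22, "RF": -0.23, "ANN": 0.51},
    "S6": {"LR": -0.61, "SVC": -0.83, "RF": -1.45, "ANN": -0.90},
    "S7": {"LR": 0.14, "SVC": -0.11, "RF": -1.00, "ANN": 0.46},
    "S8": {"LR": 0.57, "SVC": 0.57, "RF": 0.07, "ANN": 0.57},
    "S9": {"LR": 0.35, "SVC": 0.29, "RF": -0.61, "ANN": -0.08},
    "S10": {"LR": -0.16, "SVC": -1.30, "RF": -1.30, "ANN": -0.83},
    "S11": {"LR": 0.28, "SVC": 0.00, "RF": -1.45, "ANN": 0.07},
    "S12": {"LR": 0.71, "SVC": 0.35, "RF": 0.00, "ANN": 0.35},
}

#: Published Wilcoxon signed-rank statistics (W, p as printed) per task and
#: model. For the schedule task all four W are 0.0 with p < .001.
WILCOXON_PUBLISHED: dict[str, dict[str, tuple[float, str]]] = {
    "schedule_vs_none": {
        "LR": (0.0, "<.001"), "SVC": (0.0, "<.001"),
        "RF": (0.0, "<.001"), "ANN": (0.0, "<.001"),
    },
    "fixed_vs_variable_space": {
        "LR": (4.0, ".003"), "SVC": (3.0, ".002"),
        "RF": (2.0, ".001"), "ANN": (39.0, "1.00"),
    },
    "ft_vs_vt": {
        "LR": (20.5, ".176"), "SVC": (22.0, ".204"),
        "RF": (35.0, ".791"), "ANN": (25.5, ".339"),
    },
}
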