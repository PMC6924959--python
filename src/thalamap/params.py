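"""Published group-level parameters used as simulator defaults.

``GROUP_NORM_AMP`` holds the reported normalized EPSP amplitude structure of
the two thalamocortical pathways: for each (cell_type, layer) group the
(mean, SD, n) of peak EPSP amplitude normalized to reference-layer excitatory
cells of the same slice (L4 for VPM input, L5A for POm input).  Groups
reported with a median only (n <= 2) carry SD 0.  These numbers seed the
generative model so that a simulated cohort reproduces the study's group and
sample-size structure.

``REF_ABS_AMP_MV`` anchors the absolute scale: the reported mean absolute
peak amplitude of reference-layer excitatory cells (mV).

``DEFAULT_BOUNDARIES`` transcribes the approximate layer boundaries of the
mouse C2 barrel column from Lefort et al. (2009), the anatomical reference
used for depth profiles.
"""

from __future__ import annotations

from .types import LayerBoundaries

# (cell_type, layer) -> (mean_norm_amp, sd_norm_amp, n_cells)
GROUP_NORM_AMP: dict[str, dict[tuple[str, str], tuple[float, float, int]]] = {
    "VPM": {
        ("EXC", "L2"): (0.20, 0.54, 29),
        ("EXC", "L3"): (0.46, 0.50, 45),
        ("EXC", "L4"): (1.00, 0.37, 65),
        ("EXC", "L5A"): (0.14, 0.21, 39),
        ("EXC", "L5B"): (0.17, 0.22, 44),
        ("EXC", "L6"): (0.39, 0.79, 40),
        ("PV", "L2"): (0.04, 0.02, 3),
        ("PV", "L3"): (0.35, 0.34, 9),
        ("PV", "L4"): (1.15, 0.92, 14),
        ("PV", "L5A"): (0.12, 0.22, 5),
        ("PV", "L5B"): (0.04, 0.02, 11),
        ("PV", "L6"): (0.17, 0.20, 5),
        ("SST", "L2"): (0.01, 0.00, 3),
        ("SST", "L3"): (0.09, 0.10, 3),
        ("SST", "L4"): (0.09, 0.08, 8),
        ("SST", "L5A"): (0.03, 0.01, 6),
        ("SST", "L5B"): (0.01, 0.01, 9),
        ("SST", "L6"): (0.01, 0.01, 4),
        ("VIP", "L2"): (0.13, 0.26, 10),
        ("VIP", "L3"): (0.32, 0.49, 17),
        ("VIP", "L4"): (0.15, 0.16, 8),
        ("VIP", "L5A"): (0.03, 0.01, 5),
        ("VIP", "L5B"): (0.13, 0.23, 5),
        ("VIP", "L6"): (0.011, 0.00, 1),
    },
    "POm": {
        ("EXC", "L2"): (0.11, 0.18, 38),
        ("EXC", "L3"): (0.16, 0.39, 31),
        ("EXC", "L4"): (0.13, 0.35, 38),
        ("EXC", "L5A"): (1.00, 0.52, 75),
        ("EXC", "L5B"): (0.11, 0.31, 52),
        ("EXC", "L6"): (0.23, 0.38, 47),
        ("PV", "L2"): (0.17, 0.13, 3),
        ("PV", "L3"): (0.04, 0.04, 7),
        ("PV", "L4"): (0.03, 0.06, 8),
        ("PV", "L5A"): (1.17, 0.96, 8),
        ("PV", "L5B"): (0.09, 0.10, 10),
        ("PV", "L6"): (0.03, 0.05, 10),
        ("SST", "L2"): (0.02, 0.02, 5),
        ("SST", "L3"): (0.07, 0.16, 7),
        ("SST", "L4"): (0.02, 0.01, 3),
        ("SST", "L5A"): (0.15, 0.15, 5),
        ("SST", "L5B"): (0.03, 0.04, 13),
        ("SST", "L6"): (0.01, 0.01, 18),
        ("VIP", "L2"): (0.18, 0.37, 14),
        ("VIP", "L3"): (0.17, 0.25, 20),
        ("VIP", "L4"): (0.21, 0.35, 12),
        ("VIP", "L5A"): (0.33, 0.32, 10),
        ("VIP", "L5B"): (0.20, 0.18, 7),
        ("VIP", "L6"): (0.090, 0.00, 2),
    },
}

#: Number of slices (= animals) per pathway cohort.
N_SLICES = {"VPM": 33, "POm": 43}

#: Mean absolute peak EPSP amplitude of reference-layer excitatory cells, mV.
REF_ABS_AMP_MV = {"VPM": 14.5, "POm": 11.7}

#: Dual-exponential kinetics presets per cell type, (tau_rise_ms, tau_decay_ms).
#: PV kinetics are fastest, so matched-amplitude inputs give ~2-3x larger
#: rise slopes in PV than in EXC cells, as observed.
KINETICS_MS: dict[str, tuple[float, float]] = {
    "EXC": (2.0, 40.0),
    "PV": (0.5, 15.0),
    "SST": (2.0, 40.0),
    "VIP": (1.0, 25.0),
}

DEFAULT_BOUNDARIES = LayerBoundaries(
    bands=[
        ("L1", 0.0, 128.0),
        ("L2", 128.0, 269.0),
        ("L3", 269.0, 418.0),
        ("L4", 418.0, 588.0),
        ("L5A", 588.0, 708.0),
        ("L5B", 708.0, 890.0),
        ("L6", 890.0, 1154.0),
    ]
)
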