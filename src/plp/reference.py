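"""Published summary statistics from an FDG-PET case-control study of
cerebral small vessel disease (174 patients, 206 matched healthy controls).

These are the printed group-level numbers of that study — demographics,
per-region SUVmean means/SDs with effect sizes, voxel-cluster reports,
and network-vs-region correlations.  The subject-level data are not
public, so the values serve three purposes here:

* worked examples and regression benchmarks (effect sizes and p-values
  recomputed from the printed inputs must match the printed outputs);
* realistic parameters for the synthetic cohort generator;
* the shape of the report tables the pipeline writes.
"""

from __future__ import annotations

import pandas as pd

#: (patients, controls)
GROUP_SIZES = (174, 206)
GROUP_LABELS = ("CSVD", "HC")

#: Demographics and vascular risk factors.  ``kind`` is ``continuous``
#: (value = (mean, sd)) or ``binary`` (value = count of positives).
DEMOGRAPHICS = pd.DataFrame(
    [
        ("age", "continuous", (53.75, 7.78), (53.0, 18.42), 0.613),
        ("male", "binary", 101, 132, 0.246),
        ("bmi", "continuous", (24.22, 3.19), (24.02, 3.08), 0.540),
        ("fbs", "continuous", (5.78, 1.60), (5.55, 1.20), 0.104),
        ("smoking", "binary", 28, 35, 0.890),
        ("hypertension", "binary", 52, 39, 0.016),
        ("diabetes", "binary", 30, 26, 0.245),
        ("hyperlipidemia", "binary", 44, 58, 0.562),
    ],
    columns=["characteristic", "kind", "csvd", "hc", "p_printed"],
)

_R = [
    # network, label, is_network_row, mean/sd CSVD, mean/sd HC, p, |d|
    ("visual", "Visual network", True, 1.155, 0.036, 1.155, 0.135, 0.968, 0.00),
    ("visual", "Right fusiform gyrus (lateroventral area)", False, 1.144, 0.052, 1.156, 0.052, 0.032, 0.23),
    ("visual", "Left posterior parahippocampal gyrus", False, 1.048, 0.055, 1.059, 0.050, 0.036, 0.21),
    ("visual", "Right caudal lingual gyrus", False, 0.972, 0.053, 0.984, 0.053, 0.033, 0.23),
    ("visual", "Right middle occipital gyrus", False, 1.052, 0.061, 1.040, 0.053, 0.037, 0.21),
    ("visual", "Right occipital polar cortex", False, 1.059, 0.070, 1.045, 0.056, 0.035, 0.22),
    ("visual", "Left inferior occipital gyrus", False, 1.154, 0.051, 1.166, 0.044, 0.019, 0.25),
    ("visual", "Left lateral superior occipital gyrus", False, 1.194, 0.066, 1.176, 0.064, 0.007, 0.28),
    ("somatomotor", "Somatomotor network", True, 1.074, 0.034, 1.076, 0.127, 0.896, 0.02),
    ("somatomotor", "Left superior frontal gyrus (medial area)", False, 1.096, 0.056, 1.108, 0.050, 0.036, 0.23),
    ("somatomotor", "Right precentral gyrus (head and face region)", False, 1.350, 0.088, 1.325, 0.084, 0.005, 0.29),
    ("somatomotor", "Right precentral gyrus (upper limb region)", False, 1.222, 0.068, 1.208, 0.064, 0.035, 0.21),
    ("somatomotor", "Right superior temporal gyrus (area 41/42)", False, 1.028, 0.047, 1.038, 0.043, 0.033, 0.22),
    ("somatomotor", "Left superior temporal gyrus (TE1.0 and TE1.2)", False, 1.126, 0.051, 1.141, 0.044, 0.002, 0.32),
    ("somatomotor", "Left superior parietal lobule (postcentral area)", False, 0.840, 0.055, 0.851, 0.043, 0.038, 0.23),
    ("somatomotor", "Right superior parietal lobule (postcentral area)", False, 0.864, 0.051, 0.875, 0.043, 0.030, 0.23),
    ("somatomotor", "Right inferior parietal lobule (rostroventral area)", False, 1.228, 0.085, 1.211, 0.068, 0.035, 0.22),
    ("somatomotor", "Left postcentral gyrus (upper limb, head, and face region)", False, 0.992, 0.085, 1.010, 0.074, 0.029, 0.23),
    ("somatomotor", "Right postcentral gyrus (area 2)", False, 0.958, 0.081, 0.976, 0.066, 0.019, 0.25),
    ("somatomotor", "Left postcentral gyrus (trunk region)", False, 0.837, 0.094, 0.862, 0.079, 0.007, 0.29),
    ("somatomotor", "Right postcentral gyrus (trunk region)", False, 0.862, 0.079, 0.814, 0.083, 0.010, 0.59),
    ("dorsal_attention", "Dorsal attention network", True, 0.993, 0.029, 0.994, 0.119, 0.983, 0.01),
    ("dorsal_attention", "Left middle frontal gyrus (ventrolateral area)", False, 0.919, 0.618, 0.937, 0.056, 0.003, 0.04),
    ("dorsal_attention", "Right inferior frontal gyrus (dorsal area)", False, 1.109, 0.070, 1.080, 0.064, 0.000, 0.43),
    ("dorsal_attention", "Left precentral gyrus (caudal dorsolateral area)", False, 1.301, 0.076, 1.280, 0.076, 0.007, 0.28),
    ("dorsal_attention", "Right precentral gyrus (caudal dorsolateral area)", False, 1.228, 0.071, 1.209, 0.067, 0.007, 0.28),
    ("dorsal_attention", "Right inferior temporal gyrus (ventrolateral area)", False, 1.146, 0.069, 1.161, 0.056, 0.027, 0.24),
    ("dorsal_attention", "Left superior parietal lobule (caudal area)", False, 0.832, 0.060, 0.844, 0.046, 0.028, 0.23),
    ("dorsal_attention", "Left postcentral gyrus (area 2)", False, 0.959, 0.076, 0.975, 0.063, 0.029, 0.23),
    ("ventral_attention", "Ventral attention network", True, 1.123, 0.036, 1.126, 0.133, 0.786, 0.03),
    ("ventral_attention", "Left inferior frontal gyrus (opercular area)", False, 1.090, 0.068, 1.063, 0.060, 0.000, 0.42),
    ("ventral_attention", "Left inferior frontal gyrus (ventral area)", False, 1.125, 0.084, 1.101, 0.069, 0.003, 0.31),
    ("ventral_attention", "Left paracentral lobule (lower limb region)", False, 1.142, 0.052, 1.156, 0.053, 0.013, 0.27),
    ("ventral_attention", "Left caudoposterior superior temporal sulcus", False, 1.184, 0.069, 1.159, 0.056, 0.000, 0.40),
    ("ventral_attention", "Right caudoposterior superior temporal sulcus", False, 1.202, 0.066, 1.189, 0.053, 0.036, 0.22),
    ("ventral_attention", "Right dorsal agranular insula", False, 0.887, 0.047, 0.897, 0.042, 0.021, 0.23),
    ("ventral_attention", "Right ventral dysgranular and granular insula", False, 1.147, 0.074, 1.124, 0.059, 0.001, 0.35),
    ("ventral_attention", "Left cingulate gyrus (caudodorsal area)", False, 1.169, 0.062, 1.183, 0.051, 0.019, 0.25),
    ("ventral_attention", "Right cingulate gyrus (caudodorsal area)", False, 1.151, 0.053, 1.162, 0.046, 0.024, 0.22),
    ("limbic", "Limbic network", True, 0.951, 0.031, 0.967, 0.114, 0.056, 0.18),
    ("limbic", "Left orbital gyrus (area 13)", False, 1.013, 0.053, 0.999, 0.044, 0.004, 0.29),
    ("limbic", "Right orbital gyrus (area 13)", False, 1.130, 0.067, 1.115, 0.052, 0.021, 0.25),
    ("limbic", "Right superior temporal gyrus (medial area)", False, 1.115, 0.067, 1.096, 0.058, 0.004, 0.31),
    ("limbic", "Left parahippocampal gyrus (entorhinal cortex)", False, 1.052, 0.076, 1.035, 0.053, 0.015, 0.26),
    ("frontoparietal", "Frontoparietal network", True, 1.076, 0.043, 1.076, 0.129, 0.928, 0.00),
    ("frontoparietal", "Left superior frontal gyrus (medial area)", False, 1.246, 0.097, 1.226, 0.085, 0.039, 0.22),
    ("frontoparietal", "Right middle frontal gyrus (dorsal area)", False, 0.907, 0.056, 0.919, 0.052, 0.038, 0.22),
    ("frontoparietal", "Left middle frontal gyrus (dorsolateral area)", False, 0.970, 0.054, 0.982, 0.050, 0.026, 0.23),
    ("frontoparietal", "Right middle frontal gyrus (dorsolateral area)", False, 0.936, 0.055, 0.949, 0.048, 0.019, 0.25),
    ("frontoparietal", "Right middle frontal gyrus (area 46)", False, 0.784, 0.061, 0.799, 0.054, 0.012, 0.26),
    ("frontoparietal", "Left inferior frontal sulcus", False, 1.079, 0.065, 1.063, 0.055, 0.011, 0.27),
    ("frontoparietal", "Right inferior frontal sulcus", False, 1.176, 0.081, 1.149, 0.067, 0.001, 0.37),
    ("frontoparietal", "Right orbital gyrus (lateral area)", False, 1.010, 0.055, 1.023, 0.042, 0.010, 0.27),
    ("frontoparietal", "Left inferior temporal gyrus (caudolateral area)", False, 1.074, 0.057, 1.088, 0.051, 0.011, 0.26),
    ("default", "Default network", True, 1.075, 0.025, 1.079, 0.125, 0.609, 0.04),
    ("default", "Left middle frontal gyrus (ventrolateral area)", False, 0.912, 0.064, 0.927, 0.061, 0.023, 0.24),
    ("default", "Left inferior frontal gyrus (caudal area)", False, 1.157, 0.075, 1.138, 0.066, 0.009, 0.27),
    ("default", "Right inferior frontal gyrus (caudal area)", False, 1.050, 0.068, 1.031, 0.062, 0.005, 0.29),
    ("default", "Left inferior frontal gyrus (rostral area)", False, 1.080, 0.062, 1.092, 0.051, 0.043, 0.21),
    ("default", "Left orbital gyrus (medial area)", False, 1.118, 0.064, 1.102, 0.052, 0.009, 0.28),
    ("default", "Right orbital gyrus (medial area)", False, 1.077, 0.049, 1.067, 0.045, 0.041, 0.21),
    ("default", "Left orbital gyrus (orbital area)", False, 1.233, 0.091, 1.216, 0.069, 0.035, 0.21),
    ("default", "Left superior temporal gyrus (rostral area)", False, 1.184, 0.083, 1.168, 0.068, 0.034, 0.21),
    ("default", "Left anterior superior temporal sulcus", False, 0.915, 0.083, 0.931, 0.070, 0.038, 0.21),
    ("default", "Right rostroposterior superior temporal sulcus", False, 1.160, 0.065, 1.142, 0.052, 0.005, 0.31),
    ("default", "Right precuneus (area 31)", False, 0.861, 0.079, 0.878, 0.066, 0.026, 0.24),
]

#: Per-region and whole-network SUVmean summaries with printed effect sizes.
#: ``d_printed`` is the printed magnitude (the source prints |d|).
REGION_STATS = pd.DataFrame(
    _R,
    columns=[
        "network",
        "label",
        "is_network_row",
        "mean_csvd",
        "sd_csvd",
        "mean_hc",
        "sd_hc",
        "p_printed",
        "d_printed",
    ],
)

#: Voxel-cluster report: suprathreshold clusters of the voxelwise
#: patient-vs-control t map (positive t = patient hypermetabolism).
CLUSTERS = pd.DataFrame(
    [
        ("somatomotor", "right postcentral gyrus", 25, 24, -45, 63, 3.719),
        ("somatomotor", "right superior temporal gyrus", 58, 51, 0, -6, -3.780),
        ("dorsal_attention", "right superior parietal gyrus", 174, 24, -51, 63, 3.876),
    ],
    columns=["network", "region", "cluster_size", "x", "y", "z", "t"],
)

#: Significant network-vs-member-region correlations over the pooled
#: cohort (n = 380).  ``p_printed`` as printed; "<0.001" stored as 0.001
#: with ``p_is_floor`` True.
NETWORK_REGION_CORR = pd.DataFrame(
    [
        ("visual", "Right caudal lingual gyrus", -0.150, 0.003, False),
        ("somatomotor", "Left superior parietal lobule (postcentral area)", -0.180, 0.001, True),
        ("somatomotor", "Right inferior parietal lobule (rostroventral area)", 0.157, 0.002, False),
        ("somatomotor", "Right postcentral gyrus (trunk region)", -0.150, 0.003, False),
        ("dorsal_attention", "Left postcentral gyrus (area 2)", -0.149, 0.004, False),
        ("default", "Left middle frontal gyrus (ventrolateral area)", -0.202, 0.001, True),
        ("default", "Left inferior frontal gyrus (rostral area)", -0.181, 0.001, True),
        ("default", "Right orbital gyrus (medial area)", 0.151, 0.003, False),
        ("ventral_attention", "Right ventral dysgranular and granular insula", 0.174, 0.001, False),
        ("frontoparietal", "Right middle frontal gyrus (dorsal area)", -0.181, 0.001, True),
        ("frontoparietal", "Left superior frontal gyrus (medial area)", 0.170, 0.001, False),
        ("frontoparietal", "Left middle frontal gyrus (inferior frontal junction)", -0.230, 0.001, True),
        ("frontoparietal", "Left inferior frontal sulcus", 0.175, 0.001, False),
        ("frontoparietal", "Right orbital gyrus (lateral area)", 0.173, 0.001, False),
        ("frontoparietal", "Right inferior frontal sulcus", 0.153, 0.003, False),
        ("frontoparietal", "Right middle frontal gyrus (area 46)", -0.152, 0.003, False),
        ("frontoparietal", "Right middle frontal gyrus (inferior frontal junction)", -0.166, 0.001, False),
    ],
    columns=["network", "region", "r", "p_printed", "p_is_floor"],
)
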