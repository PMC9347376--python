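"""Published method-validation records for the CVA21 (V937) RP-UPLC assay.

Bench data from the validated method: retention-time precision (two systems
x triplicate injections), FLR peak-area precision with the derived
empty/full ratios and concentrations, and the spike-mixture accuracy study.
Used as fixed test vectors for the statistics and ratio arithmetic.
"""

# Retention times (min), six injections per VP: system 1 INJ 1-3 then
# system 2 INJ 1-3. Printed overall average and %RSD rows follow.
RT_INJECTIONS = {
    "VP4": [4.336, 4.334, 4.336, 4.374, 4.370, 4.375],
    "VP1": [5.669, 5.669, 5.670, 5.696, 5.691, 5.697],
    "VP2": [7.076, 7.088, 7.073, 7.163, 7.158, 7.171],
    "VP0": [7.523, 7.536, 7.522, 7.627, 7.624, 7.641],
    "VP3": [8.769, 8.782, 8.775, 8.911, 8.913, 8.924],
}
RT_AVG = {"VP4": 4.354, "VP1": 5.682, "VP2": 7.122, "VP0": 7.579, "VP3": 8.846}
RT_RSD = {"VP4": 0.48, "VP1": 0.25, "VP2": 0.66, "VP0": 0.76, "VP3": 0.87}

# System-1 triplicate averages as printed.
RT_SYS1_AVG = {"VP4": 4.335, "VP1": 5.669, "VP2": 7.079, "VP0": 7.527, "VP3": 8.775}

# FLR peak areas per injection (area units), same six injections, plus the
# printed total, VP2+VP4, VP0/(VP2+VP4) ratio, and capsid conc (capsids/mL).
AREA_INJECTIONS = [
    # (VP4, VP1, VP2, VP0, VP3, total, vp2+vp4, ratio, conc)
    (193_564, 22_588_588, 21_890_324, 11_698_177, 17_846_286, 74_216_939, 22_083_888, 0.53, 3.66e12),
    (193_956, 22_455_981, 22_072_816, 11_671_564, 17_881_673, 74_275_990, 22_266_772, 0.524, 3.67e12),
    (200_811, 22_184_617, 22_064_813, 11_447_195, 17_769_682, 73_667_118, 22_265_624, 0.514, 3.64e12),
    (179_236, 22_026_203, 21_541_602, 11_979_694, 17_320_598, 73_047_333, 21_720_838, 0.552, 3.61e12),
    (183_989, 22_140_644, 21_649_730, 12_036_562, 17_416_280, 73_427_205, 21_833_719, 0.551, 3.63e12),
    (186_503, 21_690_748, 21_647_757, 12_123_676, 17_060_923, 72_709_607, 21_834_260, 0.555, 3.59e12),
]
AREA_VP_ORDER = ("VP4", "VP1", "VP2", "VP0", "VP3")
SYS1_AVG_RATIO = 0.523  # printed triplicate-average ratio, system 1
OVERALL_RATIO_RSD = 3.2  # %RSD of the ratio over all six injections
OVERALL_CONC_RSD = 0.8  # %RSD of the concentration over all six injections

# Spike-accuracy study: standard (1.39E12/mL, ~0.25% empty) mixed with a
# less purified batch (3.66E12/mL, 34.3% empty) in four ratios.
# (name, theo_conc, theo_ratio, meas_conc, meas_ratio, conc_pct, ratio_pct)
ACCURACY_ROWS = [
    ("Mix-1", 2.52e12, 0.3323, 2.58e12, 0.3276, 102, 99),
    ("Mix-2", 1.60e12, 0.0793, 1.68e12, 0.0715, 105, 90),
    ("Mix-3", 1.48e12, 0.0362, 1.57e12, 0.0362, 106, 100),
    ("Mix-4", 1.45e12, 0.0241, 1.52e12, 0.0237, 105, 98),
]
RATIO_SENSITIVITY_SPAN = 0.012  # Mix-3 vs Mix-4 theoretical ratio difference
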