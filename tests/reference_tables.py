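"""Published posterior summary rows from the four foreperiod experiments.

Each row: (experiment, parameter, mean, sd, rope_low, rope_high,
hdi_low, hdi_high, reject) exactly as printed (ms units; slopes in
ms/trial or ms/block).  The arousal intercept was not part of the selected
model in experiments 1-3 and has no printed row there.
"""

PUBLISHED_ROWS = [
    # experiment 1 (400/1400 ms, non-aging)
    ("exp1", "Baseline.trial", 0.32, 0.11, -0.011, 0.011, 0.11, 0.52, "Yes"),
    ("exp1", "Baseline.block", -0.40, 0.22, -0.022, 0.022, -0.83, 0.02, "No"),
    ("exp1", "CF.intercept", 24.45, 3.62, -0.362, 0.362, 17.30, 31.53, "Yes"),
    ("exp1", "CF.trial", 0.67, 0.22, -0.022, 0.022, 0.24, 1.09, "Yes"),
    ("exp1", "CF.block", 1.37, 0.45, -0.045, 0.045, 0.48, 2.25, "Yes"),
    ("exp1", "FS.intercept", 20.14, 3.31, -0.331, 0.331, 13.57, 26.68, "Yes"),
    ("exp1", "FS.trial", 0.33, 0.16, -0.016, 0.016, 0.01, 0.65, "No"),
    ("exp1", "FS.block", -0.24, 0.34, -0.034, 0.034, -0.92, 0.41, "No"),
    ("exp1", "IN.trial", -0.64, 0.24, -0.024, 0.024, -1.11, -0.18, "Yes"),
    ("exp1", "IN.block", -0.76, 0.52, -0.052, 0.052, -1.79, 0.25, "No"),
    # experiment 2 (50/200 ms, non-aging)
    ("exp2", "Baseline.trial", 0.32, 0.07, -0.007, 0.007, 0.18, 0.46, "Yes"),
    ("exp2", "Baseline.block", -0.44, 0.15, -0.015, 0.015, -0.73, -0.15, "Yes"),
    ("exp2", "CF.intercept", -10.82, 2.53, -0.253, 0.253, -15.79, -5.88, "Yes"),
    ("exp2", "CF.trial", -0.09, 0.15, -0.015, 0.015, -0.37, 0.20, "No"),
    ("exp2", "CF.block", 0.42, 0.32, -0.032, 0.032, -0.20, 1.04, "No"),
    ("exp2", "FS.intercept", 5.98, 2.31, -0.231, 0.231, 1.43, 10.46, "Yes"),
    ("exp2", "FS.trial", 0.01, 0.11, -0.011, 0.011, -0.21, 0.23, "No"),
    ("exp2", "FS.block", -0.36, 0.24, -0.024, 0.024, -0.82, 0.09, "No"),
    ("exp2", "IN.trial", -0.06, 0.16, -0.016, 0.016, -0.38, 0.26, "No"),
    ("exp2", "IN.block", -0.35, 0.36, -0.036, 0.036, -1.05, 0.34, "No"),
    # experiment 3 (50/400 ms, non-aging, 17 blocks)
    ("exp3", "Baseline.trial", 0.50, 0.06, -0.006, 0.006, 0.38, 0.64, "Yes"),
    ("exp3", "Baseline.block", 0.81, 0.11, -0.011, 0.011, 0.58, 1.02, "Yes"),
    ("exp3", "CF.intercept", 1.68, 2.22, -0.222, 0.222, -2.57, 6.02, "No"),
    ("exp3", "CF.trial", -0.04, 0.13, -0.013, 0.013, -0.29, 0.22, "No"),
    ("exp3", "CF.block", 0.45, 0.24, -0.024, 0.024, -0.02, 0.92, "No"),
    ("exp3", "FS.intercept", 13.68, 2.05, -0.205, 0.205, 9.57, 17.72, "Yes"),
    ("exp3", "FS.trial", -0.04, 0.10, -0.010, 0.010, -0.24, 0.15, "No"),
    ("exp3", "FS.block", -0.19, 0.18, -0.018, 0.018, -0.53, 0.17, "No"),
    ("exp3", "IN.trial", -0.04, 0.14, -0.014, 0.014, -0.31, 0.24, "No"),
    ("exp3", "IN.block", -0.56, 0.27, -0.027, 0.027, -1.08, -0.03, "Yes"),
    # experiment 4 (400/1400 ms, uniform, full model)
    ("exp4", "Baseline.trial", 1.22, 0.17, -0.017, 0.017, 0.89, 1.56, "Yes"),
    ("exp4", "Baseline.block", 1.00, 0.26, -0.026, 0.026, 0.48, 1.51, "Yes"),
    ("exp4", "CF.intercept", -12.07, 2.85, -0.285, 0.285, -17.72, -6.40, "Yes"),
    ("exp4", "CF.trial", 0.04, 0.24, -0.024, 0.024, -0.42, 0.50, "No"),
    ("exp4", "CF.block", 0.87, 0.36, -0.036, 0.036, 0.14, 1.59, "Yes"),
    ("exp4", "FS.intercept", 13.71, 2.81, -0.281, 0.281, 8.33, 19.32, "Yes"),
    ("exp4", "FS.trial", -0.05, 0.23, -0.023, 0.023, -0.50, 0.39, "No"),
    ("exp4", "FS.block", 0.22, 0.35, -0.035, 0.035, -0.47, 0.92, "No"),
    ("exp4", "IN.intercept", -14.40, 2.84, -0.284, 0.284, -20.07, -9.04, "Yes"),
    ("exp4", "IN.trial", -0.14, 0.33, -0.033, 0.033, -0.78, 0.51, "No"),
    ("exp4", "IN.block", -0.55, 0.49, -0.049, 0.049, -1.50, 0.42, "No"),
]
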