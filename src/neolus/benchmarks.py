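"""Reported classification results of the restricted clinical cohort.

The neonatal LUS images this framework was designed around cannot be
redistributed (REB and hospital data-sharing restrictions), so the only
public record of the clinical experiments is a set of row-percentage
confusion matrices and cohort composition tables.  They are transcribed
here as package data: the metric arithmetic (overall accuracy, weighted
F1) can be recomputed from them and checked against the reported
headline numbers, which is exactly what the acceptance checks do.

Class order throughout: Normal, CLD, CON, PTX, RDS, TTN (rows = true
class, columns = predicted class, cells = row percentages).
"""

from __future__ import annotations

import numpy as np

BENCHMARK_CLASS_ORDER = ("Normal", "CLD", "CON", "PTX", "RDS", "TTN")

#: balanced cohort: 4 subjects and 120 images per class (720 images)
BALANCED_CLASS_IMAGES = np.array([120, 120, 120, 120, 120, 120])
#: imbalanced cohort image counts per class (1550 images, 42 subjects)
IMBALANCED_CLASS_IMAGES = np.array([185, 180, 305, 105, 245, 530])

#: cohort composition: class -> (patients, videos, images)
IMBALANCED_OVERVIEW = {
    "Normal": (6, 37, 185), "CLD": (6, 36, 180), "CON": (7, 61, 305),
    "PTX": (5, 21, 105), "RDS": (7, 49, 245), "TTN": (11, 106, 530),
}
BALANCED_OVERVIEW = {
    "Normal": (4, 24, 120), "CLD": (4, 24, 120), "CON": (4, 24, 120),
    "PTX": (4, 19, 120), "RDS": (4, 24, 120), "TTN": (4, 24, 120),
}

# row-percentage confusion matrices of the four reported experiments
LOO_BALANCED_ROWPCT = np.array([
    [98.33, 0.00, 0.00, 0.83, 0.00, 0.83],
    [0.00, 100.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 95.83, 0.00, 4.17, 0.00],
    [9.17, 0.00, 0.83, 76.67, 0.00, 13.33],
    [0.00, 0.00, 4.17, 0.00, 92.50, 3.33],
    [3.33, 0.00, 0.00, 3.33, 0.00, 93.33],
])

LOO_IMBALANCED_ROWPCT = np.array([
    [17.84, 0.00, 0.00, 7.03, 0.00, 75.14],
    [0.00, 100.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 99.02, 0.00, 0.98, 0.00],
    [8.57, 0.00, 12.38, 17.14, 25.71, 36.19],
    [2.86, 0.00, 8.98, 5.31, 57.55, 25.31],
    [4.53, 0.00, 0.00, 2.26, 2.83, 90.38],
])

LOSO_BALANCED_ROWPCT = np.array([
    [93.33, 0.00, 0.00, 1.67, 0.00, 5.00],
    [0.00, 100.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 78.33, 0.00, 21.67, 0.00],
    [11.67, 0.00, 2.50, 40.83, 5.83, 39.17],
    [0.00, 0.00, 28.33, 0.00, 52.50, 19.17],
    [9.17, 0.00, 0.00, 5.83, 0.00, 85.00],
])

LOSO_IMBALANCED_ROWPCT = np.array([
    [4.86, 0.00, 0.00, 11.89, 0.00, 83.24],
    [0.00, 100.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 96.39, 0.00, 3.61, 0.00],
    [23.81, 0.00, 15.24, 3.81, 22.86, 34.29],
    [5.71, 0.00, 17.96, 6.12, 39.59, 30.61],
    [13.96, 0.00, 0.00, 5.09, 5.47, 75.47],
])

#: reported headline metrics: (overall accuracy %, weighted F1)
REPORTED_METRICS = {
    "loo_balanced": (92.78, 0.927),
    "loo_imbalanced": (74.39, 0.740),
    "loso_balanced": (75.00, 0.713),
    "loso_imbalanced": (63.48, 0.606),
}

EXPERIMENTS = {
    "loo_balanced": (LOO_BALANCED_ROWPCT, BALANCED_CLASS_IMAGES),
    "loo_imbalanced": (LOO_IMBALANCED_ROWPCT, IMBALANCED_CLASS_IMAGES),
    "loso_balanced": (LOSO_BALANCED_ROWPCT, BALANCED_CLASS_IMAGES),
    "loso_imbalanced": (LOSO_IMBALANCED_ROWPCT, IMBALANCED_CLASS_IMAGES),
}
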