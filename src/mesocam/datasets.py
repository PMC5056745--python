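"""Published summary tables from a Minshan Mountains mesocarnivore survey.

A long-term (2004-2015) baited camera-trap survey of the mesocarnivore guild
in the Minshan Mountains, Sichuan, accumulated 23,313 camera-days at 495
stations and reported seasonal diel time-budget selection ratios for five
focal species.  The printed per-period detection counts ``n_i`` and selection
ratios ``w_i`` are useful test inputs: because ``w_i = (n_i / N) / pi_i``,
each table row implies the survey-wide diel availability ``pi_i = o_i / w_i``,
and rows from different species must agree on it — a strong internal
consistency check on any selection-ratio implementation.

Counts and ratios are ordered (crepuscular, diurnal, nocturnal).
"""

from __future__ import annotations

import numpy as np

#: season -> species -> {"counts": (n_c, n_d, n_n), "w": (w_c, w_d, w_n), "chi2": float}
SELECTION_TABLE = {
    "warm": {
        "masked_palm_civet": {"counts": (32, 5, 99), "w": (1.88, 0.07, 2.17),
                              "chi2": 139.57},
        "leopard_cat": {"counts": (29, 28, 58), "w": (2.01, 0.45, 1.51),
                        "chi2": 43.32},
        "yellow_throated_marten": {"counts": (3, 71, 1), "w": (0.32, 1.75, 0.04),
                                   "chi2": 50.53},
        "siberian_weasel": {"counts": (25, 127, 56), "w": (0.96, 1.13, 0.80),
                            "chi2": 4.66},
        "hog_badger": {"counts": (34, 77, 92), "w": (1.34, 0.70, 1.35),
                       "chi2": 21.03},
    },
    "winter": {
        "yellow_throated_marten": {"counts": (1, 23, 2), "w": (0.32, 2.03, 0.17),
                                   "chi2": 21.47},
        "siberian_weasel": {"counts": (5, 11, 27), "w": (0.98, 0.59, 1.41),
                            "chi2": 6.36},
    },
}

#: camera-days by season for the same survey
EFFORT_CAMERA_DAYS = {"warm": 20_490, "winter": 2_823, "total": 23_313}

#: study-area centroid used for solar calculations
STUDY_CENTROID = (32.9, 104.1)


def backsolve_availability(season: str = "warm", min_w: float = 0.1):
    """Per-species implied availability vectors pi_i = o_i / w_i.

    Entries whose printed ratio ``w_i < min_w`` are masked (NaN): at two
    printed decimals their rounding error dominates the back-solved value.
    Returns an array of shape (n_species, 3).
    """
    rows = []
    for rec in SELECTION_TABLE[season].values():
        n = np.asarray(rec["counts"], dtype=float)
        w = np.asarray(rec["w"], dtype=float)
        o = n / n.sum()
        pi = np.where(w >= min_w, o / np.where(w > 0, w, np.nan), np.nan)
        rows.append(pi)
    return np.array(rows)
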