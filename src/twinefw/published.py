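"""Published EFW reference values used for calibration and cross-checks.

The values below are the published ultrasonographic estimated-fetal-weight
reference for Japanese twin pregnancies: integer-gram EFW at Z-scores
-2, -1.5, 0, +1.5 and +2 for gestational weeks 16 through 37. They are the
calibration anchor for the synthetic-cohort generator
(:func:`twinefw.synthetic.derive_truth_from_reference`) and the target of
the package's internal-consistency checks.

The corresponding singleton reference is *not* bundled: its values are not
public in tabular form here and must be supplied by the user (see
:mod:`twinefw.compare`).
"""

from __future__ import annotations

import pandas as pd

Z_LEVELS = (-2.0, -1.5, 0.0, 1.5, 2.0)

# week: (Z=-2, Z=-1.5, Z=0, Z=+1.5, Z=+2), grams
_TWIN_EFW_CELLS = {
    16: (48, 59, 99, 149, 167),
    17: (79, 92, 140, 198, 220),
    18: (115, 132, 189, 256, 280),
    19: (159, 179, 245, 321, 348),
    20: (209, 232, 308, 394, 425),
    21: (266, 292, 378, 474, 509),
    22: (328, 358, 455, 564, 602),
    23: (397, 431, 540, 661, 704),
    24: (472, 509, 631, 766, 814),
    25: (552, 594, 730, 880, 933),
    26: (639, 686, 837, 1002, 1061),
    27: (731, 783, 950, 1133, 1198),
    28: (828, 886, 1070, 1272, 1343),
    29: (932, 995, 1198, 1420, 1498),
    30: (1041, 1111, 1333, 1576, 1661),
    31: (1156, 1232, 1475, 1740, 1833),
    32: (1276, 1360, 1625, 1913, 2015),
    33: (1403, 1493, 1781, 2095, 2205),
    34: (1534, 1632, 1945, 2285, 2404),
    35: (1671, 1777, 2116, 2484, 2613),
    36: (1814, 1929, 2294, 2691, 2830),
    37: (1962, 2086, 2480, 2907, 3057),
}

# Headline cohort bookkeeping figures from the same study, used only as
# inputs to arithmetic cross-checks (never as fitted quantities).
RECRUITED_WOMEN = 705
EXCLUDED_WOMEN = 341
INCLUDED_WOMEN = 364
INCLUDED_FETUSES = 728
TOTAL_EFW_MEASUREMENTS = 7904


def japanese_twin_efw_reference() -> "pd.DataFrame":
    """Return the published twin EFW reference as a DataFrame.

    Index: gestational week (16..37); columns: Z level (float); cells:
    EFW in integer grams.
    """
    frame = pd.DataFrame.from_dict(_TWIN_EFW_CELLS, orient="index", dtype=float)
    frame.columns = list(Z_LEVELS)
    frame.index.name = "ga_weeks"
    return frame
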