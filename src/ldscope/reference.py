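"""Published group-level measurements used as desk-check inputs.

These are the printed group means of the Pt1/Pt4 N-starvation (D0-D11) /
N-resupply (h24, h72) time course: per ecotype x timepoint the mean LD
count and mean total LD volume (with SDs and the printed mean individual
LD volume), the mean thylakoid-volume losses over starvation, and the
population mean cell volumes from brightfield morphometry.  They serve as
inputs to the arithmetic reporting layer (ratio-of-means, derived
percentages and gains); nothing in the image pipeline depends on them.
"""

from __future__ import annotations

import pandas as pd

TIMEPOINTS = ["D0", "D3", "D7", "D11", "h24", "h72"]

#: mean +/- SD LD count per cell and total LD volume (um^3/cell), plus the
#: printed mean individual LD volume (um^3/LD), n = 24-37 cells per group.
GROUP_MEANS = pd.DataFrame(
    [
        ("Pt1", "D0", 3.57, 2.08, 0.32, 0.35, 0.09),
        ("Pt1", "D3", 6.80, 2.78, 2.36, 1.95, 0.35),
        ("Pt1", "D7", 6.20, 2.65, 3.12, 1.95, 0.50),
        ("Pt1", "D11", 6.96, 3.06, 6.15, 3.52, 0.88),
        ("Pt1", "h24", 12.10, 7.62, 4.15, 3.80, 0.34),
        ("Pt1", "h72", 2.70, 2.71, 0.39, 0.83, 0.14),
        ("Pt4", "D0", 2.65, 2.43, 0.56, 0.33, 0.21),
        ("Pt4", "D3", 4.08, 1.25, 5.41, 3.28, 1.32),
        ("Pt4", "D7", 4.59, 2.15, 5.39, 3.20, 1.17),
        ("Pt4", "D11", 5.31, 2.62, 8.72, 5.42, 1.64),
        ("Pt4", "h24", 10.39, 6.15, 2.03, 1.43, 0.20),
        ("Pt4", "h72", 4.76, 1.57, 0.61, 0.32, 0.13),
    ],
    columns=["ecotype", "timepoint", "mean_ld_count", "sd_ld_count",
             "mean_total_ld_volume_um3", "sd_total_ld_volume_um3",
             "printed_v_lipid_per_ld_um3"],
)

#: population mean cell volume (um^3) from brightfield morphometry at the
#: timepoints the derived report needs.
CELL_VOLUME_MEANS = pd.DataFrame(
    [
        ("Pt1", "D0", 199.0),
        ("Pt1", "D11", 158.0),
        ("Pt1", "h24", 171.0),
        ("Pt4", "D0", 278.0),
        ("Pt4", "D11", 258.0),
        ("Pt4", "h24", 300.0),
    ],
    columns=["ecotype", "timepoint", "mean_cell_volume_um3"],
)

#: mean thylakoid-volume loss over D0 -> D11 (um^3), per ecotype.
THYLAKOID_VOLUME_LOSS_UM3 = {"Pt1": 9.8, "Pt4": 14.8}

#: exponential-phase division rates of the N-replete precultures (day^-1).
PRECULTURE_DIVISION_RATES = {"Pt1": 0.73, "Pt4": 0.70}
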