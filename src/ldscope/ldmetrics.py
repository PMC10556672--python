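"""Per-cell and per-group lipid-droplet statistics.

Derived indicators follow the study's definitions: per cell the LD count,
the total LD volume (V_Lipid), the percentage of total LD volume held by
the two largest LDs (the inequality-of-distribution indicator), LD size
classes (basal 0.005-0.7 um^3 vs large) and LD-to-plastid distance
classes (close <= 5 um vs distant > 5 um); per group the means and sample
SDs and the mean individual LD volume V_Lipid/LD, defined as the ratio of
the group means mean(V_Lipid)/mean(LD count) — the definition that
reproduces the published group table from its printed marginals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .objects3d import CellRecord3D, ld_plastid_distance

log = logging.getLogger(__name__)

#: inclusive upper bound of the basal small-LD size class (um^3)
BASAL_MAX_UM3 = 0.7
#: below this volume an LD is flagged as likely sub-detection (um^3)
SUB_DETECTION_UM3 = 0.005
#: close/distant boundary for LD-plastid distances (um), inclusive on close
DISTANCE_THRESHOLD_UM = 5.0
#: minimum LD count for the two-largest fraction to be reported
MIN_LDS_FOR_FRACTION = 3


@dataclass
class LDMetricsRow:
    cell_id: int
    ecotype: str
    timepoint: str
    ld_volumes_um3: list[float] = field(default_factory=list)
    distances_um: list[float] = field(default_factory=list)
    thylakoid_volume_um3: float = np.nan

    @property
    def ld_count(self) -> int:
        return len(self.ld_volumes_um3)

    @property
    def total_ld_volume_um3(self) -> float:
        return float(np.sum(self.ld_volumes_um3)) if self.ld_volumes_um3 else 0.0


@dataclass
class GroupSummary:
    ecotype: str
    timepoint: str
    n_cells: int
    mean_ld_count: float
    sd_ld_count: float
    mean_total_ld_volume_um3: float
    sd_total_ld_volume_um3: float
    mean_thylakoid_volume_um3: float
    sd_thylakoid_volume_um3: float
    v_lipid_per_ld_um3: float


def fraction_two_largest(volumes) -> float:
    """Percentage of total LD volume contained in the two largest LDs.

    Scale-invariant; exactly 100 when there are only two LDs.  Requires
    at least two positive volumes (the reporting layer additionally
    restricts to cells with >= 3 LDs).
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError("fraction_two_largest needs at least 2 LD volumes")
    if np.any(v <= 0):
        raise ValueError("LD volumes must be positive")
    top2 = np.sort(v)[-2:].sum()
    return 100.0 * top2 / v.sum()


def classify_ld_size(volume_um3: float) -> str:
    """Basal small (<= 0.7 um^3, inclusive) vs large LD size class."""
    if volume_um3 <= 0:
        raise ValueError("LD volume must be positive")
    if volume_um3 < SUB_DETECTION_UM3:
        log.info("LD volume %.4g um^3 is below the basal range lower bound "
                 "(possible sub-detection)", volume_um3)
    return "basal_small" if volume_um3 <= BASAL_MAX_UM3 else "large"


def classify_distance(d_um: float) -> str:
    """Close (<= 5 um, inclusive) vs distant (> 5 um) to the plastid."""
    if d_um < 0:
        raise ValueError("distance must be >= 0")
    return "close" if d_um <= DISTANCE_THRESHOLD_UM else "distant"


def build_metrics(records: list[CellRecord3D]) -> list[LDMetricsRow]:
    """CellRecord3D -> LDMetricsRow, computing per-LD distances."""
    rows = []
    for rec in records:
        vols = [o.volume_um3 for o in rec.lds]
        if rec.thylakoid is not None:
            dists = [ld_plastid_distance(o, rec.thylakoid) for o in rec.lds]
            thyl = rec.thylakoid.volume_um3
        else:
            dists, thyl = [], np.nan
        rows.append(LDMetricsRow(cell_id=rec.cell_id, ecotype=rec.ecotype,
                                 timepoint=rec.timepoint, ld_volumes_um3=vols,
                                 distances_um=dists,
                                 thylakoid_volume_um3=thyl))
    return rows


def metrics_frame(rows: list[LDMetricsRow],
                  min_lds_for_fraction: int = MIN_LDS_FOR_FRACTION
                  ) -> pd.DataFrame:
    """Tidy per-cell table of the derived LD indicators.

    ``fraction_two_largest_pct`` is NaN for cells with fewer than
    ``min_lds_for_fraction`` LDs (excluded with a log note, mirroring the
    study's >= 3 LDs restriction).
    """
    out = []
    n_excluded = 0
    for r in rows:
        if r.ld_count >= max(min_lds_for_fraction, 2):
            frac = fraction_two_largest(r.ld_volumes_um3)
        else:
            frac = np.nan
            n_excluded += 1
        dists = np.asarray(r.distances_um, dtype=float)
        out.append(dict(
            cell_id=r.cell_id, ecotype=r.ecotype, timepoint=r.timepoint,
            ld_count=r.ld_count, total_ld_volume_um3=r.total_ld_volume_um3,
            fraction_two_largest_pct=frac,
            n_distant=int((dists > DISTANCE_THRESHOLD_UM).sum()),
            n_close=int((dists <= DISTANCE_THRESHOLD_UM).sum()),
            thylakoid_volume_um3=r.thylakoid_volume_um3,
        ))
    if n_excluded:
        log.info("fraction_two_largest undefined for %d cell(s) with < %d "
                 "LDs; rows excluded from that indicator", n_excluded,
                 max(min_lds_for_fraction, 2))
    return pd.DataFrame(out)


def v_lipid_per_ld(mean_total_ld_volume: float, mean_ld_count: float) -> float:
    """Mean individual LD volume: ratio of the two group means (um^3/LD)."""
    if mean_ld_count <= 0:
        raise ValueError("mean LD count must be positive")
    return mean_total_ld_volume / mean_ld_count


def summarize_group(rows: list[LDMetricsRow]) -> GroupSummary:
    """Group means and sample SDs plus V_Lipid/LD.

    Cells with zero LDs contribute count 0 and volume 0 to the means.
    V_Lipid/LD carries no dispersion: it is a ratio of two means, and no
    per-cell quantity has it as its mean.
    """
    if not rows:
        raise ValueError("summarize_group needs at least one cell")
    counts = np.array([r.ld_count for r in rows], dtype=float)
    totals = np.array([r.total_ld_volume_um3 for r in rows], dtype=float)
    thyl = np.array([r.thylakoid_volume_um3 for r in rows], dtype=float)

    def sd(x):
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    return GroupSummary(
        ecotype=rows[0].ecotype, timepoint=rows[0].timepoint,
        n_cells=len(rows),
        mean_ld_count=float(counts.mean()), sd_ld_count=sd(counts),
        mean_total_ld_volume_um3=float(totals.mean()),
        sd_total_ld_volume_um3=sd(totals),
        mean_thylakoid_volume_um3=float(np.nanmean(thyl)) if np.any(
            np.isfinite(thyl)) else np.nan,
        sd_thylakoid_volume_um3=sd(thyl[np.isfinite(thyl)]),
        v_lipid_per_ld_um3=v_lipid_per_ld(float(totals.mean()),
                                          float(counts.mean())),
    )


def derived_report(groups: pd.DataFrame, cell_volumes: pd.DataFrame
                   ) -> pd.DataFrame:
    """Cross-timepoint and cross-ecotype derived quantities.

    ``groups`` needs columns ecotype, timepoint, mean_total_ld_volume_um3
    (and optionally mean_thylakoid_volume_um3); ``cell_volumes`` columns
    ecotype, timepoint, mean_cell_volume_um3.  Produces, per ecotype:

    * LD percentage of cell volume per timepoint
      (100 x mean V_Lipid / mean cell volume);
    * LD volume gain and cell-volume change between the first and last
      starvation timepoints (D0 -> D11);

    plus the between-ecotype cell-volume ratio 100 x Pt4/Pt1 at D0.
    Missing ecotype/timepoint keys are reported as rows with NaN values
    rather than silently skipped.
    """
    g = groups.set_index(["ecotype", "timepoint"])
    cv = cell_volumes.set_index(["ecotype", "timepoint"])
    rows = []

    def get(frame, key, col):
        try:
            return float(frame.loc[key, col])
        except KeyError:
            log.warning("missing key %s in derived_report input", key)
            return np.nan

    for eco in g.index.get_level_values(0).unique():
        for tp in g.loc[eco].index:
            vl = float(g.loc[(eco, tp), "mean_total_ld_volume_um3"])
            vc = get(cv, (eco, tp), "mean_cell_volume_um3")
            rows.append(dict(ecotype=eco, timepoint=tp,
                             quantity="ld_pct_of_cell_volume",
                             value=100.0 * vl / vc))
        for a, b in (("D0", "D11"),):
            va = get(g, (eco, a), "mean_total_ld_volume_um3")
            vb = get(g, (eco, b), "mean_total_ld_volume_um3")
            rows.append(dict(ecotype=eco, timepoint=f"{a}->{b}",
                             quantity="ld_volume_gain_um3", value=vb - va))
            ca = get(cv, (eco, a), "mean_cell_volume_um3")
            cb = get(cv, (eco, b), "mean_cell_volume_um3")
            rows.append(dict(ecotype=eco, timepoint=f"{a}->{b}",
                             quantity="cell_volume_change_um3", value=cb - ca))

    v1 = get(cv, ("Pt1", "D0"), "mean_cell_volume_um3")
    v4 = get(cv, ("Pt4", "D0"), "mean_cell_volume_um3")
    rows.append(dict(ecotype="Pt4/Pt1", timepoint="D0",
                     quantity="cell_volume_ratio_pct",
                     value=100.0 * v4 / v1))
    return pd.DataFrame(rows)
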