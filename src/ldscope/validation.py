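"""Synthetic recovery studies: how well the pipeline retrieves known truth.

Each function generates scenes with the :mod:`ldscope.synthetic`
defaults, runs the corresponding pipeline stage end to end and scores the
result against the generator's ground truth.  These studies back the
quantitative validation claims of the package (cell retention, distractor
rejection, volume and barycenter recovery, strategy discrimination,
null-calibration of the ANOVA) and are reused by the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import morphometry, objects3d, stats, synthetic
from .pipeline import _train_on_mosaic


def recovery_2d(n_cells: int = 200, cells_per_mosaic: int = 25,
                ecotype: str = "Pt1", pixel_size_um: float = 0.1,
                seed: int = 0) -> dict:
    """Brightfield morphometry recovery on planted fusiform cells.

    Generates ``n_cells`` across several mosaics with debris/bubble
    distractors, trains the pixel classifier on ~20 % of the first
    mosaic's cells, then segments and filters every mosaic.  A planted
    cell counts as retained when a filtered particle's centroid lies
    within 3 um of its true center; a distractor counts as rejected when
    no filtered particle lies within 3 um of it.

    Returns retention and rejection percentages, the mean absolute
    relative error of the prolate-spheroid volume over matched cells, and
    the matched mean width/length.
    """
    n_mosaics = int(np.ceil(n_cells / cells_per_mosaic))
    clf = None
    matched_meas, matched_truth = [], []
    n_planted = n_retained = 0
    n_distr = n_distr_accepted = 0
    widths, lengths = [], []

    for m in range(n_mosaics):
        cfg = synthetic.SceneConfig(
            ecotype_label=ecotype, n_cells=cells_per_mosaic,
            pixel_size_um=pixel_size_um, seed=seed + 523 * (m + 1))
        img, truth = synthetic.generate_brightfield_mosaic(cfg)
        if clf is None:
            clf = _train_on_mosaic(img, truth, pixel_size_um, seed=seed)
        cells = morphometry.measure_mosaic(img, clf, ecotype=ecotype,
                                           pixel_size_um=pixel_size_um)
        n_planted += len(truth.cells)
        n_distr += len(truth.distractors)
        if len(cells) == 0:
            continue
        cx = cells.centroid_x_um.to_numpy()
        cy = cells.centroid_y_um.to_numpy()
        for t in truth.cells.itertuples():
            d = np.hypot(cx - t.x_um, cy - t.y_um)
            if d.min() <= 3.0:
                n_retained += 1
                meas = cells.iloc[int(d.argmin())]
                matched_meas.append(meas.volume_um3)
                matched_truth.append(t.volume_um3)
                widths.append(meas.width_um)
                lengths.append(meas.length_um)
        for t in truth.distractors.itertuples():
            d = np.hypot(cx - t.x_um, cy - t.y_um)
            if d.min() <= 3.0:
                n_distr_accepted += 1

    meas = np.asarray(matched_meas)
    tv = np.asarray(matched_truth)
    rel = np.abs(meas - tv) / tv
    return {
        "n_planted": n_planted,
        "retained_pct": 100.0 * n_retained / n_planted,
        "n_distractors": n_distr,
        "distractors_rejected_pct":
            100.0 * (n_distr - n_distr_accepted) / n_distr,
        "volume_mare_pct": 100.0 * float(rel.mean()),
        "mean_width_um": float(np.mean(widths)),
        "mean_length_um": float(np.mean(lengths)),
    }


def recovery_3d(n_stacks: int = 30, ecotype: str = "Pt4",
                strategy: str = "two_large_dominant",
                total_ld_volume: float = 8.0, seed: int = 0) -> dict:
    """Confocal 3D recovery of LD volumes and barycenters.

    For each stack: model the cell, match every measured LD to the
    nearest true LD center, and score the per-cell total LD volume error,
    the per-LD volume errors, the barycenter error (in units of the xy
    voxel) and the thylakoid object count.
    """
    voxel = (0.072, 0.072, 0.1)
    tot_errs, ld_errs, bary_errs, thyl_counts = [], [], [], []
    dist_pairs = []
    for s in range(n_stacks):
        cfg = synthetic.SceneConfig(
            ecotype_label=ecotype, n_cells=1, ld_strategy=strategy,
            ld_total_volume_um3=total_ld_volume,
            pixel_size_um=voxel[0], z_step_um=voxel[2],
            seed=seed + 211 * (s + 1))
        stack, mask, truth = synthetic.generate_confocal_stack(cfg)
        rec = objects3d.model_cell(stack, mask, ecotype=ecotype,
                                   voxel_size_um=voxel)
        thyl_counts.append(1 if rec.thylakoid is not None else 0)
        true_tot = truth.lds.volume_um3.sum()
        meas_tot = sum(o.volume_um3 for o in rec.lds)
        tot_errs.append(abs(meas_tot - true_tot) / true_tot)
        tc = truth.lds[["x_um", "y_um", "z_um"]].to_numpy()
        for o in rec.lds:
            b = np.asarray(o.barycenter_um)
            d = np.linalg.norm(tc - b, axis=1)
            j = int(d.argmin())
            if d[j] <= 1.0:
                ld_errs.append(abs(o.volume_um3
                                   - truth.lds.volume_um3.iloc[j])
                               / truth.lds.volume_um3.iloc[j])
                bary_errs.append(d[j] / voxel[0])
            if rec.thylakoid is not None:
                dist_pairs.append((o, rec.thylakoid))
    # Euclidean-distance oracle: implementation vs direct formula
    max_dist_dev = 0.0
    for ld, pl in dist_pairs:
        impl = objects3d.ld_plastid_distance(ld, pl)
        brute = float(np.sqrt(sum((a - b) ** 2 for a, b in
                                  zip(ld.barycenter_um, pl.barycenter_um))))
        max_dist_dev = max(max_dist_dev, abs(impl - brute))
    return {
        "n_stacks": n_stacks,
        "total_volume_median_err_pct": 100.0 * float(np.median(tot_errs)),
        "per_ld_median_err_pct": 100.0 * float(np.median(ld_errs)),
        "barycenter_median_err_vox": float(np.median(bary_errs)),
        "barycenter_max_err_vox": float(np.max(bary_errs)),
        "thylakoid_objects_per_cell": float(np.mean(thyl_counts)),
        "distance_oracle_max_dev_um": max_dist_dev,
    }


def strategy_discrimination(n_stacks: int = 8, seed: int = 0) -> dict:
    """End-to-end contrast of the LD accumulation strategies.

    Measures, through the full stack -> objects -> metrics chain, the
    mean fraction of LD volume in the two largest LDs for the
    ``two_large_dominant`` (Pt4-like) and ``many_medium`` (Pt1-like)
    strategies, and the fraction of LDs classified distant (> 5 um) under
    ``fragmented_distant`` (post-resupply state).
    """
    from . import ldmetrics

    def run(strategy, ecotype, total):
        fracs, distant, close = [], 0, 0
        for s in range(n_stacks):
            cfg = synthetic.SceneConfig(
                ecotype_label=ecotype, n_cells=1, ld_strategy=strategy,
                ld_total_volume_um3=total, pixel_size_um=0.072,
                seed=seed + 977 * (s + 1))
            stack, mask, _ = synthetic.generate_confocal_stack(cfg)
            rec = objects3d.model_cell(stack, mask, ecotype=ecotype,
                                       voxel_size_um=(0.072, 0.072, 0.1))
            vols = [o.volume_um3 for o in rec.lds]
            if len(vols) >= 3:
                fracs.append(ldmetrics.fraction_two_largest(vols))
            if rec.thylakoid is not None:
                for o in rec.lds:
                    d = objects3d.ld_plastid_distance(o, rec.thylakoid)
                    if ldmetrics.classify_distance(d) == "distant":
                        distant += 1
                    else:
                        close += 1
        return (float(np.mean(fracs)) if fracs else np.nan,
                distant, distant + close)

    frac_two_large, _, _ = run("two_large_dominant", "Pt4", 8.0)
    frac_many, _, _ = run("many_medium", "Pt1", 6.0)
    _, n_distant, n_all = run("fragmented_distant", "Pt1", 3.0)
    return {
        "fraction_two_largest_two_large_dominant_pct": frac_two_large,
        "fraction_two_largest_many_medium_pct": frac_many,
        "distant_ld_fraction_fragmented_pct": 100.0 * n_distant / n_all,
    }


def anova_null_rejection(n_reps: int = 1000, k_groups: int = 6,
                         n_per_group: int = 25, alpha: float = 0.05,
                         seed: int = 0) -> dict:
    """Type-I error of the global ANOVA over seeded null simulations."""
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{i}" for i in range(k_groups)], n_per_group)
    rejections = 0
    for _ in range(n_reps):
        values = rng.normal(0.0, 1.0, k_groups * n_per_group)
        res = stats.anova_lsd(values, groups, alpha=alpha)
        if res.p_value < alpha:
            rejections += 1
    return {"n_reps": n_reps,
            "rejection_rate_pct": 100.0 * rejections / n_reps}


def table_consistency(group_means: pd.DataFrame) -> pd.DataFrame:
    """Ratio-of-means V_Lipid/LD recomputed from printed group marginals."""
    from .ldmetrics import v_lipid_per_ld
    out = group_means.copy()
    out["computed_v_lipid_per_ld_um3"] = [
        v_lipid_per_ld(r.mean_total_ld_volume_um3, r.mean_ld_count)
        for r in group_means.itertuples()]
    out["abs_dev"] = (out.computed_v_lipid_per_ld_um3
                      - out.printed_v_lipid_per_ld_um3).abs()
    return out
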