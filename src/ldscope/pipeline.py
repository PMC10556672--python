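"""Pipeline driver: simulate -> segment -> metrics -> stats in one run.

Each stage reads only the previous stage's declared outputs and writes
tidy CSVs into the run directory; a JSON manifest records the package
version, configuration (with provenance strings for every study-stated
default), seeds and config hash.  Re-running with the same configuration
reproduces all CSV outputs bit-identically in synthetic mode.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, ldmetrics, morphometry, objects3d, stats, synthetic

log = logging.getLogger(__name__)

STAGES = ["simulate_brightfield", "morphometry_2d", "simulate_stacks",
          "objects_3d", "ld_metrics", "group_stats"]


def _train_on_mosaic(image, truth, pixel_size_um, seed,
                     annotated_fraction=0.2):
    """Emulate the manual training annotations on one mosaic.

    ~20 % of the planted cells are annotated over their full footprint
    (as freehand "Cells" regions would be) and an equal number of pixels
    outside any cell go into the background class.  Returns the trained
    classifier.
    """
    feats = morphometry.compute_features(image)
    rng = np.random.default_rng(seed + 1)
    instance = synthetic.rasterize_cells(truth, image.shape, pixel_size_um)
    labels = np.zeros(image.shape, dtype=np.uint8)
    cells = truth.cells
    n_annot = max(1, int(round(annotated_fraction * len(cells))))
    # an annotator deliberately covers the visible contrast range, from
    # the faintest to the darkest cell
    if "contrast" in cells.columns and n_annot > 1:
        by_contrast = cells.sort_values("contrast")
        pick = np.linspace(0, len(cells) - 1, n_annot).round().astype(int)
        chosen_ids = set(by_contrast.cell_id.iloc[pick] + 1)
    else:
        chosen_ids = set(cells.cell_id.iloc[:n_annot] + 1)
    cell_sel = np.isin(instance, list(chosen_ids))
    labels[cell_sel] = 1
    n_cell_px = int(cell_sel.sum())
    # background areas are drawn clear of cell outlines, as a human
    # annotator would place them
    from scipy import ndimage as ndi
    away = ~ndi.binary_dilation(instance > 0, iterations=3)
    bg = np.flatnonzero(away.ravel())
    take = rng.choice(bg, size=min(n_cell_px, bg.size), replace=False)
    labels.ravel()[take] = 2
    return morphometry.train_classifier(feats, labels, seed=seed)


def run_pipeline(config: io.RunConfig) -> dict:
    """Execute all six stages; return the manifest dict.

    On stage failure the manifest (with the completed stages and the
    failing stage's name) is still written before the exception
    propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "provenance": dict(io.RunConfig.PROVENANCE),
        "stages": [],
    }
    design = synthetic.study_design()

    def checkpoint(stage):
        manifest["stages"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        # ------------------------------------------------ brightfield sim
        stage_dir = out
        mosaics = {}
        for i, eco in enumerate(config.ecotypes):
            cfg = synthetic.SceneConfig(
                ecotype_label=eco, n_cells=config.n_cells_2d,
                pixel_size_um=config.pixel_size_2d_um,
                seed=config.seed + 101 * (i + 1))
            img, truth = synthetic.generate_brightfield_mosaic(cfg)
            io.write_tiff(stage_dir / f"brightfield_{eco}.tif", img,
                          pixel_size_um=config.pixel_size_2d_um,
                          seed=cfg.seed)
            truth.cells.to_csv(stage_dir / f"brightfield_{eco}_truth.csv",
                               index=False)
            mosaics[eco] = (img, truth)
        checkpoint("simulate_brightfield")

        # ------------------------------------------------ 2D morphometry
        cell_tables = []
        for eco, (img, truth) in mosaics.items():
            clf = _train_on_mosaic(img, truth, config.pixel_size_2d_um,
                                   config.seed)
            cells = morphometry.measure_mosaic(
                img, clf, ecotype=eco, pixel_size_um=config.pixel_size_2d_um)
            cells.insert(0, "ecotype", eco)
            cell_tables.append(cells)
        cells2d = pd.concat(cell_tables, ignore_index=True)
        io.write_table(out / "cells2d.csv",
                       cells2d[["ecotype"] + io.CSV_SCHEMAS["cells2d"]])
        checkpoint("morphometry_2d")

        # ------------------------------------------------ confocal sim
        records = []
        obj_rows = []
        sid = 0
        for eco in config.ecotypes:
            for tp in config.timepoints:
                row = design[(design.ecotype == eco)
                             & (design.timepoint == tp)].iloc[0]
                for c in range(config.n_cells_3d):
                    sid += 1
                    cfg = synthetic.SceneConfig(
                        ecotype_label=eco, n_cells=1,
                        ld_strategy=row.ld_strategy,
                        ld_total_volume_um3=float(row.ld_total_volume_um3),
                        thylakoid_volume_um3=float(row.thylakoid_volume_um3),
                        pixel_size_um=config.voxel_size_um[0],
                        z_step_um=config.voxel_size_um[2],
                        seed=config.seed + 7919 * sid)
                    stack, mask, _truth = synthetic.generate_confocal_stack(cfg)
                    rec = objects3d.model_cell(
                        stack, mask, cell_id=sid, ecotype=eco, timepoint=tp,
                        voxel_size_um=config.voxel_size_um)
                    records.append(rec)
                    for o in ([rec.thylakoid] if rec.thylakoid else []) + rec.lds:
                        obj_rows.append(dict(
                            cell_id=sid, object_id=o.label, channel=o.channel,
                            voxel_count=o.voxel_count,
                            volume_um3=o.volume_um3,
                            bx_um=o.barycenter_um[0],
                            by_um=o.barycenter_um[1],
                            bz_um=o.barycenter_um[2]))
        io.write_table(out / "objects3d.csv", pd.DataFrame(obj_rows),
                       schema="objects3d")
        checkpoint("simulate_stacks")
        checkpoint("objects_3d")

        # ------------------------------------------------ LD metrics
        rows = ldmetrics.build_metrics(records)
        metrics = ldmetrics.metrics_frame(rows)
        io.write_table(out / "metrics.csv", metrics, schema="metrics")
        group_rows = []
        for (eco, tp), sub in pd.DataFrame(
                [(r.ecotype, r.timepoint, i) for i, r in enumerate(rows)],
                columns=["ecotype", "timepoint", "i"]).groupby(
                    ["ecotype", "timepoint"], sort=False):
            summary = ldmetrics.summarize_group([rows[i] for i in sub["i"]])
            group_rows.append(summary.__dict__)
        groups = pd.DataFrame(group_rows)
        io.write_table(out / "groups.csv", groups)
        checkpoint("ld_metrics")

        # ------------------------------------------------ group stats
        stats_rows = []
        for eco in config.ecotypes:
            sub = metrics[metrics.ecotype == eco]
            if sub.timepoint.nunique() >= 2 and (
                    sub.groupby("timepoint").size() >= 2).all():
                try:
                    res = stats.anova_lsd(sub.total_ld_volume_um3.to_numpy(),
                                          sub.timepoint.to_numpy())
                    for lev, m, s, n, letter in zip(res.levels, res.means,
                                                    res.sds, res.ns,
                                                    res.letters):
                        stats_rows.append(dict(
                            ecotype=eco, metric="total_ld_volume_um3",
                            timepoint=lev, mean=m, sd=s, n=int(n),
                            letters=letter, anova_p=res.p_value))
                except ValueError as exc:
                    log.warning("ANOVA skipped for %s: %s", eco, exc)
        io.write_table(out / "stats.csv", pd.DataFrame(stats_rows))
        checkpoint("group_stats")
    except Exception as exc:
        manifest["failed_stage"] = STAGES[len(manifest["stages"])] \
            if len(manifest["stages"]) < len(STAGES) else "unknown"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(
            f"pipeline failed at stage {manifest['failed_stage']!r}: {exc}"
        ) from exc
    return manifest
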