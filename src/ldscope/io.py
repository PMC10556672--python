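"""Readers/writers and run configuration.

TIFF images carry their geometry in a JSON sidecar (``<name>.json`` next
to the file) rather than in TIFF tags: channel order, pixel/voxel sizes
in um and the generating seed.  All tabular outputs are tidy CSV with
units in the column names (``_um``, ``_um2``, ``_um3``); headers are
versioned so downstream readers can detect schema drift.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

SCHEMA_VERSION = "1"

#: pinned CSV headers, one entry per writer
CSV_SCHEMAS = {
    "cells2d": ["label", "area_um2", "perimeter_um", "circularity",
                "ellipse_major_um", "ellipse_minor_um", "feret_um", "AR",
                "roundness", "solidity", "width_um", "length_um",
                "volume_um3"],
    "objects3d": ["cell_id", "object_id", "channel", "voxel_count",
                  "volume_um3", "bx_um", "by_um", "bz_um"],
    "metrics": ["cell_id", "ecotype", "timepoint", "ld_count",
                "total_ld_volume_um3", "fraction_two_largest_pct",
                "n_distant", "n_close", "thylakoid_volume_um3"],
    "spectrum": ["wavelength_nm", "absorbance"],
}


def write_tiff(path, array: np.ndarray, *, pixel_size_um=None,
               voxel_size_um=None, channels=None, seed=None) -> None:
    """Write a (multi-page, channel-major) TIFF plus its JSON sidecar."""
    path = Path(path)
    arr = np.asarray(array)
    tifffile.imwrite(path, arr.astype(np.float32))
    meta = {"shape": list(arr.shape), "schema_version": SCHEMA_VERSION}
    if pixel_size_um is not None:
        meta["pixel_size_um"] = pixel_size_um
    if voxel_size_um is not None:
        meta["voxel_size_um"] = list(voxel_size_um)
    if channels is not None:
        meta["channels"] = list(channels)
    if seed is not None:
        meta["seed"] = int(seed)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1))


def read_tiff(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF and its sidecar (empty dict when absent)."""
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise IOError(f"could not read TIFF {path.name}: {exc}") from exc
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arr, meta


def write_table(path, frame: pd.DataFrame, schema: str | None = None) -> None:
    if schema is not None:
        missing = [c for c in CSV_SCHEMAS[schema] if c not in frame.columns]
        if missing:
            raise ValueError(f"frame missing {schema} columns: {missing}")
        frame = frame[CSV_SCHEMAS[schema]]
    frame.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_spectrum_csv(path, extract_volume_ml: float = 1.0,
                      path_cm: float = 1.0):
    from .pigments import Spectrum
    df = pd.read_csv(path)
    return Spectrum(wavelength_nm=df["wavelength_nm"].to_numpy(),
                    absorbance=df["absorbance"].to_numpy(),
                    extract_volume_ml=extract_volume_ml, path_cm=path_cm)


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    Every tunable that defaults to a study-stated value records its
    provenance string, emitted into the run manifest.
    """

    ecotypes: list[str] = field(default_factory=lambda: ["Pt1", "Pt4"])
    timepoints: list[str] = field(
        default_factory=lambda: ["D0", "D3", "D7", "D11", "h24", "h72"])
    n_cells_2d: int = 12
    n_cells_3d: int = 2
    pixel_size_2d_um: float = 0.1
    voxel_size_um: tuple[float, float, float] = (0.072, 0.072, 0.1)
    seed: int = 0
    out_dir: str = "ldscope_run"

    PROVENANCE = {
        "area_filter_um2": "2D screen: area 25-200 um^2",
        "circularity_filter": "2D screen: circularity 0-0.4",
        "shape_filters": "AR/roundness/solidity >=3 / <=0.3 / >=0.55 (Pt1), "
                         ">=3.5 / <=0.3 / >=0.5 (Pt4)",
        "channel_params_um": "smooth/background: thylakoid 0.3/0.2, "
                             "Pt1 LD 0.1/0.2, Pt4 LD 0.1/0.4",
        "z_step_um": "confocal z step 0.1 um",
        "distance_classes_um": "close <= 5 um, distant > 5 um",
        "ld_size_classes_um3": "basal 0.005-0.7 um^3",
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "voxel_size_um" in data:
            data["voxel_size_um"] = tuple(data["voxel_size_um"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_size_um"] = list(self.voxel_size_um)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
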