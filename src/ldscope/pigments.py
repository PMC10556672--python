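"""Chlorophyll quantification from 90 %-acetone extract absorbance spectra.

Chlorophyll a and chlorophyll c (c1+c2) concentrations are computed with
the classical trichromatic equations for 90 % acetone (1-cm path,
absorbances read at 664, 647 and 630 nm, turbidity-corrected at 750 nm)::

    chl a      = 11.85 A664 - 1.54 A647 - 0.08 A630   (ug/mL)
    chl c1+c2  = 24.52 A630 - 1.67 A664 - 7.60 A647   (ug/mL)

The coefficient set is stored in ``data/pigment_coefficients.yaml`` so an
alternative solvent system can be swapped in without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

log = logging.getLogger(__name__)

REQUIRED_WAVELENGTHS_NM = (630.0, 647.0, 664.0)
TURBIDITY_WAVELENGTH_NM = 750.0

#: grid spacing (nm) above which interpolation at the anchors is refused
MAX_INTERP_SPACING_NM = 2.0


def load_coefficients(name: str = "acetone90") -> dict:
    """Load a trichromatic coefficient set from the packaged config."""
    text = resources.files("ldscope").joinpath(
        "data/pigment_coefficients.yaml").read_text()
    sets = yaml.safe_load(text)
    if name not in sets:
        raise KeyError(f"no coefficient set named {name!r}")
    return sets[name]


@dataclass
class Spectrum:
    """An absorbance spectrum of a pigment extract.

    ``wavelength_nm`` must be strictly increasing; ``extract_volume_ml``
    is the total acetone volume pooled over lysis cycles (sample-specific,
    never assumed) and ``path_cm`` the cuvette path length.
    """

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    extract_volume_ml: float = 1.0
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelength_nm.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance grids differ in shape")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")

    def at(self, wavelength: float) -> float:
        """Absorbance at ``wavelength``, interpolating on fine grids only."""
        wl = self.wavelength_nm
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise ValueError(f"spectrum does not cover {wavelength} nm")
        idx = np.searchsorted(wl, wavelength)
        if idx < len(wl) and wl[idx] == wavelength:
            return float(self.absorbance[idx])
        spacing = wl[min(idx, len(wl) - 1)] - wl[idx - 1]
        if spacing > MAX_INTERP_SPACING_NM:
            raise ValueError(
                f"no sample at {wavelength} nm and grid spacing {spacing:.1f} "
                f"nm is too coarse to interpolate (max "
                f"{MAX_INTERP_SPACING_NM} nm)")
        return float(np.interp(wavelength, wl, self.absorbance))


@dataclass
class PigmentResult:
    """Chlorophyll concentrations in the extract (ug/mL, 1-cm equivalent)."""

    chl_a_ug_per_ml: float
    chl_c_ug_per_ml: float
    raw_chl_a: float = field(repr=False, default=0.0)
    raw_chl_c: float = field(repr=False, default=0.0)


def quantify(spec: Spectrum, coefficients: dict | None = None,
             turbidity_correction: bool = True) -> PigmentResult:
    """Apply the trichromatic equations to a spectrum.

    Absorbances at 630/647/664 nm are corrected for turbidity by
    subtracting A750 (standard practice; toggleable) and normalised to a
    1-cm path.  Negative raw concentrations are clipped to zero and
    logged.
    """
    coeff = coefficients if coefficients is not None else load_coefficients()
    a = {wl: spec.at(wl) for wl in REQUIRED_WAVELENGTHS_NM}
    if turbidity_correction:
        a750 = spec.at(TURBIDITY_WAVELENGTH_NM)
        a = {wl: v - a750 for wl, v in a.items()}
    a = {wl: v / spec.path_cm for wl, v in a.items()}

    ca = coeff["chl_a"]
    cc = coeff["chl_c"]
    chl_a = ca["A664"] * a[664.0] + ca["A647"] * a[647.0] + ca["A630"] * a[630.0]
    chl_c = cc["A664"] * a[664.0] + cc["A647"] * a[647.0] + cc["A630"] * a[630.0]
    if chl_a < 0 or chl_c < 0:
        log.warning("negative raw pigment concentration clipped to 0 "
                    "(chl a %.4f, chl c %.4f ug/mL)", chl_a, chl_c)
    return PigmentResult(chl_a_ug_per_ml=max(chl_a, 0.0),
                         chl_c_ug_per_ml=max(chl_c, 0.0),
                         raw_chl_a=chl_a, raw_chl_c=chl_c)


def per_cell_content(result: PigmentResult, culture_volume_ml: float,
                     cell_density_per_ml: float,
                     extract_volume_ml: float | None = None,
                     spectrum: Spectrum | None = None) -> dict:
    """Convert extract concentrations to per-cell pigment content (pg/cell).

    content = concentration (ug/mL) x extract volume (mL)
              / (culture volume (mL) x density (cells/mL)),
    converted ug -> pg (x 1e6).
    """
    if cell_density_per_ml <= 0:
        raise ValueError("cell density must be > 0")
    if culture_volume_ml <= 0:
        raise ValueError("culture volume must be > 0")
    if extract_volume_ml is None:
        if spectrum is None:
            raise ValueError("extract volume required (pass extract_volume_ml "
                             "or a Spectrum carrying it)")
        extract_volume_ml = spectrum.extract_volume_ml
    n_cells = culture_volume_ml * cell_density_per_ml
    to_pg = 1e6
    return {
        "chl_a_pg_per_cell": result.chl_a_ug_per_ml * extract_volume_ml
        / n_cells * to_pg,
        "chl_c_pg_per_cell": result.chl_c_ug_per_ml * extract_volume_ml
        / n_cells * to_pg,
    }
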