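"""Synthetic microscopy scenes with exact ground truth.

This module renders the three data products the quantification pipeline
consumes — 2D brightfield mosaics, two-channel 3D confocal stacks and
absorbance spectra — for fusiform *P. tricornutum*-like cells, together
with a ground-truth table of every generated object.  The defaults encode
the study conditions of the N-starvation/resupply time course: Pt1 cells
3.5-4.0 um wide and 22.6-23.5 um long, Pt4 cells 4.0-4.4 um wide and
27.7-28.6 um long, confocal z-step 0.1 um, and four LD placement
strategies (``basal_only``, ``two_large_dominant``, ``many_medium``,
``fragmented_distant``) mirroring the two ecotypes' accumulation modes and
the post-resupply fragmentation state.

Cell outline model
------------------
The 2D fusiform profile is a symmetric lens built from two circular arcs
of radius ``R = (L^2/4 + W^2/4)/W`` so that the tip-to-tip distance is
exactly the cell length ``L`` and the maximum thickness is exactly the
width ``W``.  The 3D envelope is the solid of revolution of that profile
about the long axis.  The moment-fitted ellipse of the lens has a minor
axis of 0.958 W and its Feret diameter equals L, which is what the
downstream width/length conventions require.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .pigments import Spectrum

ECOTYPE_WIDTH_RANGES = {"Pt1": (3.5, 4.0), "Pt4": (4.0, 4.4)}
ECOTYPE_LENGTH_RANGES = {"Pt1": (22.6, 23.5), "Pt4": (27.7, 28.6)}

LD_STRATEGIES = (
    "basal_only",
    "two_large_dominant",
    "many_medium",
    "fragmented_distant",
)

#: Volume bounds of the basal LD population (um^3).
BASAL_LD_RANGE = (0.005, 0.7)

#: LD-to-plastid distance (um) separating "close" from "distant".
DISTANT_THRESHOLD_UM = 5.0


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed inside the cell envelope."""


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    ``width_range_um``/``length_range_um`` default to the ecotype's study
    ranges.  ``pixel_size_um`` is the xy sampling (0.072 um, the confocal
    default; brightfield mosaics are typically generated at 0.1 um/px),
    ``z_step_um`` the confocal slice spacing.  ``noise_level`` scales the
    Poisson background of confocal stacks and the additive noise of
    brightfield images; 0 disables noise entirely.
    """

    ecotype_label: str = "Pt1"
    n_cells: int = 1
    width_range_um: tuple[float, float] | None = None
    length_range_um: tuple[float, float] | None = None
    ld_strategy: str = "many_medium"
    ld_total_volume_um3: float | None = None
    thylakoid_volume_um3: float = 12.0
    pixel_size_um: float = 0.072
    z_step_um: float = 0.1
    noise_level: float = 1.0
    psf_sigma_um: float = 0.1
    n_debris: int | None = None
    n_bubbles: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ecotype_label not in ECOTYPE_WIDTH_RANGES:
            raise ValueError(f"unknown ecotype {self.ecotype_label!r}")
        if self.width_range_um is None:
            self.width_range_um = ECOTYPE_WIDTH_RANGES[self.ecotype_label]
        if self.length_range_um is None:
            self.length_range_um = ECOTYPE_LENGTH_RANGES[self.ecotype_label]
        if self.ld_strategy not in LD_STRATEGIES:
            raise ValueError(f"unknown LD strategy {self.ld_strategy!r}")
        if not self.width_range_um[1] < self.length_range_um[0]:
            raise ValueError("fusiform cells are elongated: max width must be "
                             "smaller than min length")
        if self.z_step_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("pixel/voxel sizes must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")

    def replace(self, **kw) -> "SceneConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruthTable:
    """True dimensions and object parameters of a generated scene.

    ``cells`` has one row per placed cell (width/length um, prolate-spheroid volume);
    ``lds`` one row per lipid droplet (analytic sphere volume, center um);
    ``plastids`` one row per cell's thylakoid region (rendered voxel
    volume, barycenter um); ``distractors`` one row per debris blob or
    bubble ring in brightfield scenes.
    """

    cells: pd.DataFrame
    lds: pd.DataFrame | None = None
    plastids: pd.DataFrame | None = None
    distractors: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# fusiform geometry
# ---------------------------------------------------------------------------

def lens_arc_radius(width: float, length: float) -> float:
    """Radius of the two circular arcs forming a lens of given W x L."""
    return (length * length / 4.0 + width * width / 4.0) / width


def fusiform_halfwidth(u, width: float, length: float):
    """Half-thickness of the fusiform profile at axial coordinate ``u``.

    Zero at the tips (|u| = L/2), W/2 at the center; negative beyond the
    tips (distance below the arc), which doubles as a soft signed field
    for anti-aliased rendering.
    """
    u = np.asarray(u, dtype=float)
    R = lens_arc_radius(width, length)
    d = R - width / 2.0
    g = np.sqrt(np.clip(R * R - u * u, 0.0, None)) - d
    return np.where(np.abs(u) <= R, g, -d)


def fusiform_area(width: float, length: float) -> float:
    """Analytic area of the lens profile (um^2)."""
    R = lens_arc_radius(width, length)
    d = R - width / 2.0
    half_angle = math.asin((length / 2.0) / R)
    # circular-segment area times two
    seg = R * R * half_angle - d * (length / 2.0)
    return 2.0 * seg


def prolate_spheroid_volume(width: float, length: float) -> float:
    """V = pi/6 * W^2 * L — the prolate-spheroid cell-volume model."""
    return math.pi / 6.0 * width * width * length


# ---------------------------------------------------------------------------
# brightfield mosaic
# ---------------------------------------------------------------------------

def generate_brightfield_mosaic(config: SceneConfig,
                                max_tries: int = 200
                                ) -> tuple[np.ndarray, GroundTruthTable]:
    """Render a brightfield mosaic of dark fusiform cells plus distractors.

    Cells are placed at random positions and orientations without overlap
    (bounded retries; the truth table records only the cells actually
    placed).  Distractors are soft round debris blobs and high-contrast
    bubble rings, both of which the downstream shape filters are expected
    to reject.  Returns ``(image, truth)``; the image is float in [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_um
    n = config.n_cells

    side_um = max(40.0, math.sqrt(max(n, 1)) * 20.0)
    size = int(round(side_um / px))
    canvas = np.full((size, size), 0.85, dtype=float)

    if config.noise_level > 0:
        field_ = rng.normal(0.0, 1.0, canvas.shape)
        canvas += ndimage.gaussian_filter(field_, 40) * 1.5 * config.noise_level

    occupancy = np.zeros(canvas.shape, dtype=bool)
    margin_um = 1.0

    cell_rows = []
    Lmax = config.length_range_um[1]
    pad = int((Lmax / 2 + 2) / px) + 1

    def local_grid(cx, cy, half_px):
        i0 = max(0, int(cy) - half_px)
        i1 = min(size, int(cy) + half_px + 1)
        j0 = max(0, int(cx) - half_px)
        j1 = min(size, int(cx) + half_px + 1)
        sl = (slice(i0, i1), slice(j0, j1))
        ii, jj = np.mgrid[i0:i1, j0:j1]
        x = (jj + 0.5) * px
        y = (ii + 0.5) * px
        return sl, x, y

    cid = 0
    for _ in range(n):
        W = rng.uniform(*config.width_range_um)
        L = rng.uniform(*config.length_range_um)
        darkness = rng.uniform(0.38, 0.5)
        placed = False
        for _try in range(max_tries):
            cx = rng.uniform(pad, size - pad) * px
            cy = rng.uniform(pad, size - pad) * px
            theta = rng.uniform(0.0, math.pi)
            half_px = int((L / 2 + 2) / px) + 1
            sl, x, y = local_grid(cx / px, cy / px, half_px)
            u = (x - cx) * math.cos(theta) + (y - cy) * math.sin(theta)
            v = -(x - cx) * math.sin(theta) + (y - cy) * math.cos(theta)
            f = fusiform_halfwidth(u, W, L) - np.abs(v)
            inflated = f > -margin_um
            if (occupancy[sl] & inflated).any():
                continue
            coverage = np.clip(0.5 + f / px, 0.0, 1.0)
            canvas[sl] -= darkness * coverage
            occupancy[sl] |= inflated
            cell_rows.append(dict(cell_id=cid, x_um=cx, y_um=cy,
                                  theta_rad=theta, width_um=W, length_um=L,
                                  area_um2=fusiform_area(W, L),
                                  volume_um3=prolate_spheroid_volume(W, L),
                                  contrast=darkness))
            cid += 1
            placed = True
            break
        if not placed:
            # bounded-retry failure: report how many cells made it
            break

    distractor_rows = []
    if n > 0:
        n_debris = config.n_debris if config.n_debris is not None else max(1, n // 3)
        n_bubbles = config.n_bubbles if config.n_bubbles is not None else max(1, n // 4)
        for k in range(n_debris):
            a = rng.uniform(1.2, 3.0)
            b = a / rng.uniform(1.0, 1.8)
            darkness = rng.uniform(0.25, 0.45)
            for _try in range(max_tries):
                cx = rng.uniform(pad, size - pad) * px
                cy = rng.uniform(pad, size - pad) * px
                half_px = int((a + 1.5) / px) + 1
                sl, x, y = local_grid(cx / px, cy / px, half_px)
                rr = np.sqrt(((x - cx) / a) ** 2 + ((y - cy) / b) ** 2)
                f = (1.0 - rr) * min(a, b)
                if (occupancy[sl] & (f > -margin_um)).any():
                    continue
                coverage = np.clip(0.5 + f / (3 * px), 0.0, 1.0)
                canvas[sl] -= darkness * coverage
                occupancy[sl] |= f > -margin_um
                distractor_rows.append(dict(kind="debris", x_um=cx, y_um=cy,
                                            size_um=2 * a))
                break
        for k in range(n_bubbles):
            r0 = rng.uniform(2.5, 5.5)
            t = rng.uniform(0.35, 0.6)
            for _try in range(max_tries):
                cx = rng.uniform(pad, size - pad) * px
                cy = rng.uniform(pad, size - pad) * px
                half_px = int((r0 + t + 1.5) / px) + 1
                sl, x, y = local_grid(cx / px, cy / px, half_px)
                rr = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
                f_out = (r0 + t) - rr      # >0 inside outer circle
                f_ring = np.minimum(f_out, rr - (r0 - t))
                if (occupancy[sl] & (f_out > -margin_um)).any():
                    continue
                coverage = np.clip(0.5 + f_ring / px, 0.0, 1.0)
                canvas[sl] -= 0.55 * coverage
                # bright bubble interior
                interior = np.clip(0.5 + (r0 - t - rr) / px, 0.0, 1.0)
                canvas[sl] += 0.12 * interior
                occupancy[sl] |= f_out > -margin_um
                distractor_rows.append(dict(kind="bubble", x_um=cx, y_um=cy,
                                            size_um=2 * r0))
                break

    if config.noise_level > 0:
        canvas += rng.normal(0.0, 0.012 * config.noise_level, canvas.shape)
    np.clip(canvas, 0.0, 1.0, out=canvas)

    truth = GroundTruthTable(
        cells=pd.DataFrame(cell_rows, columns=["cell_id", "x_um", "y_um",
                                               "theta_rad", "width_um",
                                               "length_um", "area_um2",
                                               "volume_um3", "contrast"]),
        distractors=pd.DataFrame(distractor_rows,
                                 columns=["kind", "x_um", "y_um", "size_um"]),
    )
    return canvas, truth


def rasterize_cells(truth: GroundTruthTable, shape: tuple[int, int],
                    pixel_size_um: float) -> np.ndarray:
    """Instance label image of the true cell footprints (0 = background).

    Used for training annotations and for held-out evaluation of the
    pixel classifier against ground truth.
    """
    out = np.zeros(shape, dtype=np.int32)
    px = pixel_size_um
    for row in truth.cells.itertuples():
        half_px = int((row.length_um / 2 + 1) / px) + 1
        ci, cj = int(row.y_um / px), int(row.x_um / px)
        i0, i1 = max(0, ci - half_px), min(shape[0], ci + half_px + 1)
        j0, j1 = max(0, cj - half_px), min(shape[1], cj + half_px + 1)
        ii, jj = np.mgrid[i0:i1, j0:j1]
        x = (jj + 0.5) * px - row.x_um
        y = (ii + 0.5) * px - row.y_um
        u = x * math.cos(row.theta_rad) + y * math.sin(row.theta_rad)
        v = -x * math.sin(row.theta_rad) + y * math.cos(row.theta_rad)
        inside = (fusiform_halfwidth(u, row.width_um, row.length_um)
                  - np.abs(v)) > 0
        out[i0:i1, j0:j1][inside] = row.cell_id + 1
    return out


# ---------------------------------------------------------------------------
# LD volume strategies
# ---------------------------------------------------------------------------

def _sample_ld_volumes(strategy: str, total: float, rng: np.random.Generator
                       ) -> np.ndarray:
    """Draw per-LD volumes implementing one of the accumulation strategies.

    ``two_large_dominant`` concentrates >= 85 % of the total in two LDs on
    top of a basal set; ``many_medium`` spreads the total over >= 5
    comparable LDs (two largest <= 75 %); ``basal_only`` and
    ``fragmented_distant`` draw every volume from the basal range
    [0.005, 0.7] um^3.
    """
    if total <= 0:
        raise ValueError("total LD volume must be positive")
    if strategy == "two_large_dominant":
        big_share = rng.uniform(0.88, 0.93)
        split = rng.uniform(0.45, 0.55)
        big = np.array([big_share * total * split,
                        big_share * total * (1 - split)])
        rest = (1 - big_share) * total
        n_b = max(2, int(math.ceil(rest / (0.9 * BASAL_LD_RANGE[1]))))
        n_b = max(n_b, int(rng.integers(2, 5)))
        w = rng.dirichlet(np.full(n_b, 3.0))
        basal = np.clip(rest * w, BASAL_LD_RANGE[0], BASAL_LD_RANGE[1])
        return np.concatenate([big, basal])
    if strategy == "many_medium":
        n = int(rng.integers(5, 9))
        for _ in range(100):
            w = rng.gamma(8.0, 1.0, n)
            w = w / w.sum()
            if np.sort(w)[-2:].sum() <= 0.72:
                break
        return total * w
    if strategy in ("basal_only", "fragmented_distant"):
        lo, hi = BASAL_LD_RANGE
        n_min = 3 if strategy == "basal_only" else 10
        n_max = 7 if strategy == "basal_only" else 18
        n = int(rng.integers(n_min, n_max + 1))
        raw = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
        vols = raw * (total / raw.sum())
        # rescale must stay inside the basal range
        for _ in range(50):
            over = vols > hi
            if not over.any():
                break
            excess = (vols[over] - hi).sum()
            vols[over] = hi
            under = ~over
            vols[under] += excess * vols[under] / vols[under].sum()
        vols = np.clip(vols, lo, hi)
        return vols
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# confocal stack
# ---------------------------------------------------------------------------

CHL_AMPLITUDE = 45.0
LD_AMPLITUDE = 70.0
BACKGROUND_RATE = 1.5


def generate_confocal_stack(config: SceneConfig, max_tries: int = 400
                            ) -> tuple[np.ndarray, np.ndarray, GroundTruthTable]:
    """Render a two-channel confocal z-stack with known ground truth.

    Returns ``(stack, mask, truth)`` where ``stack`` has shape
    ``(2, nz, ny, nx)`` — channel 0 chlorophyll autofluorescence
    (central bilobed thylakoid region), channel 1 BODIPY (LD spheres) —
    and ``mask`` is an integer cell mask (0 background, i = cell i+1 of
    the truth table).  Cells lie with their long axis along x, stacked in
    y lanes.  The optical blur is an isotropic-in-xy Gaussian of
    ``psf_sigma_um``; with ``noise_level > 0`` intensities are Poisson
    photon counts over a uniform background.

    Raises :class:`PlacementError` when the requested LD volumes cannot be
    placed inside the cell envelope.
    """
    if config.n_cells < 1:
        raise ValueError("confocal scenes need n_cells >= 1")
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_um
    pz = config.z_step_um
    n = config.n_cells

    widths = rng.uniform(*config.width_range_um, n)
    lengths = rng.uniform(*config.length_range_um, n)

    margin = 1.5
    Lmax = lengths.max()
    Wmax = widths.max()
    nx = int(round((Lmax + 2 * margin) / px))
    lane_um = Wmax + 2 * margin
    ny = int(round(lane_um * n / px))
    nz = int(round((Wmax + 2 * margin) / pz))

    chl = np.zeros((nz, ny, nx), dtype=float)
    bod = np.zeros((nz, ny, nx), dtype=float)
    mask = np.zeros((nz, ny, nx), dtype=np.int32)

    zz = (np.arange(nz)[:, None, None] + 0.5) * pz
    yy = (np.arange(ny)[None, :, None] + 0.5) * px
    xx = (np.arange(nx)[None, None, :] + 0.5) * px

    cell_rows, ld_rows, plastid_rows = [], [], []

    for i in range(n):
        W, L = widths[i], lengths[i]
        cx = nx * px / 2.0
        cy = (i + 0.5) * lane_um
        cz = nz * pz / 2.0

        u = xx - cx
        v = yy - cy
        w = zz - cz
        r_env = fusiform_halfwidth(u, W, L)
        rad = np.sqrt(v * v + w * w)
        cell_vox = rad <= r_env
        mask[cell_vox] = i + 1

        # --- bilobed thylakoid region along the long axis -------------
        a_u = 0.18 * L
        lobe_offset = 0.12 * L
        # choose the lobe radius to hit the configured thylakoid volume;
        # the ~10 % lobe overlap makes the union ~1.8 x one lobe
        v_target = config.thylakoid_volume_um3
        a_r = math.sqrt(max(v_target, 1e-3) / (1.8 * 4.0 / 3.0 * math.pi * a_u))
        a_r = min(a_r, 0.45 * W)
        lobes = np.zeros_like(cell_vox)
        for s in (-1.0, 1.0):
            du = (u - s * lobe_offset) / a_u
            lobes |= (du * du + (v / a_r) ** 2 + (w / a_r) ** 2) <= 1.0
        lobes &= cell_vox
        chl[lobes] = CHL_AMPLITUDE
        p_vol = lobes.sum() * px * px * pz
        # symmetric construction: the plastid barycenter is the cell center
        plastid_rows.append(dict(cell_id=i, bx_um=cx, by_um=cy, bz_um=cz,
                                 volume_um3=p_vol))

        # --- lipid droplets -------------------------------------------
        total = config.ld_total_volume_um3
        if total is None:
            total = {"basal_only": 0.45, "two_large_dominant": 8.0,
                     "many_medium": 6.0, "fragmented_distant": 3.0}[config.ld_strategy]
        vols = _sample_ld_volumes(config.ld_strategy, total, rng)
        radii = (3.0 * vols / (4.0 * math.pi)) ** (1.0 / 3.0)
        placed: list[tuple[float, float, float, float]] = []
        for v_ld, r_ld in zip(vols, radii):
            ok = False
            for _try in range(max_tries):
                if config.ld_strategy == "fragmented_distant":
                    # 75 % of LDs beyond the 5 um close/distant threshold
                    if rng.uniform() < 0.75:
                        lo_u = DISTANT_THRESHOLD_UM + r_ld + 0.3
                        hi_u = L / 2.0 - r_ld - 0.5
                        if hi_u <= lo_u:
                            continue
                        au = rng.uniform(lo_u, hi_u) * rng.choice([-1.0, 1.0])
                    else:
                        au = rng.uniform(-4.0, 4.0)
                else:
                    umax = min(4.5, L / 2.0 - r_ld - 0.5)
                    au = rng.uniform(-umax, umax)
                envelope = fusiform_halfwidth(au, W, L) - r_ld - 0.15
                if envelope <= 0:
                    continue
                phi = rng.uniform(0.0, 2.0 * math.pi)
                s = math.sqrt(rng.uniform()) * envelope
                av, aw = s * math.cos(phi), s * math.sin(phi)
                c_new = (cx + au, cy + av, cz + aw)
                if any((c_new[0] - c[0]) ** 2 + (c_new[1] - c[1]) ** 2
                       + (c_new[2] - c[2]) ** 2 < (r_ld + c[3] + 0.1) ** 2
                       for c in placed):
                    continue
                placed.append((*c_new, r_ld))
                ld_rows.append(dict(cell_id=i, ld_id=len(ld_rows),
                                    volume_um3=v_ld, radius_um=r_ld,
                                    x_um=c_new[0], y_um=c_new[1],
                                    z_um=c_new[2]))
                ok = True
                break
            if not ok:
                raise PlacementError(
                    f"could not place LD of {v_ld:.3f} um^3 inside the cell "
                    f"envelope (W={W:.2f}, L={L:.2f}); total LD volume "
                    f"{total:.2f} um^3 exceeds envelope capacity")

        for (lx, ly, lz, r_ld) in placed:
            sphere = ((xx - lx) ** 2 + (v + cy - ly) ** 2
                      + (w + cz - lz) ** 2) <= r_ld * r_ld
            bod[sphere] = LD_AMPLITUDE

        cell_rows.append(dict(cell_id=i, width_um=W, length_um=L,
                              volume_um3=prolate_spheroid_volume(W, L),
                              cx_um=cx, cy_um=cy, cz_um=cz))

    if config.psf_sigma_um > 0:
        sig = [config.psf_sigma_um * 1.2 / pz,
               config.psf_sigma_um / px,
               config.psf_sigma_um / px]
        chl = ndimage.gaussian_filter(chl, sig)
        bod = ndimage.gaussian_filter(bod, sig)

    stack = np.stack([chl, bod])
    if config.noise_level > 0:
        stack = rng.poisson(stack + BACKGROUND_RATE * config.noise_level
                            ).astype(float)

    truth = GroundTruthTable(cells=pd.DataFrame(cell_rows),
                             lds=pd.DataFrame(ld_rows),
                             plastids=pd.DataFrame(plastid_rows))
    return stack, mask, truth


# ---------------------------------------------------------------------------
# absorbance spectra
# ---------------------------------------------------------------------------

# Red-band absorbances of a 1 ug/mL solution at the trichromatic anchor
# wavelengths, chosen so that the 90 %-acetone equations invert exactly to
# unit concentration (see ldscope.pigments).
_UNIT_A_ANCHORS = {664.0: 0.085577, 647.0: 0.008806, 630.0: 0.008558}
_UNIT_C_ANCHORS = {664.0: 0.002282, 647.0: 0.015190, 630.0: 0.045648}


def _gauss(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def generate_absorbance_spectrum(chl_a_conc: float, chl_c_conc: float,
                                 noise: float = 0.0, seed: int = 0,
                                 turbidity: float = 0.0,
                                 extract_volume_ml: float = 1.0,
                                 path_cm: float = 1.0) -> Spectrum:
    """Synthesize a 400-800 nm absorbance spectrum of a pigment extract.

    The spectrum is a sum of Gaussian absorption bands whose heights at
    the 664/647/630 nm anchors are exactly consistent, through the
    trichromatic 90 %-acetone equations, with the requested chlorophyll a
    and c concentrations (ug/mL), so ``pigments.quantify`` round-trips.
    Soret-region bands (430/450 nm) are cosmetic.  ``turbidity`` adds a
    flat offset removed by the 750 nm correction; ``noise`` is the SD of
    additive absorbance noise.
    """
    if chl_a_conc < 0 or chl_c_conc < 0:
        raise ValueError("pigment concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    wl = np.arange(400.0, 801.0, 1.0)
    absorb = np.zeros_like(wl)
    for mu, h in _UNIT_A_ANCHORS.items():
        absorb += chl_a_conc * h * _gauss(wl, mu, 4.0)
    absorb += chl_a_conc * 3.0 * _UNIT_A_ANCHORS[664.0] * _gauss(wl, 430.0, 12.0)
    for mu, h in _UNIT_C_ANCHORS.items():
        absorb += chl_c_conc * h * _gauss(wl, mu, 4.0)
    absorb += chl_c_conc * 3.0 * _UNIT_C_ANCHORS[630.0] * _gauss(wl, 450.0, 12.0)
    absorb += turbidity
    if noise > 0:
        absorb = absorb + rng.normal(0.0, noise, wl.shape)
    return Spectrum(wavelength_nm=wl, absorbance=absorb,
                    extract_volume_ml=extract_volume_ml, path_cm=path_cm)


# ---------------------------------------------------------------------------
# growth curve
# ---------------------------------------------------------------------------

def generate_growth_curve(division_rate_per_day: float = 0.73,
                          n0_per_ml: float = 1e5, days: int = 7,
                          noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Exponential cell-density series (N replete preculture emulation).

    density(t) = n0 * 2^(r t) with r in divisions/day, optionally with
    lognormal counting noise.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(days + 1, dtype=float)
    dens = n0_per_ml * 2.0 ** (division_rate_per_day * t)
    if noise > 0:
        dens = dens * np.exp(rng.normal(0.0, noise, dens.shape))
    return pd.DataFrame({"day": t, "density_per_ml": dens})


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

def study_design() -> pd.DataFrame:
    """The simulated N-starvation/resupply time course.

    One row per ecotype x timepoint with the LD strategy and the target
    group-mean total LD and thylakoid volumes used by the pipeline's
    simulation stage.  Pt1 spreads lipids over many medium LDs, Pt4
    concentrates them in two dominant LDs, and 24 h after N resupply both
    ecotypes show many small LDs far from the plastid.
    """
    rows = [
        ("Pt1", "D0", "basal_only", 0.32, 12.0),
        ("Pt1", "D3", "many_medium", 2.36, 8.0),
        ("Pt1", "D7", "many_medium", 3.12, 5.0),
        ("Pt1", "D11", "many_medium", 6.15, 2.2),
        ("Pt1", "h24", "fragmented_distant", 4.15, 6.0),
        ("Pt1", "h72", "basal_only", 0.39, 11.0),
        ("Pt4", "D0", "basal_only", 0.56, 17.6),
        ("Pt4", "D3", "two_large_dominant", 5.41, 9.0),
        ("Pt4", "D7", "two_large_dominant", 5.39, 6.0),
        ("Pt4", "D11", "two_large_dominant", 8.72, 2.8),
        ("Pt4", "h24", "fragmented_distant", 2.03, 8.0),
        ("Pt4", "h72", "basal_only", 0.61, 16.0),
    ]
    return pd.DataFrame(rows, columns=["ecotype", "timepoint", "ld_strategy",
                                       "ld_total_volume_um3",
                                       "thylakoid_volume_um3"])
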