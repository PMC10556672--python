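import numpy as np
import pytest

from ldscope import synthetic
from ldscope.pipeline import _train_on_mosaic


@pytest.fixture(scope="session")
def small_mosaic():
    """One 12-cell Pt1 mosaic with distractors and its ground truth."""
    cfg = synthetic.SceneConfig(ecotype_label="Pt1", n_cells=12,
                                pixel_size_um=0.1, seed=3)
    img, truth = synthetic.generate_brightfield_mosaic(cfg)
    return cfg, img, truth


@pytest.fixture(scope="session")
def trained_classifier(small_mosaic):
    cfg, img, truth = small_mosaic
    return _train_on_mosaic(img, truth, cfg.pixel_size_um, seed=0)


@pytest.fixture(scope="session")
def small_stack():
    """A single-cell two-channel confocal stack (Pt4, two dominant LDs)."""
    cfg = synthetic.SceneConfig(ecotype_label="Pt4", n_cells=1,
                                ld_strategy="two_large_dominant",
                                ld_total_volume_um3=8.0, pixel_size_um=0.072,
                                seed=21)
    stack, mask, truth = synthetic.generate_confocal_stack(cfg)
    return cfg, stack, mask, truth


def make_sphere_stack(radii_um, centers_um, shape_um=(6.0, 6.0, 6.0),
                      voxel=(0.072, 0.072, 0.1), amplitude=50.0):
    """Noise-free stack of analytic spheres (helper for 3D fixtures)."""
    vx, vy, vz = voxel
    nz = int(round(shape_um[2] / vz))
    ny = int(round(shape_um[1] / vy))
    nx = int(round(shape_um[0] / vx))
    zz = (np.arange(nz)[:, None, None] + 0.5) * vz
    yy = (np.arange(ny)[None, :, None] + 0.5) * vy
    xx = (np.arange(nx)[None, None, :] + 0.5) * vx
    out = np.zeros((nz, ny, nx))
    for r, (cx, cy, cz) in zip(radii_um, centers_um):
        sphere = ((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2) <= r * r
        out[sphere] = amplitude
    return out
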