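import numpy as np
import pytest

from airyqpi.beam_propagation import (
    CM,
    GaussianCubicSource,
    apply_thin_lens,
    locate_waist,
    make_gaussian_beam_field,
    make_source_field,
    scan_focal_region,
)
from airyqpi.image_formation import DetectionParams, detection_psf, system_psf


@pytest.fixture(scope="session")
def airy_small():
    """Scaled-down cubic-phase beam focused by a single f = 0.5 cm lens.

    Same physics as the full illumination train (Airy focal scale
    x0 = alpha^(1/3) f / k ~ 0.6 um) at a fraction of the grid cost; the map
    is centred on the located beam waist.
    """
    source = GaussianCubicSource(waist_mm=3.0, cubic_scaling_mm3=3.7)
    field = make_source_field(source, 2**17, 0.15, 0.488)
    field = apply_thin_lens(field, 0.5)
    coarse = scan_focal_region(field, z_window=400.0, axial_pitch=4.0,
                               z_center=0.5 * CM, transverse_halfwidth=60.0)
    waist_z = locate_waist(coarse)
    fine = scan_focal_region(field, z_window=120.0, axial_pitch=0.5,
                             z_center=waist_z, transverse_halfwidth=40.0)
    return {"field": field, "waist_z": waist_z, "map": fine, "source": source}


@pytest.fixture(scope="session")
def gauss_focus():
    """Converging Gaussian beam with a w0 = 1.2 um waist, mapped over
    +/- ~3 Rayleigh ranges around the focus."""
    wavelength = 0.488
    w_focus = 1.2
    z_r = np.pi * w_focus**2 / wavelength
    field = make_gaussian_beam_field(w_focus, wavelength, -3.2 * z_r, 2**12, 0.05)
    beam_map = scan_focal_region(field, z_window=6.2 * z_r, axial_pitch=0.25,
                                 z_center=3.2 * z_r, transverse_halfwidth=15.0)
    return {"map": beam_map, "w_focus": w_focus, "z_r": z_r, "focus_z": 3.2 * z_r}


@pytest.fixture(scope="session")
def det_psf():
    """NA 0.7 / 525 nm detection PSF at isotropic 0.1 um pitch."""
    return detection_psf(DetectionParams(), (0.1, 0.1, 0.1), (2.0, 2.0, 8.0))


@pytest.fixture(scope="session")
def cell_psf():
    """Light-sheet system PSF used for cell-scene rendering: NA 0.7 detection
    times a w0 = 1.2 um Gaussian sheet, at (0.12, 0.12, 0.24) um pitch."""
    det = detection_psf(DetectionParams(), (0.12, 0.12, 0.24), (2.0, 2.0, 8.0))
    nz = det.voxels.shape[0]
    z = (np.arange(nz) - nz // 2) * det.pitch.z
    sheet = np.exp(-2.0 * z**2 / 1.2**2)
    return system_psf(sheet, det)
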