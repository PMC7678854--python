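"""Light-sheet image formation: detection PSF, sheet profile, stack rendering
and FWHM metrology.

The system PSF of a light-sheet microscope is the detection-objective PSF
multiplied along the detection axis by the illumination-sheet intensity
profile (scanning averages the beam along the in-plane scan direction).  The
detection PSF uses the scalar Born-Wolf pupil integral, adequate at NA 0.7 for
synthetic-resolution work.  Voxel arrays follow the (z, y, x) axis convention;
pitches are quoted as (x, y, z) in um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import j0


class VoxelPitch(NamedTuple):
    x: float
    y: float
    z: float


@dataclass(frozen=True)
class DetectionParams:
    """Detection objective: NA 0.7 and 0.525 um emission (the centre of a
    525/50 bandpass) by default."""

    numerical_aperture: float = 0.7
    emission_wavelength: float = 0.525
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        if self.emission_wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.numerical_aperture < self.medium_index:
            raise ValueError("require 0 < NA < medium index")

    @property
    def lateral_fwhm_estimate(self) -> float:
        return 0.514 * self.emission_wavelength / self.numerical_aperture

    @property
    def axial_fwhm_estimate(self) -> float:
        return 1.77 * self.medium_index * self.emission_wavelength / self.numerical_aperture**2


@dataclass(frozen=True)
class ImageStack3D:
    """Non-negative intensity voxels with anisotropic pitch.

    ``voxels[z, y, x]``; ``pitch`` is (x, y, z) in um.  Physical coordinates
    refer to voxel centres, origin at voxel (0, 0, 0).
    """

    voxels: np.ndarray
    pitch: VoxelPitch

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels, dtype=np.float64)
        object.__setattr__(self, "voxels", arr)
        object.__setattr__(self, "pitch", VoxelPitch(*self.pitch))
        if arr.ndim != 3:
            raise ValueError("voxels must be 3D (z, y, x)")
        if np.any(arr < 0):
            raise ValueError("voxels must be non-negative")
        if any(p <= 0 for p in self.pitch):
            raise ValueError("pitches must be positive")

    @property
    def shape(self):
        return self.voxels.shape

    def coords(self):
        """(z, y, x) coordinate vectors in um."""
        nz, ny, nx = self.voxels.shape
        return (
            np.arange(nz) * self.pitch.z,
            np.arange(ny) * self.pitch.y,
            np.arange(nx) * self.pitch.x,
        )

    def total(self) -> float:
        return float(self.voxels.sum())


@dataclass(frozen=True)
class Bead:
    center: tuple  # (x, y, z) um
    diameter: float
    brightness: float  # expected photons integrated over the bead

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("bead diameter must be positive")
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")


@dataclass(frozen=True)
class BeadPhantom:
    beads: tuple
    background: float = 0.0  # expected photons per voxel

    def __post_init__(self) -> None:
        object.__setattr__(self, "beads", tuple(self.beads))
        if self.background < 0:
            raise ValueError("background must be >= 0")


# ---------------------------------------------------------------------------
# PSF construction
# ---------------------------------------------------------------------------


def detection_psf(
    params: DetectionParams,
    pitch: Sequence[float],
    extent: Sequence[float],
    pupil_samples: int = 400,
) -> ImageStack3D:
    """Scalar widefield detection PSF, normalised to unit sum.

    Born-Wolf pupil integral
    ``h(r, z) = int_0^1 J0(k NA r rho) exp(-i k z NA^2 rho^2 / (2 n)) rho drho``
    evaluated on a radial table per z plane and interpolated onto the voxel
    grid.  ``extent`` (x, y, z in um) must cover at least three lateral and
    axial FWHMs so the normalisation is meaningful.
    """
    pitch = VoxelPitch(*pitch)
    ex, ey, ez = extent
    if ex < 3 * params.lateral_fwhm_estimate or ey < 3 * params.lateral_fwhm_estimate:
        raise ValueError("lateral extent must cover >= 3 lateral FWHM")
    if ez < 3 * params.axial_fwhm_estimate:
        raise ValueError("axial extent must cover >= 3 axial FWHM")

    k = 2.0 * np.pi * params.medium_index / params.emission_wavelength
    na = params.numerical_aperture / params.medium_index  # angular aperture in medium

    def axis(extent_1d: float, p: float) -> np.ndarray:
        n = int(np.floor(extent_1d / (2 * p))) * 2 + 1  # odd count, centred
        return (np.arange(n) - n // 2) * p

    xs, ys, zs = axis(ex, pitch.x), axis(ey, pitch.y), axis(ez, pitch.z)
    rr = np.hypot(xs[None, :], ys[:, None])
    r_table = np.linspace(0.0, rr.max() * 1.0001, 600)

    rho = np.linspace(0.0, 1.0, pupil_samples)
    bessel = j0(k * na * np.outer(r_table, rho))  # (2 pi NA / lambda) * r * rho

    out = np.empty((zs.size, ys.size, xs.size))
    for iz, z in enumerate(zs):
        defocus = np.exp(-1j * k * z * (na**2) * rho**2 / 2.0)
        integrand = bessel * (defocus * rho)[None, :]
        h = np.trapezoid(integrand, rho, axis=1)
        inten = np.abs(h) ** 2
        out[iz] = np.interp(rr, r_table, inten)
    out /= out.sum()
    return ImageStack3D(out, pitch)


@dataclass(frozen=True)
class SheetProfile:
    """Illumination-sheet intensity versus the detection-axis coordinate at a
    fixed propagation distance."""

    coords: np.ndarray  # um along the detection axis
    intensity: np.ndarray

    def sample(self, n: int, pitch: float, center: float | None = None) -> np.ndarray:
        """Resample at ``n`` points spaced ``pitch``, centred on the profile
        peak by default (linear interpolation, zero outside)."""
        if center is None:
            center = float(self.coords[np.argmax(self.intensity)])
        z = center + (np.arange(n) - n // 2) * pitch
        return np.interp(z, self.coords, self.intensity, left=0.0, right=0.0)


def sheet_axial_profile(beam_map, x_position: float) -> SheetProfile:
    """Extract the sheet profile at propagation distance ``x_position``.

    In the sheet geometry the simulated transverse axis lies along the
    detection axis; uniform scanning averages the beam along the remaining
    in-plane direction, so a single transverse cut is the sheet profile.
    """
    zs = beam_map.z
    if not zs.min() <= x_position <= zs.max():
        raise ValueError(
            f"x_position {x_position} outside the scanned corridor [{zs.min()}, {zs.max()}]"
        )
    j = int(np.argmin(np.abs(zs - x_position)))
    return SheetProfile(coords=beam_map.x.copy(), intensity=beam_map.intensity[j].copy())


def system_psf(illumination_profile: np.ndarray, det: ImageStack3D) -> ImageStack3D:
    """Light-sheet system PSF: detection PSF times the sheet profile along z,
    renormalised to unit sum."""
    profile = np.asarray(illumination_profile, dtype=np.float64)
    if profile.ndim != 1 or profile.size != det.voxels.shape[0]:
        raise ValueError(
            f"profile length {profile.size} does not match the PSF's "
            f"{det.voxels.shape[0]} z planes"
        )
    if np.any(profile < 0):
        raise ValueError("illumination profile must be non-negative")
    out = det.voxels * profile[:, None, None]
    s = out.sum()
    if s <= 0:
        raise ValueError("profile annihilates the PSF")
    return ImageStack3D(out / s, det.pitch)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _rasterize_bead(bead: Bead, shape, pitch: VoxelPitch, supersample: int = 4) -> np.ndarray:
    """Fractional sphere occupancy on the voxel grid, normalised to unit sum
    (a bead acts as a unit point/volume source scaled by its brightness).
    Beads at or below half a voxel are deposited as trilinear deltas."""
    nz, ny, nx = shape
    cx, cy, cz = bead.center
    r = bead.diameter / 2.0
    out = np.zeros(shape)

    if bead.diameter <= 0.5 * min(pitch):
        # delta: trilinear split over the 8 neighbouring voxels
        fx, fy, fz = cx / pitch.x, cy / pitch.y, cz / pitch.z
        ix, iy, iz = int(np.floor(fx)), int(np.floor(fy)), int(np.floor(fz))
        wx, wy, wz = fx - ix, fy - iy, fz - iz
        for dz, vz in ((0, 1 - wz), (1, wz)):
            for dy, vy in ((0, 1 - wy), (1, wy)):
                for dx, vx in ((0, 1 - wx), (1, wx)):
                    z, y, x = iz + dz, iy + dy, ix + dx
                    if 0 <= z < nz and 0 <= y < ny and 0 <= x < nx:
                        out[z, y, x] += vz * vy * vx
        s = out.sum()
        if s > 0:
            out /= s
        return out

    # volume sampling at supersampled resolution within the bounding box
    def rng(c, p, n):
        lo = max(0, int(np.floor((c - r) / p)))
        hi = min(n - 1, int(np.ceil((c + r) / p)))
        return lo, hi

    zlo, zhi = rng(cz, pitch.z, nz)
    ylo, yhi = rng(cy, pitch.y, ny)
    xlo, xhi = rng(cx, pitch.x, nx)
    if zhi < zlo or yhi < ylo or xhi < xlo:
        return out
    ss = supersample
    off = (np.arange(ss) + 0.5) / ss - 0.5
    zc = (np.arange(zlo, zhi + 1)[:, None] + off[None, :]).ravel() * pitch.z
    yc = (np.arange(ylo, yhi + 1)[:, None] + off[None, :]).ravel() * pitch.y
    xc = (np.arange(xlo, xhi + 1)[:, None] + off[None, :]).ravel() * pitch.x
    inside = (
        ((zc - cz)[:, None, None] / r) ** 2
        + ((yc - cy)[None, :, None] / r) ** 2
        + ((xc - cx)[None, None, :] / r) ** 2
    ) <= 1.0
    frac = inside.reshape(zhi - zlo + 1, ss, yhi - ylo + 1, ss, xhi - xlo + 1, ss)
    frac = frac.mean(axis=(1, 3, 5))
    s = frac.sum()
    if s > 0:
        out[zlo : zhi + 1, ylo : yhi + 1, xlo : xhi + 1] = frac / s
    return out


def render_stack(
    phantom: BeadPhantom,
    psf: ImageStack3D,
    out_pitch: Sequence[float],
    shape: Sequence[int],
    noise_seed: int | None = None,
) -> ImageStack3D:
    """Render a noisy (or noiseless) bead stack.

    Expected counts are ``sum_b brightness_b * (raster_b (*) PSF) +
    background``; Poisson noise is applied when ``noise_seed`` is given.
    Beads outside the volume raise a warning and contribute only their
    in-volume part.
    """
    out_pitch = VoxelPitch(*out_pitch)
    if not np.allclose(out_pitch, psf.pitch, rtol=1e-6):
        raise ValueError(f"PSF pitch {psf.pitch} must equal output pitch {out_pitch}")
    shape = tuple(int(s) for s in shape)
    nz, ny, nx = shape
    lim = (nx * out_pitch.x, ny * out_pitch.y, nz * out_pitch.z)

    truth = np.zeros(shape)
    for bead in phantom.beads:
        if not all(0 <= c <= l for c, l in zip(bead.center, lim)):
            warnings.warn(f"bead at {bead.center} lies outside the volume; clipped",
                          stacklevel=2)
        truth += bead.brightness * _rasterize_bead(bead, shape, out_pitch)

    expected = fftconvolve(truth, psf.voxels, mode="same") if phantom.beads else truth
    expected = np.clip(expected, 0.0, None) + phantom.background
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        expected = rng.poisson(expected).astype(np.float64)
    return ImageStack3D(expected, out_pitch)


# ---------------------------------------------------------------------------
# FWHM metrology
# ---------------------------------------------------------------------------

_AXIS_INDEX = {"x": 2, "y": 1, "z": 0}


def _border_median(voxels: np.ndarray) -> float:
    faces = [voxels[0], voxels[-1], voxels[:, 0], voxels[:, -1],
             voxels[:, :, 0], voxels[:, :, -1]]
    return float(np.median(np.concatenate([f.ravel() for f in faces])))


def measure_fwhm(stack: ImageStack3D, seed_point, axis: str) -> float:
    """FWHM (um) of the background-subtracted profile through the local
    intensity maximum near ``seed_point`` (x, y, z in um) along ``axis``.

    The peak is refined within 1 um of the seed point; the background is the
    median of the stack's border voxels; half-maximum crossings are linearly
    interpolated.  Raises if no local maximum exists near the seed or if the
    profile never drops below half maximum inside the stack (truncated bead).
    """
    if axis not in _AXIS_INDEX:
        raise ValueError("axis must be one of 'x', 'y', 'z'")
    v = stack.voxels
    px, py, pz = stack.pitch
    sx, sy, sz = seed_point
    ii = np.array([sz / pz, sy / py, sx / px])  # (z, y, x) fractional index
    half = np.array([1.0 / pz, 1.0 / py, 1.0 / px])  # 1 um search radius
    lo = np.maximum(0, np.floor(ii - half)).astype(int)
    hi = np.minimum(np.array(v.shape) - 1, np.ceil(ii + half)).astype(int)
    sub = v[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    if sub.size == 0:
        raise ValueError("seed point outside the stack")
    peak_idx = np.array(np.unravel_index(np.argmax(sub), sub.shape)) + lo

    background = _border_median(v)
    peak_val = v[tuple(peak_idx)] - background
    if peak_val <= 0 or np.all(v == v.flat[0]):
        raise ValueError("no local maximum above background near the seed point")

    ax = _AXIS_INDEX[axis]
    index = list(peak_idx)
    index[ax] = slice(None)
    profile = v[tuple(index)] - background
    pitch = (stack.pitch.z, stack.pitch.y, stack.pitch.x)[ax]
    c = peak_idx[ax]
    thr = profile[c] / 2.0

    def cross(direction: int) -> float:
        i = c
        while 0 <= i + direction < profile.size and profile[i + direction] >= thr:
            i += direction
        if not 0 <= i + direction < profile.size:
            raise ValueError("profile does not drop below half maximum inside "
                             "the stack (truncated object)")
        a, b = profile[i], profile[i + direction]
        return (i + direction * (a - thr) / (a - b)) * pitch

    return float(cross(+1) - cross(-1))


def measure_bead_fwhms(stack: ImageStack3D, phantom: BeadPhantom, axis: str):
    """FWHM for every bead of a phantom rendered into ``stack`` (helper for
    the n-bead resolution protocol).  Returns an array, one value per bead."""
    return np.array([measure_fwhm(stack, b.center, axis) for b in phantom.beads])
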