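"""Ground-truthed synthetic specimens for end-to-end testing.

The generator emulates the study system: budding-yeast-like cells modelled as
prolate ellipsoids (major axis drawn around 5.3 um), each optionally carrying
one or two spherical lipid droplets (LDs) of higher optical phase, and a
GFP-tagged reporter that is either *localized* (flux concentrated on a
spherical cap of the LD surface covering a known fraction) or *diffusive*
(uniform in the cell volume).  Every scene stores its ground truth, and all
randomness is fixed by the seed.

A simplified four-bucket phase-shifting interferometry round trip
(:func:`qpi_forward_and_reconstruct`) produces and inverts interferogram
frames so the phase-retrieval side of the pipeline is testable as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .image_formation import Bead, BeadPhantom, ImageStack3D, VoxelPitch
from .qpi_analysis import PhaseImage

Mode = Literal["localized", "diffusive"]


@dataclass(frozen=True)
class SceneParams:
    """Generator defaults.

    Cell geometry follows the study organism (ellipsoids, major axis
    5.3 +/- 0.4 um); phase scale is calibrated so a typical cell peaks at
    ~1.5 rad, and LD phase excess pushes droplet pixels well above the
    cytosol.  Expression and LD-size distributions are free parameters.
    """

    field_size_um: tuple = (40.0, 40.0)
    z_extent_um: float = 10.0
    margin_um: float = 4.0  # keep cells clear of the field border
    major_axis_mean_um: float = 5.3
    major_axis_sd_um: float = 0.4
    aspect_ratio_range: tuple = (0.6, 0.85)
    cytosol_phase_per_um: float = 0.4  # rad of phase per um of chord length
    ld_count_range: tuple = (0, 2)
    ld_diameter_range_um: tuple = (1.2, 2.2)
    ld_phase_excess_rad: float = 1.2  # peak extra phase at the LD centre
    expression_mean: float = 500.0  # mean reporter density, counts per voxel
    expression_sd: float = 150.0
    localized_probability: float = 0.5
    coverage_fraction_range: tuple = (0.15, 0.9)
    shell_thickness_um: float = 0.15
    max_placement_attempts: int = 10_000


@dataclass(frozen=True)
class LipidDroplet:
    offset_um: tuple  # (dx, dy, dz) from the cell centre
    diameter_um: float
    phase_excess_rad: float


@dataclass(frozen=True)
class CellModel:
    """One ellipsoidal cell with its ground truth."""

    center_um: tuple  # (x, y, z)
    major_axis_um: float
    aspect_ratio: float
    orientation_rad: float
    lds: tuple
    expression: float
    mode: Mode
    coverage_fraction: float  # truth for localized cells; nan for diffusive
    cap_axis: tuple  # unit vector of the fluorescent cap pole

    @property
    def semi_axes_um(self) -> tuple:
        a = self.major_axis_um / 2.0
        b = self.aspect_ratio * a
        return (a, b, b)  # prolate: in-plane major, in-plane minor, vertical

    @property
    def volume_um3(self) -> float:
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * math.pi * a * b * c

    def phase_area_integral(self) -> float:
        """Analytic integral of the projected phase over the plane (rad um^2):
        cytosol chord integral equals the ellipsoid volume, each LD adds
        ``phase_excess * (sphere volume) / diameter``."""
        total = self.volume_um3  # times cytosol_phase_per_um applied by caller
        return total

    def ld_phase_area_integral(self) -> float:
        return sum(
            ld.phase_excess_rad * (math.pi * ld.diameter_um**3 / 6.0) / ld.diameter_um
            for ld in self.lds
        )


@dataclass(frozen=True)
class CellScene:
    cells: tuple
    params: SceneParams
    seed: int

    def analytic_dry_phase_integral(self) -> float:
        """Total integral of phase over area (rad um^2), from geometry alone."""
        p = self.params
        return sum(
            p.cytosol_phase_per_um * c.phase_area_integral() + c.ld_phase_area_integral()
            for c in self.cells
        )


def _sample_ld(rng: np.random.Generator, params: SceneParams, semi: tuple) -> LipidDroplet:
    d = rng.uniform(*params.ld_diameter_range_um)
    a, b, c = semi
    r = d / 2.0
    # place the LD centre well inside the shrunken ellipsoid so the droplet
    # stays in the cell and over a thick cytosol chord
    scale = np.array([max(a - r, 0.0), max(b - r, 0.0), max(c - r, 0.0)]) * 0.6
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) <= 1.0:
            break
    return LipidDroplet(tuple(u * scale), d, params.ld_phase_excess_rad)


def generate_cell_scene(n_cells: int, params: SceneParams | None = None,
                        seed: int = 0) -> CellScene:
    """Place ``n_cells`` non-overlapping cells by rejection sampling.

    Raises ``ValueError`` when placement fails after the attempt budget,
    suggesting a larger field.  The same seed reproduces the scene exactly.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if params is None:
        params = SceneParams()
    rng = np.random.default_rng(seed)
    fx, fy = params.field_size_um
    placed: list[CellModel] = []
    attempts = 0
    while len(placed) < n_cells:
        attempts += 1
        if attempts > params.max_placement_attempts:
            raise ValueError(
                f"could not place {n_cells} non-overlapping cells in a "
                f"{fx} x {fy} um field after {params.max_placement_attempts} "
                "attempts; enlarge field_size_um"
            )
        major = rng.normal(params.major_axis_mean_um, params.major_axis_sd_um)
        major = float(np.clip(major, 0.5 * params.major_axis_mean_um,
                              1.5 * params.major_axis_mean_um))
        aspect = rng.uniform(*params.aspect_ratio_range)
        theta = rng.uniform(0.0, np.pi)
        m = params.margin_um
        cx = rng.uniform(m, fx - m)
        cy = rng.uniform(m, fy - m)
        cz = params.z_extent_um / 2.0 + rng.uniform(-0.5, 0.5)
        radius = major / 2.0
        if any(
            math.hypot(cx - c.center_um[0], cy - c.center_um[1])
            < radius + c.major_axis_um / 2.0 + 0.5
            for c in placed
        ):
            continue

        semi = (radius, aspect * radius, aspect * radius)
        n_lds = int(rng.integers(params.ld_count_range[0], params.ld_count_range[1] + 1))
        lds = tuple(_sample_ld(rng, params, semi) for _ in range(n_lds))
        expression = float(max(rng.normal(params.expression_mean, params.expression_sd),
                               0.05 * params.expression_mean))
        mode: Mode = (
            "localized"
            if lds and rng.uniform() < params.localized_probability
            else "diffusive"
        )
        coverage = (
            float(rng.uniform(*params.coverage_fraction_range))
            if mode == "localized"
            else float("nan")
        )
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        placed.append(CellModel(
            center_um=(cx, cy, cz),
            major_axis_um=major,
            aspect_ratio=aspect,
            orientation_rad=theta,
            lds=lds,
            expression=expression,
            mode=mode,
            coverage_fraction=coverage,
            cap_axis=tuple(axis),
        ))
    return CellScene(tuple(placed), params, seed)


# ---------------------------------------------------------------------------
# rendering: phase
# ---------------------------------------------------------------------------


def _cell_chords(cell: CellModel, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Vertical chord length (um) of the cell ellipsoid over the (y, x) grid."""
    a, b, c = cell.semi_axes_um
    cx, cy, _ = cell.center_um
    ct, st = math.cos(cell.orientation_rad), math.sin(cell.orientation_rad)
    dx = xs[None, :] - cx
    dy = ys[:, None] - cy
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    q = 1.0 - u**2 - v**2
    return 2.0 * c * np.sqrt(np.clip(q, 0.0, None))


def scene_to_phase(scene: CellScene, pixel_pitch: float = 0.1,
                   noise_sd: float = 0.0, noise_seed: int | None = None) -> PhaseImage:
    """Project the scene to a phase map: cytosol chord length times the phase
    scale, plus each LD's chord-weighted phase excess; background is zero.

    Optional Gaussian phase noise (``noise_sd`` radians) emulates the
    shot-noise floor of interferometric phase maps.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    p = scene.params
    fx, fy = p.field_size_um
    nx, ny = int(round(fx / pixel_pitch)), int(round(fy / pixel_pitch))
    xs = (np.arange(nx) + 0.5) * pixel_pitch
    ys = (np.arange(ny) + 0.5) * pixel_pitch
    phase = np.zeros((ny, nx))
    for cell in scene.cells:
        phase += p.cytosol_phase_per_um * _cell_chords(cell, xs, ys)
        cx, cy, _ = cell.center_um
        ct, st = math.cos(cell.orientation_rad), math.sin(cell.orientation_rad)
        for ld in cell.lds:
            # LD offset is in the cell frame; rotate into the lab frame
            ox = cx + ld.offset_um[0] * ct - ld.offset_um[1] * st
            oy = cy + ld.offset_um[0] * st + ld.offset_um[1] * ct
            r = ld.diameter_um / 2.0
            rho2 = (xs[None, :] - ox) ** 2 + (ys[:, None] - oy) ** 2
            chord = 2.0 * np.sqrt(np.clip(r**2 - rho2, 0.0, None))
            phase += ld.phase_excess_rad * chord / ld.diameter_um
    if noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        phase = phase + rng.normal(0.0, noise_sd, size=phase.shape)
    return PhaseImage(phase, pixel_pitch)


# ---------------------------------------------------------------------------
# rendering: fluorescence
# ---------------------------------------------------------------------------


def _ld_lab_center(cell: CellModel, ld: LipidDroplet):
    cx, cy, cz = cell.center_um
    ct, st = math.cos(cell.orientation_rad), math.sin(cell.orientation_rad)
    return (
        cx + ld.offset_um[0] * ct - ld.offset_um[1] * st,
        cy + ld.offset_um[0] * st + ld.offset_um[1] * ct,
        cz + ld.offset_um[2],
    )


def scene_to_fluor(
    scene: CellScene,
    psf: ImageStack3D | None = None,
    pitch: Sequence[float] = (0.1, 0.1, 0.2),
    background: float = 10.0,
    noise_seed: int | None = None,
) -> ImageStack3D:
    """Render the reporter distribution of the scene to a 3D stack.

    Each cell emits a total flux proportional to its true expression level
    (``expression * cell volume``): diffusive cells emit uniformly over the
    ellipsoid, localized cells from a spherical cap of their largest LD whose
    area fraction equals the true coverage fraction.  The emission is blurred
    with ``psf`` (if given), background is added, and Poisson noise is applied
    when ``noise_seed`` is set.
    """
    pitch = VoxelPitch(*pitch)
    p = scene.params
    fx, fy = p.field_size_um
    nx, ny = int(round(fx / pitch.x)), int(round(fy / pitch.y))
    nz = int(round(p.z_extent_um / pitch.z))
    xs = (np.arange(nx) + 0.5) * pitch.x
    ys = (np.arange(ny) + 0.5) * pitch.y
    zs = (np.arange(nz) + 0.5) * pitch.z

    def crop(center, radius):
        """(z, y, x) slices of a bounding cube around ``center`` (x, y, z)."""
        (cx, cy, cz) = center
        zi = slice(max(0, int((cz - radius) / pitch.z) - 1),
                   min(nz, int((cz + radius) / pitch.z) + 2))
        yi = slice(max(0, int((cy - radius) / pitch.y) - 1),
                   min(ny, int((cy + radius) / pitch.y) + 2))
        xi = slice(max(0, int((cx - radius) / pitch.x) - 1),
                   min(nx, int((cx + radius) / pitch.x) + 2))
        return zi, yi, xi

    density = np.zeros((nz, ny, nx))
    for cell in scene.cells:
        flux = cell.expression * cell.volume_um3 / (pitch.x * pitch.y * pitch.z)
        if cell.mode == "diffusive" or not cell.lds:
            a, b, c = cell.semi_axes_um
            cx, cy, cz = cell.center_um
            zi, yi, xi = crop(cell.center_um, a)
            ct, st = math.cos(cell.orientation_rad), math.sin(cell.orientation_rad)
            dx = xs[xi][None, None, :] - cx
            dy = ys[yi][None, :, None] - cy
            dz = zs[zi][:, None, None] - cz
            u = (dx * ct + dy * st) / a
            v = (-dx * st + dy * ct) / b
            w = dz / c
            inside = u**2 + v**2 + w**2 <= 1.0
            n_vox = inside.sum()
            if n_vox:
                sub = density[zi, yi, xi]
                sub[inside] += flux / n_vox
        else:
            ld = max(cell.lds, key=lambda l: l.diameter_um)
            ox, oy, oz = _ld_lab_center(cell, ld)
            r = ld.diameter_um / 2.0
            zi, yi, xi = crop((ox, oy, oz), r + p.shell_thickness_um)
            dx = xs[xi][None, None, :] - ox
            dy = ys[yi][None, :, None] - oy
            dz = zs[zi][:, None, None] - oz
            dist = np.sqrt(dx**2 + dy**2 + dz**2)
            shell = np.abs(dist - r) <= p.shell_thickness_um
            # spherical cap of area fraction f: polar angle with
            # cos(theta_c) = 1 - 2 f around the cap axis
            ax = np.asarray(cell.cap_axis)
            with np.errstate(invalid="ignore", divide="ignore"):
                cos_angle = (dx * ax[0] + dy * ax[1] + dz * ax[2]) / np.maximum(dist, 1e-12)
            cap = cos_angle >= 1.0 - 2.0 * cell.coverage_fraction
            sel = shell & cap
            n_vox = sel.sum()
            if n_vox:
                sub = density[zi, yi, xi]
                sub[sel] += flux / n_vox

    if psf is not None:
        kernel = psf.voxels / psf.voxels.sum()
        density = np.clip(fftconvolve(density, kernel, mode="same"), 0.0, None)
    expected = density + background
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        expected = rng.poisson(expected).astype(np.float64)
    return ImageStack3D(expected, pitch)


def scene_truth_masks(scene: CellScene, pixel_pitch: float):
    """Per-cell ground-truth masks: the projected ellipse of each cell on the
    phase-image grid (list of boolean arrays, same order as ``scene.cells``)."""
    p = scene.params
    fx, fy = p.field_size_um
    nx, ny = int(round(fx / pixel_pitch)), int(round(fy / pixel_pitch))
    xs = (np.arange(nx) + 0.5) * pixel_pitch
    ys = (np.arange(ny) + 0.5) * pixel_pitch
    return [_cell_chords(cell, xs, ys) > 0 for cell in scene.cells]


def largest_ld_lab_center(cell: CellModel):
    """Ground-truth (x, y, z) centre of the cell's largest LD, or None."""
    if not cell.lds:
        return None
    ld = max(cell.lds, key=lambda l: l.diameter_um)
    return _ld_lab_center(cell, ld)


# ---------------------------------------------------------------------------
# bead fields
# ---------------------------------------------------------------------------


def generate_bead_phantom(
    n_beads: int,
    diameter_um: float,
    field_size_um: Sequence[float],
    brightness: float = 2.0e4,
    background: float = 10.0,
    margin_um: float = 1.5,
    seed: int = 0,
) -> BeadPhantom:
    """Randomly placed identical beads in a clear matrix (x, y, z field in um)."""
    rng = np.random.default_rng(seed)
    fx, fy, fz = field_size_um
    beads = tuple(
        Bead(
            center=(
                rng.uniform(margin_um, fx - margin_um),
                rng.uniform(margin_um, fy - margin_um),
                rng.uniform(margin_um, fz - margin_um),
            ),
            diameter=diameter_um,
            brightness=brightness,
        )
        for _ in range(n_beads)
    )
    return BeadPhantom(beads, background)


# ---------------------------------------------------------------------------
# simplified four-bucket phase-shifting round trip
# ---------------------------------------------------------------------------

QUARTER_SHIFTS = (np.pi / 2, np.pi, 3 * np.pi / 2, 2 * np.pi)


def _check_shifts(shifts) -> np.ndarray:
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (4,):
        raise ValueError("exactly four phase shifts are required")
    want = {0.0, 0.5, 1.0, 1.5}  # units of pi, modulo 2
    got = {round(float(s / np.pi) % 2.0, 6) for s in shifts}
    if got != want:
        raise ValueError("shifts must be the four quarter-wave steps "
                         "(pi/2, pi, 3pi/2, 2pi in any order)")
    return shifts


def qpi_forward(phase: PhaseImage, shifts=QUARTER_SHIFTS):
    """Four interferogram frames ``I_k = |e^{i delta_k} + (e^{i phi} - 1)|^2``:
    the un-scattered (background) field is phase-stepped against the scattered
    component of a unit-amplitude transparent object."""
    shifts = _check_shifts(shifts)
    scattered = np.exp(1j * phase.phase) - 1.0
    return [np.abs(np.exp(1j * d) + scattered) ** 2 for d in shifts]


def qpi_reconstruct(frames, shifts=QUARTER_SHIFTS, pixel_pitch: float = 1.0) -> PhaseImage:
    """Invert four quarter-stepped frames with the standard phase-shifting
    arctangent estimator."""
    shifts = _check_shifts(shifts)
    by_bucket = {}
    for frame, d in zip(frames, shifts):
        by_bucket[round(float(d / np.pi) % 2.0, 6)] = np.asarray(frame, dtype=float)
    g_c = by_bucket[0.0] - by_bucket[1.0]  # 4 Re(U_s)
    g_s = by_bucket[1.5] - by_bucket[0.5]  # -4 Im(U_s)
    scattered = g_c / 4.0 - 1j * g_s / 4.0
    total = 1.0 + scattered
    return PhaseImage(np.angle(total), pixel_pitch)


def qpi_forward_and_reconstruct(phase: PhaseImage, shifts=QUARTER_SHIFTS) -> PhaseImage:
    """Round trip: forward four-bucket model then arctangent reconstruction.

    For weakly scattering inputs (|phi| <= ~1 rad) the round trip is exact to
    numerical precision; stronger phases wrap through the arctangent branch.
    """
    frames = qpi_forward(phase, shifts)
    return qpi_reconstruct(frames, shifts, pixel_pitch=phase.pixel_pitch)
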