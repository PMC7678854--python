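"""Quantitative-phase cell analysis.

Cells and lipid droplets (LDs) are segmented from a phase map by direct
thresholding (cells carry a higher optical-phase delay than the background,
LDs a higher delay than the cytosol).  From each cell the module quantifies:

* dry-mass surface density  ``rho = lambda * <Phi> / (2 pi dn/dc)``,
  with dn/dc the refractive increment of biomolecular mass;
* reporter expression as cell-mean fluorescence minus extracellular
  background;
* whether the reporter is localized at the LD surface or diffusive, from the
  fraction of above-background fluorescence flux in a spherical shell around
  the LD;
* the percentage of the LD's 3D surface in contact with supra-threshold
  fluorescence voxels;

and compares groups with exact / normal-approximation Mann-Whitney tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .image_formation import ImageStack3D

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class PhaseImage:
    """2D optical-phase map in radians with square pixel pitch (um)."""

    phase: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.phase, dtype=np.float64)
        object.__setattr__(self, "phase", arr)
        if arr.ndim != 2:
            raise ValueError("phase must be 2D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("phase must be finite")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


@dataclass(frozen=True)
class DryDensityParams:
    """lambda = 0.5 um and dn/dc = 1.85e-4 m^3/kg by default."""

    wavelength_um: float = 0.5
    refractive_increment_m3_per_kg: float = 1.85e-4

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0 or self.refractive_increment_m3_per_kg <= 0:
            raise ValueError("wavelength and dn/dc must be positive")


def dry_density(mean_phase: float, params: DryDensityParams | None = None) -> float:
    """Dry-mass surface density (pg/um^2) from the mean phase (radians).

    ``rho = lambda * <Phi> / (2 pi dn/dc)``.  With lambda in m and dn/dc in
    m^3/kg the result is kg/m^2; 1 kg/m^2 = 1000 pg/um^2.
    """
    if params is None:
        params = DryDensityParams()
    lam_m = params.wavelength_um * 1e-6
    rho_kg_m2 = lam_m * mean_phase / (2.0 * np.pi * params.refractive_increment_m3_per_kg)
    return rho_kg_m2 * 1e3


def segment_by_phase(img: PhaseImage, threshold: float, min_area: float = 0.0):
    """Connected regions of ``phase > threshold`` (8-connectivity), holes
    filled, with area >= ``min_area`` (um^2), ordered by descending area.

    Returns a list of boolean masks of the image shape.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    mask = img.phase > threshold
    labels, n = ndimage.label(mask, structure=EIGHT_CONNECTED)
    min_pixels = min_area / img.pixel_pitch**2
    regions = []
    for lab in range(1, n + 1):
        region = ndimage.binary_fill_holes(labels == lab)
        if region.sum() >= min_pixels:
            regions.append(region)
    regions.sort(key=lambda m: int(m.sum()), reverse=True)
    return regions


def expression_level(stack: ImageStack3D, cell_mask: np.ndarray,
                     background_mask: np.ndarray) -> float:
    """Cell-mean fluorescence minus extracellular-background mean.

    2D masks are applied to every plane of the stack; 3D masks are applied
    voxelwise.  The result may be negative (it is not clipped).
    """
    def region_mean(mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            if mask.shape != stack.voxels.shape[1:]:
                raise ValueError("2D mask does not match stack planes")
            sel = stack.voxels[:, mask]
        elif mask.ndim == 3:
            if mask.shape != stack.voxels.shape:
                raise ValueError("3D mask does not match stack shape")
            sel = stack.voxels[mask]
        else:
            raise ValueError("mask must be 2D or 3D")
        if sel.size == 0:
            raise ValueError("empty region")
        return float(sel.mean())

    return region_mean(cell_mask) - region_mean(background_mask)


def _voxel_distance_to_point(stack: ImageStack3D, center, box=None):
    """|r - center| for voxel centres (um) within an optional (z, y, x) slice
    box; center is (x, y, z)."""
    zc, yc, xc = stack.coords()
    if box is not None:
        zc, yc, xc = zc[box[0]], yc[box[1]], xc[box[2]]
    cx, cy, cz = center
    return np.sqrt(
        (zc[:, None, None] - cz) ** 2
        + (yc[None, :, None] - cy) ** 2
        + (xc[None, None, :] - cx) ** 2
    )


def _sphere_box(stack: ImageStack3D, center, radius_um: float):
    """(z, y, x) slices of the voxel bounding box of a sphere, clipped to the
    stack."""
    nz, ny, nx = stack.voxels.shape
    cx, cy, cz = center
    px, py, pz = stack.pitch
    def sl(c, p, n):
        lo = max(0, int(np.floor((c - radius_um) / p - 0.5)))
        hi = min(n, int(np.ceil((c + radius_um) / p + 0.5)) + 1)
        return slice(lo, hi)
    return (sl(cz, pz, nz), sl(cy, py, ny), sl(cx, px, nx))


def classify_localization(
    fluor: ImageStack3D,
    ld_center,
    ld_diameter: float,
    shell_margin: float = 0.3,
    localized_fraction_threshold: float = 0.5,
    background: float = 0.0,
    cell_mask: np.ndarray | None = None,
) -> Literal["localized", "diffusive"]:
    """Localized iff the fraction of above-background flux within the
    spherical shell ``r_LD +/- shell_margin`` exceeds the threshold.

    ``ld_center`` is (x, y, z) um, or None when the cell has no LD, in which
    case the call returns "diffusive" by definition.  ``cell_mask`` (2D or 3D)
    restricts the flux bookkeeping to the cell.
    """
    if ld_center is None:
        return "diffusive"
    if ld_diameter <= 0:
        raise ValueError("ld_diameter must be positive")
    flux = np.clip(fluor.voxels - background, 0.0, None)
    if cell_mask is not None:
        mask = np.asarray(cell_mask, dtype=bool)
        if mask.ndim == 2:
            mask = np.broadcast_to(mask, fluor.voxels.shape)
        flux = np.where(mask, flux, 0.0)
    total = flux.sum()
    if total <= 0:
        return "diffusive"
    r = ld_diameter / 2.0
    box = _sphere_box(fluor, ld_center, r + shell_margin)
    dist = _voxel_distance_to_point(fluor, ld_center, box)
    shell = np.abs(dist - r) <= shell_margin
    fraction = flux[box][shell].sum() / total
    return "localized" if fraction > localized_fraction_threshold else "diffusive"


def ld_surface_coverage(
    fluor: ImageStack3D,
    ld_center,
    ld_diameter: float,
    contact_distance: float | None = None,
    intensity_threshold: float = 0.0,
    mode: Literal["contact", "radial"] = "contact",
    background: float = 0.0,
    relative_threshold: float = 0.33,
    band_halfwidth: float = 0.7,
) -> float:
    """Percentage of the LD surface in contact with fluorescence.

    The sphere surface is discretised into patches: voxels whose centre lies
    within half a voxel diagonal of the sphere of the given diameter.

    ``mode="contact"`` (default): a patch counts as covered when at least one
    supra-threshold (``intensity_threshold``) fluorescence voxel lies within
    ``contact_distance`` (default: one voxel diagonal) of it.

    ``mode="radial"``: above-``background`` flux in the band
    ``r +/- band_halfwidth`` is projected radially onto the nearest-angle
    patch, and a patch counts as covered when its accumulated flux exceeds
    ``relative_threshold`` times the 95th-percentile patch flux.  Radial
    projection undoes the radial component of PSF blur and the relative
    (half-maximum-like) threshold localises the edge of a fluorescent cap
    without bias under the remaining symmetric tangential smear, so this is
    the estimator used on blurred stacks.
    """
    if ld_diameter <= 0:
        raise ValueError("ld_diameter must be positive")
    px, py, pz = fluor.pitch
    diag = math.sqrt(px**2 + py**2 + pz**2)
    if contact_distance is None:
        contact_distance = diag
    if contact_distance < max(fluor.pitch):
        raise ValueError("contact_distance must be at least the largest voxel pitch")

    r = ld_diameter / 2.0
    cx, cy, cz = ld_center
    nz, ny, nx = fluor.voxels.shape
    lims = (nx * px, ny * py, nz * pz)
    if not all(0 <= c - r and c + r <= l for c, l in zip((cx, cy, cz), lims)):
        raise ValueError("LD sphere extends outside the imaged volume")

    box = _sphere_box(fluor, ld_center, r + diag + max(contact_distance, band_halfwidth))
    dist = _voxel_distance_to_point(fluor, ld_center, box)
    surface = np.abs(dist - r) <= diag / 2.0
    n_patches = int(surface.sum())
    if n_patches == 0:
        raise ValueError("sphere surface is not resolved by the voxel grid")

    zc, yc, xc = fluor.coords()
    grid = np.stack(
        np.meshgrid(zc[box[0]], yc[box[1]], xc[box[2]], indexing="ij"), axis=-1
    )

    if mode == "radial":
        flux = np.clip(fluor.voxels[box] - background, 0.0, None)
        band = np.abs(dist - r) <= band_halfwidth
        safe = np.maximum(dist[..., None], 1e-12)
        cx, cy, cz = ld_center
        dirs = (grid - np.array([cz, cy, cx])) / safe
        tree = cKDTree(dirs[surface])
        _, idx = tree.query(dirs[band], k=1)
        patch_flux = np.zeros(n_patches)
        np.add.at(patch_flux, idx, flux[band])
        ref = np.percentile(patch_flux, 95.0)
        if ref <= 0:
            return 0.0
        covered = int(np.sum(patch_flux > relative_threshold * ref))
        return 100.0 * covered / n_patches

    if mode != "contact":
        raise ValueError(f"unknown coverage mode {mode!r}")
    supra = fluor.voxels[box] > intensity_threshold
    if not np.any(supra):
        return 0.0
    tree = cKDTree(grid[supra])
    patch_points = grid[surface]
    d, _ = tree.query(patch_points, k=1, distance_upper_bound=contact_distance * (1 + 1e-9))
    covered = int(np.sum(np.isfinite(d)))
    return 100.0 * covered / n_patches


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

_ENUMERATION_CAP = 200_000  # labelings; C(16, 8) = 12870 sits well below


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    p_value: float
    method: Literal["exact", "normal-approximation"]


def _u_from_ranks(ranks: np.ndarray, idx_a: np.ndarray, n1: int, n2: int) -> float:
    return float(ranks[idx_a].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float],
                 mode: Literal["exact", "auto"] = "auto") -> RankTestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    U is the number of (a, b) pairs with a > b, counting ties as 1/2.  The
    exact two-sided p enumerates all labelings of the pooled sample (feasible
    whenever n1*n2 <= 400 and the number of labelings stays moderate, which
    covers all n1, n2 <= 8); otherwise a tie-corrected normal approximation
    with continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = _u_from_ranks(ranks, np.arange(n1), n1, n2)

    n = n1 + n2
    n_labelings = math.comb(n, n1)
    feasible = n1 * n2 <= 400 and n_labelings <= _ENUMERATION_CAP
    if mode == "exact" or (mode == "auto" and feasible):
        if not feasible and n_labelings > 50 * _ENUMERATION_CAP:
            raise ValueError(f"exact enumeration over {n_labelings} labelings is infeasible")
        mid = n1 * n2 / 2.0
        dev = abs(u_obs - mid) - 1e-12
        extreme = 0
        for combo in combinations(range(n), n1):
            u = _u_from_ranks(ranks, np.fromiter(combo, dtype=int, count=n1), n1, n2)
            if abs(u - mid) >= dev:
                extreme += 1
        return RankTestResult(u_obs, extreme / n_labelings, "exact")

    # tie-corrected normal approximation with continuity correction
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return RankTestResult(u_obs, 1.0, "normal-approximation")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    p = math.erfc(max(z, 0.0) / math.sqrt(2.0))
    return RankTestResult(u_obs, min(p, 1.0), "normal-approximation")


# ---------------------------------------------------------------------------
# per-cell pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and geometry parameters of the per-cell pipeline.

    Phase thresholds are in radians; the LD threshold must exceed the cell
    threshold so LD masks nest inside cell masks.  ``localized_margin`` grows
    the LD shell used for the localization call beyond the raw contact shell
    to absorb PSF blur.  Surface coverage on blurred stacks uses the
    radial-projection estimator of :func:`ld_surface_coverage` by default;
    ``coverage_mode="contact"`` switches to raw contact counting with a
    supra-threshold of background + ``intensity_threshold_sigmas`` SDs.
    """

    cell_threshold_rad: float = 0.4
    ld_threshold_rad: float = 1.8
    min_cell_area_um2: float = 3.0
    min_ld_area_um2: float = 0.05
    localized_margin_um: float = 0.6
    localized_fraction_threshold: float = 0.5
    contact_distance_um: float | None = None
    coverage_mode: Literal["radial", "contact"] = "radial"
    coverage_relative_threshold: float = 0.33
    coverage_band_um: float = 0.7
    intensity_threshold_sigmas: float = 3.0
    dry_density_params: DryDensityParams = field(default_factory=DryDensityParams)


@dataclass(frozen=True)
class CellRecord:
    """One measurement row per segmented cell."""

    cell_id: int
    area_um2: float
    mean_phase_rad: float
    dry_density_pg_um2: float
    erg6_expression: float
    expression_below_background: bool
    localization: Literal["localized", "diffusive"]
    ld_diameter_um: float  # nan when the cell has no segmented LD
    ld_coverage_pct: float  # nan when the cell has no segmented LD


def records_to_dataframe(records: Sequence[CellRecord]) -> pd.DataFrame:
    cols = ["cell_id", "area_um2", "mean_phase_rad", "dry_density_pg_um2",
            "erg6_expression", "expression_below_background", "localization",
            "ld_diameter_um", "ld_coverage_pct"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def _refine_ld_z(fluor: ImageStack3D, center0, radius: float, background: float,
                 band: float, search_halfwidth: float = 0.8, step: float = 0.1) -> float:
    """Refine the LD z-centre by grid search: the value minimising the
    flux-weighted mean squared radial residual ``(|r_i - c| - radius)^2`` over
    above-background voxels near the sphere."""
    cx, cy, cz0 = center0
    reach = radius + band + search_halfwidth
    box = _sphere_box(fluor, center0, reach)
    flux = np.clip(fluor.voxels[box] - background, 0.0, None)
    if flux.sum() <= 0:
        return cz0
    best_z, best_cost = cz0, np.inf
    for dz in np.arange(-search_halfwidth, search_halfwidth + step / 2, step):
        dist = _voxel_distance_to_point(fluor, (cx, cy, cz0 + dz), box)
        sel = np.abs(dist - radius) <= band
        w = flux[sel]
        if w.sum() <= 0:
            continue
        cost = float(np.sum(w * (dist[sel] - radius) ** 2) / w.sum())
        if cost < best_cost:
            best_cost, best_z = cost, cz0 + dz
    return float(best_z)


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def analyze_cells(
    phase: PhaseImage,
    fluor: ImageStack3D,
    config: AnalysisConfig | None = None,
):
    """Segment cells and LDs from the phase map, then quantify dry density,
    expression, localization and LD surface coverage per cell.

    The phase map and the fluorescence stack must share the lateral grid
    (same pixel pitch and xy shape).  Cells touching the image border are
    excluded.  Returns a list of :class:`CellRecord`.
    """
    if config is None:
        config = AnalysisConfig()
    ny, nx = phase.phase.shape
    if fluor.voxels.shape[1:] != (ny, nx):
        raise ValueError(
            f"fluorescence stack planes {fluor.voxels.shape[1:]} do not match "
            f"the phase map {phase.phase.shape}"
        )
    if not np.isclose(phase.pixel_pitch, fluor.pitch.x, rtol=1e-6) or \
       not np.isclose(phase.pixel_pitch, fluor.pitch.y, rtol=1e-6):
        raise ValueError("phase and fluorescence lateral pitches differ")

    pitch = phase.pixel_pitch
    cell_masks = segment_by_phase(phase, config.cell_threshold_rad, config.min_cell_area_um2)
    cell_masks = [m for m in cell_masks if not _touches_border(m)]
    if not cell_masks:
        return []

    any_cell = np.any(cell_masks, axis=0)
    background_mask = ~ndimage.binary_dilation(any_cell, structure=EIGHT_CONNECTED,
                                               iterations=3)
    if not background_mask.any():
        raise ValueError("no extracellular background region available")
    bg_voxels = fluor.voxels[:, background_mask]
    bg_mean = float(bg_voxels.mean())
    bg_sd = float(bg_voxels.std())
    supra_floor = bg_mean + config.intensity_threshold_sigmas * bg_sd

    zc, _, _ = fluor.coords()
    records = []
    for cid, cmask in enumerate(cell_masks):
        area = float(cmask.sum()) * pitch**2
        mean_phase = float(phase.phase[cmask].mean())
        expr = expression_level(fluor, cmask, background_mask)

        # LD segmentation nested inside the cell
        ld_phase = np.where(cmask, phase.phase, -np.inf)
        ld_masks = segment_by_phase(PhaseImage(np.where(np.isfinite(ld_phase), ld_phase, 0.0),
                                               pitch),
                                    config.ld_threshold_rad, config.min_ld_area_um2)
        ld_masks = [m for m in ld_masks if (m & cmask).sum() == m.sum()]

        ld_center = None
        ld_diam = float("nan")
        coverage = float("nan")
        if ld_masks:
            ld_mask = ld_masks[0]  # largest LD
            ld_diam = 2.0 * math.sqrt(ld_mask.sum() * pitch**2 / math.pi)
            cy, cx = ndimage.center_of_mass(ld_mask)
            # initial z: plane of maximal in-mask fluorescence, then refined
            # by minimising the flux-weighted radial spread about the sphere
            # (a cap pulls the argmax plane toward itself; the true centre
            # minimises the spread of shell-flux radii)
            in_mask = fluor.voxels[:, ld_mask].sum(axis=1)
            cz = float(zc[int(np.argmax(in_mask))])
            cz = _refine_ld_z(fluor, (cx * pitch, cy * pitch, cz), ld_diam / 2.0,
                              bg_mean, config.coverage_band_um)
            ld_center = (cx * pitch, cy * pitch, cz)
            try:
                coverage = ld_surface_coverage(
                    fluor, ld_center, ld_diam,
                    contact_distance=config.contact_distance_um,
                    intensity_threshold=supra_floor,
                    mode=config.coverage_mode,
                    background=bg_mean,
                    relative_threshold=config.coverage_relative_threshold,
                    band_halfwidth=config.coverage_band_um,
                )
            except ValueError:
                coverage = float("nan")  # LD sphere clipped by the volume

        loc = classify_localization(
            fluor, ld_center, ld_diam if ld_center else 1.0,
            shell_margin=config.localized_margin_um,
            localized_fraction_threshold=config.localized_fraction_threshold,
            background=bg_mean,
            cell_mask=cmask,
        )
        records.append(CellRecord(
            cell_id=cid,
            area_um2=area,
            mean_phase_rad=mean_phase,
            dry_density_pg_um2=dry_density(mean_phase, config.dry_density_params),
            erg6_expression=expr,
            expression_below_background=expr < 0,
            localization=loc,
            ld_diameter_um=ld_diam,
            ld_coverage_pct=coverage,
        ))
    return records
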