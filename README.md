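# airyqpi

Simulation and analysis toolkit for integrative **Airy-beam light-sheet** and
**quantitative-phase imaging (QPI)** microscopy of single cells.

A light sheet built from a self-accelerating Airy beam illuminates a far
longer propagation-invariant corridor than a Gaussian beam of comparable
thickness, which lets a light-sheet fluorescence channel match the
~200 × 200 µm² field of view of a QPI channel on the same microscope. This
package implements the computational side of such an instrument:

* **`beam_propagation`** — a 2D FFT beam-propagation-method (angular
  spectrum) simulator. The input field is a Gaussian carrying a cubic mask
  phase, `E₀(x) = A·exp(−x²/w₀²)·exp(i·(α/3)x³)`, relayed through a train of
  thin lenses `Tᵢ(x) = exp(−i·(2π/λ)·x²/2fᵢ)` with free-space steps
  `E ← IFFT{FFT{E}·exp(i·k_z·d)}`, `k_z = √(k² − k_x²)`. Metrology on the
  focal region: main-lobe 1/e diameter tracking, beam-waist location, and
  the diffraction-free path (longest interval with diameter ≤ √2 × minimum).
* **`image_formation`** — scalar (Born–Wolf) detection PSF, light-sheet
  system PSF (detection PSF × sheet profile along the detection axis),
  bead-stack rendering with Poisson noise, FWHM resolution measurement.
* **`deconvolution`** — Richardson–Lucy restoration
  `eₖ₊₁ = eₖ·[(d/(eₖ∗h))∗h⁻]`, used to remove the Airy beam's transverse
  structure from rendered stacks.
* **`qpi_analysis`** — phase-threshold segmentation of cells and lipid
  droplets (LDs), dry-mass surface density `ρ = λ⟨Φ⟩/(2π·dn/dc)`, reporter
  expression (cell mean minus extracellular background), LD-localization
  classification, % LD-surface coverage in 3D, and exact /
  normal-approximation Mann–Whitney U tests.
* **`synthetic_phantoms`** — ground-truthed scenes: *Yarrowia lipolytica*-like
  ellipsoidal cells (major axis 5.3 ± 0.4 µm) with high-phase LDs and either
  LD-localized or diffusive fluorophore distributions, fluorescent bead
  fields, and a four-bucket (π/2-stepped) phase-shifting QPI round trip.
* **`cli_io`** — the `airyqpi` command-line front end and TIFF/CSV/YAML I/O.

## Worked example

Generate a ground-truthed three-cell scene and analyse it:

```bash
airyqpi phantom --type cells --n 3 --seed 3 --out-prefix ex
airyqpi analyze --phase ex_phase.tiff --fluor ex_fluor.tiff --out ex_cells.csv
```

`ex_cells.csv` (rounded):

```
cell_id  area_um2  mean_phase_rad  dry_density_pg_um2  erg6_expression  localization  ld_diameter_um  ld_coverage_pct
      0     18.20           1.191               0.512          127.928     localized           1.291           59.970
      1     17.18           1.295               0.557          147.213     diffusive           1.781           85.374
      2     15.44           1.221               0.525          131.716     localized           1.436           69.231
```

Each row is one segmented cell: its 2D area, mean optical phase (radians),
dry-mass surface density from `ρ = λ⟨Φ⟩/(2π·dn/dc)` (λ = 0.5 µm,
dn/dc = 1.85 × 10⁻⁴ m³ kg⁻¹ — ⟨Φ⟩ = 1.19 rad gives 0.51 pg µm⁻²),
background-subtracted reporter expression, whether the reporter is localized
at the LD surface, and the percentage of the LD's 3D surface in contact with
reporter signal. The scene's ground truth (`ex_truth.csv`) put localized
caps covering 59% and 68% of the two LD surfaces; the pipeline recovers
60.0% and 69.2%, and labels all three cells correctly.

The illumination simulator prints its headline number directly:

```bash
airyqpi simulate-beam --out beam.tiff --metrics metrics.csv
# diffraction-free length: 205.0 um            (~2 min on one core)
```

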