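# fmpi

Simulation and analysis of **functional magnetic particle imaging (fMPI)**:
time-series imaging of cerebral blood volume (CBV) with a mechanically
rotating field-free-line (FFL) MPI scanner.

MPI detects the nonlinear (Langevin) magnetization harmonics of a
superparamagnetic iron-oxide tracer confined to the blood pool — there is
no tissue background, so the signal of a brain voxel is directly
proportional to its blood volume.  Alternating hyper-/hypocapnia (5 min
states) modulates CBV by ~25%; imaging at 5 s per frame and fitting a
hemodynamic general linear model turns that modulation into
contrast-to-noise (CNR) and percent-signal-change maps.  The package is
aimed at people developing or evaluating MPI instrumentation and
functional-imaging analysis chains who need a fully synthetic, seeded,
end-to-end testbed.

It provides:

* `fmpi.scanner_sim` — FFL scanner physics: Langevin magnetization,
  harmonic sinogram formation (27 angles × 66 samples per 5 s frame, sets
  of 5 with an 83% duty cycle), HDF5 serialization;
* `fmpi.study_synth` — phantoms (dilution wells, a 210 ng/voxel brain
  map), the capnic CBV response `(block ⊛ t e^{−t/τ₁}) · e^{−t/τ₂}`, and
  the two-component instrument noise model
  `σ_tot = √(σ₀² + (λS)²)` plus alternating-quadrant gain artifacts;
* `fmpi.recon` — forward-model reconstruction: simulated system matrix,
  PCA-truncated pseudoinverse keeping singular vectors with >10% spectral
  energy in the low-frequency band, 3 mm Gaussian smoothing, PSF
  measurement;
* `fmpi.preprocess` — zero-phase band-stop at 0.2/0.4 cycles/sample
  (bandwidth 0.075), Rician-corrected ROI SNR, series assembly;
* `fmpi.glm` — the 5-regressor GLM (activation, constant, linear,
  quadratic, warm-up transient; phantom and BOLD variants), τ₁/τ₂/Δt
  optimization, CNR / ΔS/S / Bonferroni-thresholded activation maps;
* `fmpi.metrics` — dilution linearity (0.86 SNR/ng), detection limit at
  SNR = 5, noise-model fitting, blood-pool iron accounting;
* `fmpi.io_cli` — YAML-configured pipeline driver (`fmpi run-all …`).

## Worked example

A reduced-scale 10-minute experiment: a 210 ng/voxel brain phantom, one
capnic cycle, reconstruction on an 11×11 grid, noise at the instrument's
characterized levels, and a GLM fit at the reference time constants:

```python
from fmpi import io_cli

cfg = io_cli.load_config({
    "seed": 1,
    "duration": 600.0,
    "output_dir": "fmpi_demo",
    "recon": {"n_xy": 11, "voxel_size": 2.5, "harmonics": [3, 5]},
    "glm": {"optimize": False},
})
report = io_cli.cli_run_all(cfg)
g = report["glm"]
print(f"max CNR              : {g['max_cnr']:.1f}")
print(f"mean percent change  : {g['mean_percent_change']:.1f} %")
print(f"implied half-life    : {g['half_life_s']/60:.1f} min")
print(f"active voxels        : {g['n_active_voxels']} of {g['n_tests']}")
```

prints

```
max CNR              : 18.2
mean percent change  : 24.9 %
implied half-life    : 35.8 min
active voxels        : 59 of 59
```

The mean percent change recovers the generator's 25% CBV modulation; the
half-life is τ₂·ln 2 for the 3100 s clearance constant; every brain voxel
survives the corrected p < 10⁻¹² activation threshold; and the peak CNR
of ~18 sits where a hypercapnia experiment at these noise levels should.
`fmpi_demo/` receives the sinogram (HDF5), reconstructed series and
statistical maps (NIfTI), the state trace (CSV), and a provenance-stamped
JSON report.  The same pipeline runs from the shell:
`fmpi run-all --config run.yaml --seed 1`.

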