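# xcdyn

Does a nuclear RNA compartment physically exclude a diffusing protein?
During X-chromosome inactivation the Xist-coated territory (XC) appears
depleted of RNA polymerase II, which has been read as evidence of a
biophysical barrier (e.g. a phase-separated domain). `xcdyn` implements
the quantitative framework that distinguishes a real barrier from lost
chromatin binding, for people analysing live-cell microscopy of nuclear
compartments:

* **FCS-calibrated imaging** — fit autocorrelation curves
  G(τ) = (1 + T/(1−T)·e^(−τ/τ_T))·(1/N)·Σᵢ fᵢ(1+(τ/τᵢ)^αᵢ)⁻¹(1+(τ/τᵢ)^αᵢ/κ²)^(−½),
  anchor the confocal volume V = π^{3/2}κw₀³ with a reference dye
  (w₀ = 2√(D_dye·τ_dye)), and convert image intensities to absolute
  concentrations C = a·(I − I_bkg) + b and molecule counts per region.
* **SPT dynamics** — jump-length statistics, MSD/VAC, jump-angle
  anisotropy, entering-event flux into the compartment versus
  randomized shifted-control regions (Kolmogorov–Smirnov comparison),
  and a two-state bound/free fit of the jump-length CDFs
  with a defocalization correction for molecules escaping the axial
  detection window, F̂_bound and D̂_free with bootstrap errors.
* **FRAP** — double normalization (background subtraction, prebleach
  scaling, acquisition-bleach correction via an unbleached control),
  aggregation across cells, recovered-fraction readout.
* **Synthetic ground truth** — a generator producing trajectories,
  masks, FCS curves, calibration stacks and FRAP traces with known
  parameters, so every estimator above is testable without raw movies.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

Simulate a cell whose molecules are 40% chromatin-bound
(D_bound = 0.005 μm² s⁻¹) and 60% free (D_free = 3.8 μm² s⁻¹), imaged
at 5.477 ms per frame with 28 nm localization error and a 0.7 μm
detection depth, then fit the two-state model back:

```python
from xcdyn.simulate import SimGeometry, SimKinetics, SimCamera, simulate_trajectories
from xcdyn.spt import compute_jumps, fit_two_state

geometry = SimGeometry()                      # 8 x 6 um nucleus, r = 1.5 um compartment
kinetics = SimKinetics(f_bound_nucleoplasm=0.4, f_bound_xc=0.4)
camera = SimCamera(n_frames=2000)

table, truth = simulate_trajectories(geometry, kinetics, camera,
                                     seed=11, n_molecules=40000)
fit = fit_two_state(compute_jumps(table), n_boot=50, boot_size=3000, seed=1)
print(f"trajectories: {table.n_trajectories}")
print(f"F_bound = {fit.f_bound:.3f} +/- {fit.f_bound_sd:.3f}   (truth 0.400)")
print(f"D_free  = {fit.d_free:.2f} +/- {fit.d_free_sd:.2f} um^2/s (truth 3.80)")
```

```
trajectories: 6262
F_bound = 0.356 +/- 0.023   (truth 0.400)
D_free  = 3.71 +/- 0.14 um^2/s (truth 3.80)
```

The fitted bound fraction sits a few percent below truth — the
documented residual bias of the 3-jumps-per-trajectory cap — and
D_free is recovered within ~3%. The same workflow is available from the shell:

```
xcdyn simulate spt --seed 11 --out sim/
xcdyn spt fit2 --trajectories sim/trajectories.csv --out fit.csv
xcdyn regions controls --masks sim/ --seed 2 --out controls/
xcdyn frap normalize --traces frap.csv --out frap_norm.csv
```

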