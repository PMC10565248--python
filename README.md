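# morphograd

Quantitative machinery for studying how a secreted morphogen forms an
extracellular concentration gradient and patterns its target tissue.
The package covers the full analysis chain used in gradient studies
built on fluorescence correlation spectroscopy (FCS) and single-molecule
FISH:

- **FCS** — multi-tau autocorrelation of photon-count traces, 3D
  one-/two-component diffusion model fitting with a fixed triplet term,
  observation-volume calibration, and conversion of fits to diffusion
  coefficients (D = ω₀²/4τ_D) and molar concentrations
  (C = N_p/(V_eff·N_A), V_eff = π^{3/2}ω₀²z₀);
- **Brownian-dynamics simulation** of fluorophore mixtures under a 3D
  Gaussian detection profile, emitting Poisson photon traces with known
  ground truth;
- **Synthetic embryos** — graded ligand curves, inhomogeneous-Poisson
  smFISH foci, graded nuclear reporters, rendered 3D stacks, and mixed
  pixel spectra;
- **Quantification** — NNLS spectral unmixing, sum-projection strip
  profiles, 3D Laplacian-of-Gaussian blob detection, and 10-µm spatial
  binning of foci counts and nuclear intensities;
- **Gradient mapping** — background-subtracted, per-sample-normalized
  40-µm count-rate gradients; overlay of expression profiles onto the
  gradient to read off relative-concentration thresholds at domain
  boundaries; cell-tier conversion (14 µm/tier); pooled t-test and
  Pearson statistics;
- **Hindered diffusion** — a 1D reaction–diffusion model (source,
  diffusion, reversible binding to immobile sites, degradation) with
  presets for binding-site removal (heparinase), membrane-tethered
  clones and an extracellular ligand trap.

It is aimed at quantitative developmental biologists and biophysicists
who want a tested, scriptable re-implementation of these steps on
synthetic or tabular data.  See `docs/methods.md` for the models,
parameter defaults and their rationale.

## Worked example

Simulate a 10-s FCS measurement of a freely diffusing ligand at the
measured fast diffusion coefficient (55 µm²/s) and source concentration
(~8 nM), correlate it and fit the one-component model:

```python
from morphograd import fcs_core as fcs, fcs_sim as sim

cfg = sim.SimConfig([sim.SpeciesSpec(diffusion_coefficient=55.0,
                                     brightness=3.0, expected_count=220)],
                    duration=10.0, seed=2)
trace, truth = sim.simulate_trace(cfg)
curve = fcs.autocorrelate(trace)
cal = fcs.CalibrationResult(omega_o=0.2, z_o=1.0, reference_d=435.0)
fit = fcs.fit_curve(curve, fcs.FcsModel.one_component(),
                    calibration=cal, lag_range=(4e-5, 0.1))
print(f"count rate   : {fcs.count_rate(trace):.2f} kHz")
print(f"fitted D     : {fit.derived_d[0]:.1f} um^2/s (input 55.0)")
print(f"fitted N_p   : {fit.model.n_particles:.2f} molecules in focus")
print(f"concentration: {fit.concentration_nm:.1f} nM")
```

```
count rate   : 1.16 kHz
fitted D     : 49.6 um^2/s (input 55.0)
fitted N_p   : 1.12 molecules in focus
concentration: 8.4 nM
```

A single 10-s trace at ~1 kHz recovers D to ~±20 % and the
concentration to ~±10 %; the validation runs average twenty such
repetitions before fitting, which is also the only reliable way to
resolve the minor (7 %) slow component of the two-species mixture
(`morphograd.pipeline.averaged_mixture_fit`).  Map synthetic expression
profiles onto the gradient curve:

```python
from morphograd import synthetic_embryo as emb
from morphograd.profiles import BlobSet, bin_foci
from morphograd.gradient_mapping import overlay_thresholds

phantoms = [emb.make_phantom(seed) for seed in range(20)]
profile = bin_foci([BlobSet.from_points(p.foci["tbxta"])
                    for p in phantoms])
tmap = overlay_thresholds(phantoms[0].gradient, profile, label="tbxta")
b = tmap["tbxta_boundary"]
print(f"boundary at {b.position_um:.0f} um = {b.position_tiers} tiers, "
      f"gradient level {b.relative_level:.2f} "
      f"(~{b.absolute_nm:.1f} nM)")
```

```
boundary at 140 um = 10.0 tiers, gradient level 0.40 (~3.2 nM)
```

The margin-confined target switches off where the gradient falls to
0.4 of its source value (~10 cell tiers out) — the package's
re-derivation of the input–output threshold map.

A command-line interface wraps the same stages
(`morphograd simulate-fcs | correlate | fit | calibrate | phantom |
profile | map | rd | run`); `morphograd run fig3 … fig6` executes
end-to-end workflow presets whose outputs embed their config and seed.

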