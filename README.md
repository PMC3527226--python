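# stat1ple

Delay-ODE modelling of IFNγ-induced STAT1 signalling in pancreatic stellate
(PSC) and cancer (PC) cells, with profile-likelihood identifiability
analysis, a randomized-data overfitting test, and time-dependent metabolic
control analysis.

IFNγ inhibits proliferation of both the stromal and the tumour compartment
of pancreatic cancer, but live-cell data show a striking difference: PSC
accumulate (phospho-)STAT1 in the nucleus after stimulation, PC cells do
not. This package is for modellers who want to ask, with sparse immunoblot
and immunofluorescence time series, *which reactions* cause such differences
and *which predictions survive* parameter uncertainty. It provides:

- a delay differential equation model of the pathway
  (receptor activation → STAT1 phosphorylation → nuclear shuttling →
  delayed SOCS1/STAT1 transcription with SOCS1 negative feedback), with an
  observation map to immunoblot and nuclear:cytoplasmic ratio channels;
- χ² estimation, `χ²(θ) = Σ_observables Σ_times (y_ij − f_ij(θ))²/σ_ij²`,
  by hybrid simulated-annealing + trust-region multistart;
- profile likelihoods per parameter with pointwise (df = 1) and simultaneous
  (df = #parameters) confidence intervals at the χ² quantile `Δ_α = Q(α, df)`,
  classification into identifiable / practically / structurally
  nonidentifiable, parameter correlations along profiles, and trajectory
  uncertainty bands;
- the parametric-bootstrap overfitting statistic
  `χ²_orig(θ̂_random) − χ²_orig(θ̂)`, its comparison with χ²_d laws,
  effective degrees of freedom, and confidence-level recalculation;
- finite-time metabolic control coefficients
  `C_p^x(t) = (p/x(t))·(∂x(t)/∂p)` under −1% perturbations, with CI bands
  over profile-derived parameter sets and finite-fraction inhibition runs.

Because no machine-readable time series are publicly deposited for this
system, a synthetic-data generator (Gaussian per-point noise, sparse 0–540 min
sampling, calibrated PSC-like/PC-like presets) defines the data regime; see
`docs/methods.md` for what it does and does not emulate.

## Worked example

```python
import numpy as np
from stat1ple import make_preset, simulate_observables, mcc

psc = make_preset("PSC_like")
grid = np.linspace(0, 540, 55)
obs = simulate_observables(psc, dose=100.0, time_grid=grid)
late = grid >= 300
print(f"late nuclear:cytoplasmic phospho-STAT1: "
      f"{np.nanmean(obs['ratio_STAT1D_nc'][late]):.2f}")
print(f"peak nuclear:cytoplasmic total STAT1:   "
      f"{np.nanmax(obs['ratio_STAT1_nc']):.2f}")
series = mcc(psc, "k_deph", "STAT1Dn")
print(f"MCC of nuclear dephosphorylation on STAT1Dn at t=540: "
      f"{series.coefficient[-1]:+.2f}")
```

prints

```
late nuclear:cytoplasmic phospho-STAT1: 3.50
peak nuclear:cytoplasmic total STAT1:   3.79
MCC of nuclear dephosphorylation on STAT1Dn at t=540: -0.97
```

The 3.5-fold late nuclear accumulation of phospho-STAT1 is the PSC regime's
signature; the control coefficient near −1 says a 1% inhibition of nuclear
dephosphorylation raises nuclear phospho-STAT1 by ≈1% at all observed times
— which is why `k_deph` (and not the nuclear-import rate, whose coefficient
stays below 0.2 in magnitude) is the actionable target in both cell types.

## Analysis scripts

The full study lives in numbered drivers under `analysis/` (each writes its
tables to `results/`):

| script | what it does |
|---|---|
| `01_simulate_presets.py` | simulates both presets, tabulates the two-regime contrast |
| `02_fit_synthetic.py` | multistart fits of the 5 freed transport/activation parameters |
| `03_identifiability.py` | profiles, CI classification, correlations, trajectory bands |
| `04_overfitting.py` | overfitting distributions, effective dof, corrected levels |
| `05_sensitivity.py` | MCCs for every parameter, CI bands, 50% inhibition runs |

A `stat1ple` command-line interface mirrors the stages
(`generate`, `simulate`, `fit`, `profile`, `overfit`, `sensitivity`,
`bands`, `run`, `report`); `stat1ple run --out out/` executes the reduced
end-to-end workflow with a manifest of seeds and output hashes.

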