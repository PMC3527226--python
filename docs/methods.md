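# Methods

## The model

The package implements a delay differential equation model of IFNγ-induced
STAT1 signalling in two pancreatic cell types: stellate cells (PSC), where
IFNγ drives a strong nuclear accumulation of STAT1, and carcinoma cells (PC),
where it does not. Eight state variables, all in arbitrary units (a.u.):

| state | meaning |
|---|---|
| `IIr` | active type II IFN receptor complex (JAKs lumped in) |
| `STAT1Uc`, `STAT1Un` | unphosphorylated STAT1, cytoplasm / nucleus |
| `STAT1Dc`, `STAT1Dn` | phosphorylated STAT1, cytoplasm / nucleus |
| `mSTAT1`, `mSOCS1` | STAT1 and SOCS1 mRNA |
| `SOCS1` | SOCS1 protein, the negative-feedback inhibitor |

Equations (dose *u* in ng/ml, rates per minute):

```
IIr'     = k_act·u·(R_tot − IIr) − k_inact·IIr
flux     = k_phos·IIr·STAT1Uc / (1 + k_inh·SOCS1)
STAT1Uc' = −flux − k_impU·STAT1Uc + k_exp·STAT1Un + k_tl_stat·mSTAT1 − d_stat·STAT1Uc
STAT1Dc' = flux − k_impD·STAT1Dc
STAT1Dn' = k_impD·STAT1Dc − k_deph·STAT1Dn
STAT1Un' = k_deph·STAT1Dn + k_impU·STAT1Uc − k_exp·STAT1Un − d_stat·STAT1Un
mSOCS1'  = k_tc_socs·STAT1Dn(t − tau_socs) − d_m_socs·mSOCS1
mSTAT1'  = b_m_stat + k_tc_stat·STAT1Dn(t − tau_stat) − d_m_stat·mSTAT1
SOCS1'   = k_tl_socs·mSOCS1 − d_socs·SOCS1
```

Phospho-STAT1 dimerization is collapsed into the phosphorylation step and all
phospho pools are counted in monomer equivalents, so total STAT1 is conserved
when synthesis and turnover are off — a property the tests exercise. SOCS1
feedback acts on the protein through the saturating factor
`1/(1 + k_inh·SOCS1)`; a structurally identical mRNA-feedback variant was
considered and rejected as indistinguishable at this data resolution.
Receptor deactivation (`k_inact`) and STAT1 protein turnover (`d_stat`) are
included with zero-permitted defaults, since neither is required for the
qualitative behaviour but both are biologically plausible.

Observation map (five measured channels):

- `pSTAT1_wb  = s_pstat·(STAT1Dc + STAT1Dn)` — phospho-STAT1 immunoblot;
- `STAT1_wb   = s_stat·(STAT1Uc + STAT1Un + STAT1Dc + STAT1Dn)` — total STAT1;
- `SOCS1_mrna = s_socs·mSOCS1`;
- `ratio_STAT1_nc  = v_nc·(STAT1Dn + STAT1Un)/(STAT1Dc + STAT1Uc)`;
- `ratio_STAT1D_nc = v_nc·STAT1Dn/STAT1Dc`.

`s_*` are arbitrary-unit immunoblot scaling factors estimated jointly with
the kinetics. `v_nc` is the cytoplasm:nucleus volume ratio: states are
*amounts* (so conservation holds without compartment bookkeeping), while
immunofluorescence quantifies *concentrations* (summed pixel intensity per
area), so the measured nuclear:cytoplasmic ratio is the amount ratio times
`v_nc`. This one geometric constant is what reconciles three observations
that are jointly impossible in a pure amount model: a measured late-time
phospho ratio near 3.5, nuclear import and dephosphorylation rates of
similar magnitude (`k_deph/k_impD ≈ 1`, as the identifiability analysis
finds), and insensitivity of nuclear phospho-STAT1 to the import rate. At a
flux steady state `STAT1Dn/STAT1Dc = k_impD/k_deph ≈ 1` in amounts; with
`v_nc = 3.5` (a typical cytoplasm:nucleus volume ratio for adherent cells)
the measured concentration ratio is ≈ 3.5, and because
`STAT1Dn ≈ flux/k_deph` the output is robust to `k_impD` at all times once
transport is fast. `v_nc` defaults to 1.0 (pure amount ratios) and both
ratio observables remain invariant under rescaling of all STAT1 species.

Ratio denominators below 1e-9 a.u. mark the observable undefined (NaN) at
that time point; `t = 0` is always undefined for the phospho ratio.

## Integration of the delays

Constant transcriptional lags are integrated by the method of steps: a single
scipy solver instance (LSODA by default; any `solve_ivp` method name works)
steps with `max_step` equal to the smallest positive lag, and every accepted
step's dense interpolant is appended to a history object from which
`STAT1Dn(t − τ)` is evaluated; history for `t < 0` is the basal state. Lags
below 1e-4 of the horizon are treated as the plain-ODE limit (they would
otherwise force pathologically small steps while being numerically
indistinguishable). Default tolerances are rtol 1e-8 / atol 1e-10; fitting
uses rtol 1e-7 for speed. Two independent cross-checks guard the integrator:
a second solver family at tighter tolerance (agreement to 1e-6 of each
state's scale), and a linear-chain (Erlang-stage) approximation of the lags
that converges to the constant-lag solution as the order grows (order 20
agrees within 2% on the default grid). States more negative than
max(1e-8, rtol) times the trajectory scale abort with an integration error;
smaller undershoots are clipped to zero.

## Estimation

The cost is the chi-square: the double sum over observables and time points
of squared sigma-normalized residuals — the maximum-likelihood objective for
independent Gaussian measurement errors. A record whose model observable is
undefined at its time point contributes an error, never a silent skip.
Estimation is a hybrid multistart: each restart draws a uniform start in the
log10-transformed bounding box (delays stay linear with lower bound 0), runs
a Metropolis simulated-annealing stage (geometric cooling, default 200
steps, proposal SD 0.1 of the box width, initial temperature set by the
start cost), then polishes with scipy's trust-region-reflective
least-squares. The finite-difference Jacobian step is 1e-5 in internal
coordinates — deliberately far above the integrator's noise floor, without
which the local stage stalls on ODE problems. Default 50 restarts (reduced
in the analysis scripts; sizes below); ties within 1e-9 resolve to the
earliest restart; failed integrations cost +infinity rather than aborting a
restart; if no restart converges the result says so explicitly.

## Identifiability

Profiles re-minimize all other parameters while the target walks away from
the optimum in log10 space, warm-started from the neighbouring grid point
with a 5-restart cold fallback. Steps adapt toward delta-chi2 increments of
0.1× the largest threshold, clamped to [1e-3, 0.3] decades with at most 100
steps per direction; a step that overshoots twice the target increment is
retracted and halved so threshold crossings are finely resolved (without
this, CI interpolation error is first-order in the step). A re-minimization
that beats the anchor by more than 1e-3 re-anchors the optimum and restarts
the profile (at most 3 times). CI bounds interpolate delta-chi2 linearly
across the crossing, in log10 of the parameter where applicable; an uncrossed
side reports the explored endpoint plus an explicit unbounded flag, never an
extrapolation. Classification: identifiable (both bounds finite), structurally
nonidentifiable (profile below 0.01× threshold over the whole explored
range), practically nonidentifiable (rises but stays uncrossed on at least
one side); a side lost to numeric failure yields `indeterminate`.
Correlations along a profile are ordinary least squares on
(log10 profiled, log10 co-fitted) over in-CI points, flagged unreliable when
the co-fitted value sits at a bound on more than half of them. Trajectory
bands simulate parameter sets (profiled value plus co-fitted partners) evenly
spaced along the in-CI portion, the best fit always included.

The linear-Gaussian closed form is the primary oracle: for `y = a·t` with
known sigma the profile CI must match the Wald interval (the likelihood is
exactly quadratic), and the tests require agreement to 1% of the standard
error. A constructed `p1·p2` model validates the structural-nonidentifiability
path and the slope −1 correlation.

## Overfitting and effective degrees of freedom

The overfitting statistic of a randomized dataset is the chi-square (against
the *original* data) of the parameters fitted to the randomized copy, minus
the original best-fit chi-square. Randomization is a per-point parametric
bootstrap: each value is redrawn from a Gaussian centred on the original
value with that record's measurement sigma. The per-series-moments reading
("same mean and SD" applied to whole series) is implemented behind
`mode="series_moments"` and flagged experimental: only the per-point
construction makes the statistic follow its exact chi-square-p law for
linear models, which is the property the validation leans on. Effective dof
is the chi-square law with minimal Kolmogorov–Smirnov distance to the
empirical sample (ties to the smaller dof, at least 100 samples required,
an all-zero sample flagged degenerate); a formal distance is used because a
by-eye density comparison is not reproducible. Re-evaluating the chi-square
CDF at a fixed threshold with a smaller dof yields a strictly higher
confidence level — the mechanism by which the reduced pipeline's 68%
simultaneous threshold certifies ~88% on the PSC-like run in `analysis/04`.
Refits of randomized data reuse the main settings with restarts reduced
(default 10; 1 with a warm start at the original optimum in the reduced
runs), a tractability knob that leaves the linear-model law exact.

## Sensitivity

The time-dependent metabolic control coefficient of parameter p on variable
x is `(p/x(t))·(Δx(t)/Δp)`, realized as a one-sided finite difference with
the headline −1% perturbation; `x` below 1e-9 a.u. masks the point (reported,
never interpolated; `t = 0` is always masked for STAT1Dn). Parameters that
provably cannot reach the variable (static reachability through the reaction
graph) return an exact zero series. Bands over parameter uncertainty
evaluate the coefficient for 20 parameter sets evenly spaced along the in-CI
profile, reusing co-fitted partners; even spacing in profiled value was
chosen over spacing in delta-chi2 to match the equal-distance construction
of the trajectory figures.

The independent oracle is a forward-sensitivity integration: the state is
augmented with `s = dx/dp` and the sensitivity right-hand side — including
the delayed sensitivity terms — is obtained exactly by complex-step
differentiation of the model right-hand side (step 1e-100, no subtractive
cancellation), within the same method-of-steps machinery. Delay parameters
are outside this construction (the derivative with respect to a lag involves
the delayed time derivative) and are validated by the finite-difference
convergence test instead. One numerical caveat is load-bearing: the
one-sided difference carries a truncation bias of
`((1+δ)^C − 1)/(Cδ) − 1 ≈ (1+|C|)·|δ|/2` for a locally power-law response,
which is ≈1.005% at δ = −0.01 when C ≈ −1 — right at a naive 1% agreement
budget. The validation therefore compares at δ = −0.005 (bias ≈0.5%),
asserts separately that the δ = −0.01 deviation equals the truncation-bias
model to 0.2%, and checks that the gap to the exact derivative halves from
δ = −0.02 to −0.01 to −0.005.

## Synthetic data and the presets

No public machine-readable time series exist for this system, so a generator
stands in for them and defines the data regime: independent Gaussian
noise around model observables, sparse irregular sampling (11–12 points per
observable over 0–540 min, denser before 120 min), one 100 ng/ml dose, and
per-record sigmas defaulting to 10% of the observable's series maximum with
a 5% floor — typical immunoblot error magnitudes, a convention rather than
an estimate. Values are left untruncated; negative draws are legitimate
measurement noise. What the generator does **not** emulate: blot-to-blot
batch effects, non-Gaussian error tails, correlated errors within a gel, and
cell-to-cell heterogeneity behind the immunofluorescence averages — so
passing tests certify the algorithms under the stated error model, not
robustness of the original biological conclusions to violations of it.

Preset calibration (once, by forward simulation; all values in the table in
`data.py`): both cell types share the biochemistry of the
STAT1/SOCS1 branch and `v_nc = 3.5`. The PSC-like set has fast receptor
activation (`k_act·dose = 0.5/min`), fast balanced nuclear transport
(`k_impD = k_deph = 2.0/min`) and slow export (`k_exp = 1e-3/min`), so
phosphorylated STAT1 equilibrates within minutes, the measured phospho ratio
sits at `v_nc·k_impD/(k_deph − λ) ≈ 3.5` (λ ≈ 0.002/min is the slow decay of
the phosphorylation flux as the cytoplasmic pool depletes), and
dephosphorylated STAT1 accumulates in the nucleus, driving the total-STAT1
ratio above 2. The PC-like set has 25-fold slower activation, 10-fold slower
import with fast dephosphorylation (`k_deph/k_impD = 5`) and fast export, so
phosphorylation proceeds but STAT1 stays cytoplasmic (total ratio < 0.3).
Initial conditions come from the turnover/shuttling steady state
(`consistent_initial_stat1`), making the unstimulated model an exact
equilibrium.

## Problem sizes in the shipped runs

The analysis scripts and tests run deliberately reduced designs, chosen as
the smallest sizes at which every qualitative conclusion is stable: 5 free
parameters (transport/activation block) with 8 restarts for the main fits;
profile walks capped at 60 steps per direction; 150 randomizations for the
pathway overfitting run and 1000 for the linear-model law checks; 20
parameter sets per MCC band. The full-size defaults (50 restarts, 400
randomizations, 100 profile steps) remain the package defaults.

## Known limitations

- The reconstruction is calibrated to synthetic data; absolute parameter
  values are illustrative, and only the relations the identifiability
  analysis exposes (products, ratios, CI contrasts) carry meaning.
- Profile walks inherit the usual PLE caveat: a warm-started local refit can
  track a secondary valley; the re-anchoring rule catches improvements but
  not disconnected optima.
- The effective-dof selection treats samples as i.i.d.; refits that share
  the warm start are weakly dependent in hard nonlinear regimes.
- Forward sensitivities are unavailable for the two delay parameters.
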