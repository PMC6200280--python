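# Methods

## The model

`pd1tcr` implements a deterministic kinetic model of the earliest
signaling events downstream of ligated TCR/CD3ζ, CD28 and PD-1
cytoplasmic domains, the stage probed by liposome-reconstitution FRET
experiments in which receptor tails are tethered to large unilamellar
vesicles and cytosolic kinases/adaptors are supplied in solution. The
system comprises 20 ODEs over species concentrations in nM with time in
seconds:

* **Lck** exists in five phosphoforms set by its activating (Y394) and
  inhibitory (Y505) tyrosines: unphosphorylated Lck_i, Lck_ya (pY394),
  Lck_yi (pY505), Lck_yiya (Y394 then Y505, still active) and Lck_pi
  (Y505 then Y394, closed and inactive). Only Lck_ya + Lck_yiya
  (`lck_active`) phosphorylate substrates. Interconversion is by
  auto-phosphorylation (first order) and by dephosphorylation catalysed
  by PD-1-bound Shp2 (mass action in the CP concentration).
* **PD-1** is phosphorylated distributively at two sites by active Lck
  (Michaelis–Menten). Shp2 binds singly and doubly phosphorylated PD-1
  with identical rate constants, forming the catalytically active
  complexes CP1 and CP2; free Shp2 has no catalytic activity. CP
  complexes self-dephosphorylate PD-1 (CP2 → CP1 → release), which is
  the negative feedback that lets Shp2 dissociate again.
* **Receptors**: CD3ζ and CD28 tails are phosphorylated by active Lck
  and dephosphorylated by CP (both Michaelis–Menten). Phospho-CD3ζ
  recruits Zap70, which Lck activates sequentially (Y315 then Y493);
  fully active Zap70 phosphorylates LAT; phospho-LAT binds Gads, Gads
  binds Slp76, and active Zap70 phosphorylates complexed Slp76.
  Phospho-CD28 binds PI3K.
* A phenomenological **saturation correction**
  `max(0, 1 − (PD1p1+PD1p2)/(Lck_T·k))`, k = 41, scales only the first
  PD-1 phosphorylation step. It reproduces the experimentally observed
  saturation of Shp2 recruitment with increasing PD-1 at fixed Lck. It
  is clamped at zero from below so the flux can never become negative
  (the regime PD1p1+PD1p2 > 41·Lck_T is otherwise undefined).

Unbound/unphosphorylated pools (free CD3ζ, CD28, Zap70, PI3K, Lck_i,
LAT, Gads, Slp76) are eliminated algebraically via conservation at every
RHS evaluation rather than integrated, so those totals are conserved
exactly by construction; the integrated PD-1 and Shp2 family totals are
conserved because their fluxes cancel term by term, and the integrator
is checked against 1e-6 nM drift at every stored point.

The 36 rate constants (defaults in
`src/pd1tcr/data/default_parameters.yaml`) are the model's calibrated
values; 13 have direct literature support, the rest were tuned to the
reconstitution data. One deliberate oddity is retained as printed:
`k_dp_cp2 = 5e-8 s⁻¹` makes the CP2 → CP1 route essentially inert on the
30-minute timescale (the dominant self-dephosphorylation route is
`k_d2_shp`).

## Simulation

Scenarios are integrated with LSODA (SciPy `solve_ivp`) at rtol 1e-8 and
atol 1e-10 nM; the RHS kernel is numba-compiled. These tolerances were
chosen so conservation drift stays below 1e-6 nM over 30 simulated
minutes, and halving them moves 30-minute readouts by far less than
0.1% (asserted in the test suite). Sub-tolerance negative undershoot is
clipped to zero inside the kernel for flux evaluation and scrubbed from
stored trajectories; negatives beyond 1e-9 nM are an error. The default
output grid is 200 even points on [0, 1800 s]; all endpoint reporting
uses t = 1800 s (30 min), the reporting convention of the underlying
experiments.

Initial conditions: ligated PD-1 starts unphosphorylated, Shp2 free, and
Lck split 25/25/25/25/0 (%) over Lck_i/Lck_ya/Lck_yi/Lck_yiya/Lck_pi,
matching phosphoform proportions measured in Jurkat T cells; Lck_pi
starts at 0. Without PD-1 this split leaves active Lck pinned at
50 ± 1% for 30 minutes, which the suite asserts.

Concentrations convert to vesicle surface densities via
d = N/σ, N = [P]·V·N_A, σ = [L]·V·N_A·f·a_L, with 1 mM lipid, exposed
fraction f = 0.526 and head area a_L = 0.65 nm² — i.e. ≈2.9
molecules/μm² per nM. Dose–response reporting uses the conventional
constant 2.9 exactly; the geometry-derived factor (2.925) is available
through `DensityConversionSpec`.

## Scenario catalogue

`builtin_scenario` encodes each benchmarked protocol: Shp2
binding-domain recruitment (all catalysis off), full-length Shp2
recruitment and its perturbation variants (no CP-mediated Lck
dephosphorylation; no PD-1 self-dephosphorylation), Zap70-vs-PI3K
engagement without PD-1, the no-Lck disengagement protocol (receptors
pre-phosphorylated and occupied, membrane-tethered Shp2 represented as
a clamped, non-exchanging CP2 pool with catalysis intact), the standard
dose–response concentration set (100 nM Lck and CD3ζ, 200 nM PI3K,
300 nM CD28/Zap70/Shp2/LAT/Gads/SLP76), and 2-D scan bases. Where a
protocol does not name a concentration, full-network scenarios fall
back to the dose–response set; the pure binding protocol leaves
uninvolved pools at zero (with catalysis disabled they cannot couple to
the readout). `random_scenario` draws pool totals uniformly (default
0–500 nM, the concentration band of the experiments) with an explicit
seed for property tests.

What the generator emulates — and does not: scenarios reproduce the
well-mixed reconstitution system with fixed totals. They do not model
ligand binding upstream of the cytoplasmic domains, membrane geometry,
Csk/CD45 regulation of Lck, expression feedback between TCR and PD-1,
or cell-to-cell variability; passing tests therefore validate the
deterministic network model, not in-vivo T-cell behaviour.

## Dose–response analysis

`scan_pd1` runs 30-minute endpoints over a PD-1 dose grid (default 0
plus 30 log-spaced doses from 1 to 10⁴ nM, wide enough to bracket the
shallowest curves), records the eight phospho-aggregates
(CD3ζ: CD3a+Zap70i+Zap70a1+Zap70a2; CD28: CD28a+PI3Kb; Lck pY505;
Lck pY394; Zap70 pY315; Zap70 pY493; LAT: LATa+Gadsa+Slp76i+Slp76a;
Slp76a) and normalizes each to its zero-PD-1 value. `fit_hill` fits
k·xⁿ/(IC50ⁿ+xⁿ) to the *inhibition fraction* (1 − normalized) versus
surface density, so IC50 is the dose of half-maximal dephosphorylation
and k the maximum inhibition — a reading that keeps k meaningful for
curves saturating below 100%. Fitting is bounded nonlinear least
squares (k ∈ (0, 1.2], n ∈ (0, 10], IC50 ∈ [1, 10⁵] molecules/μm²)
multi-started from five log-spaced IC50 guesses; an all-zero curve is
flagged non-identifiable rather than raised. Doubling the dose grid
moves fitted IC50s by well under 2%.

## Multi-parametric sensitivity analysis

Each module varies its parameters simultaneously within ±50% of
defaults by Latin hypercube (one sample per equal-width stratum,
independent per-parameter permutation, explicit seed). Per parameter
set, the chosen percentage readout (% bound Shp2, % bound PI3K, % active
Slp76) is recorded at 10 time points (180 s spacing on (0, 1800 s];
t = 0 is excluded as information-free) for 11 PD-1 doses (0 plus 10
log-spaced on [1, 1000] nM), and the overall error is the summed squared
deviation from the default-parameter reference. Sets with error strictly
below the ensemble mean are acceptable (ties unacceptable, for
deterministic behaviour); a parameter's K-S statistic is the two-sample
Kolmogorov–Smirnov distance between its acceptable and unacceptable
marginals. Module parameter lists: the 15-parameter Shp2-recruitment
set (PD-1 phosphorylation, CP formation/turnover, Lck auto-/de-
phosphorylation), plus the 6 CD28/PI3K constants for the 21-parameter
PI3K module; the Slp76 module varies all 36 minus those 6 and minus the
correction constant (29). Whether the published 29-parameter list
excluded the correction constant or another parameter is not stated;
the chosen list is recorded in result metadata. The error is computed on
percentage readouts (the units the sensitivity bar plots use), another
choice the source leaves open.

Ensemble runs integrate at rtol 1e-6 / atol 1e-8: classification is
driven by ±50% parameter effects, orders of magnitude above integration
error at these settings. The package default of 2000 sets keeps a
3-module analysis within minutes on one CPU and already reproduces the
reference ranking (k_a_pi3k; k_p1_zap; {k_p_pd1, k_a_shp}) and K-S
magnitudes; 20000 sets is the full-fidelity setting.

## Known limitations

* Deterministic only — no stochastic (SSA/Langevin) variant, hence no
  single-cell predictions.
* No upstream ligand-binding kinetics, spatial effects or Lck
  regulation by Csk/CD45.
* The saturation correction is phenomenological; outside the calibrated
  regime (PD1p1+PD1p2 approaching 41·Lck_T) it merely clamps to zero.
* Endpoints are fixed-horizon (30 min), not asymptotic steady states.
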