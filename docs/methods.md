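# Methods

## Kinetic model

The model is a deliberately minimal mass-action reconstruction of
proximal GPVI signalling containing every interaction the analysis
needs: receptor ligation by CRP, receptor-catalysed Syk activation,
Syk trans-autoactivation, TULA-2-catalysed dephosphorylation, c-Cbl-
mediated irreversible removal of active Syk, and receptor
down-regulation (a c-Cbl-dependent term plus a small constitutive
term). It is not a transcription of any published equation set; it is
this package's own reference network, chosen as the smallest mass-action
system that (a) contains the named regulators, (b) produces a single
interior phospho-Syk peak followed by decline under negative
regulation, and (c) lets copy numbers alone differentiate the species.

States are concentrations in mol/L: free receptor `R`, ligated receptor
`LR`, inactive Syk `S`, active (activation-loop phosphorylated) Syk
`Sp` — the observable — and Cbl-inactivated Syk `Si`. TULA-2 and c-Cbl
act as constant catalytic pools: neither is consumed, so their effect is
proportional to their concentration. `S + Sp + Si` is conserved exactly
by construction; the integrator preserves it to ~1e-15 relative.

**Ligand handling.** CRP enters only through the effective ligation
rate `k_on·[L]`, with `[L]` computed from the dose (default 10 µg/mL)
at a nominal 36 kDa molar mass. Because the dose is constant and
saturating in all reported experiments, the molar-mass constant trades
off exactly against `k_on` during calibration and has no independent
effect. Zero dose gives an identically zero phospho-Syk trajectory.

**Solver.** LSODA (stiff-capable) at rtol 1e-8 / atol 1e-12, output on
a regular grid (default 120 s at 0.1 s). Peak times in the 18–40 s
range need sub-second output resolution; halving the grid and
tightening tolerances tenfold moves the baseline time-to-peak by well
under 0.5 s. Negative excursions beyond 1000·atol abort the run;
smaller ones are clipped to zero. Time-to-peak is the earliest grid
time attaining the global maximum (earliest-tie rule, for determinism
on plateaus).

## Parameters

Copy-number baselines (copies/platelet; volumes human 7.4 fL, mouse
4.3 fL):

| protein | human | mouse |
|---------|-------|-------|
| GPVI    | 5000  | 5586  |
| Syk     | 2763  | 23286 |
| c-Cbl   | 2581  | 3241  |
| TULA-2  | 600*  | 21469 |

*Human TULA-2 was not quantified in the flow panel; 600 copies is a
model assumption, set well below the measured mouse pool on the view
that mouse platelets compensate for their larger Syk complement with a
proportionally larger phosphatase pool. This asymmetry is load-bearing
(see below), and is the single most important free choice in the model.

Rate constants ship in `data/default_rates.yaml`. The *structural* set
(`nominal_rates()`) consists of round values in 1/(µM·s): k_on 0.7,
k_off 0.05 s⁻¹, k_act 0.02, k_auto 0.35, k_tula 3.0, k_cbl 0.1, k_down
0.03, k_int 0.01 s⁻¹. These fix which dynamical regime each species
occupies. Calibration then fits one number: because every right-hand-
side term is linear in a rate constant, scaling all rates by γ rescales
time by 1/γ exactly, so fitting the absolute timescale to the human
experimental time-to-peak (34 s) is a one-dimensional Brent root find
(γ ≈ 0.449). Only human data enter the fit; the mouse window is held
out. The calibration is deterministic — no random initialization — and
re-running `calibrate_rates()` reproduces the shipped file.

**Why the species differ.** In the mouse platelet the TULA-2 sink
(`k_tula·[T]` ≈ 13× the human value) keeps the phospho-fraction small
and phospho-Syk quasi-statically slaved to receptor dynamics; peak
timing is then set by receptor ligation and down-regulation (hence the
mouse's earlier peak, via its higher c-Cbl concentration, and its
insensitivity to Syk copy number — a linear system's argmax does not
depend on the substrate pool). The human platelet sits much closer to
the autocatalytic threshold (`k_auto·[S]` comparable to the total Sp
sink), so relaxation is slow and the peak time shifts with the Syk
pool: ±50% Syk moves it by ~±3 s (|score| ≈ 0.09), while the same
perturbation moves the mouse peak by < 0.1 s.

## Virtual populations

"Normal range" variation is read as uniform on mean·(1 ± f) — the
stated figures are ranges, not SDs — with f = 0.12 (GPVI), 0.22 (Syk),
0.25 (c-Cbl); TULA-2 is fixed per species because no range is stated
for it. A truncated-normal option (half-range = 2 SD, truncated at the
range) is available behind `distribution="truncnorm"`. Each member
draws from a counter-based substream (`SeedSequence(seed,
spawn_key=(i,))`), so member *i* is identical whatever population size
is requested, and the unit deviate is drawn before the fraction is
applied, which makes the peak-time spread monotone in the fractions at
fixed seed. Default population size is 100 per species.

## Flow-cytometry quantification

The standard curve is an ordinary least-squares fit of geometric-mean
MFI on bead ABC, with a free intercept (forcing through the origin is
not assumed). Saturation is accepted when R² ≥ 0.95 ("close to 1" made
operational); below that the fit raises rather than returning a curve.
Platelet MFIs are inverted as `(MFI − control − intercept)/slope`,
floored at zero; the isotype-control MFI is subtracted before inversion
and recorded with the estimate. Replicates aggregate as mean ± SD.
One practical finding baked into the tests: quantifying a ~5 600-copy
protein against a panel whose lowest bead is 5 000 sites leaves the
estimate dominated by intercept noise (per-replicate CV ~30% at 5%
bead noise); a panel bracketing the analyte brings this to ~8%.

## SMLM cluster analysis

Localization tables (x, y in nm, photon count) are filtered strictly
(`photons > 500`), then clustered with DBSCAN at eps 25 nm and
min_pts 10, counting the query point itself — the common convention,
and the one the reference implementation used for cross-checking
follows. Border (edge) points are included and assigned
deterministically to the cluster of the lowest-index core point that
reaches them; the partition of *core* points is order-independent and
is verified against scikit-learn's DBSCAN on random instances. Cluster
area is the convex hull of the cluster's detections (zero for < 3 or
collinear points); density is detections/hull-area; zero-area clusters
stay in counts but are excluded from density statistics and logged.
Cluster metrics pool within technical replicates, and condition-level
means ± SD are taken across replicates (n = replicates, not fields of
view). ROI areas are external scalar inputs in µm²; no per-cell
segmentation is attempted.

## Synthetic data

The generators emulate the *structure* of each input class, not the
physics behind it:

- **Localization fields**: uniform cluster centers in a square ROI
  (default 12 µm², 30 clusters, ≥ 10 σ apart in well-separated mode; a
  hard mode allows overlap), isotropic Gaussian detections (σ 10 nm,
  matching typical localization precision; Poisson mean 60 per
  cluster), uniform background (2 /µm²), log-normal photon counts
  (median 1000, log-σ 0.5, so the >500 filter removes a nontrivial
  ~8%). No PSF, blinking kinetics, drift or multiple-emitter effects —
  passing recovery tests shows the analysis chain is correct, not that
  it is robust to those artefacts.
- **Bead panels**: exact line plus mean-one multiplicative log-normal
  noise per bead level.
- **Blot-like time courses**: a log-normal-shaped unimodal curve whose
  maximum sits exactly at the requested peak time, with multiplicative
  noise; used to exercise peak extraction on sparse samplings.

The shipped two-condition SMLM configuration gives the "mouse"
condition 2.7× the cluster count of the "human" condition in the same
ROI, with 1.3× cluster area (σ scaled by √1.3) and 1.2× detections per
cluster, mirroring the measured cross-species contrasts.

All generators are seed-deterministic and emit truth tables beside the
data.

## Problem sizes and determinism

Populations run at n = 100 per species (one LSODA solve ≈ 5 ms, so a
species population is ~1 s); recovery suites use 20–200 seeds per
statistic; DBSCAN oracle checks use 100 random instances of ≤ 200
points. Pipeline summaries serialize with sorted keys and full float
repr, so a fixed config + seed reproduces byte-identical JSON.

## Known limitations

- The network is a minimal reconstruction; it has no LAT/PLCγ2/calcium
  tier, no receptor clustering, no ligand depletion, and no spatial or
  stochastic effects. Its mouse predictions inherit the human TULA-2
  assumption above.
- The human population window is tuned only through the one-parameter
  timescale calibration; the window *width* is an emergent property of
  the structural rates and the stated copy-number ranges.
- Flow quantification assumes upstream gating and geometric-mean
  extraction are done; no FCS parsing or antibody-affinity modelling.
- ROI areas for clusters/µm² are taken as given; drawing ROIs is not
  reproducible computationally.
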