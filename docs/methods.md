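# Methods

## Scope and model

`pin1dyn` analyses the coupling between interdomain separation and
intradomain conformation in a two-domain protein. Three data streams are
supported: (i) NMR peak-intensity decay tables for transverse relaxation
rates and PREs, (ii) ¹⁵N R₂−R₁/2 rate tables for domain rotational
mobility, and (iii) multi-frame coordinate trajectories for distances,
contacts, gyration radii, and hydrogen bonds. Domain bookkeeping follows
the Pin1 convention (WW 1–39, linker 40–52, PPIase 53–163, boundaries
inclusive) but every boundary is configurable.

## Relaxation fitting

Peak decays are fitted to I(t) = I₀·exp(−R·t) by nonlinear least squares,
seeded from a log-linear regression on the positive intensities.
Non-convergent fits or non-positive rates yield a MISSING status rather
than a silent drop. The intensity noise σ is the RMS/√2 of paired
differences at duplicated relaxation delays, pooled over residues (the
default delay schedule is 4 (2×), 6, 8, 10, 12, 15, 20 (2×), 25, 30 ms).
Rate uncertainties are the SD of rates refit to `n_draws = 500` synthetic
decays generated from the fitted curve plus iid Gaussian noise; the Monte
Carlo SD agrees with the analytic information-matrix (Cramér–Rao) value to
well within 25% at the default schedule.

Units: rates are rad/s throughout (the field's convention for Γ₂); delays
are seconds internally, with milliseconds accepted in files via a
`delay_ms` column.

## Domain-mobility regression

Bound-state R₂−R₁/2 is regressed on apo-state values per domain by OLS
with an intercept (an intercept-free fit is available by flag). Linker
residues are reported but excluded from per-domain fits. Residues with
|internally studentized residual| > 2 are flagged as outliers but the fit
is **not** repeated without them — outliers here are the scientifically
interesting exchange-broadened residues, and they remain plotted against
the global fit. The J_eff(0)/τ_c conversion uses

    R₂−R₁/2 = (2C_N/3)(1 + 3D_IN/C_N)·J_eff(0),  τ_c = 5·J_eff(0)/2,

with C_N = (ω_N·Δσ_N)²/3 and D_IN = ((μ₀/4π)ħγ_Hγ_N/r³)² in SI units
(Δσ_N = −170 ppm, r_NH = 1.02 Å, 700.13 MHz ¹H field, CODATA constants).
Because typeset prefactor conventions vary across the literature, the
conversion is validated primarily by its exact round-trip identity
(τ_c → rate → τ_c to 1e-12 relative) rather than by absolute τ_c values;
the constants live in one auditable bundle (`constants.NMRConstants`).

## PRE analysis

Γ₂ = R₂,PARA − R₂,DIA with quadrature-summed uncertainties. Peak-detection
statuses are assigned from per-residue maximum intensities: OVERFLOW iff
the DIA peak exceeds k·noise_floor (default k = 3) while the PARA peak does
not; MISSING if absent in both. OVERFLOW values never enter threshold
statistics — a fully broadened peak has no finite rate and would dominate
any mean — and are instead reported qualitatively (always "significant").

The significance threshold is the three-pass trimmed rule: compute M1/STD1
(sample SD, ddof = 1) of all finite values and drop values strictly outside
M1 ± STD1; repeat with M2/STD2; the threshold is M3 ± 2·STD3 of the final
core. Values exactly at a filter bound are kept (with an ulp-scaled slack
so exact ties never vanish to rounding), and final significance is strict
(> upper, or outside [lower, upper] for difference profiles, which are
generally asymmetric about zero). This rule presumes the spread of the
*true* background PREs dominates measurement noise; under pure iid noise a
2-SD trimmed threshold would flag ~25% of residues, so high-noise data
should not be classified this way (see the synthetic-data section).

The forward model is the Solomon–Bloembergen transverse PRE for a nitroxide
label (S = ½), with the unit-system prefactor configurable (SI default,
(μ₀/4π)²) and τ_c optionally composed as 1/τ_c = 1/τ_R + 1/τ_elec.
Ensemble averaging substitutes ⟨r⁻⁶⟩ = Σ w_f·r_f⁻⁶; by Jensen's
inequality this never underestimates the value at the mean distance. The
spin-label position is proxied by a Cα site rather than an explicit
nitroxide rotamer.

## Trajectory geometry

Heavy atoms are all non-hydrogen atoms; contact numbers count heavy-atom
pairs (one per residue) within 4.5 Å, cutoff inclusive. Fluctuating pairs
are same-domain pairs with nonzero count variance; sequence-adjacent pairs
are eligible, with the ≥3-residue separation recorded as a flag.
Hydrogen bonds require donor-heavy→acceptor distance ≤ 3.2 Å and a
D–H···A angle ≥ 135° (180° linear), keyed per (donor-H, acceptor atom);
the per-residue-pair metric Π_XY sums the per-bond occupancies. Centers of
mass and gyration radii are mass-weighted by default (unweighted by flag)
using standard atomic masses. All observables are invariant under rigid
transforms to 1e-9, and contact counts and Π_XY are monotone in their
cutoffs.

## Correlation statistics

Pearson r uses the standard product-moment formula, clipped to [−1, 1]
against rounding; degenerate (zero-variance) series raise or are reported
as excluded, never silently dropped. SE_r = √((1−r²)/(N−2)). The null
probability P_N(|r| ≥ r₀) is evaluated two ways — adaptive quadrature of
the null density (with a log-gamma prefactor and a split integration range
so the ~N^(−1/2)-wide peak cannot be missed) and the exact two-sided t-tail
with N−2 df — and the evaluation errors out if they disagree beyond 1e-6
absolute. N is always taken from the data, never from a constant. Frames
are treated as independent samples; no autocorrelation or effective-sample-
size correction is applied (a deliberate non-goal). The default
significance cutoff is |r| ≥ 0.05, inclusive.

Top-fraction selection takes the ceil(n·fraction/2) largest positive
coefficients by value plus the ceil(n·fraction/2) largest-magnitude
negative coefficients, capped by each side's population, with
deterministic tie-breaking by (|r| desc, labels lexicographic).

## Two-cluster analysis

Frames are clustered on a scalar interdomain distance (default: the
Cα–Cα distance between the label site and its strongest PRE responder) by
agglomerative average linkage cut at two clusters. On a line, the
unweighted average pairwise distance between disjoint clusters equals the
difference of their means and cluster means stay ordered under merging, so
the closest pair is always adjacent in sorted order; the implementation
exploits this for an exact O(n log n) path verified label-for-label
against naive pairwise-matrix linkage. Ties break by lower sorted
position. Series longer than 50,000 points are deterministically strided
before linkage (labels propagated by the cluster-mean midpoint), with the
stride recorded in the output. Cluster labels are COMPACT (lower mean) and
EXTENDED (higher mean); contrasts report EXTENDED − COMPACT differences of
per-cluster mean contacts and H-bond occupancies recomputed over member
frames.

## Synthetic-data design

The generators capture the statistical structure of the real inputs, not
force-field physics. The two-state ensemble is a 52-residue toy chain
(WW-like 1–20, 2-residue linker, PPIase-like 23–52; N/H/CA/C/O/CB beads,
8 Å residue spacing so non-designed pairs never touch). Each frame draws a
Bernoulli(p_compact) state (default 0.5) that simultaneously sets:

* the interdomain separation — Gaussian with means 32.7 / 50.1 Å
  (compact / extended, matching the two-cluster geometry) and 2 Å jitter,
  truncated at 3 SD below the compact mean so close-approach distances stay
  physical; a reporter Cα pair tracks the separation exactly;
* the WW hinge — designed mobile residues dock onto partners in their
  assigned state, producing integer-valued state-dependent contact counts
  and a designed N–H···O bond (2.9 Å, linear). EXTENDED-closing pairs dock
  toward the domain centroid and the COMPACT-closing pair away from it, so
  the WW gyration radius genuinely anticorrelates with separation;
* PRE geometry — the spin-label proxy sits at residue 2; two PPIase
  residues protrude to ~10.5 Å from the label in the compact state, WW
  neighbours sit at 8–16 Å (the 8-Å neighbours and the label site itself
  broaden beyond detection), and everything else stays ≥ 24 Å.

For a two-state mixture with state means (x₁,y₁)/(x₀,y₀) the implied
Pearson correlation has a closed form
(cov = p q Δx Δy, var = p q Δx² + σ², …); the generator stores this as the
planted truth and tests verify it against an independent moment
computation to 1e-12.

The PRE experiment generator produces PARA/DIA decay tables whose true
PREs come from the ensemble-averaged ⟨r⁻⁶⟩ of each residue's amide proton
to the label (τ_c = 5 ns, R₂,DIA = 40 rad/s, I₀ = 100). Its default noise
emulates high signal-to-noise spectra (σ = 0.1, i.e. 0.1% of I₀) so that
the trimmed-threshold classification reflects geometry rather than
spectral noise — consistent with the rule's structure-dominated-background
assumption above. The planted significant set is defined as the
classification of the *noiseless* true-Γ₂ profile under the identical
rule; the end-to-end test then checks that noise and fitting leave this
classification unchanged. Rate-recovery and Monte-Carlo studies use the
noisier σ = 2% of I₀ condition.

What passing these tests shows — and does not. Recovery on this toy
demonstrates the estimators' correctness and calibration under the planted
statistical structure (two-state exchange, r⁻⁶ distance weighting,
state-dependent contacts). It does not validate force-field accuracy,
spin-label rotamer behaviour, autocorrelated frame sampling, anisotropic
tumbling, or chemical-exchange contributions to rates — all outside the
generators' model.

## Problem sizes and numerical choices

Default test-time problem sizes are chosen for desk-scale runs: ensembles
of 600–2,000 frames (the correlation-recovery checks use the full
N = 22,400 series, which are cheap to draw), 200-replicate recovery loops,
and 500-draw Monte Carlo. Tolerances: 1e-12 for algebraic identities, 1e-9
for geometric invariances, 1e-6 for the quadrature/t-tail agreement, and
read/write round trips preserve values to 1e-9. Degenerate inputs
(constant decays, zero-variance series, identical cluster values, empty
selections) raise informative errors rather than propagating NaNs.

## Known limitations

* The combined-CSP weighting convention is implemented as (0.154·Δδ_N)², with
  the alternative 0.154·Δδ_N² exposed by flag, since both appear in the
  literature.
* The fluctuating-pair rule is variance > 0; with finite trajectories this
  is sensitive to rare contacts, and real-data pair counts will depend on
  trajectory length.
* P_N assumes independent frames; with 200-ps snapshot spacing this
  overstates the effective N for slowly decorrelating observables.
* The 1-D linkage fast path applies only to scalar clustering variables;
  multidimensional clustering is out of scope.
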