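# pin1dyn

Analysis tools for **coupled intra- and interdomain dynamics in two-domain
proteins**, built around the Pin1 prototype: an N-terminal WW domain
(residues 1–39) flexibly tethered to a C-terminal peptidyl-prolyl isomerase
(PPIase) domain (residues 53–163). The package is aimed at NMR
spectroscopists and simulators who want to quantify transient interdomain
contacts from paramagnetic relaxation enhancements (PREs) and relate them to
intradomain conformational fluctuations observed in MD trajectories.

## What it computes

**PRE quantification.** Amide-proton transverse PREs are rate differences
between a spin-labelled (PARA) and diamagnetic-reference (DIA) sample,

    Γ₂(¹Hᴺ) = R₂,PARA(¹Hᴺ) − R₂,DIA(¹Hᴺ),

with rates from monoexponential fits of peak-intensity decays,
uncertainties by Monte Carlo resampling of the replicate-based noise, and
fully broadened ("disappeared") peaks carried as qualitative OVERFLOW
entries. Significance thresholds come from a three-pass trimmed mean/SD
procedure (filter outside M1 ± STD1, then M2 ± STD2; threshold
M3 ± 2·STD3). The Solomon–Bloembergen forward model

    Γ₂ = K·S(S+1)(g μ_B γ_I)²/15 · ⟨r⁻⁶⟩ · [4τ_c + 3τ_c/(1+(ω_H τ_c)²)]

back-calculates Γ₂ from electron–proton distances with ⟨r⁻⁶⟩ ensemble
averaging over trajectory frames.

**Domain mobility.** Per-domain linear regression of bound-state versus
apo-state ¹⁵N R₂−R₁/2 values (a per-residue measure of rotational
mobility, proportional to J_eff(0) = 2τ_c/5); a shallower slope for one
domain reports increased relative rotational mobility, i.e. weakened
interdomain contact. Combined amide CSPs use
Δδ_NH = √(Δδ_H² + (0.154·Δδ_N)²).

**Trajectory correlation statistics.** Per-frame interdomain distances
(atom, Cα, or domain center-of-mass), gyration radii, heavy-atom
interresidue contact numbers (pairs within 4.5 Å), and hydrogen-bond
occupancies (3.2 Å / 135° cutoffs; Π_XY = Σᵢ O_i,XY per residue pair).
Pearson correlations between contact-number and distance series carry the
standard error SE_r = √((1−r²)/(N−2)) and the exact null probability

    P_N(|r| ≥ r₀) = 2Γ[(N−1)/2] / (√π Γ[(N−2)/2]) ∫_{r₀}^{1} (1−r²)^{(N−4)/2} dr,

evaluated by adaptive quadrature and cross-checked against the equivalent
t-tail with N−2 degrees of freedom. Frames are partitioned into
compact/extended sub-ensembles by exact 1-D average-linkage clustering on a
scalar interdomain distance, and per-cluster contact/H-bond contrasts are
reported.

**Synthetic data.** Seeded generators emulate every input: noisy
monoexponential decay tables, PARA/DIA pairs with overflow peaks, and a
two-domain bead trajectory with a latent compact↔extended exchange that
plants known inter/intradomain correlations, state-dependent contacts, and
H-bond triads — all with recorded ground truth for recovery tests.

## Worked example

Null significance of a correlation magnitude at trajectory size N = 22,400:

```console
$ pin1dyn pn --r0 0.014 --n 22400
P_N = 0.0361431 (3.6%), SE_r = 0.00668183
```

i.e. two *uncorrelated* series of 22,400 frames produce |r| ≥ 0.014 (twice
the standard error) only 3.6% of the time; the package's default
significance cutoff |r| ≥ 0.05 (~7·SE_r) is far more conservative.

Full synthetic pipeline from one config file (simulate → fit rates → PRE →
threshold → contacts/distances → correlate → cluster → contrast):

```console
$ echo "n_frames: 2000" > config.yaml
$ pin1dyn --seed 1 --out-dir out pipeline --config config.yaml
{
 "threshold": {"m3": 0.0077, "std3": 0.2295, "upper": 0.4667, "lower": -0.4513},
 "significant": [1, 3, 4, 5, 26, 27],
 "overflow": [2],
 "fluctuating_per_domain": {"WW": 3},
 "cluster": {"mean_compact": 32.71, "mean_extended": 50.08,
             "sizes": {"COMPACT": 1002, "EXTENDED": 998}},
 "rg_vs_separation_r": -0.975,
 "all_signs_ok": true
}
```

Reading the output: the trimmed threshold (upper bound 0.47 rad/s) flags
exactly the residues the generator placed near the spin label — WW-domain
neighbours (1, 3, 4, 5) and the two PPIase residues that approach the label
in the compact state (26, 27); the label site itself (residue 2) is fully
broadened (overflow). The two-cluster partition of the reporter distance
recovers the designed 32.7 / 50.1 Å state means, the WW gyration radius
anticorrelates with interdomain separation (r = −0.975, the domain
compacts as the domains separate), and every designed contact pair's
correlation with separation carries its planted sign.

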