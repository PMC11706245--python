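# Methods

## The model

The system is a codon:anticodon triplet inside the ribosomal preinitiation
complex P-site, reduced to its three base-pair distances d₁, d₂, d₃
(angstrom), sampled on 4.0 ≤ dᵢ ≤ 9.0.  The energy (kJ/mol) is

    U(d₁,d₂,d₃) = Σᵢ wellᵢ(dᵢ) + stack(d₁,d₂) + stack(d₂,d₃) + wall(d₁)

with three ingredients, each mapping one-to-one onto a mechanism of start-codon
selection:

* **Pairing wells** — Morse form εᵢ[(1 − e^{−aᵢ(d−d₀ᵢ)})² − 1], minimum −εᵢ at
  d₀ᵢ = 5.0 Å, zero at large separation.  The depth encodes how well the codon
  base pairs the anticodon base at that position: cognate Watson–Crick pairs
  are deep (10 kJ/mol), mismatches shallow (3.8–5 kJ/mol), graded C > G > U at
  the first position.
* **Stacking coupling** — a negative bivariate Gaussian
  −J·exp(−[(dᵢ−d₀ᵢ)² + (dⱼ−d₀ⱼ)²]/2σ²) on adjacent pairs, rewarding
  simultaneous closure of neighbouring base pairs.  Pseudouridine at the
  second codon position raises J from 4 to 7 kJ/mol (Ψ:A stacks more strongly
  than U:A); this is the sole difference between CΨG/GΨG and CUG/GUG.
* **Steric wall** — a one-sided harmonic κ(d_w − d₁)² for d₁ < d_w = 5.4 Å,
  standing in for the eIF1 β-hairpin (N34) clash with bulky first-position
  bases.  κ is graded by base bulk (C 3, G/U 6, 5mC 12 kJ/mol/Å²); an A first
  base sees no wall and instead gains a +2.5 kJ/mol well-depth bonus (eIF1
  stabilizes cognate first-position pairing).  `*_noeIF1` preset variants
  remove both the wall and the bonus.

The energy scale was chosen so that U varies by at most a few k_BT across one
0.5 Å bin wherever the probability mass is appreciable: that is the regime in
which a per-bin histogram estimator can resolve the landscape, and it is what
makes every estimator in the package verifiable against quadrature.  The
parameterization reproduces, by construction (verified through the oracle),
the qualitative codon hierarchy: AUG strongest; CUG > GUG > UUG among
near-cognates; Ψ rescues, 5mC penalizes; removing eIF1 stabilizes the
wall-carrying codons and destabilizes AUG.  Absolute ΔG values are properties
of this coarse-grained model, not predictions for the all-atom complex.

Units: energies kJ/mol, distances Å, k_B = 0.0083145 kJ/mol/K, T = 310 K
(k_BT ≈ 2.577 kJ/mol).  Mass and time are reduced units.

## Two tiers

* **direct-CV** (primary test surface): overdamped Langevin dynamics directly
  on (d₁,d₂,d₃).  The stationary density is exp(−U/k_BT) exactly — times a
  dᵢ² density-of-states factor per coordinate when the Jacobian flag is on
  (off by default, so the PMF equals U) — which is what makes a brute-force
  oracle possible.  The integrator is the Leimkuhler–Matthews averaged-noise
  scheme x′ = x + (Δt/γ)F + σ(ξₙ+ξₙ₊₁)/2, whose stationary-density bias is
  O(Δt²); with the default Δt = 2×10⁻³ and γ = 2 the per-step RMS displacement
  is ≈0.07 Å.
* **cartesian-beads** (realism tier): six beads in 3D, bead pair (i, i+3)
  realizing dᵢ, integrated with BAOAB.  With γ = 0 and T → 0 BAOAB reduces to
  velocity Verlet, which the energy-conservation test exploits (drift
  < 10⁻³ kJ/mol over 10⁵ steps on a harmonic system).

One-sided harmonic restraints (400 kJ/mol/Å²) just outside [4, 9] Å keep the
coordinates near the grid; excursions are allowed but never accumulated, and
the restraint energy is excluded from reported U.

## ABF estimator

Bins are half-open [lo, lo+Δd) with the top edge closed; the default grid is
10×10×10 = 1000 bins.  Each in-range step deposits the instantaneous
generalized force −∂U/∂dᵢ (plus 2k_BT/dᵢ when the Jacobian flag is on) into
S(b) and increments N(b); the applied bias is the ramped running mean
−min(1, N/N_full)·S/N with N_full = 200 samples/bin.  Bias application and
accumulation both happen every step.  Out-of-range samples are discarded and
counted separately (ΣN + discarded = total accumulated steps).

Two choices matter for accuracy and are documented as this package's own:

* **Unbiased burn-in** — the first 5% of steps run without bias or
  accumulation (stand-in for an equilibration phase).
* **Histogram reset** — at 10% of the accumulation phase, per-bin counts are
  capped at N_full while the learned mean forces are retained.  Early samples
  are collected before the bias has flattened the landscape and pile up in
  the wells; without the reset they dominate the final histogram and bias
  ΔG_binding by ~2 kJ/mol on the shipped presets.

## Probability reconstruction and free energies

`probability_from_state` reweights each bin's count by exp(−A_bias(b)/k_BT),
where A_bias integrates the final applied bias force field over the grid
(least-squares solution of ∇A = F_bias on the occupancy mask; the mask must
be connected).  For an unbiased run this reduces exactly to the raw
normalized histogram.  G = −k_BT ln P is min-shifted to zero with
never-visited bins masked (NaN sentinel).  2D surfaces marginalize P first
and only then take −k_BT ln (never averaging G directly).

Region free energies use −k_BT ln ΣP over bins fully inside the window
(Boltzmann-weighted region population — the standard statistical-mechanical
state free energy, not the mean of bin G values).  Windows must align to bin
edges; the bound window is [4,6]³, the unbound [7,9]³, and the 6–7 Å shell
belongs to neither.  ΔG_binding is computed from the five-trial-averaged P
(per-trial values are reported alongside for transparency); ΔΔG subtracts the
AUG reference computed with identical grid, windows, k_BT and trial count.

`free_energy_from_mean_force` integrates −⟨F⟩ the same way and is the
independent route used for cross-validation.  The two routes agree to
< 0.5 kJ/mol RMSE on the smooth diagnostic system (shallow wide wells,
5 trials × 4×10⁶ steps).  On the codon presets the steep inner repulsive
bins (d around 4.0–4.5 Å, where the gradient traverses >100 kJ/mol/Å within
one bin) make bin-center values and bin integrals genuinely different
objects; disagreement concentrated there reflects the 0.5 Å binning, not an
estimator defect, and the bound/unbound region sums are insensitive to it
because those bins carry negligible probability.

## Convergence statistic

L(τ₁,τ₂) = Σ_b [P(b;τ₁) − P(b;τ₂)]² between checkpoint probability grids
(computed by the same reweighting route, frozen at checkpoint time).  L is
symmetric, non-negative and exactly zero for identical grids.  On the
documented converged run (AUG, 4×10⁶ steps, checkpoints at 25/50/75/100% of
accumulation) L(τ_k, τ_final) trends downward; because adjacent checkpoints
are both noisy estimates, a single-step rise is tolerated if it is smaller
than 10% of the running maximum level.

## Study conditions and problem sizes

The production protocol is five trials per preset (trial t uses seed
master + t), 2×10⁶ steps per trial on the 10³ grid — about 0.35 s per trial
on one CPU with the compiled kernel, ~35 s for the full 18-preset sweep.
These sizes were chosen so the count-statistics error of the five-trial
ΔG_binding (≈0.2 kJ/mol SD, ≈0.35 kJ/mol systematic) sits well inside the
1 kJ/mol oracle-agreement tolerance while the whole validation suite stays
interactive.

## Structure metrics

Average structures are independent per-coordinate arithmetic means over all
snapshots whose CVs lie inside a representative window (inclusive bounds on
both sides; default the bound state (4.5, 4.5, 4.5) ± Δd/2).  No structural
alignment is applied before averaging (an optional Kabsch superposition
pre-step exists but is off by default); because independent averaging can be
skewed where fluctuations are large, particles whose coordinate standard
deviation exceeds 1.5 Å are flagged.  Base-pair centers are midpoints of the
designated particle pair — the two beads of a position on the toy tier
(written as C1′ pseudo-atoms in PDB output, a convention, so the C1′-midpoint
rule applies uniformly to imported full-atom structures) — and the
inter-base-pair pitch is the Euclidean distance between consecutive centers.
Direct-CV states are embedded as 3D bead coordinates with a 3.4 Å helical
rise for visualization; the embedding preserves the pair distances exactly.

## Synthetic cytometry and the expression link

The generator emulates a two-colour reporter experiment: per cell, a common
log-normal size factor (log-SD 0.458) multiplies both channels, each channel
adds its own log-normal noise (log-SD 0.2, total per-channel spread 0.5), and
the construct's programmed efficiency sets the median GFP/iRFP ratio.  5% of
cells are dead and 5% iRFP-negative so gating (live AND iRFP strictly above
threshold) is exercised.  It does not emulate spectral spillover,
autofluorescence, instrument drift, or cell-cycle structure — passing tests
show the quantification rule is implemented correctly, not that real
cytometry is this clean.

Translation efficiency is 100 × median(GFP/iRFP) / median(control GFP/iRFP).
The linkage stage regresses frequency on ΔΔG; the log transform is the
default because on a Boltzmann-consistent table f ∝ exp(−ΔΔG/k_BT) it
recovers slope −1/k_BT with r = −1 exactly (the linear transform is
first-class for sensitivity analysis).  The shipped expression table is a
synthetic fixture generated from the presets' oracle ΔΔG at k_BT(310 K); its
perfect rank correlation with the penalties is a property of that
construction, stated as such in the tests.

## Known limitations

* The coarse-grained energy scale is ~2–3× softer than all-atom pairing
  energetics; ΔΔG spans ~1–8 kJ/mol rather than tens.  Orderings, not
  magnitudes, are the claim.
* The count-reweighting estimator has a residual systematic of ≈ +0.3 kJ/mol
  at the production timestep (within-bin effects of the piecewise-constant
  bias force); it is included in the verified oracle-agreement margin.
* The mean-force route inherits a within-bin sample-weighting bias in steep
  bins and is used for cross-validation, not for headline numbers.
* Five-trial averaging is across independent seeds of the same model; there
  is no across-model (force-field) uncertainty, and no error bars beyond the
  across-trial spread are provided.
* External CV series or probability/mean-force grids can be imported
  (TSV/OpenDX), but the atom-to-atom anchoring of the three distances in any
  external all-atom data is the user's convention to supply.
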