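# Methods

## The model

`deltasolv` implements a delta-learning strategy for implicit solvation.
The premise: continuum solvent models (generalized-Born on the classical
side, CPCM-style dielectric continua on the electronic-structure side) are
accurate at long range but miss the discrete structure of the first solvent
shell — the *explicit-solvent effect*. A force model trained against
explicit-solvent reference forces captures that effect on classical solutes;
its deviation from the matching continuum description,

    ΔΔG_corr(r) = ΔG_model(r) − ΔG_GB(r),
    F_corr(r)   = F_model(r) − F_GB(r),

is assumed transferable to a continuum-solvated electronic-structure
description of the same molecule. Adding it to a continuum-QM backend gives
the combined free-energy surface

    G(r) = E_backend(r) + G_model(r) − G_GB(r) − T·S_vib(r),

with gradients and Hessians available term by term, so structures can be
optimized and thermochemistry evaluated directly on the corrected surface.
S_vib is the quasi-RRHO vibrational entropy of the combined Hessian
(backend Hessian plus the Hessian of the correction).

Key structural identity: if the learned model reproduces the GB model
exactly, the correction vanishes and every downstream quantity — energies,
forces, Hessians, optimized geometries, free energies — equals the bare
backend result bit for bit. The suite enforces this reduction law; it
guarantees the correction is purely additive and introduces no coupling
artifacts.

## Generalized-Born model

The GB term is a neck-corrected model of the HCT/OBC family:

* pairwise HCT descreening integrals over scaled, offset-reduced atomic
  spheres (offset 0.195141 Å),
* a neck correction `m0 / (1 + (r−d0)² + 0.3 (r−d0)⁶)` for the interstitial
  volume between atom pairs, scaled by 0.826836,
* tanh rescaling `R_i⁻¹ = ρ̃_i⁻¹ − ρ_i⁻¹ tanh(αΨ − βΨ² + γΨ³)` with
  per-element α, β, γ,
* the canonical GB cross term
  `f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j)))` with prefactor
  `−½ k_e (1/ε_in − 1/ε_out)`, summed over all pairs including the Born
  self terms.

Parameters (mbondi2-style radii, per-element descreening and rescaling
coefficients) ship in `data/gbneck2_params.yaml`. The neck pair constants
(d0, m0) are **not** literature look-ups: at setup the package integrates
the 1/r⁴ descreening kernel over the exact two-sphere solvent-excluded neck
region (probe 1.4 Å; the two-sphere accessibility test has a closed form)
on a cylindrical grid, scans the maximum over the separation, and caches
(d0, m0) per radius pair. This keeps the model self-contained and
documented; the functional form matches the published neck shape.

No nonpolar surface-area term is included: the correction is defined as a
difference of two polar solvation models, so the polar term is the operative
quantity. Gradients are fully analytic, including the chain through the
Born radii and the neck term; the suite checks them against central finite
differences at 1e-5 relative on 20 random systems. Hessians are central
differences of the analytic gradient (default step 5e-3 Å), which is
accurate to ~1e-4 relative — sufficient for quasi-RRHO entropies, and far
less error-prone than hand-derived GB second derivatives. The sulfur
descreening factor in the shipped refit set is negative (a quirk of that
parameterization); test fixtures therefore use H/C/N/O.

## The learned solvent model

The trainable reference model is a small invariant graph model written in
numpy. Per-atom descriptors are message sums over neighbours,
`s_{i,a,k} = Σ_j a_j g_k(r_ij)`, with source channels a ∈ {1, q_j, ρ_j} and
16 Gaussian radial bases under a cosine cutoff (8 Å). The readout basis per
atom concatenates (i) skip products {1, q_i, ρ_i} × s_{i,a,k} × {1, 1−1/ε}
and (ii) a fixed, seeded random tanh layer over
[s_i, q_i, ρ_i, 1−1/ε, one-hot solvent label]. The energy is the sum of
atomic readouts, **linear in the trainable coefficient vector**; positions
enter only through interatomic distances, so the energy is exactly
invariant and the analytic forces exactly covariant under rigid motions.
Force/energy consistency is verified to machine precision by complex-step
differentiation.

Because forces are linear in the coefficients, force-matching training is a
linear least-squares problem. `train_on_delta_forces` builds the force
design matrix over an 80/10/10 frame split, column-normalizes it, and runs
conjugate-gradient iterations on the ridge-regularized (λ=1e-9) normal
equations — one iteration per reported epoch, so the loss trace is
non-increasing and converges to the global optimum. Solvent identity enters
as the dielectric factor 1−1/ε plus a one-hot label embedding, the minimal
analog of a multi-solvent model.

The synthetic training field (`AnalyticSolventField`) is a sum of Gaussian
pair bumps with amplitude `(1−1/ε)(c_qq q_i q_j + c_rr ρ_i ρ_j + c_const)`
— within the span of the skip features up to radial-basis resolution, so
noiseless recovery to well under 5% of the target force RMS is an exact
property of the construction, not a tuned outcome; with label noise the
held-out error is bounded below by the noise floor. What this does **not**
demonstrate: transferability to real solvent mean forces, many-body terms
beyond pairwise structure, or chemistry outside the toy parameter ranges.

## Backends

The continuum-QM backend is a contract (energy, gradient, Hessian,
capability descriptor). Three deterministic surrogates support desk-scale
work: an anchored harmonic well (constant analytic Hessian; deliberately
frame-anchored so optimizer tests are deterministic, flagged via
`capabilities.anchored` — built from bond springs it is instead rigid-motion
invariant), a pairwise Morse potential, and a dielectric-scaled softened
Coulomb toy. An adapter seam shells out to an external engine and parses
plain-text energy/gradient files (eV, eV/Å); it is fixture-tested only and
never required.

## Optimization

BFGS on the combined energy with Armijo backtracking, a trust-style cap on
the step length (0.2 Å per atom RMS), convergence on the **maximum per-atom
force norm** (matching the per-force semantics of the quoted tolerance),
and an inverse-Hessian reset after 3 consecutive rejected steps. Default
tolerance 0.025 eV/Å = 2.41213 kJ mol⁻¹ Å⁻¹, converted once at the config
boundary. Accepted energies are monotone non-increasing by construction.

## Thermochemistry

Normal modes: mass-weighted Hessian, rigid modes projected out via an
orthonormalized translation/rotation basis (rank detection drops the
vanishing rotation of linear molecules, giving 5 instead of 6), spectrum of
the projected block, eigenvalues mapped to wavenumbers with negative
eigenvalues encoded as negative wavenumbers. A mode below −5 cm⁻¹ flags the
conformer as a non-minimum (the operational cutoff for the exclusion rule);
values in (−5, 0) are treated as numerical noise from the
finite-difference Hessian and floored to zero with a warning.

Quasi-RRHO entropy per mode interpolates `w·S_HO + (1−w)·S_FR` with
`w = 1/(1+(ω0/ω)^α)`, defaults ω0 = 100 cm⁻¹, α = 4, and free-rotor moment
regularized by `μ' = μB/(μ+B)`, B = 1e-44 kg m². One deliberate numerical
choice: per-mode free-rotor entropies are floored at zero. For stiff modes
the classical free-rotor expression is slightly negative (≈ −2 J mol⁻¹ K⁻¹
at 3000 cm⁻¹); although damped by w ≈ 1−1e-6, the leak is large relative to
the tiny harmonic entropy of such a mode and would spoil the harmonic
limit. The floor restores `S → S_HO` as ω ≫ ω0 and is physically motivated
— a mode's entropy contribution cannot be negative.

## Ensemble analysis

* **Pruning**: conformers sorted by ascending G; greedy retention iff the
  minimum all-atom RMSD (Kabsch superposition, no symmetry permutations) to
  every retained conformer exceeds the threshold (default 0.05 nm).
  Deterministic and idempotent.
* **Rotamers**: gauche iff the central dihedral lies strictly inside
  (−2.1, 2.1) rad, trans otherwise; the boundary value is trans (open
  interval).
* **Populations**: `w ∝ exp(−G/RT)` via log-sum-exp; R = 8.31446 J/mol/K;
  default T = 298.15 K with per-run override.
* **Balance statistics**: both ΔΔG series mean-centered per balance before
  the Pearson correlation and least-squares slope (scipy.stats); points
  that only bound the free energy (detection limits) are excluded first;
  negative slopes map to −∞ on the log scale.
* **IR spectra**: unit-area Gaussians (default σ = 5 cm⁻¹ — the width is
  stated ambiguously in Hz in parts of the literature; a cm⁻¹ reading is
  the operational choice and configurable) at each real frequency,
  population-weighted; mode intensities treated as constant (no dipole
  derivatives).

## Problem sizes and determinism

All shipped tests and the acceptance script run on toy systems (2–8 atoms,
tens of frames, ≤ 400 training epochs); the whole suite completes in well
under a minute on one core. Every stochastic input is generated from an
explicit seed; CLI runs serialize their full configuration into a manifest
and reruns are bit-identical for deterministic backends.

## Known limitations

No pre-trained weights for real solvents ship with the package — the
reference model demonstrates the machinery at toy scale. No nonpolar/SASA
term, no salt screening, no periodic systems, no transition-state search,
no symmetry-aware RMSD, no anharmonic corrections, no IR intensities from
dipole derivatives. The external-engine adapter is a parsing seam, not an
integration with any specific engine.
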