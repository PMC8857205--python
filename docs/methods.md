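# Methods

This note documents the models, numerical choices and limitations of each
stage of the pipeline, in the order the analysis runs.

## Two-spin REDOR simulation

The observed amide proton (I) couples to one fluorine (S) through the
point-dipole interaction d = (μ₀/4π)·γ_I γ_S ħ / (2π r³) (Hz); for a
¹H–¹⁹F pair at 3.8 Å this is 2.06 kHz. Under MAS a rotor-synchronised
π-pulse train on the fluorine channel (two pulses per rotor period, at
Tr/4 and 3Tr/4) prevents the dipolar coupling from refocusing, and the
normalised dephased intensity S/S₀ falls with recoupling time at a rate
set by r⁻³.

The simulator propagates only the fluorine two-level system, conditioned
on the two observed-spin Zeeman states:

    H_±(t) = 2π[±ω_d(t) + ω_CSA(t)]·S_z + 2π·ν₁(t)·S_x
    S/S₀   = ⟨ Re Tr[U₊ U₋†] / 2 ⟩_powder

The observed spin is treated as a spectator refocused ideally, which keeps
the Hilbert space two-dimensional while retaining every fluorine-side
finite-pulse effect. Time dependence is piecewise-constant with 256 steps
per rotor period (convergence-tested; propagators are analytic SU(2)
exponentials), the period propagator is computed once and powered to each
rotor-synchronised mixing time. Tensor time modulations are obtained by
rotating Cartesian tensors into the rotor frame and contracting with the
instantaneous B₀ direction, which handles arbitrary CSA asymmetry and
orientation without special-casing.

Parameters and defaults:

* MAS rate 38 kHz; mixing times 64/96/144 rotor periods (1.684, 2.526,
  3.789 ms). The commonly quoted 1.68/2.53/3.78 ms are rounded values —
  rotor synchronisation is a hard constraint of the experiment, so the
  package snaps times to integer rotor cycles and the fitter matches
  mixing times with 0.5% tolerance.
* ¹⁹F CSA: reduced anisotropy 60 ppm at a 564.6 MHz ¹⁹F Larmor frequency,
  asymmetry η = 1, tensor coincident with the dipolar frame. These are
  documented defaults for an aryl fluorine and are config-overridable.
* RF inhomogeneity: flip angles 180°–145° in 5° steps, weighted by a
  half-Gaussian centred at 180° with σ = 15°; weights renormalised to 1.
* Powder averaging: a seeded electrostatic-repulsion orientation set
  ("repulsion", 320 points, deterministic given its seed) or a
  deterministic Fibonacci spiral, each combined with a regular γ grid
  (32 angles by default). Doubling the orientation count changes S/S₀ by
  < 5×10⁻³ for both schemes at the default sizes.
* With zero pulse length the pulses are exact π rotations, the CSA phase
  cancels between the two branches, and the simulator reduces to phase
  integration; this path agrees with the analytic powder-averaged
  universal curve 1 − (√2π/4)·J₁/₄(√2λ)·J₋₁/₄(√2λ), λ = d·t, to better
  than 10⁻³, which is the simulator's primary oracle.
* Finite pulses are discretised onto the step grid with the RF amplitude
  recalibrated so the delivered flip angle is exact regardless of grid
  alignment; as the pulse length goes to zero the finite-pulse path
  converges to the ideal one.

## Distance fitting

The measured S/S₀ values are compared against a simulated library
(3.0–15.0 Å, 0.1 Å steps; 121 curves) by the unweighted root-mean-square
deviation over the available mixing times. The reported interval is the
contiguous grid interval around the minimum with RMSD ≤ 0.2. Choices:

* A curve indistinguishable from S/S₀ = 1 within the threshold carries no
  distance information beyond a lower bound: it is reported as ≥ 10 Å with
  the upper uncertainty set to 40 Å (the approximate diameter of the
  dimer).
* Exact RMSD ties resolve to the shorter distance (the more conservative
  restraint).
* Disjoint sub-threshold intervals (possible in the oscillatory
  short-distance regime with three time points) are reported as the widest
  enclosing interval, with a warning.
* Sites whose 2D peaks overlap get their lower uncertainty widened by a
  configurable factor (default 2), implementing the qualitative
  "increased lower uncertainty" rule.

With Gaussian intensity noise of sd 0.05, the interval covers the true
distance in ≥ 95% of seeded replicates for truths in 3.5–8.5 Å (verified
over 200 replicates in the test suite).

## Restraints and scoring

A measured restraint is the proton versus all four equivalent fluorines;
its effective distance in a model is the minimum of the four pair
distances (or the assigned pair after disambiguation), and its violation
is the distance by which the effective distance leaves [lower, upper]. A
weak (lower-bound) measurement becomes four independent single-pair ≥ 10 Å
constraints — each fluorine must individually satisfy the bound — which
keeps the bookkeeping 4·(weak) + (measured) exact. Models are ranked by
ascending violation sum and, separately, by ascending violation count with
the sum as tie-break; both rankings are stable in the input order.
Disambiguation assigns each measured restraint to the fluorine nearest its
proton in the chosen reference model; ties within 10⁻⁶ Å stay ambiguous.
Because the nearest fluorine realises the effective distance, the
assignment leaves violations on the reference model unchanged.

Docking and MD refinement themselves are out of scope: the module consumes
candidate structures as multi-model PDB files. Single-pair restraints can
be exported as an r0/r1/r2 table compatible with piecewise-linear
time-averaged MD distance restraints.

## Ensemble metrics

Pairwise RMSD superposes each model pair on the same selection being
measured (switchable to fit-on-backbone/measure-on-selection); the spread
is the n−1 standard deviation over all C(n,2) pairs. Superposition is the
least-squares rigid transform (Kabsch, via rotation alignment); degenerate
(collinear) selections are rejected. Ensemble distances are per-model
Euclidean (or minimum-over-set) distances reduced to mean ± sd across
models. Pocket waters are water oxygens within a cutoff (default 15 Å) of
any ligand atom whose z coordinate lies between two bounding Cα atoms; the
deposited frame is assumed to have z along the membrane normal (as after
OPM-style alignment), and the count is monotone in both the cutoff and the
z-window. Multi-model PDB parsing follows MODEL/ENDMDL; blank altloc then
'A' are used; insertion codes are rejected.

## Exchange fitting

Row-normalised diagonal and cross-peak volumes are fit to single
exponentials (decay toward plateau P from Y₀; buildup from Y₀ toward P)
with rates bounded non-negative and initialised from a log-spaced grid
(multi-start). Point errors are ε = 2I·√(SNR_i⁻² + SNR_norm⁻²), i.e. 2σ
bars. Parameter uncertainties are the sd of refits over 1000 Monte-Carlo
datasets in which each point is shifted by N(0, 0.3)·ε. The 0.3 fraction
of the full (2σ) error bar is kept exactly as specified for the original
analysis even though it corresponds to 0.6σ of the underlying noise —
fidelity over convention; the consequence, verified in the tests, is that
the MC σ is ≈ 0.6 of the analytic covariance σ. The equilibrium plateau is
left free (measured intensities deviate from the ideal 0.25), but on
conservative synthetic data the four plateaus of a row sum to ≈ 1.

The per-row normalisation SNR is treated as one value per row shared
across mixing times; the alternative (per-spectrum) reading only rescales
ε slightly and does not change the fitted rates.

## Hydration analysis

Saturation-recovery curves I(t) = P(1 − e^(−R₁t)) give site R₁ rates with
the same MC error scheme. The water-edited ratio uses t₁ = 30 ms (edited)
and t₂ = 325 ms (equilibrated): H = (S/S₀)·e^(R₁(t₁−t₂)). Which mixing
time is t₁ versus t₂ is recorded here as an assumption (the correction
formula does not label them): the edited spectrum is the short one, so the
correction always shrinks ratios inflated by relaxation during the long
equilibrated mixing. σ_H combines the two spectral SNRs and σ_R₁ by
Gaussian propagation and is verified against a finite-difference Jacobian.
Between-condition comparisons report per-site differences with quadrature
errors and flag sites present in only one condition.

## Titration and ITC

Each reporter shift follows δ(pH) = (δ_H·10^(−pH) + δ_D·10^(−pKa)) /
(10^(−pH) + 10^(−pKa)). The global fit shares only the pKa; for a fixed
pKa the endpoints are linear parameters solved per series by least
squares, so the fit is a bounded one-dimensional search over pKa (profile
likelihood), which is fast, derivative-free and has no multi-start issues.
Flat series are excluded with a warning. σ_pKa comes from Monte-Carlo
resampling with each series' residual scale. ¹H and ¹⁵N series are fit
separately and combined by inverse-variance weighting as a convenience
output, since the combination rule behind the single reported value is not
stated. Recovery bias is < 0.05 across seeded synthetic datasets at
0.01 ppm noise.

The composite amide shift difference is √(½[Δω_H² + (0.10·Δω_N)²]); the
carbon variant omits the 0.10 factor. The sample-temperature calibration
T_eff(K) = 96.9·(7.83 − δ_H₂O) is exact and linear; shifts ≥ 7.83 ppm give
non-physical temperatures and are returned with a warning.

The ITC extrapolation regresses observed binding enthalpies on buffer
ionisation enthalpies: the slope is the number of protons released, the
intercept the buffer-independent ΔH, and −TΔS = ΔG − ΔH. The entropic
term is consistency arithmetic on the fitted intercept; published values
derived from error-weighted fits of the underlying isotherms can differ at
the ±1 kJ/mol level, and such discrepancies are reported, not reconciled.

## Synthetic data

The generators define the study conditions: 92 weak + 24 measured REDOR
sites at the three protein-ligand mixing times with intensity noise of sd
0.05; exchange rates (200, 250, 180, 300) s⁻¹ spanning the observed
165–318 s⁻¹ range with plateaus at the 0.25 equilibration value and SNR 50
at mixing times 0.1–80 ms; recovery rates 0.5–2 s⁻¹ over 0.05–3 s delays;
six reporter residues titrated at four pH values with 0.01 ppm noise and a
pKa drawn in [6, 8] unless fixed. The toy complex is two antiparallel
four-helix poly-alanine bundles on a 10 Å circle with a central
tetrahedral ligand (P, four C at 1.8 Å, four F at 6.3 Å), waters placed
inside/outside the pocket criteria in known counts, and models 2..n drawn
as seeded per-atom Gaussian perturbations (default 0.5 Å RMS). Identical
configs give bit-identical outputs, and every generator returns a truth
table for closed-loop recovery tests.

What the toy data do not emulate: real helix packing and side-chain
geometry, multi-spin dipolar networks, ¹⁹F spin diffusion, relaxation
during recoupling, and correlated (non-Gaussian) spectral noise. Passing
the closed-loop tests therefore demonstrates the correctness of the
computations and their statistical calibration under the stated noise
model, not the experimental accuracy of the original measurements.

## Problem sizes

The default test-suite and analysis configurations use the full 121-point
distance grid with spiral powder sets of 64–512 orientations × 8–16 γ
angles, 200 round-trip replicates for interval calibration, and 100–1000
Monte-Carlo refits per error estimate. These sizes were chosen so the
whole suite completes in well under a minute while every convergence
invariant (powder doubling, MC scaling) is still asserted; the
repulsion-320/32γ production setting is the library-building default in
the configuration layer.

## Known limitations

* The simulator is strictly two-spin; multi-fluorine dephasing of one
  proton is approximated by the nearest fluorine (consistent with the
  restraint model, which bounds the nearest-fluorine distance).
* The CSA default (60 ppm, η = 1) stands in for tensor values that are
  instrument- and site-specific; users fitting short contacts should
  supply measured values.
* The exchange model is four independent single-exponentials, not a
  coupled 4-site kinetic matrix; rates from the two descriptions agree
  only when cross-relaxation pathways are comparable, which the original
  analysis also assumed.
* Water counting assumes the structure is already membrane-aligned
  (z = bilayer normal); no alignment is performed.
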