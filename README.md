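# redorlab

Quantitative analysis of solid-state NMR observables for a membrane
transporter bound to a fluorinated cationic substrate. The package
re-implements, as a tested and reusable pipeline, the chain of
computations by which magic-angle-spinning (MAS) NMR measurements on the
EmrE–tetra(4-fluorophenyl)phosphonium (F₄-TPP⁺) complex become structural
and dynamical conclusions:

* **REDOR distance extraction** (`redorlab.spinsim`) — simulation of
  two-spin ¹H–¹⁹F rotational-echo double-resonance (REDOR) dephasing under
  MAS, with finite ¹⁹F pulses, the ¹⁹F chemical-shift anisotropy, RF
  inhomogeneity (half-Gaussian flip-angle distribution) and quasi-uniform
  powder averaging; distances are extracted from measured S/S₀ curves by
  grid-search RMSD minimisation over a 3.0–15.0 Å library (0.1 Å steps)
  with an RMSD ≤ 0.2 uncertainty interval.
* **Ambiguous restraints and structure scoring** (`redorlab.restraints`) —
  the four chemically equivalent fluorines make each measured amide-proton
  contact four-fold ambiguous; weak dephasing expands into four independent
  ≥ 10 Å lower bounds (so 92 weak + 24 measured sites yield
  4·92 + 24 restraints). Candidate structures are ranked by total violation
  and by violation count, and the best structure disambiguates each
  measured restraint to its nearest fluorine.
* **Ensemble metrics** (`redorlab.ensemble`) — pairwise RMSD over all model
  pairs of a multi-model PDB (least-squares superposition), ensemble-mean
  inter-atomic distances, and binding-pocket water counting (water oxygens
  within 15 Å of any ligand atom inside a membrane z-window).
* **¹⁹F–¹⁹F exchange** (`redorlab.exchange`) — single-exponential fits of
  diagonal decay, I(t) = (Y₀−P)e^(−kt) + P, and cross-peak buildup,
  I(t) = (P−Y₀)(1−e^(−kt)) + Y₀, with 2σ point errors
  ε = 2I·√(SNR_i⁻² + SNR_norm⁻²) and Monte-Carlo parameter uncertainties.
* **Water-edited hydration** (`redorlab.hydration`) — saturation-recovery
  R₁ fits, relaxation-corrected hydration ratios
  H = (S/S₀)·e^(R₁(t₁−t₂)) for the 30/325 ms mixing-time pair, and full
  Gaussian error propagation.
* **Titration and thermodynamics** (`redorlab.titration`) — global
  Henderson–Hasselbalch fits sharing one pKa across reporter residues,
  composite ¹H/¹⁵N shift differences, the water-shift temperature
  calibration T_eff(K) = 96.9·(7.83 − δ_H₂O), and the ITC
  buffer-ionisation extrapolation (slope = protons released, intercept =
  buffer-independent ΔH, −TΔS = ΔG − ΔH).
* **Synthetic data** (`redorlab.synthetic`) — seeded generators for every
  input kind, including a toy antiparallel helix-dimer + tetrahedral
  four-fluorine ligand + placed waters, each with a machine-readable truth
  table, so the full pipeline runs and is tested without downloads.

The numbered scripts under `analysis/` are thin narrative drivers over the
library; every computation they report lives in `src/redorlab/` and is
unit-tested.

## Worked example

Fit distances for a synthetic 116-site measurement set (92 weak + 24
measured, matching the composition of the experimental dataset):

```bash
python analysis/02_fit_protein_ligand_distances.py
```

prints

```
sites: 116 (24 measured, 92 weak)
measured sites with truth inside [lower, upper]: 100.0%
weak sites flagged as >= 10 A lower bounds:      100.0%
```

i.e. every fitted uncertainty interval contains the generating distance,
and every ≥ 10 Å site is correctly reported as a lower bound. The global
titration fit and thermodynamic extrapolation:

```bash
python analysis/07_titration_and_itc.py
```

prints (seed 1)

```
H-series global pKa: 7.526 +/- 0.046
N-series global pKa: 7.611 +/- 0.007
inverse-variance combined pKa: 7.609 +/- 0.007 (truth 7.610)
effective temperature at water shift 4.89 ppm: 284.9 K
ITC at pH 7.5: dH = -20.0 kJ/mol, -TdS = -21.1 kJ/mol, protons released = 0.80
```

The shared pKa is recovered within its Monte-Carlo error, the water shift
of 4.89 ppm corresponds to a 285 K sample temperature, and the ITC
regression returns the planted proton-release count and binding enthalpy
exactly. The same operations are available from the command line, e.g.

```bash
redorlab titrate temperature --water-shift-ppm 4.89
redorlab synth complex --seed 1 --out scratch/complex
redorlab ensemble rmsd --structures scratch/complex/toy_complex.pdb
```

To compute the ensemble statistics of a locally downloaded deposited
multi-model structure, pass its path to
`analysis/04_ensemble_metrics.py --pdb <file>`.

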