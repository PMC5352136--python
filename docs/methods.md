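# Methods

`mgfold` implements a hybrid all-atom structure-based model of RNA folding
under an explicit divalent-ion atmosphere, together with the analysis stack
that connects such simulations to solution experiments: umbrella-sampling
free-energy landscapes along the fraction of native contacts, ion and
contact observables, Förster (FRET) and Debye (SAXS) predictions, and
two-state Bloch–McConnell CEST simulation and fitting.  This note records
the model, its assumptions, the defaults, and the numerical choices.

## The energy function

The potential is a sum of three parts,

Φ = Φ_SBM + Φ_Mg-size + Φ_ion,

in reduced units: the depth of one native-contact well, ε, is the energy
unit; lengths are in Å; charges in elementary charges; k_B = 1.

**Φ_SBM** is a standard all-atom structure-based ("Gō-type") potential whose
global minimum is the input native structure:

- harmonic bonds (k_b = 100 ε/Å²) and angles (k_a = 20 ε/rad²) at their
  native values; angles whose native geometry is within 0.05 rad of
  collinear are dropped, because a harmonic in arccos is ill-conditioned
  there;
- periodic dihedrals K[1 − cos Δφ] + (K/2)[1 − cos 3Δφ] (K = 1 ε by
  default); torsions with a degenerate native geometry (three near-collinear
  atoms) are dropped;
- harmonic improper torsions (k = 10 ε/rad²) at sp³/sp² centres preserve
  chirality and planarity;
- each native contact pair (i, j) gets a 12-6 well
  ε[(r₀/r)¹² − 2(r₀/r)⁶] with its minimum −ε at the native distance r₀;
- all other non-bonded pairs repel as a truncated-and-shifted r⁻¹²
  excluded volume (pair diameter σ = 2.5 Å, cutoff 2σ).

Native contacts are heavy-atom pairs within 4.0 Å between residues at least
three apart in sequence; a shadow variant additionally removes pairs whose
connecting segment passes within 1 Å of a third atom.  Both the cutoff and
the method are arguments of `build_contact_map`.

**Φ_Mg-size** adds the same r⁻¹² excluded volume for the explicit Mg²⁺
ions, using a hydrated-ion radius of 3.5 Å (an outer-sphere picture: in the
SAM-II system no chelated, inner-sphere ions have been reported, so the ion
keeps its first hydration shell and touches phosphates through it).

**Φ_ion** carries the electrostatics:

- Every phosphate P atom holds charge −1e, every Mg²⁺ +2e.  All
  phosphate–phosphate, phosphate–Mg and Mg–Mg pairs interact through a
  Debye–Hückel potential l_B q_i q_j e^{−κr}/r with Bjerrum length
  l_B = 7.1 Å (water, 298 K).
- The screening constant κ comes from the monovalent salt only (KCl is
  implicit; Mg²⁺ is explicit and must not be double-counted):
  κ² = 8π l_B n with n the free-ion number density.  When a simulation box
  is present the continuum ions are removed from the volume the RNA
  occupies, implemented as rescaling the free concentration by
  (V_box − V_RNA)/V_box with V_RNA the summed hard-core volume.  κ is held
  global and independent of the instantaneous condensation state, so all
  gradients remain exact; depletion of free ions by condensation is
  neglected (dilute-reservoir assumption).
- **Generalized Manning condensation.**  Each phosphate i carries a
  dynamical variable θ_i ∈ [0, 1], the fraction of its charge neutralised
  by locally condensed monovalent counterions.  The condensed cloud is an
  equal-weight mixture of two normalised Gaussians (widths 3 Å and 6 Å)
  centred on the P atom — a compact, tightly held layer plus a looser
  diffuse one — integrating to θ_i.  Condensation acts three ways:
  1. the phosphate's effective pair charge becomes −(1 − θ_i)e;
  2. the cloud gains its electrostatic attraction to its own phosphate,
     −l_B θ_i ⟨1/r⟩ with the closed-form Gaussian expectation
     ⟨1/r⟩ = ½√(2/π)(1/σ₁ + 1/σ₂);
  3. it pays an ideal-mixing entropy
     T[θ ln(θ/θ_ref) + (1−θ) ln((1−θ)/(1−θ_ref))] against the bulk
     reservoir.  θ_ref = 1/(1 + c_mono/100 mM), clamped to [0.01, 0.99]:
     at low salt the reservoir favours more condensation, which is the
     qualitative Manning limit; the 100 mM half-point is a model choice
     exposed in `EnergyParams`.
  Cloud–cloud and cloud–ion cross terms are absorbed into the charge
  renormalisation and not double-counted.

All terms have analytic gradients, including the generalised forces ∂Φ/∂θ;
the test suite verifies every degree of freedom against central finite
differences at 10⁻⁵ relative tolerance.

## Dynamics

RNA atoms, Mg²⁺ ions and the condensation variables evolve together under
BAOAB-split Langevin dynamics, chosen for its accurate configurational
sampling at practical timesteps.  θ variables get a small fictitious mass
(0.05) and a higher friction (10/τ) so they relax faster than ion
diffusion.  Mg²⁺ ions are confined by reflecting walls of a cubic box —
concentration is the experimental control variable and reflecting walls
keep it fixed without introducing periodic images of a charged system; the
RNA is never wrapped.  θ is re-clamped to [0, 1] after each drift, zeroing
the velocity of a clamped variable.  The ion count is
round(c · N_A · V_box); at 2 mM in a 30 nm box that is 33 ions.  Default
timestep 0.0005 τ (tests use larger steps on stiff toy systems where noted).
Pair searches use a k-d tree rebuilt at every force call rather than a
skin-based Verlet list; at the system sizes this package targets the
rebuild is cheap and always exact.

Ligand (SAM) handling: in holo mode the ligand enters as a block of heavy
atoms held rigid by stiff all-pair internal restraints, with native
contacts to the RNA and no internal angle/torsion terms.  Its modelling
role is to bridge the L1–P2b gap, not to flex.

## Reaction coordinate and free energy surfaces

Q is the fraction of native contacts.  Two estimators are used: a hard
count (r < 1.2 r₀, for analysis) and a smooth count (logistic switching
centred at 1.2 r₀ with steepness 10 Å⁻¹) that is differentiable and drives
the umbrella restraint ½k_Q(Q_smooth − Q₀)².  The switching width (~0.4 Å)
is narrow against the 0.2 r₀ margin, keeping the two estimators within
0.03 of each other on perturbed ensembles.

Umbrella windows default to centres every 0.05 in Q over [0.1, 1.0]; the
recombination uses binless WHAM: the self-consistent window free energies
are iterated on the unbinned samples to 10⁻⁷ k_BT and the unbiased sample
weights are then histogrammed, which avoids the bias of evaluating the
restraint at bin centres.  Empty bins are NaN, never extrapolated.
Uncertainties are moving-block bootstraps (≥ 20 resamples) with block
lengths set by the integrated autocorrelation time per window.  2D surfaces
(e.g. total contacts vs Mg-bridged phosphate contacts, or Q vs a regional
Q) reweight the same samples onto auxiliary coordinates — the bias acts on
Q only.

Basin free energies are population-weighted: ΔG_{A−B} = −ln Σ_A e^{−G} +
ln Σ_B e^{−G}.  Default basin intervals on Q: U < 0.35, O 0.35–0.60,
PO 0.60–0.80, PC 0.80–0.95, C > 0.95 — approximate mode locations, exposed
in `BasinSet`.  Titration curves (mean Rg, basin ΔG, …) against ion
concentration are fitted to a four-parameter logistic; the midpoint is the
reported Mg₁/₂ (or K₁/₂, Ca₁/₂).  Data that a constant model explains at
least as well (AIC) are flagged and the midpoint reported undefined.  The
folding temperature T_f is interpolated from the crossing of folded and
unfolded basin weights across temperatures; production runs are meant to
sit slightly below it.

## Observables

- Radius of gyration: mass-weighted RMS distance from the centre of mass.
- Ion-solvation layer: Mg²⁺ within d_layer of any phosphate P atom
  (default 10 Å); direct coordination within d_coord (default 6 Å).  Both
  defaults stand in for the first minimum of the Mg–P radial distribution
  function; `mg_p_rdf` recomputes that function so users can recalibrate
  for their own parameterisation.
- Coordination classes: an in-layer ion with exactly one phosphate within
  d_coord is single-coordinating, with ≥ 2 multiple-coordinating;
  PHOS_cont counts unique phosphate pairs sharing at least one
  coordinating ion — the bridging "glue" of compact states.
- FRET: E = 1/(1 + (R/R₀)⁶) with R₀ = 53 Å (cy3/cy5); the dye pair sits at
  residues 52 (donor) and 14 (acceptor) and the distance is anchored at a
  ribose atom of each labelled residue — dyes are not modelled explicitly,
  so an orientation factor and linker dynamics are outside the model.
- SAXS: the Debye sum I(q) = ΣΣ f_i f_j sin(qr)/(qr) with q-independent
  per-element effective scattering lengths (solvent-contrast constants).
  No hydration-layer model: the package's contract is the Debye sum and
  qualitative ensemble comparison (Kratky shape, relative compaction), not
  absolute fits that depend on a hydration parameterisation.  χ between a
  computed and an experimental profile uses the closed-form optimal scale.

## CEST

The two-state CEST simulator propagates the 7-vector
[1, MxA, MyA, MzA, MxB, MyB, MzB] under the Bloch–McConnell generator:
rotating-frame precession at each state's offset, RF nutation ω₁ = 2πB₁
about x, relaxation with the constant first column returning Mz to its
equilibrium (p_A, p_B), and exchange k_AB = p_minor·k_ex,
k_BA = (1 − p_minor)·k_ex.  The profile is the major-state Mz after the
spin-lock time, normalised by the no-saturation reference.  Internally the
propagation is solved per offset by eigendecomposition of the homogeneous
6×6 block around the steady state, batched over offsets; this equals the
7×7 matrix exponential to 10⁻¹³ and an adaptive ODE integration to 10⁻⁸.

Fitting is global nonlinear least squares of (p_minor, k_ex, Δω, R1, R2)
shared across all B₁ fields, with multi-starts over the sign and magnitude
of Δω to escape the mirror minimum.  R1/R2 are shared between states by
default (standard low-information practice; per-state values can be
enabled).  Defaults follow the acquisition they emulate: offsets −600 to
600 Hz, three references, B₁ ∈ {17.5, 27.9, 37.8} Hz, saturation 0.1 s for
base carbons and 0.2 s for ribose.  Parameter uncertainties come from the
Gauss–Newton covariance; comparing minor-state populations between
conditions uses a z-test on the fitted parameters.

## Synthetic data

The generator module produces every input the tests need, seeded and with
the truth parameters stored next to the data:

- **Hairpin** structures: two straight strands (3 Å rise) of 4-heavy-atom
  residues (P, C4', C1', N1) joined by a short loop, paired N1 atoms 3.5 Å
  apart — one native contact per stem pair under the 4 Å cutoff, with a
  hand-countable bond table (4n − 1 bonds for n residues).  These are
  miniature stand-ins with the full topology machinery (phosphates,
  segments, contacts); they do not have realistic base pairing, stacking
  energetics or sequence, so passing tests demonstrate the machinery and
  the model's qualitative physics, not quantitative RNA thermodynamics.
- **Two-state Q series**: Markov switching with prescribed stationary
  occupancy and Gaussian jitter, modes at the open (Q≈0.7) and bound-like
  (Q≈0.9) states.
- **Debye–Hückel ion gas**: Metropolis sampling of like charges in a closed
  box; at low density the pair correlation matches e^{−u(r)/k_BT}.  g(r)
  is normalised against a Monte-Carlo ideal-gas reference, which handles
  the non-periodic box geometry exactly.
- **CEST profiles**: simulator output plus Gaussian noise, normalised by
  three noisy reference points.
- **Double-well umbrella samples**: exact Boltzmann draws (rejection
  sampling) from biased quartic double wells — the independent oracle that
  pins the WHAM implementation; the recovered barrier must match the
  analytic height within 0.1 k_BT.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
hairpins of 8–30 residues, 10⁴-sample Langevin statistics, 15-window ×
4000-sample WHAM problems, 200-scatterer Debye oracles, and 5–20-replicate
CEST recovery studies.  Full riboswitch landscapes (52-nt RNA, many Mg²⁺
concentrations, long umbrella runs) use the same code paths unchanged; the
two-concentration demonstration in the acceptance script shows the
direction of the Mg²⁺ effect on a hairpin, not the converged landscape.

## Known limitations

- No inner-sphere/chelated Mg²⁺ chemistry, polarisability, explicit water
  or sequence-dependent charges.
- The Manning reference θ_ref(c) and the two Gaussian widths are model
  choices; the testable contract is the normalisation of the condensed
  cloud and the qualitative salt dependence, not those constants.
- SAXS omits the hydration layer; χ values against real data depend on
  that choice.
- Kinetics (rates, transition paths) are out of scope; every claim the
  pipeline supports is thermodynamic.
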