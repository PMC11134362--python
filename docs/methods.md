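# Methods

`regucharge` simulates charge regulation of short weak-base oligocations
(lysine-like, side-chain conjugate-acid pKa = 10.68) interacting with a
long, permanently ionized polyanion (methacrylate-like) in implicit
solvent, and analyses the resulting titration, condensation and
conformational observables.

## Coarse-grained model

Each monomer is two spherical beads: a neutral backbone bead and a
side-chain bead carrying the (possibly fluctuating) charge.  Backbone beads
form a linear chain; each side-chain bead is bonded to its backbone bead.
Chain ends are protected: they carry no additional ionizable groups.
Polyanion side chains are fixed at valence −1 — the solution pH of interest
(> 8) is far above the methacrylate pKa ≈ 4.3, so its ionization never
fluctuates appreciably.  Oligocation side chains titrate between 0 and +1.

Reduced units: energies in k_BT (k_BT ≡ 1), lengths in nm, all masses 1.
Defaults (all config keys):

| parameter | default | meaning |
|---|---|---|
| σ | 0.35 nm | bead diameter (WCA) |
| ε | 1 k_BT | WCA energy scale |
| k_bond | 400 k_BT/nm² | harmonic bond constant |
| r₀ | 0.4 nm | bond rest length (= backbone charge spacing b) |
| λ_B | 0.71 nm | Bjerrum length of water at 298 K |
| I | 0.01 M | 1:1 salt ionic strength |
| pKa | 10.68 | oligocation side chain |
| m | 48 | polyanion length |
| n | 2, 4, 8 | oligocation lengths studied |
| ratio | 1:2 | oligocation : polyanion monomers |
| c_mon | 5×10⁻³ M | polyanion monomer concentration (sets the box) |

The monomer concentration is not uniquely determined by the problem
statement; 5×10⁻³ M gives a cubic box of L ≈ 25.2 nm for m = 48, which
comfortably exceeds the polyanion contour length (18.8 nm) and twice the
electrostatic cutoff, and corresponds to sub-g/L polymer content typical of
dilute-solution titration experiments.  The builder enforces
L > contour length and rejects concentrations that violate it.

## Interactions

* **Excluded volume** — Weeks–Chandler–Andersen (cut-and-shifted LJ at
  2^{1/6}σ) between all bead pairs.
* **Bonds** — harmonic, (k/2)(r−r₀)².
* **Electrostatics, default mode** (`debye_hueckel_implicit_ions`) —
  screened pairs u(r) = z₁z₂ λ_B e^{−κr}/r with κ² = 8π λ_B N_A I for the
  1:1 electrolyte; truncated at 4/κ (capped at L/2) and shifted to zero at
  the cutoff.  Small ions exist only as integer bookkeeping for
  electroneutrality.
* **Electrostatics, cross-check mode** (`coulomb_explicit_ions`) — bare
  Coulomb with explicit small-ion beads and standard Ewald summation
  (real-space erfc within r_c, reciprocal sum with α = s/r_c,
  k_max = ⌈sαL/π⌉, s = √(−ln a) for accuracy a).  Validated against the
  NaCl Madelung constant to < 10⁻⁶ relative and against numerical force
  differentiation.  Intended for small systems; tests confirm both modes
  produce the same qualitative contact-enhancement of ionization.

### Manning renormalization of the polyanion charge

The polyanion's bare line-charge density is one charge per b = 0.4 nm,
i.e. a Manning parameter ξ = λ_B/b ≈ 1.78 > 1.  In an explicit-ion
description a condensed counterion layer reduces the effective charge to
≈ 1/ξ per bare charge; linearized Debye–Hückel theory has no mechanism for
this, and using the bare charge makes the implicit model systematically
overbind oligocations (their release transitions shift ≈ 0.5–1 pH unit too
high).  The default model therefore applies the Oosawa–Manning closure:
permanently ionized polyanion site charges are scaled by min(1, b/λ_B) in
the energetics (`ForceField.manning_renormalize`, on by default,
switchable).  Oligocation charges are never renormalized — they are weak,
fluctuating, and below the threshold.  Bare integer charges are retained
everywhere else (electroneutrality bookkeeping, trajectory files,
observables).

Known cost of this closure: renormalization is a far-field concept.  At
contact an oligocation displaces the condensed counterions and interacts
with a locally bare chain, gaining the counterion-release entropy
TΔS ≈ (z−1)k_BT; a single distance-independent effective charge cannot
represent both regimes.  The model therefore underestimates the
cooperativity that makes the longest oligomer's condensation collapse very
sharp (≈ 0.5 pH in the explicit-ion picture); here the Lys₈ collapse is
correctly positioned but spread over roughly 1.5 pH units.  This is a
limitation of any linear implicit-ion treatment, not a sampling artifact.

## Constant-pH Monte Carlo

A trial move flips one uniformly chosen titratable site.  Deprotonation
(ξ = +1) inserts a monovalent cation (count-only in implicit mode; placed
uniformly at random in explicit mode); protonation (ξ = −1) deletes one,
auto-rejecting when none is available.  Acceptance:

    P_acc = min{1, exp(−ΔU/k_BT + ξ ln10 (pH − pKa))}

In implicit-ion mode ΔU is the change in the screened polymer
electrostatics only (the inserted/deleted ion carries no explicit
interactions; the ideal-gas bookkeeping lives in the ξ ln10(pH−pKa) term).
The convention ξ = +1 ⇔ deprotonation is fixed by the decisive ideal-limit
test: with interactions off, sampled ionization must reproduce the
Henderson–Hasselbalch Bernoulli law at every pH, which it does (χ² and
3-s.e.m. checks).  Against the exact 2^N enumeration oracle
(`theory.exact_titration`) the sampler agrees within statistical error on
frozen-geometry toys.

## Configuration sampling

Langevin dynamics with the BAOAB splitting, k_BT = 1, masses 1, γ = 1/time,
dt = 0.005.  The WCA wall at σ = 0.35 nm sets the stiffest timescale
(ω_eff dt ≈ 0.3 at dt = 0.005 in these units); dt = 0.01 is measurably
unstable under thermal collisions, dt = 0.005 conserves equipartition to
within 2% and dt = 0.002 is indistinguishable from exact.  Verified:
energy conservation in the γ→0 limit, ⟨v²⟩/3 = k_BT, free diffusion
D = k_BT/γ, and the Boltzmann bond-length distribution (KS test including
the WCA contribution of the bonded pair).

Between the ionization sweep and the LD block, each cycle attempts one
rigid-body Monte Carlo displacement per oligocation (50% Gaussian step of
1 nm, 50% uniform teleport across the box, Metropolis on the interaction
energy change).  These moves leave the sampled ensemble invariant and are
essential at desk scale: with diffusion alone the condensation/release
exchange time exceeds practical run lengths and molecule-level condensed
fractions freeze at multiples of 1/N_molecules.

One numpy Generator drives every stochastic choice in a documented order
(site indices, acceptance uniforms, translation draws, LD noise), so runs
are bit-for-bit reproducible at fixed seed in implicit-ion mode.

## Observables

* **Degree of ionization** α: mean over sites and recorded frames;
  standard errors from block averaging (10 blocks).
* **Condensed fraction**: fraction of (molecule, frame) pairs whose
  oligocation centre of mass lies within 2 nm of the nearest polyanion
  bead (minimum-image distances, molecules unwrapped bond-by-bond).  The
  2 nm threshold corresponds to the population minimum between the
  condensed and free clusters.
* **Distance-resolved ionization**: per-molecule-per-frame (distance, α)
  scatter plus 0.25-nm-binned means over 0..L/2 — the two-population
  analysis.
* **End-to-end distance** of the polyanion backbone, unwrapped.
* **Local-H⁺ proxy**: c_H(r) = 10^{−pH} e^{−ψ(r)} with ψ the mean DH
  potential of the polyanion configuration sampled by random probe points,
  binned by distance to the nearest polyanion bead (cation counting in
  explicit mode).  This is an estimator choice, flagged as a proxy; it
  reproduces the bulk value in the far field and the closed-form
  single-charge law exactly.

## Synthetic fixtures

`fixtures.generate_mixture_trajectory` emulates the statistical structure
the analysis assumes — a condensed population at short distance with high
α and a free population far away with low α, placed perpendicular to an
ideal straight polyanion so every distance is exact by construction — and
writes the same on-disk format as the simulator.  It deliberately does NOT
emulate configurational correlations, chain flexibility, or coupling
between distance and ionization within a population; passing fixture tests
therefore validates the analysis arithmetic, not the physics of real
trajectories (which the simulation tests cover).
`generate_titration_series`/`fit_titration` provide Hill-sigmoid generation
and least-squares recovery of (pKa_eff, slope); recovery is within 0.1 pH
units at noise σ = 0.02 over 20-point grids.

## Problem sizes and runtimes

Production analyses use 1000 warmup + 5000 recorded cycles per pH point
(one frame per cycle; each cycle = one MC sweep over all sites + one
oligocation translation attempt each + 100 LD steps), roughly half a
minute per point on one CPU for the m = 48 systems.  The test suite uses
800 + 2200 cycles per point, enough for ~2-s.e.m. discrimination of all
qualitative orderings.  The exact enumeration oracle is limited to N ≤ 12
sites (4096 microstates at N = 12).

## Known limitations

* Implicit-ion DH electrostatics with a single effective polyanion charge:
  no counterion-release entropy, no ion–ion correlations; transition
  sharpness for the longest oligomers is underestimated (see above).
* No hydrogen bonding, hydrophobicity or specific-ion effects; the model
  isolates the electrostatic mechanism.
* The explicit-ion Ewald mode is O(N²)-ish per energy and intended only
  for cross-checks on small systems.
* Hill fits assume a single sigmoidal transition; curves that do not cross
  α = 0.5 within the sampled pH window raise a fit error rather than
  extrapolating.
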