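# Methods

This note documents the models, numerical choices and limitations behind
`cgcalib`. It is the package's own account; every number quoted here is
computed by the test suite or the bundled scripts.

## Building blocks and parameter space

A CG lipid is an ordered bead list with harmonic bonds and angles. Every
bonded term is classified by the canonical tuple of its bead types — the
lexicographically smaller of the tuple and its reverse, so classification
is orientation-independent and angles keep their middle bead in place.
Blocks are keyed by bead types only, never by lipid: a motif shared by two
lipids has one parameter pair, which encodes cross-lipid transferability
and is the reason a training set of eight PC lipids needs only tens of
parameters.

Each block carries an equilibrium value (nm for bonds, degrees for
angles) and a force constant (kJ mol⁻¹ nm⁻², kJ mol⁻¹ rad⁻²), GROMACS
conventions throughout; the loss converts bond quantities to Å where its
calibration is stated in Å. Angle blocks may pin their equilibrium at
180° (linear terms); pinned equilibria leave the optimizer's parameter
vector, giving the accounting `free = 2·(B+A) − fixed`. The vector
layout is deterministic (bonds before angles, lexicographic keys), so
encode/decode is a bijection on the free subspace and runs are
reproducible.

### Bundled representations

The two shipped representation files are *synthetic reconstructions*:
the original per-lipid bead assignments live in supplementary material
that is not available here, so the files were engineered from the stated
construction rules (mixed-resolution: regular beads = 4 heavy atoms,
small = 3, ≤ 1 unsaturation per bead, regulars stacked first;
homogeneous-tail: regular-bead bulk with a small 3-to-1 or regular
5-to-1 next-to-ester bead) to reproduce the published accounting
exactly: 16 bond + 27 angle types with 9 pinned angles = 77 free
parameters, and 13 + 12 with 2 pinned = 48. The first representation
enumerates all connected bead triples as angles; the second restricts
angles to the glycerol backbone and tail chains (listed explicitly in
the YAML). Tests assert the accounting, not the (unknowable) atom-level
assignments.

## Mapping and distributions

Bead positions are mass-weighted centers of their mapped atoms (center
of mass is the Martini convention; a center-of-geometry switch would be
a one-line change in `map_trajectory`). Atoms of a bead are made whole
across periodic boundaries before averaging; all intra-lipid geometry
uses the minimal-image convention in orthorhombic boxes. Histogram grids
are fixed module-wide — bonds: 0.05 Å bins on [0, 15 Å]; angles: 2° bins
on [0°, 180°] — fine relative to the 0.2 Å / 10° scales on which
mismatches are judged; a test verifies that halving the bin width moves
a Wasserstein distance by less than one coarse bin.

## Loss

The exact printed forms of the composite loss were not recoverable from
the source text (the equations are typeset as images), so the package
defines a canonical form chosen to satisfy every quantitative statement
about the loss simultaneously:

* per-system percentage deviations are hinged at ε and averaged
  arithmetically over systems (ε = 1.5 % is a dead zone, not a target);
* the two top-down terms add and are weighted by w1 = 10;
* the bottom-up term scales bond distances (Å) by w2 = 50 onto the
  angle-degree scale, takes per-type means over instances, and averages
  over the B + A types.

Under this form: 0.4 Å ↔ 20° and 0.2 Å ↔ 10° contribute equally
(verified to 1e-9 from explicit histograms), and at the 0.2 Å / 10°
crossover the bottom-up term equals the top-down cost of a joint
1 %-beyond-ε deviation — the prioritization property the defaults are
meant to encode. Whether the original combines top-down terms additively
or in quadrature, and whether the bottom-up term averages or sums over
types, is genuinely open; the alternatives are pluggable behind the same
interface.

The 1-D Wasserstein distance between same-grid histograms is computed as
`bin_width · Σ|CDF_p − CDF_q|`, which is exact for the discrete ground
metric |bin center difference|; tests cross-check it against an exact
quantile-function integration and against an established reference
implementation on random histogram pairs.

## Observables

* **APL** = Lx·Ly / (n_lipids/2) per frame, averaged over the final 50 %
  of frames (the analysis window treats the first half as
  equilibration; the original averaging window is unstated).
* **D_HH** = separation of the two phosphate-density peaks along z.
  Profiles use 1 Å bins, symmetric about z = 0, accumulated after
  re-centering the membrane center of mass each frame (removes drift
  without unwrapping). Each leaflet's peak is the density-weighted
  centroid of the bins within 75 % of that leaflet's maximum — this
  centroid rule is this package's documented choice; argmax alone is
  noisier. A unimodal profile (destroyed bilayer) raises
  `InvalidObservableError` rather than returning a number.
* **Tilt** = mean angle between per-lipid tail vectors (first to last
  tail bead) and the bilayer normal, leaflet-sign corrected via |v_z|.
  This first-to-last definition only approximates the experimental
  hydrocarbon-tilt definition and is documented as such.

## Optimizer

FST-PSO-style self-tuning swarm. Population ⌊10 + 2√d⌋. Particle 0 is
seeded with the AA-mapped mean equilibrium values (computed from the
reference distributions) and midpoint force constants of the configured
prior ranges; all others start uniform in bounds with zero velocities.
Strict (<) improvement updates personal/global bests and resets the
stale counter; ties do not. Termination: 10 stale iterations
(configurable) or the iteration cap. Positions reflect at the bounds.
Failed evaluations (crashed simulations, non-finite losses) count as
+∞.

The fuzzy rule base is a reconstruction — the cited method's exact
membership breakpoints are not restated in the available text. Inputs
are φ (fitness change, normalized by the worst-to-best spread seen over
the whole run — the per-iteration spread collapses to noise late in a
run and made coefficient adaptation erratic) and δ (distance to the
global best / bounds diagonal). The rule direction that proved right
empirically, and is shipped: *improvement → low inertia and small steps
(refine locally); worsening → high inertia and larger steps (leave);
far from the best → strong social pull.* Output singletons: inertia
0.3/0.5/1.0, social 1/2/3, cognitive 0.1/1.5/3, velocity clamp
0.1/0.15/0.2 of the per-dimension range, velocity floor 0/0.001/0.01.
With these rules FST-PSO beats the plain fallback (ω = 0.72,
c1 = c2 = 1.49, flagged in run metadata) on the 5-D sphere and on the
surrogate recovery problems; the opposite rule direction consistently
underperformed plain PSO.

Two numerical details matter: (i) a particle whose velocity update is
exactly zero — notably the seeded first particle, which starts on the
initial global best — receives a small random kick (σ = 0.002 × range),
otherwise the seeded optimum could never be refined; (ii) with a fixed
seed and a deterministic objective the whole run is bit-reproducible.

## Surrogate backend

The surrogate emulates an equilibrium CG bilayer simulation: bond
samples ~ N(b₀, RT/k) (plain Gaussians without the r² Jacobian —
adequate for stiff bonds and it keeps the planted optimum exact), angle
samples likewise with reflection at the [0°, 180°] walls, and APL/D_HH
responding linearly to normalized parameter errors against a hidden
truth with sparse ±[0.01, 0.05] coefficients plus 0.3 % Gaussian noise.
kB = 0.008314 kJ mol⁻¹ K⁻¹; the temperature comes from each training
system, so temperature transferability of shared blocks is testable.

All random draws use **common random numbers**: per-(system, block)
streams independent of the candidate parameters. Every candidate is
therefore evaluated against the same noise realization, the loss
landscape is a smooth deterministic function of the parameters, and —
because the demo generates its references from the same streams — the
planted optimum is exact (loss ≡ 0 at the truth). Without this, frozen
per-candidate sampling noise of the same magnitude as the residual loss
made strict-improvement search stall. The cost is that the surrogate's
"statistical error" is a fixed offset rather than resampling noise; for
optimizer benchmarking that is the right trade.

The demo problem (2 lipids sharing 6 bond + 6 angle blocks, 24 free
parameters, 2 systems, 2000 samples per block instance) recovers all
planted equilibria within 0.1 Å / 4° in 10/10 seeds within 100
iterations (~6 s per run on one CPU); a 4 + 4-block variant with a
30-particle swarm drives the loss below 1.0 in 9/10 seeds. What passing
these tests does *not* show: that the surrogate's linear response
resembles real MD observables far from the optimum, that 200 ns CG runs
are as well-behaved as the surrogate, or anything about nonbonded
parameters — the MD adapter contract exists precisely because the
surrogate is not an engine.

## Phase classification

LENS per particle and frame pair: |set_t Δ set_{t+stride}| / (|set_t| +
|set_{t+stride}|), zero when both neighbor sets are empty. Defaults —
one representative bead per lipid (first tail bead), 11 Å cutoff — are
this package's documented choices; outputs carry the parameters used.
Labels come from thresholding the time-smoothed (5-frame moving
average, edge-corrected) LENS signal at the midpoint between the two
dominant modes of its pooled histogram (5-bin-smoothed, modes must be
≥ 4 bins apart); a unimodal population falls back to a fixed 0.2
threshold so an all-mobile system reads liquid and an all-static one
gel, and an all-equal signal yields a single-phase labeling with a
warning. Mass fractions are exact mass-weighted bookkeeping; gel% +
liquid% = 100 identically.

## Known limitations

* Orthorhombic boxes only; no trajectory alignment or whole-membrane
  unwrapping; no dihedral or constraint terms.
* The ITP dialect covers harmonic bonds (func 1) and angles (func 2/1);
  reading a free angle that happens to sit at exactly 180° marks it
  pinned.
* The surrogate's observable response is linear and its distributions
  exactly Boltzmann; real bilayers are neither.
* Representation files reproduce published *accounting*, not published
  bead assignments.
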