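# Methods

This note records the models implemented in `clayped`, their assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open.  Everything quantitative stated here is computed by the
test suite or the acceptance script; nothing is asserted that the code does
not reproduce.

## System and scope

The modelled system is a stack of positively charged Mg₃Al(OH)₈ layered
double hydroxide (LDH) layers, 5.3 Å thick, with amino acids / short
peptides, water and counterions in the interlayer galleries.  At high pH
the molecules are deprotonated and adsorb on the layer faces through their
C-terminal carboxylate oxygens.  `clayped` covers the *analysis* of such
systems and a *statistical emulator* of their trajectories.  It does not do
force-field physics: no electrostatics, no water structure, no bonded
terms, and no claim about the chemistry of peptide-bond formation (reactive
pairs are a geometric proxy only).

## Synthetic trajectory generator

The generator's role is to produce inputs with *known* statistical
structure for every analysis stage.

* **Slab.** Metals on a triangular lattice (spacing `lattice_a` = 3.05 Å,
  a typical M–M distance in brucite-like layers); Al occupies the
  (even, even) sites of a 2×2 superlattice, which realises the 3:1 Mg:Al
  stoichiometry exactly and disperses Al so no two are nearest neighbours.
  Each metal carries one hydroxyl (O + H bead) on each face; hydroxyl H
  planes delimit the layer thickness (default 5.3 Å).  Layers repeat every
  `layer_thickness + interlayer_gap` along z; the default gap of 7.7 Å
  gives a 13 Å hydrated repeat, typical of amino-acid-intercalated LDH.
* **Molecules.** Bead models carrying only the sites the analyses consult:
  C-terminal carbon CT, terminal oxygens OT1/OT2 (±0.3 Å laterally, 0.45 Å
  below CT), one backbone nitrogen per residue (the N-terminal free amine
  is named NT), and side-chain beads (OD1/OD2 oxygen pair for aspartate,
  one generic bead otherwise).  Chains extend 3.5 Å per residue.  Waters
  are single OW beads, `hydration` per amino-acid residue (per anion with
  `water_per="anion"`, for mixtures specified that way); Cl⁻ beads top up
  the charge balance against the +1-per-unit-cell slab.
* **Kinetics.** Each molecule carries a two-state (bound/free) Markov
  chain: per frame, a free molecule binds with probability `w·p` and a
  bound one unbinds with probability `w·(1−p)`, so the stationary bound
  fraction is exactly `p = residence_fraction` (default 0.95, the observed
  post-first-binding residence of adsorbed amino acids) and the relaxation
  scale is `1/w` frames (`switch_rate` w = 0.2).  Bound molecules pose
  their OT oxygens 1.5 Å above the local hydroxyl face — within the 2.5 Å
  detection cutoff for every lateral registry — and free molecules sit at
  mid-gap, at least 3.3 Å from either face, so the generated state is
  recovered unambiguously by the adsorption analysis.
* **Lateral motion.** Rigid xy steps of Rayleigh-distributed length
  (`step_scale` = 1 Å per 0.1 ns frame, i.e. ~10 Å ns⁻¹ drift, the scale
  seen for hydrated interlayers); step direction is uniform, or with
  probability `hex_bias` an exact multiple of 60° along the lattice axes.
  `hex_bias=1` therefore produces a strictly six-fold walk,
  `hex_bias=0` an isotropic one — the two ground truths for the six-fold
  detector.
* **Undulation.** A static sinusoid `A·sin(2πx/λ + φ_layer)` added to all
  LDH z-coordinates (per-layer random phase).  Sampled on the dense metal
  lattice, its pooled z-spread is A/√2, the closed form the undulation
  analysis is tested against.
* **Templated mode.** With `templated=True`, bound C-termini snap to the
  nearest Al site, making the in-plane OT–Al pair distribution echo the
  Al–Al lattice — the ground truth for the templating RDF signal.
* **Energies.** A user-suppliable monotone profile of the water count
  (default linear, −40 kJ/mol per water on a −500 kJ/mol offset) plus
  Gaussian noise (σ = 5 kJ/mol).  The default slope lies below the bulk
  reference on purpose: hydrated LDH interlayers are swelling-prone.

Everything is drawn from one `numpy` generator seeded by `rng_seed`; the
same seed and configuration reproduce the trajectory bit for bit.

**What the generator does *not* emulate** — and hence what passing tests do
not show about real systems: no inter-molecular forces (molecules can
overlap), no coupling between hydration and gap width, no aggregation or
hydrophobic collapse, no z-exchange between galleries, waters are inert
markers, and the adsorption process is memoryless.  Tests against the
generator validate the *estimators* (that each analysis recovers known
structure), not molecular behaviour.

## Layer geometry

Layers are collections of metal atoms at most 5 Å apart, found by DBSCAN on
the full 3-D coordinates with `eps = 5 Å`.  `min_samples = 4` (the
clustering parameter the definition leaves open) keeps thin layers intact
while demoting stray atoms to reported noise.  In-plane metal spacing
(~3 Å) is well below eps and inter-layer spacing (≳12 Å) well above, so
the assignment is insensitive to either choice within a wide band.

Local d-spacing slides a 5 × 5 Å window in 1 Å steps across the xy-plane;
the window value is the difference of mean metal z of the two adjacent
layers inside it.  Windows wrap around the periodic box by default
(non-periodic windowing, with its `⌊(L−5)/1⌋+1` grid, is a flag) and
windows in which either layer contributes no atom are excluded as missing
rather than zero-filled.  Undulation centres each layer at its mean z,
pools residuals over frames and layers, and reports the standard
deviation; a sinusoid of amplitude A gives A/√2.  The same spread computed
on the local d-spacing map separates correlated from anti-correlated layer
undulations: anti-correlated layers inflate the d-spacing spread above the
single-layer spread.

## Adsorption, RDF, orientation, reactive pairs

* **Surface definition.** "The LDH surface" is taken as the hydroxyl O and
  H beads of the layer faces; the 2.5 Å cutoff is the first-hydration-layer
  distance.  Which partner atom the H-bond criterion refers to is not
  uniquely determined, so the surface set is switchable
  (`surface="hydroxyl" | "hydroxyl_o" | "hydroxyl_h" | "metal"`).
  A molecule is backbone-adsorbed if *either* OT1 or OT2 is within the
  cutoff (an "either-of-pair" reading); aspartate's OD1/OD2 are scored the
  same way, separately.  Distances are periodic minimum-image, via a
  KD-tree with periodic box support.
* **Summary window.** Percent-adsorbed summaries average over the last half
  of frames as the equilibrated portion (configurable); peptide side-chain
  percentages are divided by residues-per-terminus (2 for dipeptides, 6 for
  hexapeptides) so chains of different length are comparable.
* **RDF.** Standard pair-distribution normalization against the ideal-gas
  density of the partner species, exact shell volumes, periodic minimum
  image, 0.1 Å bins by default (resolving first-shell structure at 2–3 Å);
  self-pairs excluded for like-species RDFs.  A `lateral=True` mode uses
  xy-projected distances and ring-area normalization: the templating
  signal (C-termini seated on the Al sublattice) lives in the plane, and
  3-D distances would shift every shell by the ~4.5 Å height of the
  adsorbed oxygens above the Al plane.
* **Orientation.** Θ is the elevation of the CT→N vector of the terminal
  residue against z, folded to [0°, 90°] (up/down equivalence; 0° ⊥,
  90° ∥), 1° bins.  The terminal-residue nitrogen is identified as the
  backbone N nearest to CT in the frame — robust to file round-trips that
  lose residue partitioning (1.9 Å in the bead model vs ≥3.5 Å for other
  residues).  Zero-length vectors are skipped with a warning.
* **Reactive pairs.** A pair is molecule i's carboxylate carbon within 4 Å
  (strict) of molecule j's free amine, i ≠ j, both molecules adsorbed: the
  donor through the matching site (C-terminus for α pairs; for aspartate's
  β route, the side-chain carboxylate, located at the OD1/OD2 midpoint
  since the bead model carries no side-chain carbon), the amine bearer
  through any site.  Same-molecule closures — the geometries that could
  only cyclize — are excluded; α and β counts are summed.  The reported
  percentage is the fraction of molecules participating in at least one
  pair.

## Surface dynamics

Velocity is the finite-difference xy drift per frame interval (Å ns⁻¹) of
the C-terminal carbon, for steps whose molecule is adsorbed in both frames
— not a mean-squared-displacement diffusion coefficient, since per-step
drift is the observable of interest for surface-templated motion.  Steps
are unwrapped by minimum image; directions (1° bins) are rounded to
microdegrees so exact lattice steps land in their nominal bin.

The direction histogram's circular autocorrelation (mean-subtracted,
normalized to the lag-0 value) is scanned for six-fold structure.  The
**six-fold score** is the mean autocorrelation at lags {60°, 120°, 240°,
300°} minus the mean over off-peak lags.  Lag 180° is excluded from the
peak set (any inversion-symmetric histogram peaks there, so it carries no
specifically six-fold information) and lags {90°, 180°, 270°} are excluded
from the baseline (they carry four-fold/two-fold structure); with these
exclusions a four-fold-biased control walk scores ≈ 0 while a six-fold walk
scores strongly positive.  Significance comes from a seeded Monte-Carlo
null: the same number of directions redrawn uniformly on [0°, 360°) 1000
times (histogram shuffling would be a no-op, since the histogram is
invariant under permutation of its inputs); the p-value is the fraction of
null scores at least as large as the observed one, with the +1 correction.

Residence is the per-molecule fraction of frames adsorbed from the first
adsorbed frame (inclusive) onward; molecules never adsorbed are excluded
from the population mean/std and counted separately.

## Hydration energetics

ΔU_H = (⟨U(N)⟩ − ⟨U(0)⟩)/N on equilibrated potential-energy series
(potential energy only — the kinetic part cancels in equilibrium averages
at fixed temperature).  The verdict `will_rehydrate` uses a *strict*
inequality against the bulk-water reference (−33.25 kJ mol⁻¹, a
configurable constant): the exact boundary does not classify as swelling.
Uncertainty is the quadrature sum of the two series' block-averaged
standard errors (5 blocks — enough to average over correlation times
without starving each block) divided by N.

## Wetting–drying kinetics

State: concentrations X₁…X_Nmax of surface-adsorbed chains, capacity 100,
one rate constant k = 1.  Dehydration integrates

    dX₁/dt = −k X₁ Σ_{n≥2} Xₙ
    dXₙ/dt =  k X₁ (Xₙ₋₁ − Xₙ),  n ≥ 2   (Xₙ₋₁ = X₁ for n = 2)

with LSODA (rtol 1e−9, atol 1e−12) until X₁ < 1e−6 — the practical reading
of "reactions stop when the monomers are exhausted", which an ODE reaches
only asymptotically.  In this default rate law the monomer pool is depleted
by chain extension but not by the two monomers a dimerization consumes; the
surface behaves as if the bath topped monomers up during drying, and the
total chain population stays at capacity.  This variant produces the
model's characteristic milestones, both recomputed by the acceptance
machinery: after a single dehydration the longest chain holding ≥ 1% of
capacity is the hexamer, and 10-mers first reach that threshold at cycle
12 (> 10 cycles).

The strictly stoichiometric closed-surface variant (`mass_conserving=True`)
adds the factor-2 dimerization loss, −k X₁(2X₁ + Σ_{n≥2} Xₙ), under which
the monomer-unit mass Σ n·Xₙ is conserved to integrator tolerance (tested
to < 1e−6 × capacity).  That variant is the deterministic limit of the
physical reaction set, and is what the **Gillespie twin** cross-checks:
discrete molecules, propensities k·n₁(n₁−1) for dimerization (consuming
two monomers) and k·n₁·nₓ for extension, run to monomer exhaustion.  The
ODE matches the 1000-run ensemble mean within 3 Monte-Carlo standard errors
per length (with a 1/n_runs error floor for lengths the ensemble never
realized, and the converged ODE X₁ ≤ tolerance compared as zero).

Wetting: every chain of length ≥ 2 releases `desorb_fraction` (5%) into a
cumulative ledger, then monomers top the surface back up to capacity.
Monomers do not desorb explicitly — repopulation would make their
desorption unobservable.  Chain lengths are truncated at N_max = 64; mass
reaching the last bin beyond 1e−9 × capacity raises an error rather than
silently leaking.  The "significant amount" threshold θ is 1% of capacity
by default and exposed as a parameter, with first-appearance cycles
reported per length so the θ-dependence is transparent.

## Problem sizes and numerical choices

Validation runs use slabs of 8–24 lattice cells per side, 2–5 layers,
4–100 molecules and 4–1000 frames — large enough that closed forms (A/√2,
ideal-gas RDF level, stationary Markov fractions) are resolved against
their sampling error, and small enough that the whole suite runs in
seconds on one CPU.  Degenerate inputs fail loudly: zero metal atoms,
fewer than two layers, equal-mean-z layers, r_max beyond half the box,
empty energy series, single-frame diffusion input, molecules without
terminal oxygens (skipped with a warning).  Exact-boundary conventions:
adsorption uses ≤ cutoff, reactive pairs use < cutoff, the swelling verdict
uses < reference.

## Known limitations

* The generator's independence assumptions (no excluded volume, no
  hydration–geometry coupling) mean quantitative adsorption/diffusion
  values are illustrative, not predictive; only the kinetic model's
  numbers are intended quantitatively.
* PDB carries no time stamps, so trajectories read from PDB default to a
  nominal frame interval; velocity magnitudes from PDB input need an
  explicit time rescale (GRO and XYZ round-trip times exactly).
* The reactive-pair criterion is purely geometric; no angular H-bond
  terms, charges, or reaction energetics.
* The kinetic model is sequence-blind (lengths only), uses one rate
  constant for all lengths, and has no reverse (hydrolysis) reactions.
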