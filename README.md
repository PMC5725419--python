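# clayped

Analysis toolkit for the behaviour of amino acids and short peptides
intercalated in hydrated **layered double hydroxide (LDH)** interlayers —
a candidate mineral scaffold for prebiotic peptide formation.  Positively
charged Mg₃Al(OH)₈ layers adsorb deprotonated amino acids through their
C-terminal carboxylates; drying the interlayer crowds and aligns the
adsorbed molecules, and repeated wetting–drying cycles can ratchet chain
growth.  `clayped` provides the complete desk-scale analysis machinery for
this system, plus a synthetic trajectory generator so every stage can be
exercised and validated without any molecular-dynamics data.

Intended users: molecular-simulation and origins-of-life researchers who
want the interlayer observables (layer geometry, adsorption statistics,
surface diffusion, hydration energetics) and the wetting–drying kinetic
model as tested, reusable components.

## What it computes

**Layer geometry** (`layer_geometry`).  Metal atoms are clustered into
mineral layers with DBSCAN (neighbourhood radius 5 Å); d-spacing between
adjacent layers is mapped locally with a 5 × 5 Å window slid in 1 Å steps
across the xy-plane; undulation is the pooled standard deviation of metal
z-coordinates after centring each layer.

**Adsorption and templating** (`adsorption_templating`).  A molecule is
adsorbed when either C-terminal oxygen (OT1/OT2) lies within 2.5 Å of a
surface hydroxyl (the first hydration layer of LDH); aspartate side-chain
carboxylates (OD1/OD2) are scored separately, and peptide side-chain
percentages are scaled by residues-per-terminus.  The OT–Al radial
distribution function (against the Al–Al reference) probes lattice
templating; the elevation Θ of the terminal C→N vector (1° bins, 0° ⊥ /
90° ∥ to the surface) quantifies backbone alignment; *reactive pairs* —
C- and N-termini of two adsorbed molecules within 4 Å, intramolecular
(cyclic) closures excluded, aspartate α + β routes summed — are a geometric
proxy for bond-forming arrangements.

**Surface dynamics** (`surface_dynamics`).  For every molecule adsorbed in
two consecutive frames, the xy drift velocity (Å ns⁻¹) and polar direction
are collected; the circular autocorrelation of the direction histogram is
tested for the 60°-periodic peaks of lattice-templated diffusion (with a
seeded Monte-Carlo significance null); residence is the fraction of time a
molecule stays bound after its first adsorption event.

**Hydration energetics** (`energetics`).  The per-water hydration energy

    ΔU_H = (⟨U(N)⟩ − ⟨U(0)⟩) / N

is compared against bulk SPC water (−33.25 kJ mol⁻¹): strictly lower means
the interlayer is prone to rehydrate (swell).

**Wetting–drying kinetics** (`wetdry_kinetics`).  Surface-activated chain
extension X₁ + Xₙ → Xₙ₊₁ with a single rate constant k = 1 on a surface of
capacity 100 is integrated to monomer exhaustion (a dehydration); each
wetting releases 5% of every chain (n ≥ 2) and repopulates the surface with
monomers from an infinite bath.  A seeded Gillespie stochastic twin
cross-checks the deterministic integration.

**Synthetic generator** (`synth_traj`).  Builds the 5-layer hexagonal
Mg₃Al(OH)₈ slab (layer thickness 5.3 Å, exact 3:1 Mg:Al), populates
interlayers with bead amino acids/peptides at a chosen hydration (waters
per amino acid from the ladder 20/15/10/7/5/3/2/0), and evolves them with a
two-state adsorption Markov chain (stationary bound fraction 0.95 by
default), optionally six-fold-biased lateral walks, sinusoidal layer
undulations, and a monotone energy-vs-water profile — all bit-reproducible
from one seed.

## Worked example

```python
from clayped import *

cfg = GeneratorConfig(nx=12, ny=12, n_layers=5, rng_seed=42, hydration=7)
traj, energies = generate(cfg, ["ALA"] * 24, n_frames=100)

la = assign_layers(traj.first_frame())
print("layers:", la.n_layers, "d-spacing:", round(d_spacing(la, traj.first_frame()).mean, 2), "A")

ads = adsorption_fraction(traj, cutoff=2.5)
print("percent adsorbed (backbone):", round(ads.summary()["percent_backbone"], 1))
print("residence after first binding:", round(residence(traj, ads).mean, 3))

st = track_velocities(traj, ads)
print("mean drift velocity:", round(float(st.velocities.mean()), 1), "A/ns")

cfg0 = GeneratorConfig(nx=12, ny=12, n_layers=5, rng_seed=42, hydration=0)
_, e0 = generate(cfg0, ["ALA"] * 24, n_frames=100)
he = hydration_energy(energies, e0)
print(f"dU_H = {he.delta_u:.2f} kJ/mol per water; rehydrates: {he.will_rehydrate}")
```

prints

```
layers: 5 d-spacing: 13.0 A
percent adsorbed (backbone): 94.3
residence after first binding: 0.945
mean drift velocity: 12.4 A/ns
dU_H = -40.00 kJ/mol per water; rehydrates: True
```

— a 5-layer slab with a 13 Å repeat; at 7 waters per amino acid nearly all
molecules are bound through their carboxylates and, once bound, stay bound
~95% of the time while still drifting laterally; the hydrated interlayer is
energetically favourable relative to bulk water, so the dry system would
re-swell.

The kinetic model from the command line:

```bash
clayped kinetics --cycles 20 --out ledger.csv
```

```json
{
  "longest_after_cycle_1": 6,
  "first_cycle_at_threshold": {
    "X2": 1, "X3": 1, "X4": 1, "X5": 1, "X6": 1,
    "X7": 4, "X8": 7, "X9": 10, "X10": 12, "X11": 15, "X12": 18
  }
}
```

A single dehydration grows dimers through hexamers (longest chain holding
at least 1% of the surface capacity); each additional wetting–drying cycle
extends the reach by roughly one length every few cycles, and 10-mers — the
length of the shortest protein — first appear in significant amount at
cycle 12.

Other subcommands: `clayped generate | layers | adsorption | rdf | orient |
pairs | diffusion | energy | run` (see `--help`); `clayped run --config
run.yaml` executes a whole configured pipeline with a provenance record.

## Layout

```
src/clayped/
  io.py                    trajectory containers, GRO/PDB/XYZ + energy CSV I/O
  synth_traj.py            synthetic slab/interlayer generator
  layer_geometry.py        DBSCAN layers, d-spacing maps, undulation
  adsorption_templating.py adsorption, RDF, orientation, reactive pairs
  surface_dynamics.py      drift velocities, six-fold test, residence
  energetics.py            hydration energy vs bulk water
  wetdry_kinetics.py       ODE + Gillespie wetting-drying model
  pipeline.py, cli.py      configured runs, click CLI
docs/methods.md            model and implementation notes
```
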