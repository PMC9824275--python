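# Methods

This note records the models behind `nanofib`, their assumptions, the
parameters that matter, and the limits of what the synthetic data can
show. Internal units are nm, Da, e and a pseudo-ns time label; the
dynamical modules additionally use reduced (dimensionless) energies,
forces and times.

## Polymer mappings and chains

Chains follow the 4-heavy-atoms-per-bead convention of coarse-grained
polymer force fields:

| material | beads per monomer | bead masses (Da) | backbone bond (nm) |
|----------|-------------------|------------------|--------------------|
| PS | 4 (1 backbone CH2–CH + 3 phenyl) | 27.05 + 3 × 25.70 | 0.27 |
| PE | 1 per 2 monomers (C4H8) | 56.10 | 0.47 |
| PP | 1 per monomer (C3H6) | 42.08 | 0.36 |

Bead masses are chosen so the CG mass of a monomer equals its chemical
mass (styrene 104.15, ethylene 28.05, propylene 42.08 Da); `chemical_mass`
and the CG bead-mass total therefore agree, and a particle's mass is
unambiguous. PE's half-bead-per-monomer granularity means odd monomer
counts round down (with a warning), and a charged PE bead can carry 2 e
(one per monomer it spans) so that charge accounting stays exact on a
monomer basis.

Charge percentages refer to **monomers**: 20% of a 450-monomer PS
particle is 90 charged monomers carrying ±90 e. The charge sits on the
monomer's backbone bead. The alternative reading (percent of beads) is
available by charging a system built with the appropriate density but is
not the default, because only the monomer basis reproduces the
±18/±45/±90 e series for 4/10/20% on 450 monomers.

Default multi-chain systems: PS 9 × 50, PE 18 × 160, PP 12 × 160
monomers — within the 50–160 monomers-per-chain and 9–18 copies ranges
that produce a few-nm particle. The default initial conformation is a
zig-zag with a seeded random orientation; the study-assembly path uses
seeded random-walk conformations instead, because a 160-monomer zig-zag
(≈37 nm) cannot be packed into a working box. Chains are placed with a
0.47 nm inter-chain clash floor (one bead diameter). The chemical mass
of the default PS particle is 46.9 kDa; no attempt is made to force a
particular kDa figure, since it depends on the mapping convention —
both chemical and CG masses are reported.

## Nanoparticle assembly

Assembly substitutes a desk-scale surrogate for vacuum MD. Forces on
beads: a Lennard-Jones-like pair attraction (ε = 1, σ = 0.47 nm, 1.2 nm
cutoff, force-capped at 500 to tolerate bad initial contacts), harmonic
bonds (k = 500), an **unscreened** Coulomb term over all charged-bead
pairs (vacuum has no dielectric screening; strength 40 reduced units),
and a two-phase mean-field cohesion term: during the *gather* phase
(first 35% of 1200 steps) every chain is pulled rigidly toward the
system centroid (k = 12 × ε), standing in for the diffusive encounters
a cutoff pair potential cannot produce at toy scale; during the
*release* phase the pull drops to 0.02 so the final structure is decided
by the pair interactions alone. Overdamped Langevin integration
(dt = 2 × 10⁻⁴, kT = 0.1) is followed by 150 steps of zero-temperature
descent. Cluster count is reported as the connected components of the
bead graph at 0.8 nm.

The Coulomb strength was calibrated once, against the qualitative
physics the model must show: at 4–20% charge density cohesion wins and
a single compact particle forms, while at 50% the electrostatic
repulsion prevails and the system fragments into several clusters
during the release phase. At strength 40 the window is wide on both
sides (20% never fragments, 50% fragments into ~3–6 clusters in most
seeds). Neutral particles come out as irregular spheroids of ≈10 nm
equivalent diameter and shape factor ≈0.35 — somewhat larger and more
anisotropic than a fully equilibrated vacuum-MD particle, which is
acceptable because downstream analyses depend on contact geometry, not
on hitting a particular diameter.

Limit behaviours are exact: with ε = 0 and kT = 0 assembly is the
identity, and assembly never alters the bond topology.

## Fibril model

One bead per residue at the backbone position. The in-plane peptide
trace is a β-hairpin: residues 1–20 along one leg (0.35 nm spacing),
the E22–D23 region at the turn, 24–42 on the antiparallel return leg
0.6 nm away. This is *not* a copy of any deposited fold; it preserves
the two features the analyses care about — the N-terminal charges
(D1, E3, R5, D7, E11) and the K16–F20 stripe are exposed on the lateral
surface, and E22–D23 sit at an exposed corner. The base unit is two
C2-related protofilaments (lateral offset 1.0 nm, axial offset half a
rise) × four layers at 0.48 nm rise; 4 longitudinal repeats give the
32-chain, ≈8 nm working fibril.

Annotation: Asp/Glu −1, Lys/Arg +1, His neutral-polar; hydrophobic set
A V L I M F W P G; everything else polar. Termini are uncharged, so
each chain nets −3 e and the 32-chain fibril −96 e. Annotation is a
pure function of residue identity (position-independent), asserted by
tests.

Faces: *frontal* = all residues whose chain lies in the first or last
layer along the axis (depth configurable, default one layer — the
minimal unambiguous reading of "growth ends"); *side* = the rest.

Loading an external base unit (PDB/GRO, Cα or backbone bead per
residue) reuses the same annotation pipeline. The stacking axis of a
loaded unit is inferred from the displacement of the two closest chain
centres of mass — adjacent rungs of one protofilament — rather than
from the smallest-inertia principal axis, because for a flat 8-chain
unit the smallest-moment axis lies in the peptide plane, not along the
stack. Layers are then assigned by flooring axial positions onto a
one-rise grid, which keeps half-rise-interdigitated protofilament
partners in the same layer.

## Toy binding trajectories

The nanoparticle moves as a rigid body (overdamped Langevin for
translation and rotation; friction proportional to bead count, and to
bead count × squared gyration radius for rotation) around a fixed
fibril in a periodic 20 nm box with minimum-image distances. The rigid
body and fixed fibril are deliberate: the analyses need relative motion
and contact geometry, and adsorbed particles neither deform much nor
disassemble fibrils on these scales.

Forces, per `InteractionMatrix`:

* residue-wise attractive wells, depth by class / residue code / 1-based
  sequence position (precedence in that order), range
  exp(−(r − 0.47)/0.6), cutoff 3 nm, with a soft-core contact repulsion
  (k = 200) below 0.47 nm;
* screened Coulomb (strength 30, Debye length 1.5 nm) between charged
  NP beads and charged residues — this term shapes *which* residues a
  charged particle touches;
* an approach bias: a constant force (6 per bead) toward a target point
  (default the fibril centroid), released once the closest bead pair is
  within 0.7 nm. It stands in for the slow diffusive search that a
  125-step toy trajectory cannot perform. The particle's **net** charge
  modulates this bias as a mean-field monopole: the product of NP and
  fibril net charges is subtracted from it (1 reduced unit per e), so
  like-charged solutes are driven apart — this term, not the bead-pair
  Coulomb sum, is what guarantees that negatively charged particles
  never reach contact, mirroring their expected electrostatic exclusion
  from an overall-negative fibril.

Integration: dt = 0.01, kT = 1, translational steps capped at 0.3 nm
for stability. Frames (default 25, stride 5 → 125 steps) are labelled
in pseudo-ns spanning a nominal 1000 ns so time-series plots have
conventional axes; no physical time mapping is claimed.

Default material presets: PS favours aromatics (F 2.0, Y/W 1.6,
hydrophobic 1.2), PE/PP are generically hydrophobic (1.0); polar and
charged residues get 0.2–0.3.

**Study design.** `generate_study_fixtures` enumerates 9 NP species
(PS, PE, PP, PS4±, PS10±, PS20±; charged variants share the assembled
PS body with surface-placed charges) × 8 random-pose replicas
(placement gap > 4 nm) + 8 fibril-only controls = 80 systems, with all
per-system seeds derived from one master seed via `SeedSequence`
hashing. Trajectories are bit-reproducible for a (config, interactions,
seed) triple.

**Steered configurations** (`make_steered_config`) exist to give the
analysis pipeline a constructed truth: the bias target becomes a
tweezer-like hold point at a fixed standoff outside a chosen surface
region (a growth end, the lateral surface, or a stripe of sequence
positions), and the bias never releases. The recovery tests use a small
bead-ball probe (48 beads, 0.5 nm radius) rather than a full-size
particle, because a footprint smaller than a fibril face makes the
intended label unambiguous; a 10 nm particle parked on an 8 nm fibril's
end necessarily drapes onto the sides, which is a geometric fact, not
an analysis error.

## Contact analytics

A residue is in contact when its minimum-image bead–NP-bead distance is
≤ the cutoff (default 0.8 nm; closed boundary; centre-to-centre — the
convention is explicit because bead radii are not part of the model).
Counts are **residues in contact**, not bead pairs. Detection uses a
periodic k-d tree and is tested for exact equality against an O(N²)
brute-force oracle on randomized frames, including images across the
box boundary.

First-contact time: first frame opening a run of ≥ k consecutive
contact frames (k = 1 by default; higher k filters grazing blips in
noisy toy data). Per-position frequency: fraction of frames in which
any chain's copy of a position is in contact (per-chain resolution
available). Contact type: among all contact events from the first
persistent contact onward, *frontal* if the frontal-face fraction
exceeds 0.5, else *side*; ties go to side (the modal outcome for
lateral surfaces, which dominate the fibril's area); *none* if no
contact ever forms.

## Shape factor

Point-mass inertia tensor about the centre of mass; eigenvalues sorted
ascending; the defining expression SF = 1 − Ix/((Iy + Iz)/2) is a
*ratio* of the smallest moment to the mean of the other two — that is
the only reading with the sphere → 0 and rod → 1 limits. Alignment of
the lowest-moment axis to x is provided for output conventions but SF
itself is rotation-, translation- and mass-scale-invariant (tested to
1e−10). Degenerate spectra (spheres) are resolved deterministically by
the eigensolver's ordering plus a largest-coordinate sign convention.
Bead masses are used when available; SF is insensitive to this for
compositionally homogeneous particles.

Oracles: a uniform solid ellipsoid with semi-axes (a,b,c) has
I = m/5 · (b²+c², a²+c², a²+b²), giving SF = 0.6 for (2,1,1); a
10⁴-bead sampled sphere gives |SF| < 0.02; an axis-aligned collinear
rod gives SF = 1.0 exactly (its smallest moment is exactly zero).

## What the synthetic data does and does not show

The generator reproduces, by construction: the model-construction
arithmetic (bead counts, masses, charges, 8 × 4 × 42 fibril, 80-system
design); persistent binding for attractive species; electrostatic
exclusion of negatively charged particles; assembly fragmentation at
50% charge density; and recoverable ground truth for face- and
position-resolved analyses. Passing tests therefore validate the
*analysis operators* and the *model builders*, not the binding
thermodynamics: the toy force field has no solvent, no counter-ions, no
calibrated energetics, and its approach bias replaces genuine diffusive
search. Quantities that depend on real energetics — which species binds
in how many replicas out of eight, the 50–800 ns onset times, the
specific side/frontal split per material, the 0.25–0.40 initial SF of
MD-relaxed particles — are monitored where convenient but never
asserted.

## Numerical choices and degenerate inputs

* Contact boundary closed (≤); binary-exact cutoffs used in boundary
  tests to avoid representation artefacts.
* Assembly force cap 500 and trajectory step cap 0.3 nm prevent
  singular kicks from bad initial geometry; genuinely non-finite forces
  raise a `NumericalFailureError` naming the bead.
* Zero-bead, zero-mass, collocated-bead, single-layer and
  unknown-residue inputs raise typed errors (`errors.py`) rather than
  propagating NaNs.
* All stochastic operations take explicit integer seeds; fixture seeds
  derive from a master seed by fixed hashing. Equal seeds are
  bit-identical everywhere.
* Problem sizes in tests and examples (125-step trajectories, 1200-step
  assemblies, 10-seed repetition counts) are the package's chosen toy
  scale: large enough for every qualitative regime to be exercised,
  small enough to keep the full suite interactive.

## Known limitations

* The hairpin cross-section is an idealisation; analyses that depend on
  the true LS-fold surface topography (e.g. exact per-residue exposure)
  will differ on real structures, which can be loaded via
  `load_base_unit`.
* The mean-field monopole folded into the approach bias makes the
  *sign* of the net-charge interaction decisive and ignores dipole and
  patch effects at long range; patch-level electrostatics act only
  through the short-range bead-pair term.
* GRO round trips preserve coordinates to the format's 3 decimals but
  not chain identifiers (a GRO limitation); use PDB for multi-chain
  round trips.
* The assembly surrogate conserves topology and reaches compact
  spheroids but its density is set by the LJ σ and the force caps, not
  by a fitted equation of state; particle diameters are ≈1.5× those of
  fully equilibrated MD particles.
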