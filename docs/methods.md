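# Methods

`groovedyn` analyses trajectories of the *membrane-anchored* conformation of
Bcl-xL: the soluble head (helices α1–α7) keeps its solution fold above the
bilayer while the C-terminal helix α8 sits transmembrane. The package
computes per-frame geometric descriptors of that architecture, the
charge/ion bookkeeping of the simulation systems, and ships a ground-truth
synthetic-trajectory generator used to validate everything.

## Descriptors

**Helix principal axis.** For a helix defined by an inclusive residue span,
the axis is the eigenvector with the *smallest* eigenvalue of the
moment-of-inertia tensor of the helix Cα atoms, taken with unit masses
about their centroid:

    I = Σ_i (|r_i − r̄|² E − (r_i − r̄)(r_i − r̄)ᵀ)

The smallest-eigenvalue eigenvector is the long axis; its sign is fixed so
that it points N→C (positive dot product with `last Cα − first Cα`). Unit
masses are used because the descriptor is purely geometric; mass-weighting
Cα-only selections would change nothing but reproducibility. If the two
smallest eigenvalues agree to better than 1e-9 (relative), the point set
has no unique long axis and a degenerate-geometry error is raised rather
than picking an arbitrary direction.

Helix *memberships* (which residues belong to α5, α8, …) are fixed from the
initial configuration; the axis itself is recomputed on every frame —
otherwise an orientation time series would be impossible. A `frozen_axis`
option freezes the frame-0 vector instead, for comparison.

**BH3-groove vector.** With `a` the α5 (residues 143–153) principal axis
and `c` the vector from the geometric center of the Cα of residues 143–146
(α5) to that of residues 170–173 (α6),

    g = unit(a × c)

is the normal of the α5/axis–connector plane. The cross-product order is a
convention: flipping it maps every deviation angle ϕ to 180° − ϕ (an exact
involution, exposed as a `flip` flag and tested). The default order is
chosen so that angles above 90° correspond to the groove facing the
membrane (partially occluded) and below 90° to a solvent-exposed
(accessible) groove, which is the semantics that matters; only that 90°
boundary is physically meaningful, not the absolute sign.

**Deviation angles.** ϕ (groove) and ψ (TM helix α8, residues 209–231) are
`arccos(v·n)` in degrees, in [0, 180], against the membrane normal `n`.
The normal is the simulation-box z axis: the bilayers analysed are planar
and assembled normal to z, and fitting instantaneous normals is out of
scope. Accessibility classification puts the 90° boundary itself in the
occluded class (conservative); angles within 1e-9° of 90 are treated as
exactly 90 so floating-point noise cannot flip the class.

**Membrane frame.** Per frame, lipid phosphorus atoms (default atom name
`P`) are split into leaflets by the sign of `z − median(P z)` — robust for
planar bilayers, no clustering — and each leaflet's phosphate plane is the
arithmetic mean of its P z-coordinates. Insertion depths are signed
distances from the upper phosphate plane by default (the midplane is a
config option); positive points into the solvent on the head side. The
analysis assumes whole molecules; a protein split across periodic z-images
must be recentred upstream.

**Loop descriptors.** The α1–α2 loop spans residues 21–81 (Gly-21 is its
first residue; 61 residues). Its per-frame compactness is the unit-mass
Cα radius of gyration `Rg = sqrt(mean |r_i − centroid|²)`; whether an
all-atom, mass-weighted Rg was preferable is unknowable from a Cα
descriptor alone, so Cα/unit-mass is the default with a flagged
alternative. Marker residues (Gly-21 near the loop start, Gly-70 near its
middle) are tracked as Cα z-positions relative to the upper phosphate
plane.

**Interval statistics.** Time windows are half-open `[t0, t1)` so
consecutive windows partition a trajectory without double counting; the
non-stationary initial portion of a trajectory (e.g. t < 1 μs) is declared
by the user in the config — no automatic changepoint detection. Histograms
are density-normalized (integral exactly 1, asserted to 1e-9) with edges
anchored at integer multiples of the bin width so bins are comparable
across intervals; defaults are 2.5° for angles, 1 Å for z, 0.5 Å for Rg.
Summaries are plain linear mean/mode-bin/standard deviation: the deviation
angle is a polar angle against a fixed axis on [0°, 180°], not a circular
variable.

## Model building

The full-length anchored model is a chimera of a head structure (residues
1–222) and an isolated anchor-helix structure (residues 209–231), built in
three rigid steps (pairwise distances preserved to 1e-6 Å, deterministic,
no minimization):

1. the tail is rotated so the α8 principal axis lies along z. The N→C
   direction is a parameter: the anchored topology needs the N-terminal
   end of α8 (which carries Trp-213 and connects to the head) pointing
   *up* toward the head-side leaflet, so the build pipeline aligns N→C to
   −z. (Aligning N→C to +z makes the depth constraints below
   unsatisfiable, since Trp-213 would sit near the bottom of the helix.)
2. the head is least-squares superposed (Kabsch) onto the tail over the Cα
   atoms of an overlap window around the junction Gln-207 (default
   207–214; atoms are paired on the residues both sources actually cover,
   effectively 209–214). Residues ≤ 207 are kept from the head, > 207 from
   the tail, as one chain; the fit RMSD is reported, and a large RMSD
   warns rather than fails because the two sources are independent
   experimental structures.
3. the chimera is translated along z so that (a) the Trp-213 Cα lies just
   below the upper phosphate plane — within (0, 3] Å below it, the "just
   below" band being a package choice; (b) the closest head heavy atom
   (residues 1–207) is within 4 Å of the upper phosphate plane (the
   "membrane surface"); (c) the TM helix spans both phosphate planes.
   Anchor depths across the band are scanned and the feasible placement
   closest to the band midpoint is returned; if none exists the error
   names the violated constraints.

## Composition bookkeeping

Protein net charge is summed from integer sidechain charges plus charged
termini (+1/−1, net 0): `unprotonated` = Asp/Glu −1, His 0;
`protonated` = all acidic sidechains and histidines protonated, i.e.
Asp/Glu 0, His +1; Lys/Arg +1 always. Cardiolipin (TOCL) carries −1 per
lipid (singly ionized). Excess NaCl pairs come from the water count:
`floor(n_water · c / 55.345 M)`, the molarity of pure water; the floor (not
round) matters at the published water counts. Neutralizing ions then cover
`−(q_protein + q_lipid)` and both species carry the excess pairs on top, so
total system charge is exactly zero — a property asserted over randomized
sequences and compositions.

The default sequence is the full-length 233-residue human Bcl-xL. Its
titratable content (10 Asp, 21 Glu, 4 His) and its net charges (−11
unprotonated, +24 protonated) are the unique combination that reproduces
the ion counts of all four published simulation systems simultaneously
(43 Na⁺/32 Cl⁻, 32 Na⁺/56 Cl⁻, 131 Na⁺, 96 Na⁺); a 1–231 truncation, which
drops Arg-232/Lys-233, does not (−13/+22). The geometric model nonetheless
spans residues 1–231, the union of the two source structures — sequence
bookkeeping and structural coverage are independent inputs.

## The synthetic generator

Real microsecond trajectories of this system cannot be regenerated at desk
scale, so the pipeline is validated on synthetic data with known ground
truth:

* **Ideal helices** — canonical Cα traces (1.5 Å rise, 100° twist, 2.3 Å
  radius). A finite discrete helix generically has a small inertia-axis
  tilt (the x–z/y–z cross moments do not cancel over a non-integer number
  of turns; ≈5° for an 11-residue helix), so the trace is de-sheared —
  the per-coordinate regression on z is removed — making the inertia long
  axis equal the build axis *exactly*. The correction is a fraction of an
  Å.
* **Toy anchored protein** — a Cα-only two-domain model on the production
  residue numbering (α1 1–20, loop 21–81 as a semicircular arc, α5
  143–153, α6 164–181 offset ≈12 Å — a realistic packed-helix separation —
  filler strands, α8 209–231 transmembrane with residue 209 up). Real
  selections and configs run on it unchanged.
* **Membrane slab** — two planes of P-named beads at ±14 Å with optional
  seeded Gaussian z-noise. The 28 Å plane separation is thinner than a
  real POPC bilayer (~38 Å P-to-P) by design: a 23-residue Cα helix is
  34.5 Å long and must span both planes while its fifth residue stays just
  below the upper one.
* **Rigid-body trajectories** — per frame, the head is rotated about an
  in-plane axis so the *recomputed* groove angle equals the scheduled
  ϕ(t) exactly (the rotation is built from the recomputed reference
  vectors; equivariance of the inertia eigenvector and cross product under
  rotation does the rest), the TM helix is rotated to the prescribed tilt
  the same way, and the loop is optionally rescaled about its centroid to
  a prescribed Rg, or individual loop Cα atoms pinned at prescribed
  z-offsets (the two prescriptions are mutually exclusive — pinning
  perturbs the realized Rg). Schedules: constant, sharp piecewise, linear
  ramp, and an Ornstein–Uhlenbeck process discretized with its exact
  conditional law (so stationary mean/sd are analytic); OU draws are
  clipped to [0.5°, 179.5°]. Per-atom Gaussian noise is applied last.
  Identical seeds give byte-identical coordinates.

What the generator does **not** emulate: internal protein flexibility
beyond the scripted loop, lipid structure beyond phosphate planes, any
force field or thermodynamics, membrane curvature, periodic-image
artifacts. Passing recovery tests therefore demonstrates the correctness
of the geometric pipeline, not anything about real conformational
dynamics.

## Problem sizes and numerics

Synthetic validation runs use 500-frame, 5 μs trajectories (0.01 μs/frame,
~430 atoms), small enough that the complete test suite and the acceptance
script finish in seconds while the recovery bounds are tight: noise-free
recovery of prescribed angles is exact to ≪1e-6°, and with 0.5 Å per-atom
Gaussian noise the mean groove-angle error is ≈1.7–1.8°, dominated by the
α5-axis and 4-atom-center estimates. Times are μs, lengths Å, angles
degrees throughout. Rigid transforms preserve pairwise distances to
1e-6 Å; superposition uses scipy's Kabsch implementation; collinearity of
the groove construction vectors below 1e-6 rad and inertia-eigenvalue
gaps below 1e-9 raise errors rather than returning arbitrary vectors.

## Known limitations

* The baseline trajectory dialect is multi-model PDB (3-decimal
  coordinates); binary formats can be adapted behind the same `Trajectory`
  contract but are not included.
* The membrane normal is the box z axis; tilted or curved bilayers are out
  of scope.
* Leaflet assignment by median z fails deliberately (with an error) if all
  phosphorus atoms fall on one side.
* No pKa prediction: protonation states are discrete inputs, not
  predictions.
* The builder never remodels the α1–α2 loop or repacks sidechains; it is
  rigid-body only.
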