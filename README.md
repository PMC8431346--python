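# groovedyn

Conformational-geometry analysis for the **membrane-anchored conformation
of Bcl-xL** — the anti-apoptotic Bcl-2-family protein whose C-terminal
helix α8 sits transmembrane while the soluble head (helices α1–α7) retains
its fold above the bilayer. Whether the head's BH3-binding groove faces the
solvent or the membrane decides whether Bcl-xL can engage the BH3 domains
of its pro-apoptotic partners, so the orientation of that groove, the
dynamics of the long α1–α2 loop, and the tilt of the anchor helix are the
descriptors that matter when comparing simulation conditions (protonation
states, cardiolipin content).

The package is aimed at people analysing MD trajectories of
membrane-anchored Bcl-2-family proteins, and at anyone who needs tested,
seeded synthetic fixtures for validating this class of trajectory
descriptor.

## What it computes

Per trajectory frame, against the membrane normal **n** (the bilayer z
axis, with per-leaflet phosphate planes taken as the mean lipid-phosphorus
z):

* **Groove deviation angle** ϕ = ∠(g, n), where the groove vector
  g = unit(a × c), a is the principal axis of helix α5 (residues 143–153;
  smallest-eigenvalue eigenvector of the Cα inertia tensor, sign-fixed
  N→C) and c connects the Cα centers of residues 143–146 (α5) to
  170–173 (α6). ϕ > 90° means the groove faces the membrane (partially
  occluded), ϕ < 90° a more accessible groove.
* **TM tilt** ψ = ∠(a_α8, n) for the anchor helix (residues 209–231).
* **Loop descriptors**: Cα radius of gyration of the 61-residue α1–α2 loop
  (residues 21–81) and z-positions of Gly-21/Gly-70 relative to the upper
  phosphate plane.
* **Interval statistics**: half-open stationary windows, density-normalized
  histograms, linear summaries.
* **System bookkeeping**: titratable-residue counts, protein net charge
  under the two protonation conventions (acids −1/His 0 vs acids 0/His +1),
  cardiolipin charge, excess-salt pairs from the water count, and the
  neutralizing Na⁺/Cl⁻ counts that bring the total charge to zero.

It also *builds* the anchored model (align anchor helix to z, superpose and
join head/tail at Gln-207, embed with Trp-213 just below the phosphate
plane and the head within 4 Å of the membrane surface) and *generates*
synthetic rigid-body trajectories in which ϕ(t), ψ(t) and the loop Rg
follow prescribed schedules exactly — the ground truth every test is
checked against. See `docs/methods.md` for the full method description.

## Worked example

```python
import numpy as np
from groovedyn import (AngleSchedule, make_anchored_toy, make_membrane_slab,
                       make_rigid_body_trajectory, groove_angle_series,
                       select_interval, histogram, summarize)

toy = make_anchored_toy()                 # Cα toy on production numbering
slab = make_membrane_slab(seed=0)         # phosphate planes at ±14 Å
sched = AngleSchedule("piecewise", levels=[100.0, 40.0], switch_fractions=[0.6])
traj, truth = make_rigid_body_trajectory(toy, slab, sched,
                                         n_frames=500, seed=11, noise_sd=0.5)

phi = groove_angle_series(traj)           # ϕ(t), one value per frame
err = np.abs(phi.values - truth.groove_angle)
print(f"mean |recovered − prescribed| = {err.mean():.2f} deg")

late = histogram(select_interval(phi, 3.5, 5.0), bin_width=2.5)
stats = summarize(late)
print(f"late-window mode bin: {stats.mode_bin}, mean {stats.mean:.1f} deg")
```

prints

```
mean |recovered − prescribed| = 1.80 deg
late-window mode bin: (40.0, 42.5), mean 40.1 deg
```

— the trajectory was generated with the groove occluded at 100° for the
first 3 μs and accessible at 40° afterwards, with 0.5 Å Gaussian noise on
every atom; the pipeline recovers the prescribed schedule to under 2° and
the late stationary window peaks at the prescribed 40° level.

The charge bookkeeping side:

```python
from groovedyn import CompositionSpec, ion_counts
spec = CompositionSpec(n_popc=411, n_tocl=0, n_water=36055, salt_mM=50.0)
print(ion_counts(spec, "unprotonated"))   # -> (43, 32)
```

i.e. 43 Na⁺ and 32 Cl⁻ neutralize the unprotonated 100% POPC system at
50 mM excess NaCl.

## Command line

```
groovedyn build-model --head head.pdb --tail tail.pdb --out model.pdb
groovedyn make-fixtures --schedule piecewise --levels 100,40 --out fixtures/
groovedyn analyze-groove traj.pdb --out groove.tsv
groovedyn analyze-loop traj.pdb --out loop.tsv
groovedyn analyze-tm traj.pdb --out tm.tsv
groovedyn composition-check --state unprotonated --popc 411 --water 36055 --salt 50
groovedyn report --config run.yaml --out run1/
```

`report` runs the full pipeline from one YAML config (residue spans and
stationary intervals must be stated explicitly) and writes time series,
per-interval histograms, summaries and a manifest with the config hash.

The numbered scripts under `analysis/` are narrative drivers: they build
the model, generate four synthetic study conditions (protonation ×
membrane-composition analogs with prescribed groove/loop behaviour), and
run the groove, loop, TM and composition analyses, writing tables under
`results/`.

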