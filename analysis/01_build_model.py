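"""Build the anchored chimera from synthetic head and tail sources.

Splits the toy anchored protein into a head (residues ≤ 222) and an anchor
tail (residues ≥ 209), rigidly scrambles both, then rebuilds: align the
anchor helix to z (N-terminal end up), superpose-and-join at Gln-207, and
embed at a phosphate-plane pair at ±14 Å.  Verifies the rebuilt model
matches the original and that every embedding constraint holds, and writes
the model plus a build report.
"""

import json
import os

import numpy as np

from groovedyn import (
    ALPHA8,
    JoinSpec,
    MembraneFrame,
    align_helix_to_z,
    embed_in_membrane,
    join_structures,
    make_anchored_toy,
    superpose,
    write_structure,
)
from groovedyn.model_builder import EmbeddingSpec, embedding_report

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)

rng = np.random.default_rng(5)


def scramble(model):
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return model.transformed(q, rng.normal(0, 25, 3))


toy = make_anchored_toy()
head = scramble(toy.subset(np.nonzero(toy.residue_numbers <= 222)[0]))
tail = scramble(toy.subset(np.nonzero(toy.residue_numbers >= 209)[0]))

tail = align_helix_to_z(tail, ALPHA8, direction="-z")
chimera, fit_rmsd = join_structures(JoinSpec(head_model=head, tail_model=tail))

membrane = MembraneFrame(np.array([0.0, 0.0, 1.0]), 14.0, -14.0)
spec = EmbeddingSpec()
embedded = embed_in_membrane(chimera, membrane, spec)
report = embedding_report(embedded, membrane, spec)
report["fit_rmsd_A"] = fit_rmsd
report["n_atoms"] = embedded.n_atoms

_, _, rebuild_rmsd = superpose(embedded.positions, toy.positions)
report["rmsd_to_reference_A"] = rebuild_rmsd

write_structure(embedded, os.path.join(OUT, "anchored_model.pdb"))
with open(os.path.join(OUT, "model_build_report.json"), "w") as fh:
    json.dump(report, fh, indent=2)

print("rebuilt anchored model from scrambled head + tail sources")
print(f"  overlap fit RMSD          : {fit_rmsd:.2e} Å (identical sources)")
print(f"  RMSD to reference pose    : {rebuild_rmsd:.2e} Å after superposition")
print(f"  anchor (Trp-213) depth    : {report['anchor_depth']:.2f} Å below upper plane")
print(f"  head–membrane gap         : {report['head_gap']:.2f} Å (≤ 4 Å required)")
print(f"  TM span                   : {report['tm_bottom_z']:.1f} … "
      f"{report['tm_top_z']:.1f} Å vs planes ±14 Å")
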