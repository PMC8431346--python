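"""Charge and ion bookkeeping for the four simulation systems.

From the full-length Bcl-xL sequence and each system's lipid/water/salt
composition, recomputes the titratable-residue counts, the protein net
charge under both protonation states, and the Na⁺/Cl⁻ counts that
neutralize each system — the published values for all four systems must
come out of one single charge-rule configuration.
"""

import os

import pandas as pd

from groovedyn import (
    BCLXL_SEQUENCE,
    CompositionSpec,
    count_residues,
    excess_salt_pairs,
    ion_counts,
    protein_net_charge,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)

print(f"construct: {len(BCLXL_SEQUENCE)} residues; titratable: "
      f"{count_residues(BCLXL_SEQUENCE, 'D')} Asp, "
      f"{count_residues(BCLXL_SEQUENCE, 'E')} Glu, "
      f"{count_residues(BCLXL_SEQUENCE, 'H')} His")
for state in ("unprotonated", "protonated"):
    print(f"net charge ({state:12s}): {protein_net_charge(BCLXL_SEQUENCE, state):+d}")

systems = [
    ("unprotonated", "100% POPC", 411, 0, 36055, 50.0),
    ("protonated", "100% POPC", 412, 0, 36094, 50.0),
    ("unprotonated", "2:1 POPC:TOCL", 239, 120, 46584, 0.0),
    ("protonated", "2:1 POPC:TOCL", 239, 120, 46586, 0.0),
]
rows = []
for state, membrane, popc, tocl, water, salt in systems:
    spec = CompositionSpec(n_popc=popc, n_tocl=tocl, n_water=water, salt_mM=salt)
    n_na, n_cl = ion_counts(spec, state)
    rows.append({
        "state": state, "membrane": membrane, "n_popc": popc, "n_tocl": tocl,
        "n_water": water, "salt_mM": salt,
        "excess_pairs": excess_salt_pairs(water, salt),
        "protein_charge": protein_net_charge(BCLXL_SEQUENCE, state),
        "lipid_charge": -tocl, "n_na": n_na, "n_cl": n_cl,
    })

table = pd.DataFrame(rows)
table.to_csv(os.path.join(OUT, "composition.tsv"), sep="\t", index=False)
print("\nion bookkeeping -> results/composition.tsv")
print(table.to_string(index=False))
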