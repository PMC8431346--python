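"""Simulation-system charge and ion bookkeeping.

A solvated protein–bilayer system is neutralized by adding counterions, on
top of any excess salt.  The arithmetic is elementary but easy to get
subtly wrong, so it lives here as tested code:

* protein net charge from the sequence under one of two protonation
  states — ``unprotonated`` (Asp/Glu −1, His 0) or ``protonated`` (all
  acidic sidechains and histidines protonated: Asp/Glu 0, His +1) — with
  Lys/Arg +1 and charged termini (+1/−1, net 0) in both;
* anionic-lipid charge (singly-ionized cardiolipin, −1 per TOCL);
* excess NaCl pairs from the water count and molar concentration,
  ``floor(n_water * conc / 55.345 M)``, using the molarity of pure water;
* Na⁺/Cl⁻ counts that bring the total system charge to exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigError

__all__ = [
    "ProtonationState",
    "UNPROTONATED",
    "PROTONATED",
    "CompositionSpec",
    "BCLXL_SEQUENCE",
    "count_residues",
    "protein_net_charge",
    "excess_salt_pairs",
    "ion_counts",
]

#: pure-water molarity (mol/L) used to convert water counts to box volume
WATER_MOLARITY = 55.345

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Human Bcl-xL (Bcl-2-like protein 1, 233 aa).  The anchored model is a
#: chimera of two NMR structures of this sequence; the charge bookkeeping
#: uses the full-length sequence.
BCLXL_SEQUENCE = (
    "MSQSNRELVVDFLSYKLSQKGYSWSQFSDVEENRTEAPEGTESEMETPSA"
    "INGNPSWHLADSPAVNGATGHSSSLDAREVIPMAAVKQALREAGDEFELR"
    "YRRAFSDLTSQLHITPGTAYQSFEQVVNELFRDGVNWGRIVAFFSFGGAL"
    "CVESVDKEMQVLVSRIAAWMATYLNDHLEPWIQENGGWDTFVELYGNNAA"
    "AESRKGQERFNRWFLTGMTVAGVVLLGSLFSRK"
)


@dataclass(frozen=True)
class ProtonationState:
    """Integer sidechain charges for the titratable residues, plus termini."""

    name: str
    charges: Mapping[str, int]
    n_terminus: int = +1
    c_terminus: int = -1

    def residue_charge(self, aa: str) -> int:
        return self.charges.get(aa, 0)


UNPROTONATED = ProtonationState(
    "unprotonated", {"D": -1, "E": -1, "H": 0, "K": +1, "R": +1}
)
PROTONATED = ProtonationState(
    "protonated", {"D": 0, "E": 0, "H": +1, "K": +1, "R": +1}
)

_STATES = {"unprotonated": UNPROTONATED, "protonated": PROTONATED}


def get_state(name: str | ProtonationState) -> ProtonationState:
    if isinstance(name, ProtonationState):
        return name
    try:
        return _STATES[name]
    except KeyError:
        raise ConfigError(
            f"unknown protonation state {name!r} (choose from {sorted(_STATES)})"
        ) from None


@dataclass(frozen=True)
class CompositionSpec:
    """Membrane/solvent composition of one simulation system."""

    n_popc: int
    n_tocl: int
    n_water: int
    salt_mM: float
    sequence: str = BCLXL_SEQUENCE
    tocl_charge_per_lipid: int = -1

    def __post_init__(self) -> None:
        if min(self.n_popc, self.n_tocl, self.n_water) < 0 or self.salt_mM < 0:
            raise ConfigError("lipid, water and salt amounts must be non-negative")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ConfigError(f"unknown residue letters in sequence: {sorted(bad)}")
    return seq


def count_residues(sequence: str, residue_type: str) -> int:
    """Occurrences of a one-letter residue type in the sequence."""
    if residue_type.upper() not in AMINO_ACIDS:
        raise ConfigError(f"unknown residue type {residue_type!r}")
    return _validate_sequence(sequence).count(residue_type.upper())


def protein_net_charge(sequence: str, state: str | ProtonationState) -> int:
    """Net integer charge of the protein: sidechains plus termini."""
    state = get_state(state)
    seq = _validate_sequence(sequence)
    charge = state.n_terminus + state.c_terminus if seq else 0
    return charge + sum(state.residue_charge(aa) for aa in seq)


def excess_salt_pairs(n_water: int, conc_mM: float) -> int:
    """Number of excess NaCl pairs for a target molar concentration,
    ``floor(n_water * conc / WATER_MOLARITY)``."""
    if n_water < 0 or conc_mM < 0:
        raise ConfigError("water count and concentration must be non-negative")
    return math.floor(n_water * (conc_mM / 1000.0) / WATER_MOLARITY)


def ion_counts(
    spec: CompositionSpec, state: str | ProtonationState
) -> tuple[int, int]:
    """(n_Na, n_Cl) neutralizing the system and supplying the excess salt.

    The neutralizing species covers ``-(q_protein + q_lipid)``; both species
    carry the excess-salt pair count on top.  Total charge after placement
    is exactly zero.
    """
    q_p = protein_net_charge(spec.sequence, state)
    q_l = spec.n_tocl * spec.tocl_charge_per_lipid
    pairs = excess_salt_pairs(spec.n_water, spec.salt_mM)
    q = q_p + q_l
    n_na = pairs + max(0, -q)
    n_cl = pairs + max(0, q)
    assert q + n_na - n_cl == 0
    return n_na, n_cl
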