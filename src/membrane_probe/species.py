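"""Particle species vocabulary and the residue/atom-name mapping.

The toolkit works on coarse bead models of a hydrated bilayer.  Every particle
carries one of a small set of species tags; the mapping between those tags and
the residue/atom names used in PDB/GRO files is shipped as an editable YAML
file (``species_map.yaml``) so that users can adapt the readers to their own
naming conventions without touching code.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import yaml

LIPID_HEAD = "LIPID_HEAD"
LIPID_TAIL = "LIPID_TAIL"
DDA_C = "DDA_C"
DDA_O = "DDA_O"
DDA_H = "DDA_H"
WATER_O = "WATER_O"
WATER_H = "WATER_H"
FLAV = "FLAV"

ALL_SPECIES = (LIPID_HEAD, LIPID_TAIL, DDA_C, DDA_O, DDA_H, WATER_O, WATER_H, FLAV)

#: molecule family implied by each species tag
SPECIES_FAMILY: Mapping[str, str] = {
    LIPID_HEAD: "lipid",
    LIPID_TAIL: "lipid",
    DDA_C: "dda",
    DDA_O: "dda",
    DDA_H: "dda",
    WATER_O: "water",
    WATER_H: "water",
    FLAV: "flav",
}

#: residue name used when writing each molecule family
FAMILY_RESNAME: Mapping[str, str] = {
    "lipid": "DOPC",
    "dda": "DDA",
    "water": "SOL",
    "flav": "FLV",
}

#: atom-name prefix used when writing each species
SPECIES_ATOM_PREFIX: Mapping[str, str] = {
    LIPID_HEAD: "HD",
    LIPID_TAIL: "T",
    DDA_C: "C",
    DDA_O: "O",
    DDA_H: "H",
    WATER_O: "OW",
    WATER_H: "HW",
    FLAV: "F",
}


class SpeciesMap:
    """Residue/atom-name -> species resolution plus per-species electron counts."""

    def __init__(self, residues: Mapping[str, Mapping[str, str]], electrons: Mapping[str, int]):
        self.residues = {r: dict(a) for r, a in residues.items()}
        self.electrons = {s: int(e) for s, e in electrons.items()}
        for sp, e in self.electrons.items():
            if sp not in ALL_SPECIES:
                raise ValueError(f"unknown species {sp!r} in electron table")
            if e < 1:
                raise ValueError(f"electron count for {sp} must be >= 1, got {e}")

    def resolve(self, resname: str, atom_name: str) -> str:
        """Resolve a (residue, atom) pair to a species tag by longest-prefix match."""
        try:
            table = self.residues[resname]
        except KeyError:
            raise KeyError(resname) from None
        best = None
        for prefix, species in table.items():
            if atom_name.startswith(prefix) and (best is None or len(prefix) > len(best[0])):
                best = (prefix, species)
        if best is None:
            raise KeyError(f"{resname}/{atom_name}")
        return best[1]

    def electrons_for(self, species: str) -> int:
        return self.electrons[species]


def load_species_map(path: str | None = None) -> SpeciesMap:
    """Load the species map from ``path``, or the packaged default when omitted."""
    if path is None:
        text = resources.files("membrane_probe").joinpath("species_map.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    return SpeciesMap(data["residues"], data["electrons"])


DEFAULT_SPECIES_MAP = load_species_map()
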