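"""Core containers: particle frames, trajectories, and periodic-box geometry.

Positions are in nm throughout; boxes are orthorhombic (lengths only).
Molecules are never split across the periodic boundary by the generators, so
centres of mass are plain bead averages (all beads carry equal mass by
construction of the coarse model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .species import SPECIES_FAMILY


@dataclass
class Frame:
    """One configuration: positions (N,3) nm, per-particle species tags,
    molecule ids, electron counts and the orthorhombic box lengths (nm)."""

    positions: np.ndarray
    species: np.ndarray
    molecule_id: np.ndarray
    electrons: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.electrons = np.asarray(self.electrons, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        for name in ("species", "molecule_id", "electrons"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match positions")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if np.any(self.electrons < 1):
            raise ValueError("electron counts must be >= 1")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def validate_molecules(self) -> None:
        """Every molecule id must map to a single species family."""
        fams = np.array([SPECIES_FAMILY[s] for s in self.species])
        for mol in np.unique(self.molecule_id):
            if len(set(fams[self.molecule_id == mol])) != 1:
                raise ValueError(f"molecule {mol} mixes species families")

    def wrapped_positions(self) -> np.ndarray:
        """Positions wrapped into [0, box) along each axis."""
        return np.mod(self.positions, self.box)

    def select(self, species) -> np.ndarray:
        """Boolean mask of particles whose species is in ``species``
        (a tag or an iterable of tags)."""
        if isinstance(species, str):
            species = (species,)
        return np.isin(self.species, list(species))

    def molecule_family(self) -> dict[int, str]:
        fams = {}
        for sp, mol in zip(self.species, self.molecule_id):
            fams.setdefault(int(mol), SPECIES_FAMILY[sp])
        return fams

    def molecules_of(self, family: str) -> np.ndarray:
        """Sorted molecule ids belonging to one family ('lipid', 'dda', ...)."""
        fams = self.molecule_family()
        return np.array(sorted(m for m, f in fams.items() if f == family), dtype=int)

    def molecule_com(self, mol_ids) -> np.ndarray:
        """Equal-mass centres of mass, one row per id in ``mol_ids``."""
        mol_ids = np.asarray(mol_ids, dtype=int)
        order = np.argsort(self.molecule_id, kind="stable")
        sorted_ids = self.molecule_id[order]
        out = np.empty((len(mol_ids), 3))
        for i, mol in enumerate(mol_ids):
            lo = np.searchsorted(sorted_ids, mol, side="left")
            hi = np.searchsorted(sorted_ids, mol, side="right")
            if lo == hi:
                raise KeyError(f"molecule {mol} not present")
            out[i] = self.positions[order[lo:hi]].mean(axis=0)
        return out


@dataclass
class Trajectory:
    """Ordered frame sequence with constant particle count and ordering."""

    frames: list
    frame_interval: float = 1.0  # ns, metadata only
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        n0 = self.frames[0].n_particles
        for i, fr in enumerate(self.frames):
            if fr.n_particles != n0:
                raise ValueError(f"frame {i} has {fr.n_particles} particles, expected {n0}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def window(self, fractions: tuple[float, float] | None) -> list:
        """Frames whose index falls in [start, end) fractions of the length.

        ``window((0.25, 1.0))`` keeps the last 75 % of the frames (at least one
        frame is always kept).
        """
        if fractions is None:
            return list(self.frames)
        lo, hi = fractions
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("window fractions must satisfy 0 <= lo < hi <= 1")
        n = len(self.frames)
        i0 = min(int(np.floor(lo * n)), n - 1)
        i1 = max(int(np.ceil(hi * n)), i0 + 1)
        return list(self.frames[i0:i1])


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors ``d``.

    Works on the trailing axis; ``box`` may have fewer components than 3 for
    lateral (2D) displacements.
    """
    d = np.asarray(d, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def pair_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum-image distance between two points."""
    return float(np.linalg.norm(minimum_image(np.asarray(b) - np.asarray(a), box)))
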