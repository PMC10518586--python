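"""Structural statistics of bilayer trajectories.

All distances use the minimum-image convention in the orthorhombic box; pair
searches go through a periodic KD-tree on wrapped coordinates (the test suite
checks them against independent brute-force enumeration).  The bilayer
midplane is defined per frame as the mean z of the lipid head beads; leaflets
are assigned by the sign of the head-bead z relative to it.

Averaging windows are expressed as fractions of the trajectory length so that
"the last three quarters" or "the last quarter" of a run can be selected
regardless of frame count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import species as sp
from .core import Frame, Trajectory, minimum_image

#: default geometric hydrogen-bond criterion: donor-acceptor distance (nm)
#: and donor-H...acceptor angle (deg).  Standard values; configurable.
DEFAULT_DA_CUTOFF = 0.35
DEFAULT_ANGLE_MIN = 150.0


# ---------------------------------------------------------------------------
# Leaflets

@dataclass
class LeafletAssignment:
    upper: np.ndarray  # lipid molecule ids
    lower: np.ndarray
    midplane: float  # z of the head-bead mean (nm)


def assign_leaflets(frame: Frame) -> LeafletAssignment:
    """Split lipids into leaflets by head-bead z relative to the midplane.

    Translation invariant; warns (does not fail) when all lipids end up on one
    side.
    """
    heads = frame.select(sp.LIPID_HEAD)
    if heads.sum() < 2:
        raise ValueError("need at least two lipids to assign leaflets")
    z0 = float(frame.positions[heads, 2].mean())
    mols = frame.molecule_id[heads]
    upper = np.unique(mols[frame.positions[heads, 2] > z0])
    lower = np.unique(mols[frame.positions[heads, 2] <= z0])
    if len(upper) == 0 or len(lower) == 0:
        warnings.warn("all lipids assigned to a single leaflet", stacklevel=2)
    return LeafletAssignment(upper=upper, lower=lower, midplane=z0)


def _midplane(frame: Frame) -> float:
    heads = frame.select(sp.LIPID_HEAD)
    return float(frame.positions[heads, 2].mean()) if heads.any() else 0.0


# ---------------------------------------------------------------------------
# Density profiles

@dataclass
class DensityProfile:
    bin_edges: np.ndarray  # nm, along the bilayer normal (midplane-centred)
    values: np.ndarray  # number (or electron) density per nm^3
    n_frames_averaged: int
    species: tuple
    weighted_by_electrons: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def integral(self, lateral_area: float) -> float:
        """Sum of value x bin volume: the mean particle (or electron) count."""
        dz = np.diff(self.bin_edges)
        return float(np.sum(self.values * dz) * lateral_area)


def _z_profile(traj: Trajectory, mask_fn, bin_width: float, recenter: bool,
               weight_fn=None) -> tuple[np.ndarray, np.ndarray]:
    box = traj[0].box
    lz = box[2]
    n_bins = max(1, int(round(lz / bin_width)))
    edges = np.linspace(-lz / 2.0, lz / 2.0, n_bins + 1)
    acc = np.zeros(n_bins)
    for frame in traj:
        mask = mask_fn(frame)
        z = frame.positions[mask, 2]
        if recenter:
            z = z - _midplane(frame)
        z = minimum_image(z, lz)  # fold into [-lz/2, lz/2)
        w = weight_fn(frame, mask) if weight_fn is not None else None
        hist, _ = np.histogram(z, bins=edges, weights=w)
        acc += hist
    volume_per_bin = box[0] * box[1] * (lz / n_bins)
    return edges, acc / len(traj) / volume_per_bin


def number_density_profile(traj: Trajectory, species, bin_width: float = 0.1,
                           recenter: bool = True) -> DensityProfile:
    """Frame-averaged number density along z, recentred on the midplane.

    Conservation holds exactly: integrating value x bin volume returns the
    mean particle count of the selection.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(species, str):
        species = (species,)
    if not traj[0].select(species).any():
        raise ValueError(f"no particles of species {tuple(species)} present")
    edges, values = _z_profile(traj, lambda fr: fr.select(species), bin_width, recenter)
    return DensityProfile(bin_edges=edges, values=values, n_frames_averaged=len(traj),
                          species=tuple(species))


def electron_density_profile(traj: Trajectory, bin_width: float = 0.1, species=None,
                             recenter: bool = True) -> DensityProfile:
    """z-profile of electron density (e/nm^3): the trajectory-side counterpart
    of the SAXS electron-density profile.  Empty selections give a zero
    profile rather than an error."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if species is None:
        mask_fn = lambda fr: np.ones(fr.n_particles, dtype=bool)  # noqa: E731
        tag: tuple = ("all",)
    else:
        if isinstance(species, str):
            species = (species,)
        mask_fn = lambda fr: fr.select(species)  # noqa: E731
        tag = tuple(species)
    edges, values = _z_profile(traj, mask_fn, bin_width, recenter,
                               weight_fn=lambda fr, m: fr.electrons[m].astype(float))
    return DensityProfile(bin_edges=edges, values=values, n_frames_averaged=len(traj),
                          species=tag, weighted_by_electrons=True)


# ---------------------------------------------------------------------------
# Radial distribution functions

@dataclass
class RDFResult:
    r_centers: np.ndarray
    g: np.ndarray
    mode: str  # "3d" | "lateral"
    n_molecules: int
    n_frames: int


def _resolve_molecules(frame: Frame, selection) -> np.ndarray:
    if isinstance(selection, str):
        return frame.molecules_of(selection)
    return np.asarray(sorted(selection), dtype=int)


def com_rdf(traj: Trajectory, selection, mode: str = "3d", r_max: float = 3.0,
            bin_width: float = 0.05) -> RDFResult:
    """Radial distribution function of molecule centres of mass.

    ``selection`` is a molecule family ('dda', 'lipid', 'water', 'flav') or an
    iterable of molecule ids.  Distances use the minimum image; g(r) is
    normalised by the ideal-gas expectation of the chosen mode (3D shells, or
    lateral annuli on the xy projection).  Aggregation shows up as g >> 1 at
    small r.
    """
    if mode not in ("3d", "lateral"):
        raise ValueError(f"unknown rdf mode {mode!r}")
    box = traj[0].box
    limit = min(box[:3]) / 2.0 if mode == "3d" else min(box[:2]) / 2.0
    if r_max > limit + 1e-12:
        raise ValueError(f"r_max {r_max} exceeds half the smallest box edge ({limit:.3f})")
    mols = _resolve_molecules(traj[0], selection)
    n = len(mols)
    if n < 2:
        raise ValueError("need at least two molecules for an RDF")
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    acc = np.zeros(n_bins)
    for frame in traj:
        coms = frame.molecule_com(mols)
        if mode == "3d":
            pts = np.mod(coms, box)
            tree = cKDTree(pts, boxsize=box)
        else:
            pts = np.mod(coms[:, :2], box[:2])
            tree = cKDTree(pts, boxsize=box[:2])
        pairs = tree.query_pairs(edges[-1], output_type="ndarray")
        if len(pairs):
            d = minimum_image(pts[pairs[:, 0]] - pts[pairs[:, 1]],
                              box if mode == "3d" else box[:2])
            hist, _ = np.histogram(np.linalg.norm(d, axis=1), bins=edges)
            acc += hist
    acc /= len(traj)
    n_pairs = n * (n - 1) / 2.0
    if mode == "3d":
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        domain = box[0] * box[1] * box[2]
    else:
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        domain = box[0] * box[1]
    g = acc / (n_pairs * shell / domain)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = centers <= r_max
    return RDFResult(r_centers=centers[keep], g=g[keep], mode=mode, n_molecules=n, n_frames=len(traj))


# ---------------------------------------------------------------------------
# Density maps

@dataclass
class DensityMap:
    values: np.ndarray  # 2D, number density nm^-3 averaged along the collapsed axis
    axis_u: np.ndarray  # cell centres along the first map axis (nm)
    axis_v: np.ndarray
    projection: str  # "parallel" (xy map) | "perpendicular" (xz map)
    voxel: float  # requested voxel edge (nm); actual cells below
    cell_u: float  # actual cell size along the first map axis (nm)
    cell_v: float
    mean_particles: float  # mean selected count per frame (conservation anchor)
    collapsed_length: float


def density_map(traj: Trajectory, species, projection: str = "parallel",
                voxel: float = 0.5, window: tuple | None = (0.75, 1.0)) -> DensityMap:
    """Time-averaged density map projected parallel (xy) or perpendicular
    (xz) to the bilayer plane.

    The frame window defaults to the last quarter of the trajectory, the
    convention for equilibrated lateral maps.  Summing value x voxel area x
    collapsed length recovers the mean particle count.
    """
    if projection not in ("parallel", "perpendicular"):
        raise ValueError(f"unknown projection {projection!r}")
    box = traj[0].box
    if voxel > min(box):
        raise ValueError("voxel larger than the box")
    if isinstance(species, str):
        species = (species,)
    frames = traj.window(window)
    axes = (0, 1, 2)
    nbins = [max(1, int(round(box[a] / voxel))) for a in axes]
    edges = [np.linspace(0.0, box[a], nbins[a] + 1) for a in axes]
    acc = np.zeros(nbins)
    count = 0.0
    for frame in frames:
        mask = frame.select(species)
        if not mask.any():
            raise ValueError(f"no particles of species {tuple(species)} present")
        pts = np.mod(frame.positions[mask], box)
        hist, _ = np.histogramdd(pts, bins=edges)
        acc += hist
        count += mask.sum()
    acc /= len(frames)
    count /= len(frames)
    voxel_vol = np.prod([box[a] / nbins[a] for a in axes])
    density3d = acc / voxel_vol
    if projection == "parallel":
        values = density3d.mean(axis=2)  # (x, y)
        u = 0.5 * (edges[0][:-1] + edges[0][1:])
        v = 0.5 * (edges[1][:-1] + edges[1][1:])
        cells = (box[0] / nbins[0], box[1] / nbins[1])
        collapsed = box[2]
    else:
        values = density3d.mean(axis=1)  # (x, z)
        u = 0.5 * (edges[0][:-1] + edges[0][1:])
        v = 0.5 * (edges[2][:-1] + edges[2][1:])
        cells = (box[0] / nbins[0], box[2] / nbins[2])
        collapsed = box[1]
    return DensityMap(values=values, axis_u=u, axis_v=v, projection=projection, voxel=voxel,
                      cell_u=float(cells[0]), cell_v=float(cells[1]),
                      mean_particles=float(count), collapsed_length=float(collapsed))


# ---------------------------------------------------------------------------
# Inter-leaflet thickness map

@dataclass
class ThicknessMap:
    x_centers: np.ndarray
    y_centers: np.ndarray
    distance: np.ndarray  # (nx, ny) nm; NaN where undefined
    occupancy: np.ndarray  # mean lipid count per cell per frame
    valid: np.ndarray  # bool; cells with both leaflets present in >= 1 frame
    n_frames: int


def interleaflet_distance_map(traj: Trajectory, cell: float = 0.5,
                              window: tuple | None = None) -> ThicknessMap:
    """Lateral map of the distance between leaflet lipid centre-of-mass planes.

    Per frame and lateral cell: (mean COM z of upper-leaflet lipids) - (mean
    COM z of lower-leaflet lipids), averaged over the frames in which both
    leaflets populate the cell.  Cells never populated on both sides are NaN
    and flagged invalid, never silently zero.
    """
    box = traj[0].box
    nx = max(1, int(round(box[0] / cell)))
    ny = max(1, int(round(box[1] / cell)))
    diff_sum = np.zeros((nx, ny))
    diff_frames = np.zeros((nx, ny), dtype=int)
    occ_sum = np.zeros((nx, ny))
    frames = traj.window(window)
    for frame in frames:
        leaf = assign_leaflets(frame)
        per_leaflet = {}
        for name, ids in (("upper", leaf.upper), ("lower", leaf.lower)):
            coms = frame.molecule_com(ids)
            xy = np.mod(coms[:, :2], box[:2])
            ix = np.minimum((xy[:, 0] / box[0] * nx).astype(int), nx - 1)
            iy = np.minimum((xy[:, 1] / box[1] * ny).astype(int), ny - 1)
            zsum = np.zeros((nx, ny))
            cnt = np.zeros((nx, ny))
            np.add.at(zsum, (ix, iy), coms[:, 2])
            np.add.at(cnt, (ix, iy), 1.0)
            per_leaflet[name] = (zsum, cnt)
            occ_sum += cnt
        both = (per_leaflet["upper"][1] > 0) & (per_leaflet["lower"][1] > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (per_leaflet["upper"][0] / per_leaflet["upper"][1]
                 - per_leaflet["lower"][0] / per_leaflet["lower"][1])
        diff_sum[both] += d[both]
        diff_frames[both] += 1
    valid = diff_frames > 0
    distance = np.full((nx, ny), np.nan)
    distance[valid] = diff_sum[valid] / diff_frames[valid]
    return ThicknessMap(
        x_centers=(np.arange(nx) + 0.5) * box[0] / nx,
        y_centers=(np.arange(ny) + 0.5) * box[1] / ny,
        distance=distance,
        occupancy=occ_sum / len(frames),
        valid=valid,
        n_frames=len(frames),
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds

@dataclass
class HBondCriteria:
    da_cutoff: float = DEFAULT_DA_CUTOFF  # donor-acceptor distance, nm
    angle_min: float = DEFAULT_ANGLE_MIN  # D-H...A angle at the hydrogen, deg
    donor_species: tuple = (sp.DDA_O,)
    hydrogen_species: tuple = (sp.DDA_H,)
    acceptor_species: tuple = (sp.DDA_O,)
    dh_bond_max: float = 0.115  # covalent O-H association cutoff, nm


@dataclass
class HBond:
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    donor_molecule: int
    acceptor_molecule: int
    distance: float  # D...A, nm
    angle: float  # deg


@dataclass
class HBondGraph:
    bonds: list
    criteria: HBondCriteria

    def intermolecular(self) -> list:
        """Bonds between distinct molecules (intramolecular ones excluded)."""
        return [b for b in self.bonds if b.donor_molecule != b.acceptor_molecule]

    def count_intermolecular(self) -> int:
        return len(self.intermolecular())


def _donor_hydrogen_pairs(frame: Frame, crit: HBondCriteria) -> list:
    """(donor_index, hydrogen_index) pairs: each hydrogen of a hydrogen
    species is attached to the nearest donor-species atom of its own molecule
    within the covalent cutoff."""
    donors = np.nonzero(frame.select(crit.donor_species))[0]
    hydros = np.nonzero(frame.select(crit.hydrogen_species))[0]
    if len(hydros) == 0:
        warnings.warn("hydrogen-bond species set contains no hydrogens", stacklevel=3)
        return []
    pairs = []
    for h in hydros:
        same_mol = donors[frame.molecule_id[donors] == frame.molecule_id[h]]
        if len(same_mol) == 0:
            continue
        d = np.linalg.norm(
            minimum_image(frame.positions[same_mol] - frame.positions[h], frame.box), axis=1)
        j = int(np.argmin(d))
        if d[j] <= crit.dh_bond_max:
            pairs.append((int(same_mol[j]), int(h)))
    return pairs


def detect_hbonds(frame: Frame, criteria: HBondCriteria | None = None) -> HBondGraph:
    """Geometric hydrogen-bond detection on one frame.

    A bond exists iff the donor-acceptor minimum-image distance is at most the
    cutoff and the D-H...A angle (at the hydrogen) is at least the angular
    cutoff.  The graph is simple: at most one bond per (donor O, acceptor O)
    pair (the largest-angle hydrogen route is kept).
    """
    crit = criteria if criteria is not None else HBondCriteria()
    dh = _donor_hydrogen_pairs(frame, crit)
    acceptors = np.nonzero(frame.select(crit.acceptor_species))[0]
    bonds: dict = {}
    if dh and len(acceptors):
        wrapped = frame.wrapped_positions()
        tree = cKDTree(wrapped[acceptors], boxsize=frame.box)
        for d_idx, h_idx in dh:
            near = tree.query_ball_point(wrapped[d_idx], crit.da_cutoff)
            for a_loc in near:
                a_idx = int(acceptors[a_loc])
                if a_idx == d_idx:
                    continue
                dist = np.linalg.norm(
                    minimum_image(frame.positions[a_idx] - frame.positions[d_idx], frame.box))
                if dist > crit.da_cutoff:
                    continue
                v_d = minimum_image(frame.positions[d_idx] - frame.positions[h_idx], frame.box)
                v_a = minimum_image(frame.positions[a_idx] - frame.positions[h_idx], frame.box)
                cosang = np.dot(v_d, v_a) / (np.linalg.norm(v_d) * np.linalg.norm(v_a))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < crit.angle_min:
                    continue
                bond = HBond(
                    donor_index=d_idx, hydrogen_index=h_idx, acceptor_index=a_idx,
                    donor_molecule=int(frame.molecule_id[d_idx]),
                    acceptor_molecule=int(frame.molecule_id[a_idx]),
                    distance=float(dist), angle=angle,
                )
                key = (d_idx, a_idx)
                if key not in bonds or bonds[key].angle < angle:
                    bonds[key] = bond
    return HBondGraph(bonds=list(bonds.values()), criteria=crit)


@dataclass
class HBondStats:
    mean: float
    sd: float | None  # population sd; None for a single frame
    counts: np.ndarray
    window: tuple | None


def hbond_statistics(traj: Trajectory, criteria: HBondCriteria | None = None,
                     window: tuple | None = (0.25, 1.0)) -> HBondStats:
    """Mean ± population sd of intermolecular donor/acceptor-family bonds per
    frame over the selected window (default: the last three quarters of the
    trajectory, the usual equilibrated-statistics convention)."""
    frames = traj.window(window)
    counts = np.array([detect_hbonds(fr, criteria).count_intermolecular() for fr in frames], dtype=float)
    sd = float(counts.std(ddof=0)) if len(counts) > 1 else None
    return HBondStats(mean=float(counts.mean()), sd=sd, counts=counts, window=window)


# ---------------------------------------------------------------------------
# Molecule clusters

@dataclass
class ClusterSet:
    clusters: list  # list of frozensets of molecule ids, largest first
    sizes: np.ndarray
    largest_z_span: float  # max - min particle z over the largest cluster, nm
    edge_rule: str


def molecule_clusters(frame: Frame, selection="dda", edge_rule: str = "hbond",
                      cutoff: float | None = None,
                      criteria: HBondCriteria | None = None) -> ClusterSet:
    """Connected components of the molecule graph.

    Edges come from intermolecular hydrogen bonds (``edge_rule='hbond'``) or
    from centre-of-mass proximity (``edge_rule='com_distance'`` with a cutoff
    in nm).  Clusters partition the selection; the z-span of the largest
    cluster measures whether an aggregate extends across the membrane.
    """
    mols = _resolve_molecules(frame, selection)
    if len(mols) == 0:
        raise ValueError("empty molecule selection")
    graph = nx.Graph()
    graph.add_nodes_from(int(m) for m in mols)
    mol_set = set(int(m) for m in mols)
    if edge_rule == "hbond":
        for b in detect_hbonds(frame, criteria).bonds:
            if (b.donor_molecule != b.acceptor_molecule
                    and b.donor_molecule in mol_set and b.acceptor_molecule in mol_set):
                graph.add_edge(b.donor_molecule, b.acceptor_molecule)
    elif edge_rule == "com_distance":
        if cutoff is None or cutoff <= 0:
            raise ValueError("com_distance edge rule needs a positive cutoff")
        coms = frame.molecule_com(mols)
        pts = np.mod(coms, frame.box)
        tree = cKDTree(pts, boxsize=frame.box)
        for i, j in tree.query_pairs(cutoff):
            graph.add_edge(int(mols[i]), int(mols[j]))
    else:
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    clusters = [frozenset(c) for c in comps]
    largest = clusters[0]
    member_mask = np.isin(frame.molecule_id, list(largest))
    z = frame.positions[member_mask, 2]
    return ClusterSet(clusters=clusters, sizes=np.array([len(c) for c in clusters]),
                      largest_z_span=float(z.max() - z.min()), edge_rule=edge_rule)


# ---------------------------------------------------------------------------
# Water penetration and wires

@dataclass
class WaterReport:
    slab_bounds: tuple  # (-z_cut, +z_cut) relative to the midplane
    penetrating_waters: np.ndarray  # count per frame
    wires: list  # per frame: list of wires, each a list of molecule ids (by z)
    wire_present: np.ndarray  # bool per frame


def water_analysis(traj: Trajectory, z_cut: float = 1.0, oo_cutoff: float = 0.35) -> WaterReport:
    """Water penetration into the hydrophobic slab and spanning water wires.

    Penetrating waters are oxygens with |z - midplane| < z_cut.  A wire is a
    connected component of the O-O adjacency graph (minimum-image distance at
    most ``oo_cutoff``) whose z-extent covers the whole slab [-z_cut, +z_cut].
    """
    frames = list(traj)
    first = frames[0]
    heads = first.select(sp.LIPID_HEAD)
    if heads.any():
        head_offset = float(np.abs(first.positions[heads, 2] - _midplane(first)).mean())
        if z_cut >= head_offset:
            warnings.warn(
                f"z_cut {z_cut} reaches the head planes (~{head_offset:.2f} nm); slab is meaningless",
                stacklevel=2,
            )
    counts, wires_per_frame, present = [], [], []
    for frame in frames:
        o_idx = np.nonzero(frame.select(sp.WATER_O))[0]
        if len(o_idx) == 0:
            counts.append(0)
            wires_per_frame.append([])
            present.append(False)
            continue
        z0 = _midplane(frame)
        zrel = minimum_image(frame.positions[o_idx, 2] - z0, frame.box[2])
        counts.append(int(np.sum(np.abs(zrel) < z_cut)))
        wrapped = np.mod(frame.positions[o_idx], frame.box)
        tree = cKDTree(wrapped, boxsize=frame.box)
        graph = nx.Graph()
        graph.add_nodes_from(range(len(o_idx)))
        graph.add_edges_from(tree.query_pairs(oo_cutoff))
        frame_wires = []
        for comp in nx.connected_components(graph):
            comp = list(comp)
            zc = zrel[comp]
            if zc.min() <= -z_cut and zc.max() >= z_cut:
                order = np.argsort(zc)
                frame_wires.append([int(frame.molecule_id[o_idx[comp[k]]]) for k in order])
        wires_per_frame.append(frame_wires)
        present.append(bool(frame_wires))
    return WaterReport(slab_bounds=(-z_cut, z_cut), penetrating_waters=np.array(counts),
                       wires=wires_per_frame, wire_present=np.array(present, dtype=bool))
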