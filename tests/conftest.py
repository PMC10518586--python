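"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (explicit Python loops, O(N^2)
enumeration, union-find) so that they share no code path with the library
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from membrane_probe import species as sp
from membrane_probe.core import Frame
from membrane_probe.synthetic import (
    AggregateSpec,
    BilayerSpec,
    ThinPatchSpec,
    WaterSpec,
    WireSpec,
    build_trajectory,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Frame builders

def make_frame(molecules, box):
    """Build a Frame from [(species_list, positions_list), ...] molecules."""
    pos, spcs, mols, elec = [], [], [], []
    from membrane_probe.species import DEFAULT_SPECIES_MAP

    for mol_id, (species_list, positions) in enumerate(molecules):
        for s, p in zip(species_list, positions):
            spcs.append(s)
            pos.append(p)
            mols.append(mol_id)
            elec.append(DEFAULT_SPECIES_MAP.electrons_for(s))
    return Frame(positions=np.array(pos, dtype=float), species=np.array(spcs),
                 molecule_id=np.array(mols), electrons=np.array(elec),
                 box=np.array(box, dtype=float))


def make_hb_pair(x, y, z, oo=0.28, axis=(1.0, 0.0, 0.0)):
    """Two minimal 'DDA' molecules with one planted donor->acceptor bond.

    Molecule A: acceptor O (its own carbonyl), donor O and H; molecule B: a
    lone acceptor O at distance ``oo`` along ``axis`` from A's donor O, plus a
    far-away H so each molecule has complete species.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    d_o = np.array([x, y, z])
    h = d_o + 0.096 * axis
    a_o = d_o + oo * axis
    mol_a = ([sp.DDA_O, sp.DDA_H, sp.DDA_C], [d_o, h, d_o + (0.0, 0.3, 0.0)])
    mol_b = ([sp.DDA_O, sp.DDA_C], [a_o, a_o + (0.0, 0.3, 0.0)])
    return mol_a, mol_b


def water(o_xyz):
    o = np.asarray(o_xyz, dtype=float)
    return ([sp.WATER_O, sp.WATER_H, sp.WATER_H],
            [o, o + (0.096, 0.0, 0.0), o + (-0.024, 0.093, 0.0)])


# ---------------------------------------------------------------------------
# Brute-force oracles

def minimum_image_brute(d, box):
    d = np.array(d, dtype=float)
    for k in range(len(d)):
        while d[k] > box[k] / 2.0:
            d[k] -= box[k]
        while d[k] < -box[k] / 2.0:
            d[k] += box[k]
    return d


def brute_hbonds(frame, da_cutoff=0.35, angle_min=150.0,
                 donor_species=(sp.DDA_O,), hydrogen_species=(sp.DDA_H,),
                 acceptor_species=(sp.DDA_O,), dh_max=0.115):
    """All-pairs enumeration of geometric hydrogen bonds; returns a set of
    (donor_index, acceptor_index) pairs."""
    found = {}
    n = frame.n_particles
    for h in range(n):
        if frame.species[h] not in hydrogen_species:
            continue
        best_d, best = None, None
        for d in range(n):
            if frame.species[d] not in donor_species:
                continue
            if frame.molecule_id[d] != frame.molecule_id[h]:
                continue
            dist = np.linalg.norm(minimum_image_brute(frame.positions[d] - frame.positions[h], frame.box))
            if dist <= dh_max and (best_d is None or dist < best_d):
                best_d, best = dist, d
        if best is None:
            continue
        d = best
        for a in range(n):
            if frame.species[a] not in acceptor_species or a == d:
                continue
            da = np.linalg.norm(minimum_image_brute(frame.positions[a] - frame.positions[d], frame.box))
            if da > da_cutoff:
                continue
            v1 = minimum_image_brute(frame.positions[d] - frame.positions[h], frame.box)
            v2 = minimum_image_brute(frame.positions[a] - frame.positions[h], frame.box)
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang >= angle_min:
                key = (d, a)
                if key not in found or found[key] < ang:
                    found[key] = ang
    return set(found)


def brute_clusters(node_ids, edges):
    """Union-find connected components; returns a set of frozensets."""
    parent = {n: n for n in node_ids}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for n in node_ids:
        comps.setdefault(find(n), set()).add(n)
    return {frozenset(c) for c in comps.values()}


def brute_pair_distance_counts(points, box, edges, lateral=False):
    """O(N^2) minimum-image pair-distance histogram."""
    counts = np.zeros(len(edges) - 1)
    pts = np.asarray(points, dtype=float)
    dims = 2 if lateral else 3
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = minimum_image_brute(pts[i, :dims] - pts[j, :dims], box[:dims])
            r = float(np.sqrt(np.sum(d * d)))
            for b in range(len(edges) - 1):
                if edges[b] <= r < edges[b + 1]:
                    counts[b] += 1
                    break
    return counts


def brute_thickness_cells(frame, cell):
    """Per-cell mean upper/lower lipid-COM z difference, explicit loops."""
    from membrane_probe import analysis

    leaf = analysis.assign_leaflets(frame)
    nx = int(round(frame.box[0] / cell))
    ny = int(round(frame.box[1] / cell))
    sums = {}
    for name, ids in (("u", leaf.upper), ("l", leaf.lower)):
        for mol in ids:
            beads = frame.positions[frame.molecule_id == mol]
            com = beads.mean(axis=0)
            ix = min(int(com[0] % frame.box[0] / frame.box[0] * nx), nx - 1)
            iy = min(int(com[1] % frame.box[1] / frame.box[1] * ny), ny - 1)
            key = (ix, iy, name)
            sums.setdefault(key, []).append(com[2])
    out = np.full((nx, ny), np.nan)
    for ix in range(nx):
        for iy in range(ny):
            up = sums.get((ix, iy, "u"))
            lo = sums.get((ix, iy, "l"))
            if up and lo:
                out[ix, iy] = np.mean(up) - np.mean(lo)
    return out


# ---------------------------------------------------------------------------
# Fixtures

@pytest.fixture(scope="session")
def plain_bilayer():
    """64 lipids/leaflet, one frame, no planted features."""
    spec = BilayerSpec(lipids_per_leaflet=64, seed=7)
    return build_trajectory(spec, n_frames=1)


@pytest.fixture(scope="session")
def patch_bilayer():
    """The thinned-patch system used for thickness-recovery checks."""
    spec = BilayerSpec(
        lipids_per_leaflet=64,
        lateral_box=(10.0, 10.0),
        head_plane_offset=1.85,
        patch=ThinPatchSpec(center_xy=(5.0, 5.0), radius=1.5, head_plane_offset_inside=1.35),
        seed=42,
    )
    return build_trajectory(spec, n_frames=1)


@pytest.fixture(scope="session")
def aggregate_bilayer():
    """Bilayer with a hydrogen-bonded DDA aggregate, a spanning water wire
    and bulk water; 2 frames."""
    spec = BilayerSpec(
        lipids_per_leaflet=36,
        lateral_box=(9.0, 9.0),
        aggregate=AggregateSpec(n_dda=8, center_xy=(4.5, 4.5), carboxyl_pairing=1.0),
        water=WaterSpec(count=120, slab_bounds=(2.2, 2.9),
                        wire=WireSpec(n_waters=9, spacing=0.28, endpoints_z=(-1.12, 1.12))),
        seed=11,
    )
    return build_trajectory(spec, n_frames=2)
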