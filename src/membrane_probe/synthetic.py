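"""Synthetic bilayer datasets with planted, exactly known ground truth.

Every input the analysis stages consume can be generated here: coarse bead
trajectories of a hydrated DOPC-like bilayer with optional planted features
(a thinned circular patch, a laterally localised hydrogen-bonded DDA
aggregate spanning the hydrophobic core, an interstitial water wire,
flavonoid particles near the polar heads), SAXS curves from a known
electron-density profile, EPR splitting tables, AFM force curves and height
maps.  Each generator is deterministic given its integer seed, and each
trajectory carries a ground-truth manifest (molecule ids of every planted
feature) so that downstream detectors can be audited against construction.

Geometry of the bead model: each lipid is a straight chain of
``beads_per_lipid`` equal-mass beads, the head bead on the leaflet head plane
and the rest spaced ``bead_spacing`` toward the midplane, so the lipid centre
of mass sits (beads_per_lipid-1)/2 * bead_spacing below the head bead —
thickness analyses based on centres of mass are therefore not a trivial echo
of the input head plane.  Jitter is applied to the z coordinate of every
lipid bead, independently per bead and per frame (lateral order is preserved;
out-of-plane disorder dominates membrane roughness).

Randomness: one ``numpy`` Generator seeded from the spec's integer seed.
Draw order is fixed and documented in :func:`build_trajectory` so outputs are
stable across versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import species as sp
from .core import Frame, Trajectory
from .afm import ForceCurve, HeightMap, hertz_force
from .saxs import EDPParams, MCTParams, SAXSCurve, model_intensity
from .species import DEFAULT_SPECIES_MAP


class SpecValidationError(ValueError):
    """A generator spec is internally inconsistent; names the offending field."""


# ---------------------------------------------------------------------------
# Specs

@dataclass
class ThinPatchSpec:
    """Circular region where the head planes sit closer to the midplane."""

    center_xy: tuple = (5.0, 5.0)
    radius: float = 1.5
    head_plane_offset_inside: float = 1.35

    def validate(self, outside_offset: float) -> None:
        if self.radius <= 0:
            raise SpecValidationError("patch.radius must be positive")
        if not 0 < self.head_plane_offset_inside < outside_offset:
            raise SpecValidationError(
                "patch.head_plane_offset_inside must be positive and below the global head_plane_offset"
            )


@dataclass
class AggregateSpec:
    """Laterally localised DDA cluster with hydrogen-bonded carboxyl pairs."""

    n_dda: int = 8
    center_xy: tuple = (5.0, 5.0)
    lateral_sigma: float = 0.8
    carboxyl_pairing: float = 1.0
    oo_distance: float = 0.28
    hbond_angle_deg: float = 175.0
    z_span: float = 2.4

    def validate(self) -> None:
        if self.n_dda < 1:
            raise SpecValidationError("aggregate.n_dda must be >= 1")
        if not 0.0 <= self.carboxyl_pairing <= 1.0:
            raise SpecValidationError("aggregate.carboxyl_pairing must lie in [0, 1]")
        if self.z_span <= 0:
            raise SpecValidationError("aggregate.z_span must be positive")
        if self.oo_distance <= 0.12:
            raise SpecValidationError("aggregate.oo_distance must exceed the O-H bond length")


@dataclass
class WireSpec:
    """Chain of water molecules spanning the hydrophobic slab."""

    n_waters: int = 8
    spacing: float = 0.28
    endpoints_z: tuple = (-1.0, 1.0)

    def validate(self) -> None:
        if self.n_waters < 2:
            raise SpecValidationError("wire.n_waters must be >= 2")
        if self.spacing <= 0:
            raise SpecValidationError("wire.spacing must be positive")
        lo, hi = self.endpoints_z
        if not lo < 0 < hi:
            raise SpecValidationError("wire.endpoints_z must straddle the midplane")


@dataclass
class WaterSpec:
    """Bulk water slabs (mirrored at ±|z|) plus an optional planted wire."""

    count: int = 200
    slab_bounds: tuple = (2.2, 3.0)  # |z| range of the bulk slabs, nm
    wire: Optional[WireSpec] = None

    def validate(self) -> None:
        if self.count < 0:
            raise SpecValidationError("water.count must be >= 0")
        lo, hi = self.slab_bounds
        if not 0 < lo < hi:
            raise SpecValidationError("water.slab_bounds must satisfy 0 < lo < hi")
        if self.wire is not None:
            self.wire.validate()


@dataclass
class BilayerSpec:
    """Full synthetic system description; see module docstring for geometry."""

    lipids_per_leaflet: int = 64
    lateral_box: tuple = (10.0, 10.0)
    head_plane_offset: float = 1.85
    beads_per_lipid: int = 11
    bead_spacing: float = 0.12
    positional_jitter_sigma: float = 0.05
    patch: Optional[ThinPatchSpec] = None
    aggregate: Optional[AggregateSpec] = None
    water: Optional[WaterSpec] = None
    flavonoid_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.lipids_per_leaflet < 1:
            raise SpecValidationError("lipids_per_leaflet must be >= 1")
        if min(self.lateral_box) <= 0:
            raise SpecValidationError("lateral_box lengths must be positive")
        if self.beads_per_lipid < 1:
            raise SpecValidationError("beads_per_lipid must be >= 1")
        if self.bead_spacing <= 0:
            raise SpecValidationError("bead_spacing must be positive")
        tail_half = (self.beads_per_lipid - 1) * self.bead_spacing / 2.0
        if self.head_plane_offset <= tail_half:
            raise SpecValidationError(
                "head_plane_offset must exceed (beads_per_lipid-1)*bead_spacing/2 "
                "(leaflet chains would cross the midplane)"
            )
        if self.positional_jitter_sigma < 0:
            raise SpecValidationError("positional_jitter_sigma must be >= 0")
        if self.flavonoid_count < 0:
            raise SpecValidationError("flavonoid_count must be >= 0")
        if self.patch is not None:
            self.patch.validate(self.head_plane_offset)
        if self.aggregate is not None:
            self.aggregate.validate()
        if self.water is not None:
            self.water.validate()
            if self.water.wire is not None:
                half_z = self.box_z / 2.0
                lo, hi = self.water.wire.endpoints_z
                if lo < -half_z or hi > half_z:
                    raise SpecValidationError("water.wire.endpoints_z extends outside the box")

    @property
    def box_z(self) -> float:
        z_extent = self.head_plane_offset + 0.5
        if self.water is not None:
            z_extent = max(z_extent, self.water.slab_bounds[1] + 0.4)
        return 2.0 * z_extent

    @property
    def box(self) -> np.ndarray:
        return np.array([self.lateral_box[0], self.lateral_box[1], self.box_z])


# ---------------------------------------------------------------------------
# Trajectory construction

def _lipid_grid(n: int, lx: float, ly: float) -> np.ndarray:
    nx = int(np.ceil(np.sqrt(n)))
    ny = int(np.ceil(n / nx))
    xs = (np.arange(nx) + 0.5) * lx / nx
    ys = (np.arange(ny) + 0.5) * ly / ny
    pts = np.array([(x, y) for y in ys for x in xs])
    return pts[:n]


def _dda_molecule(x: float, y: float, z_top: float, z_span: float) -> tuple[np.ndarray, list]:
    """Vertical DDA chain at (x, y): two terminal carboxyls (C, O=, O-H, H)
    bridged by ten chain carbons.  Returns (positions, species)."""
    pos, spec = [], []
    for sign, z_end in ((+1, z_top), (-1, z_top - z_span)):
        pos += [
            (x, y, z_end),                         # carboxyl carbon
            (x - 0.10, y, z_end + sign * 0.08),    # carbonyl O (acceptor)
            (x + 0.11, y, z_end + sign * 0.05),    # hydroxyl O (donor)
            (x + 0.11 + 0.096, y, z_end + sign * 0.05),  # hydroxyl H
        ]
        spec += [sp.DDA_C, sp.DDA_O, sp.DDA_O, sp.DDA_H]
    for k in range(1, 11):
        pos.append((x, y, z_top - k * z_span / 11.0))
        spec.append(sp.DDA_C)
    return np.array(pos), spec


def _acceptor_offset(oo_distance: float, angle_deg: float, oh: float = 0.096) -> np.ndarray:
    """Offset from the donor hydroxyl O to an acceptor O such that the
    planted D-H...A angle equals ``angle_deg`` and O...O = ``oo_distance``,
    with the O-H bond along +x and the geometry in the xz plane."""
    theta = np.deg2rad(angle_deg)
    # direction of (A - H): rotate +x by (pi - theta) about y
    v = np.array([np.cos(np.pi - theta), 0.0, np.sin(np.pi - theta)])
    b = 2.0 * oh * v[0]
    r = 0.5 * (-b + np.sqrt(b * b - 4.0 * (oh * oh - oo_distance**2)))
    return np.array([oh, 0.0, 0.0]) + r * v  # offset from donor O (H at +x*oh)


def _water_molecule(o_xyz: np.ndarray) -> tuple[np.ndarray, list]:
    o = np.asarray(o_xyz, dtype=float)
    return (
        np.array([o, o + (0.096, 0.0, 0.0), o + (-0.024, 0.093, 0.0)]),
        [sp.WATER_O, sp.WATER_H, sp.WATER_H],
    )


def build_trajectory(spec: BilayerSpec, n_frames: int = 1) -> Trajectory:
    """Generate a seeded trajectory realising every planted feature exactly.

    Draw order (one Generator stream, fixed for reproducibility):

    1. aggregate lateral positions (pairs, then unpaired molecules),
    2. bulk water lateral/z positions,
    3. flavonoid lateral positions,
    4. per frame: one z-jitter draw for all lipid beads in construction
       order (upper leaflet row-major grid, then lower leaflet).

    Planted DDA/water/flavonoid coordinates are static across frames; frames
    differ by the lipid jitter realisation.  The returned trajectory carries a
    ground-truth manifest in ``metadata`` (molecule ids per planted feature,
    planted hydrogen-bond pairs, patch parameters).
    """
    spec.validate()
    if n_frames < 1:
        raise SpecValidationError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    box = spec.box
    smap = DEFAULT_SPECIES_MAP

    template_pos: list = []
    species: list = []
    mol_id: list = []
    manifest: dict = {"seed": spec.seed, "n_frames": n_frames, "box": box.tolist()}
    next_mol = 0

    # --- lipids -----------------------------------------------------------
    grid = _lipid_grid(spec.lipids_per_leaflet, *spec.lateral_box)
    n_beads = spec.beads_per_lipid
    leaflet_ids = {"upper": [], "lower": []}
    head_offsets = np.zeros(spec.lipids_per_leaflet)
    for i, (x, y) in enumerate(grid):
        off = spec.head_plane_offset
        if spec.patch is not None:
            cx, cy = spec.patch.center_xy
            if np.hypot(x - cx, y - cy) < spec.patch.radius:
                off = spec.patch.head_plane_offset_inside
        head_offsets[i] = off
    for leaflet, zsign in (("upper", +1.0), ("lower", -1.0)):
        for i, (x, y) in enumerate(grid):
            z_head = zsign * head_offsets[i]
            for k in range(n_beads):
                template_pos.append((x, y, z_head - zsign * k * spec.bead_spacing))
                species.append(sp.LIPID_HEAD if k == 0 else sp.LIPID_TAIL)
                mol_id.append(next_mol)
            leaflet_ids[leaflet].append(next_mol)
            next_mol += 1
    n_lipid_beads = len(template_pos)
    manifest["lipids"] = {
        "upper": leaflet_ids["upper"],
        "lower": leaflet_ids["lower"],
        "com_offset_below_head": (n_beads - 1) * spec.bead_spacing / 2.0,
    }
    if spec.patch is not None:
        inside = [
            int(leaflet_ids[leaf][i])
            for leaf in ("upper", "lower")
            for i in range(spec.lipids_per_leaflet)
            if head_offsets[i] != spec.head_plane_offset
        ]
        manifest["patch"] = {
            "center_xy": list(spec.patch.center_xy),
            "radius": spec.patch.radius,
            "head_plane_offset_inside": spec.patch.head_plane_offset_inside,
            "lipid_ids_inside": inside,
            "expected_com_distance_inside": 2.0 * (spec.patch.head_plane_offset_inside
                                                   - (n_beads - 1) * spec.bead_spacing / 2.0),
            "expected_com_distance_outside": 2.0 * (spec.head_plane_offset
                                                    - (n_beads - 1) * spec.bead_spacing / 2.0),
        }
    else:
        manifest["patch"] = None

    # --- DDA aggregate ----------------------------------------------------
    manifest["aggregate"] = None
    if spec.aggregate is not None:
        agg = spec.aggregate
        dda_ids: list = []
        planted_bonds: list = []

        def _draw_site(existing: list, min_sep: float = 0.6) -> np.ndarray:
            for _ in range(200):
                xy = rng.normal(agg.center_xy, agg.lateral_sigma, size=2)
                xy = np.mod(xy, spec.lateral_box)
                if all(np.hypot(*(xy - e)) > min_sep for e in existing):
                    return xy
            return xy  # crowded spec: accept the last draw

        n_pairs = int(np.floor(agg.carboxyl_pairing * agg.n_dda / 2.0))
        sites: list = []
        z_top = agg.z_span / 2.0
        for _ in range(n_pairs):
            xy = _draw_site(sites, min_sep=1.0)
            sites.append(xy)
            pos_a, spec_a = _dda_molecule(xy[0], xy[1], z_top, agg.z_span)
            mol_a = next_mol
            template_pos.extend(pos_a)
            species.extend(spec_a)
            mol_id.extend([mol_a] * len(pos_a))
            next_mol += 1
            # partner: its top carbonyl O accepts the donor H of molecule A
            donor_o = pos_a[2]  # top hydroxyl O of A
            acceptor_o = donor_o + _acceptor_offset(agg.oo_distance, agg.hbond_angle_deg)
            xb = acceptor_o[0] + 0.10
            yb = acceptor_o[1]
            zb_top = acceptor_o[2] - 0.08
            pos_b, spec_b = _dda_molecule(xb, yb, zb_top, agg.z_span)
            pos_b[1] = acceptor_o  # exact planted acceptor position
            # keep B's own donor H pointing away from A
            mol_b = next_mol
            template_pos.extend(pos_b)
            species.extend(spec_b)
            mol_id.extend([mol_b] * len(pos_b))
            next_mol += 1
            dda_ids += [mol_a, mol_b]
            planted_bonds.append((mol_a, mol_b))
            sites.append(np.array([xb, yb]))
        for _ in range(agg.n_dda - 2 * n_pairs):
            xy = _draw_site(sites, min_sep=0.8)
            sites.append(xy)
            pos_s, spec_s = _dda_molecule(xy[0], xy[1], z_top, agg.z_span)
            template_pos.extend(pos_s)
            species.extend(spec_s)
            mol_id.extend([next_mol] * len(pos_s))
            dda_ids.append(next_mol)
            next_mol += 1
        manifest["aggregate"] = {
            "molecule_ids": dda_ids,
            "planted_hbonds": planted_bonds,
            "center_xy": list(agg.center_xy),
            "z_span": agg.z_span,
        }

    # --- water ------------------------------------------------------------
    manifest["wire"] = None
    water_ids: list = []
    if spec.water is not None:
        wat = spec.water
        if wat.wire is not None:
            wire = wat.wire
            center = 0.5 * (wire.endpoints_z[0] + wire.endpoints_z[1])
            z0 = center - (wire.n_waters - 1) * wire.spacing / 2.0
            if spec.aggregate is not None:
                wx, wy = np.asarray(spec.aggregate.center_xy) + (1.2, 0.0)
            else:
                wx, wy = box[0] / 2.0, box[1] / 2.0
            wire_ids = []
            for k in range(wire.n_waters):
                pos_w, spec_w = _water_molecule(np.array([wx, wy, z0 + k * wire.spacing]))
                template_pos.extend(pos_w)
                species.extend(spec_w)
                mol_id.extend([next_mol] * 3)
                wire_ids.append(next_mol)
                water_ids.append(next_mol)
                next_mol += 1
            manifest["wire"] = {
                "molecule_ids": wire_ids,
                "xy": [float(wx), float(wy)],
                "z_extent": [float(z0), float(z0 + (wire.n_waters - 1) * wire.spacing)],
            }
        lo, hi = wat.slab_bounds
        for j in range(wat.count):
            zsign = 1.0 if j % 2 == 0 else -1.0
            xy = rng.uniform((0, 0), spec.lateral_box)
            z = zsign * rng.uniform(lo, hi)
            pos_w, spec_w = _water_molecule(np.array([xy[0], xy[1], z]))
            template_pos.extend(pos_w)
            species.extend(spec_w)
            mol_id.extend([next_mol] * 3)
            water_ids.append(next_mol)
            next_mol += 1
    manifest["water_ids"] = water_ids

    # --- flavonoids -------------------------------------------------------
    flav_ids: list = []
    for j in range(spec.flavonoid_count):
        zsign = 1.0 if j % 2 == 0 else -1.0
        xy = rng.uniform((0, 0), spec.lateral_box)
        template_pos.append((xy[0], xy[1], zsign * (spec.head_plane_offset - 0.3)))
        species.append(sp.FLAV)
        mol_id.append(next_mol)
        flav_ids.append(next_mol)
        next_mol += 1
    manifest["flavonoid_ids"] = flav_ids

    template = np.asarray(template_pos, dtype=float)
    species_arr = np.asarray(species)
    mol_arr = np.asarray(mol_id, dtype=int)
    electrons = np.array([smap.electrons_for(s) for s in species_arr], dtype=int)

    frames = []
    for _ in range(n_frames):
        pos = template.copy()
        if spec.positional_jitter_sigma > 0 and n_lipid_beads > 0:
            pos[:n_lipid_beads, 2] += rng.normal(0.0, spec.positional_jitter_sigma, size=n_lipid_beads)
        # z is midplane-centred (may be negative); wrapping is applied where needed
        frames.append(Frame(positions=pos, species=species_arr.copy(), molecule_id=mol_arr.copy(),
                            electrons=electrons.copy(), box=box.copy()))
    return Trajectory(frames=frames, frame_interval=1.0, metadata=manifest)


# ---------------------------------------------------------------------------
# SAXS curve generation

@dataclass
class SAXSGenSpec:
    """Forward-model curve: known EDP + MCT parameters, relative noise."""

    edp: EDPParams = field(default_factory=lambda: EDPParams(
        rho=(334.0, 275.0, 185.0, 260.0), R=(0.55, 1.35, 2.35), sigma=(0.22, 0.40, 0.45)))
    mct: MCTParams = field(default_factory=MCTParams)
    q_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.05, 6.0, 1200))
    noise_fraction: float = 0.01
    scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise SpecValidationError("q_grid must be strictly increasing and positive")
        if self.noise_fraction < 0:
            raise SpecValidationError("noise_fraction must be >= 0")
        if self.scale <= 0:
            raise SpecValidationError("scale must be positive")


def generate_saxs_curve(spec: SAXSGenSpec) -> SAXSCurve:
    """I(q) = scale * model(q) * (1 + eps_q), eps_q ~ N(0, noise^2), seeded.

    The reported uncertainty column is noise_fraction * model intensity (the
    planted relative error), so weighted fits use the true weights.
    """
    spec.validate()
    q = np.asarray(spec.q_grid, dtype=float)
    ideal = model_intensity(spec.edp, spec.mct, q, scale=spec.scale)
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, 1.0, size=len(q)) * spec.noise_fraction if spec.noise_fraction > 0 else 0.0
    noisy = ideal * (1.0 + eps)
    sigma = spec.noise_fraction * ideal
    return SAXSCurve(q=q, I=noisy, sigma_I=sigma,
                     metadata={"noise_fraction": spec.noise_fraction, "seed": spec.seed})


# ---------------------------------------------------------------------------
# EPR table generation

def generate_epr_table(samples: Sequence[tuple], path=None) -> pd.DataFrame:
    """CSV-ready table of (sample, 2A_par G, 2A_perp G); validated rows.

    Round-trips losslessly through :func:`membrane_probe.epr.read_epr_table`.
    """
    rows = []
    for entry in samples:
        name, par, perp = entry[0], float(entry[1]), float(entry[2])
        if not np.isfinite(par) or not np.isfinite(perp):
            raise SpecValidationError(f"{name}: splittings must be numeric")
        if not par > perp > 0:
            raise SpecValidationError(f"{name}: require 2A_par > 2A_perp > 0")
        rows.append({"sample": name, "two_A_par_G": par, "two_A_perp_G": perp})
    df = pd.DataFrame(rows, columns=["sample", "two_A_par_G", "two_A_perp_G"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# AFM generation

def generate_force_curve(
    modulus: float,
    tip_radius: float = 10.0,
    breakthrough: Optional[tuple] = None,
    noise: float = 0.0,
    seed: int = 0,
    poisson_ratio: float = 0.5,
    s_max: float = 5.0,
    s_min: float = -8.0,
    ds: float = 0.01,
    substrate_stiffness: float = 2.0e4,
) -> ForceCurve:
    """Approach curve: Hertz contact, optional planted breakthrough, noise.

    With ``breakthrough = (force pN, width nm)`` the curve follows the Hertz
    model up to the breakthrough force, drops to zero over one sample (the
    jump), stays flat for exactly ``width`` nm of separation, then meets a
    stiff substrate whose force resumes at the yield level and climbs with
    ``substrate_stiffness`` (pN/nm).  The separation grid is augmented with
    the exact breakpoints so the planted (force, width) pair is recovered
    exactly by the detector at zero noise.
    """
    if modulus <= 0:
        raise SpecValidationError("modulus must be positive")
    grid = np.arange(s_max, s_min, -ds)
    if breakthrough is not None:
        f_b, width = float(breakthrough[0]), float(breakthrough[1])
        if f_b <= 0:
            raise SpecValidationError("breakthrough force must be positive")
        if width <= 0:
            raise SpecValidationError("breakthrough width must be positive")
        e_eff = modulus / (1.0 - poisson_ratio**2)
        delta_b = (f_b / ((4.0 / 3.0) * e_eff * np.sqrt(tip_radius) * 1e-6)) ** (2.0 / 3.0)
        s_b = -delta_b
        if s_b - width <= s_min:
            raise SpecValidationError("breakthrough lies outside the separation range (raise |s_min|)")
        grid = np.unique(np.concatenate([grid, [s_b, s_b - width]]))[::-1]
    force = np.zeros_like(grid)
    contact = grid <= 0
    force[contact] = hertz_force(-grid[contact], modulus, tip_radius, poisson_ratio)
    if breakthrough is not None:
        flat = (grid < s_b) & (grid >= s_b - width)
        force[flat] = np.where(np.isclose(grid[flat], s_b - width), f_b, 0.0)
        substrate = grid < s_b - width
        force[substrate] = f_b + substrate_stiffness * ((s_b - width) - grid[substrate])
    if noise > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise, size=len(force))
    return ForceCurve(separation=grid, force=force, tip_radius=tip_radius, poisson_ratio=poisson_ratio,
                      metadata={"modulus": modulus, "breakthrough": breakthrough, "noise": noise, "seed": seed})


@dataclass
class Flat:
    pass


@dataclass
class Sinusoid:
    amplitude: float  # nm
    period: float  # nm
    axis: int = 1  # vary along columns by default


@dataclass
class GaussianRoughness:
    sigma: float  # nm


def generate_height_map(shape: tuple, waveform=Flat(), seed: int = 0, pixel_size: float = 25.4) -> HeightMap:
    """Height map with analytically known roughness statistics.

    flat: R_a = RMS = 0.  Sinusoid of amplitude A sampled at pixel centres
    over whole periods: R_a -> 2A/pi and RMS = A/sqrt(2) (the RMS is exact on
    any uniform grid covering whole periods; R_a converges at second order in
    the pixel size).  Gaussian roughness of sd sigma: RMS -> sigma as the
    grid grows.
    """
    ny, nx = shape
    if ny < 2 or nx < 2:
        raise SpecValidationError("shape must be at least 2x2")
    if isinstance(waveform, Flat):
        z = np.zeros(shape)
    elif isinstance(waveform, Sinusoid):
        n = shape[waveform.axis]
        coord = (np.arange(n) + 0.5) * pixel_size
        wave = waveform.amplitude * np.cos(2.0 * np.pi * coord / waveform.period)
        z = np.broadcast_to(wave if waveform.axis == 1 else wave[:, None], shape).copy()
    elif isinstance(waveform, GaussianRoughness):
        rng = np.random.default_rng(seed)
        z = rng.normal(0.0, waveform.sigma, size=shape)
    else:
        raise SpecValidationError(f"unknown waveform {waveform!r}")
    return HeightMap(heights=z, pixel_size=pixel_size)
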