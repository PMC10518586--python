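"""AFM post-processing: breakthrough detection, roughness, contact mechanics.

Force curves are approach curves of a spherical tip against a supported lipid
bilayer: force (pN) versus tip-sample separation (nm, decreasing along the
approach; negative separation means indentation).  Puncturing the bilayer
produces the breakthrough "jump": a sudden force drop whose separation width
estimates the bilayer thickness.  Elasticity uses the Hertz sphere model

    F = (4/3) * E/(1 - nu^2) * sqrt(R_tip) * delta^(3/2)

with Poisson ratio nu = 0.5 by default; an optional constant adhesion offset
(DMT-style) can be removed before fitting.  Height maps are post-processed
with first-order plane flattening before roughness statistics
(R_a = mean |z - z̄|, RMS = sqrt(mean (z - z̄)^2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# pN/nm^(3/2) per Pa for F[pN] = 4/3 E/(1-nu^2) sqrt(R[nm]) delta[nm]^(3/2)
_HERTZ_UNIT = 1e-6


@dataclass
class ForceCurve:
    """Approach force curve: separation (nm, strictly decreasing), force (pN)."""

    separation: np.ndarray
    force: np.ndarray
    tip_radius: float = 10.0  # nm
    poisson_ratio: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.separation) != len(self.force):
            raise ValueError("separation and force must have equal length")
        if np.any(np.diff(self.separation) >= 0):
            raise ValueError("separation must be strictly decreasing (approach)")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")


@dataclass
class HeightMap:
    """Rectangular topography grid (nm) with square pixels (nm)."""

    heights: np.ndarray
    pixel_size: float = 25.4

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or min(self.heights.shape) < 2:
            raise ValueError("heights must be a grid of at least 2x2")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class Breakthrough:
    yield_force: float  # pN
    thickness: float  # nm
    index: int  # sample index of the last point before the jump


def hertz_force(delta_nm, modulus_pa: float, tip_radius_nm: float, poisson_ratio: float = 0.5):
    """Hertz sphere force (pN) at indentation delta (nm, clipped at 0)."""
    delta = np.clip(np.asarray(delta_nm, dtype=float), 0.0, None)
    e_eff = modulus_pa / (1.0 - poisson_ratio**2)
    return (4.0 / 3.0) * e_eff * np.sqrt(tip_radius_nm) * delta**1.5 * _HERTZ_UNIT


def detect_breakthrough(
    curve: ForceCurve,
    drop_threshold: float = 50.0,
    max_drop_width: float = 0.5,
) -> Optional[Breakthrough]:
    """Locate the bilayer breakthrough jump, if any.

    The jump is the largest contiguous force drop of at least
    ``drop_threshold`` pN occurring within ``max_drop_width`` nm of
    separation.  The yield force is the force immediately before the drop and
    the thickness is the separation travelled until the force first recovers
    to the yield level (tip landing on the substrate).  Returns ``None`` when
    no drop exceeds the threshold (e.g. a smooth non-penetrating contact).
    """
    s, f = curve.separation, curve.force
    n = len(s)
    best = None  # (drop, i_start, i_end)
    i = 0
    while i < n - 1:
        if f[i + 1] < f[i]:
            j = i + 1
            while j < n - 1 and f[j + 1] < f[j] and (s[i] - s[j + 1]) <= max_drop_width:
                j += 1
            drop = f[i] - f[j]
            if drop >= drop_threshold and (s[i] - s[j]) <= max_drop_width:
                if best is None or drop > best[0]:
                    best = (drop, i, j)
            i = j
        else:
            i += 1
    if best is None:
        logger.debug("no force drop >= %.1f pN within %.2f nm: no breakthrough", drop_threshold, max_drop_width)
        return None
    _, i0, j0 = best
    yield_force = float(f[i0])
    rec = np.nonzero(f[j0:] >= yield_force)[0]
    if len(rec) == 0:
        logger.debug("force never recovers to the yield level after the jump")
        return None
    j_rec = j0 + int(rec[0])
    return Breakthrough(yield_force=yield_force, thickness=float(s[i0] - s[j_rec]), index=int(i0))


@dataclass
class ModulusFit:
    modulus: float  # Pa
    contact_point: float  # nm
    n_points: int
    rss: float


def fit_modulus(
    curve: ForceCurve,
    model: str = "hertz_sphere",
    contact_point: float = 0.0,
    exclude_after_breakthrough: bool = True,
    drop_threshold: float = 50.0,
    adhesion_offset: float = 0.0,
    max_indentation: float | None = None,
) -> ModulusFit:
    """Fit the Young's modulus on the pre-breakthrough contact segment.

    Linear least squares of (F - adhesion_offset) against delta^(3/2) through
    the origin, where delta = contact_point - separation > 0.  Points after a
    detected breakthrough are excluded so that substrate contact never biases
    the bilayer modulus.
    """
    if model != "hertz_sphere":
        raise ValueError(f"unknown contact model {model!r}")
    s, f = curve.separation, curve.force.astype(float) - adhesion_offset
    mask = s < contact_point
    if exclude_after_breakthrough:
        bt = detect_breakthrough(curve, drop_threshold=drop_threshold)
        if bt is not None:
            mask &= s > curve.separation[bt.index + 1]
    delta = contact_point - s
    if max_indentation is not None:
        mask &= delta <= max_indentation
    if not np.any(mask):
        raise ValueError("no contact segment (no points with separation below the contact point)")
    x = delta[mask] ** 1.5
    y = f[mask]
    coef = float(np.dot(x, y) / np.dot(x, x))
    e_eff = coef / ((4.0 / 3.0) * np.sqrt(curve.tip_radius) * _HERTZ_UNIT)
    modulus = e_eff * (1.0 - curve.poisson_ratio**2)
    rss = float(np.sum((y - coef * x) ** 2))
    return ModulusFit(modulus=float(modulus), contact_point=contact_point, n_points=int(mask.sum()), rss=rss)


def _plane_subtract(z: np.ndarray) -> np.ndarray:
    """Remove the best-fit first-order plane (flattening)."""
    ny, nx = z.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([np.ones(z.size), xx.ravel(), yy.ravel()])
    coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
    return z - (A @ coef).reshape(z.shape)


def surface_roughness(heights: np.ndarray, flatten: bool = True) -> tuple[float, float]:
    """(R_a, RMS) of a height region after first-order plane subtraction."""
    z = np.asarray(heights, dtype=float)
    if flatten:
        z = _plane_subtract(z)
    dev = z - z.mean()
    return float(np.mean(np.abs(dev))), float(np.sqrt(np.mean(dev**2)))


@dataclass
class RoughnessReport:
    r_a: np.ndarray  # per region, nm
    rms: np.ndarray  # per region, nm
    origins: list  # (row, col) of each region
    region_size: int
    r_a_mean: float
    r_a_se: float
    rms_mean: float
    rms_se: float


def roughness(
    hmap: HeightMap,
    n_regions: int = 4,
    region_size: int | None = None,
    seed: int | None = None,
) -> RoughnessReport:
    """Roughness over ``n_regions`` random square regions of the map.

    Each region is plane-flattened independently; the summary is the mean with
    its standard error over regions (the instrument-style "four random
    regions" protocol by default).  ``region_size`` is in pixels and defaults
    to a quarter of the smaller map dimension.
    """
    z = hmap.heights
    if region_size is None:
        region_size = max(2, min(z.shape) // 4)
    if region_size > min(z.shape):
        raise ValueError(f"region_size {region_size} exceeds map dimensions {z.shape}")
    rng = np.random.default_rng(seed)
    origins, ras, rmss = [], [], []
    for _ in range(n_regions):
        r0 = int(rng.integers(0, z.shape[0] - region_size + 1))
        c0 = int(rng.integers(0, z.shape[1] - region_size + 1))
        ra, rms = surface_roughness(z[r0:r0 + region_size, c0:c0 + region_size])
        origins.append((r0, c0))
        ras.append(ra)
        rmss.append(rms)
    ras, rmss = np.array(ras), np.array(rmss)
    ra_m, ra_se, _ = mean_se(ras)
    rms_m, rms_se, _ = mean_se(rmss)
    return RoughnessReport(
        r_a=ras, rms=rmss, origins=origins, region_size=region_size,
        r_a_mean=ra_m, r_a_se=ra_se, rms_mean=rms_m, rms_se=rms_se,
    )


def mean_se(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, standard error, n); SE is NaN for n = 1 (flagged, not zero)."""
    v = np.asarray(list(values), dtype=float)
    n = len(v)
    if n < 1:
        raise ValueError("at least one value is required")
    se = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(v.mean()), se, n


def summarize(values_by_system: Mapping[str, Sequence[float]], control: str | None = None) -> pd.DataFrame:
    """Per-system mean ± SE table with the sign of the change versus control.

    ``control`` defaults to the first system.  The ``change_vs_control``
    column holds -1/0/+1 so that directional claims (increase/decrease) can be
    read off directly.
    """
    systems = list(values_by_system)
    if control is None:
        control = systems[0]
    rows = []
    for name in systems:
        m, se, n = mean_se(values_by_system[name])
        rows.append({"system": name, "mean": m, "se": se, "n": n})
    df = pd.DataFrame(rows).set_index("system")
    ref = df.loc[control, "mean"]
    df["change_vs_control"] = np.sign(df["mean"] - ref).astype(int)
    return df


# ---------------------------------------------------------------------------
# Tabular text I/O

def write_force_curve(curve: ForceCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# separation_nm force_pN  tip_radius_nm={curve.tip_radius} poisson_ratio={curve.poisson_ratio}\n")
        for s, f in zip(curve.separation, curve.force):
            fh.write(f"{s:.6f} {f:.6f}\n")


def read_force_curve(path) -> ForceCurve:
    tip_radius, poisson = 10.0, 0.5
    with open(path) as fh:
        first = fh.readline()
    for tok in first.replace("#", "").split():
        if tok.startswith("tip_radius_nm="):
            tip_radius = float(tok.split("=", 1)[1])
        elif tok.startswith("poisson_ratio="):
            poisson = float(tok.split("=", 1)[1])
    data = np.atleast_2d(np.loadtxt(path, comments="#"))
    return ForceCurve(separation=data[:, 0], force=data[:, 1], tip_radius=tip_radius, poisson_ratio=poisson)


def write_height_map(hmap: HeightMap, path) -> None:
    np.savetxt(path, hmap.heights, fmt="%.6f", header=f"height_nm grid, pixel_size_nm={hmap.pixel_size}")


def read_height_map(path) -> HeightMap:
    pixel = 25.4
    with open(path) as fh:
        first = fh.readline()
    if "pixel_size_nm=" in first:
        pixel = float(first.split("pixel_size_nm=")[1].split()[0])
    return HeightMap(heights=np.loadtxt(path, comments="#"), pixel_size=pixel)
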