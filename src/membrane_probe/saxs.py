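"""SAXS modelling of lamellar lipid systems.

The electron-density profile (EDP) across the bilayer is a symmetric linear
combination of three Gaussian-smoothed rectangular steps,

    rho(r) = rho0 + 1/2 * sum_i (rho_{i-1} - rho_i)
                    * [erf((r - R_i)/(sqrt(2) sigma_i)) - erf((r + R_i)/(sqrt(2) sigma_i))]

with solvent baseline rho0, step positions R_1 < R_2 < R_3 and widths
sigma_i.  Because each term is a rectangle of half-width R_i convolved with a
Gaussian, the bilayer form factor has the closed form

    F(q) = sum_i (rho_i - rho_{i-1}) * 2 sin(q R_i)/q * exp(-sigma_i^2 q^2 / 2),

which is validated against adaptive quadrature of the profile in the test
suite.  Multilamellar interference is described by modified Caillé theory
(MCT): a finite stack of N lamellae with repeat distance d whose thermal
fluctuations, governed by the dimensionless Caillé parameter eta,
algebraically damp the Bragg peaks.  The measured 1D intensity is assembled
with the 1/q^2 Lorentz factor for lamellar scattering and a diffuse
(uncorrelated, unilamellar) fraction:

    I(q) = scale/q^2 * |F(q)|^2 * [f_diffuse + (1 - f_diffuse) * S(q)].

Fitting is weighted least squares (1/sigma_I^2) through lmfit, with the step
ordering enforced by fitting R_1 and positive increments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.special import erf

EULER_GAMMA = float(np.euler_gamma)


@dataclass
class EDPParams:
    """Electron-density-profile parameters: levels rho0..rho3 (e/nm^3,
    rho0 = solvent baseline), step positions R1<R2<R3 (nm), widths (nm)."""

    rho: tuple
    R: tuple
    sigma: tuple

    def __post_init__(self):
        self.rho = tuple(float(x) for x in self.rho)
        self.R = tuple(float(x) for x in self.R)
        self.sigma = tuple(float(x) for x in self.sigma)
        if len(self.rho) != 4:
            raise ValueError("rho must hold four levels rho0..rho3")
        if len(self.R) != 3 or len(self.sigma) != 3:
            raise ValueError("R and sigma must each hold three values")
        if not (0 < self.R[0] < self.R[1] < self.R[2]):
            raise ValueError("R must be strictly increasing and positive")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma must be positive")


@dataclass
class MCTParams:
    """Modified Caillé structure-factor parameters.

    ``n_layers`` is the (small, fixed) number of correlated lamellae,
    ``d_spacing`` the lamellar repeat (nm), ``eta`` the Caillé fluctuation
    parameter and ``diffuse_fraction`` the weight of uncorrelated
    (unilamellar) scattering in the intensity combination.
    """

    n_layers: int = 10
    d_spacing: float = 6.3
    eta: float = 0.1
    diffuse_fraction: float = 0.3

    def __post_init__(self):
        self.n_layers = int(self.n_layers)
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.d_spacing <= 0:
            raise ValueError("d_spacing must be positive")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise ValueError("diffuse_fraction must lie in [0, 1]")


@dataclass
class SAXSCurve:
    """1D scattering curve: q (nm^-1, increasing), intensity, uncertainty."""

    q: np.ndarray
    I: np.ndarray
    sigma_I: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma_I = np.asarray(self.sigma_I, dtype=float)
        if not (len(self.q) == len(self.I) == len(self.sigma_I)):
            raise ValueError("q, I and sigma_I must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("intensities must be finite")


def edp_evaluate(params: EDPParams, r) -> np.ndarray:
    """Electron density rho(r) (e/nm^3) at distance r (nm) from the midplane.

    Even in r; tends to the solvent baseline rho0 for |r| -> infinity and to
    rho3 at the centre in the sharp-step limit.
    """
    r = np.asarray(r, dtype=float)
    rho = np.full_like(r, params.rho[0])
    for i in range(3):
        drho = params.rho[i] - params.rho[i + 1]
        Ri, si = params.R[i], params.sigma[i]
        rho = rho + 0.5 * drho * (erf((r - Ri) / (np.sqrt(2) * si)) - erf((r + Ri) / (np.sqrt(2) * si)))
    return rho


def form_factor(params: EDPParams, q) -> np.ndarray:
    """Bilayer form factor F(q) = ∫ (rho(r) - rho0) cos(qr) dr (e/nm^2).

    Closed form for Gaussian-smoothed symmetric slabs; F(0) equals the total
    excess electrons per unit area.
    """
    q = np.asarray(q, dtype=float)
    F = np.zeros_like(q)
    for i in range(3):
        drho = params.rho[i + 1] - params.rho[i]
        Ri, si = params.R[i], params.sigma[i]
        # 2 sin(q R)/q written via sinc for a finite q -> 0 limit (= 2R)
        F = F + drho * 2.0 * Ri * np.sinc(q * Ri / np.pi) * np.exp(-0.5 * si**2 * q**2)
    return F


def mct_structure_factor(params: MCTParams, q) -> np.ndarray:
    """Modified Caillé structure factor S(q) for a stack of N lamellae.

    S(q) = N + 2 sum_{k=1}^{N-1} (N-k) cos(k q d)
               * exp(-(d q / 2 pi)^2 eta * gamma_E) * (pi k)^(-(d q / 2 pi)^2 eta)

    At eta = 0 this reduces exactly to the ideal finite-lattice interference
    function sin^2(N q d / 2)/sin^2(q d / 2) (value N^2 at the Bragg
    positions); N = 1 gives S identically 1.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    N, d, eta = params.n_layers, params.d_spacing, params.eta
    S = np.full_like(q, float(N))
    if N > 1:
        k = np.arange(1, N)[:, None]  # (N-1, 1)
        x = (d * q[None, :] / (2.0 * np.pi)) ** 2 * eta
        damp = np.exp(-x * EULER_GAMMA) * (np.pi * k) ** (-x)
        S = S + 2.0 * np.sum((N - k) * np.cos(k * q[None, :] * d) * damp, axis=0)
    return np.maximum(S, 0.0)


def model_intensity(edp: EDPParams, mct: MCTParams, q, scale: float = 1.0) -> np.ndarray:
    """Lamellar intensity I(q) with Lorentz factor and diffuse mixing."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be strictly positive (q = 0 excluded)")
    F = form_factor(edp, q)
    if mct.n_layers == 1:
        interference = np.ones_like(q)
    else:
        S = mct_structure_factor(mct, q)
        interference = mct.diffuse_fraction + (1.0 - mct.diffuse_fraction) * S
    return scale * F**2 / q**2 * interference


@dataclass
class FitResult:
    """Outcome of a SAXS fit: best-fit parameters, scale, reduced chi^2,
    per-parameter uncertainties, and the q-window used."""

    edp: EDPParams
    mct: MCTParams
    scale: float
    redchi: float
    stderr: dict
    q_window: tuple
    success: bool
    message: str
    nfev: int = 0


def initial_guess(curve: SAXSCurve, rho0: float = 334.0, q_window=(0.5, 2.5)) -> EDPParams:
    """Heuristic starting profile: the head-group position R3 is taken from
    the first maximum of q^2 I(q) inside the window via R3 ~ pi/q_max; the
    remaining steps are spaced proportionally and the contrasts set to generic
    phospholipid values around the solvent baseline."""
    mask = (curve.q >= q_window[0]) & (curve.q <= q_window[1])
    if not np.any(mask):
        raise ValueError("q_window contains no data points")
    qw, iw = curve.q[mask], curve.I[mask]
    kink = qw[np.argmax(iw * qw**2)]
    R3 = float(np.clip(np.pi / kink, 0.8, 3.5))
    return EDPParams(
        rho=(rho0, rho0 - 10.0, rho0 - 130.0, rho0 - 45.0),
        R=(R3 * 0.27, R3 * 0.64, R3),
        sigma=(0.25, 0.3, 0.3),
    )


def _params_from_lmfit(p, rho0: float, mct0: MCTParams) -> tuple[EDPParams, MCTParams, float]:
    edp = EDPParams(
        rho=(rho0, p["rho1"].value, p["rho2"].value, p["rho3"].value),
        R=(p["r1"].value, p["r1"].value + p["dr2"].value, p["r1"].value + p["dr2"].value + p["dr3"].value),
        sigma=(p["s1"].value, p["s2"].value, p["s3"].value),
    )
    mct = MCTParams(
        n_layers=mct0.n_layers,
        d_spacing=p["d"].value if "d" in p else mct0.d_spacing,
        eta=p["eta"].value if "eta" in p else mct0.eta,
        diffuse_fraction=mct0.diffuse_fraction,
    )
    return edp, mct, p["scale"].value


def fit_saxs(
    curve: SAXSCurve,
    edp0: EDPParams | None = None,
    mct0: MCTParams | None = None,
    scale0: float | None = None,
    q_window: tuple = (0.5, 2.5),
    vary_mct: bool = False,
    rho_bounds: tuple = (50.0, 800.0),
    sigma_max: float = 0.6,
    n_restarts: int = 4,
    vary_scale: bool = True,
) -> FitResult:
    """Weighted least-squares fit of the lamellar model over ``q_window``.

    The step ordering R1 < R2 < R3 is enforced by fitting R1 and the positive
    increments dR2, dR3; widths and scale are bounded positive.  rho0 (the
    solvent baseline) is held fixed — only contrast differences are
    identifiable.  The number of lamellae N is a fixed small integer (not
    fitted); d and eta are refined when ``vary_mct`` is set.  Non-convergence
    is reported through ``success``/``message``, never silently.

    Note that rescaling every contrast (rho_i - rho_0) by a factor while
    dividing ``scale`` by its square leaves I(q) exactly unchanged: with
    arbitrary intensity units the profile amplitude is determined only up to
    that factor.  Pass ``vary_scale=False`` (with a known ``scale0``) when
    absolute electron densities are meaningful, e.g. in recovery studies on
    simulated curves.
    """
    mask = (curve.q >= q_window[0]) & (curve.q <= q_window[1])
    if not np.any(mask):
        raise ValueError(f"q_window {q_window} excludes all data points")
    mct0 = mct0 if mct0 is not None else MCTParams(n_layers=1)
    edp0 = edp0 if edp0 is not None else initial_guess(curve, q_window=q_window)
    rho0 = edp0.rho[0]
    q, I = curve.q[mask], curve.I[mask]
    # weights 1/sigma_I; points without a stated uncertainty fall back to
    # relative weighting (1/I) with a floor so that exact zeros of a
    # noise-free curve cannot acquire unbounded weight
    sig = curve.sigma_I[mask]
    fallback = np.maximum(np.abs(I), 1e-4 * np.max(np.abs(I)))
    w = 1.0 / np.where(sig > 0, sig, fallback)

    if scale0 is None:
        guess = model_intensity(edp0, mct0, q)
        scale0 = float(np.sum(w**2 * I * guess) / np.sum(w**2 * guess**2))
        scale0 = max(scale0, 1e-12)

    def make_params(edp: EDPParams, scale: float) -> lmfit.Parameters:
        p = lmfit.Parameters()
        p.add("rho1", value=edp.rho[1], min=rho_bounds[0], max=rho_bounds[1])
        p.add("rho2", value=edp.rho[2], min=rho_bounds[0], max=rho_bounds[1])
        p.add("rho3", value=edp.rho[3], min=rho_bounds[0], max=rho_bounds[1])
        p.add("r1", value=edp.R[0], min=0.02, max=5.0)
        p.add("dr2", value=edp.R[1] - edp.R[0], min=1e-3, max=5.0)
        p.add("dr3", value=edp.R[2] - edp.R[1], min=1e-3, max=5.0)
        p.add("s1", value=edp.sigma[0], min=0.01, max=sigma_max)
        p.add("s2", value=edp.sigma[1], min=0.01, max=sigma_max)
        p.add("s3", value=edp.sigma[2], min=0.01, max=sigma_max)
        p.add("scale", value=scale, min=0.0, vary=vary_scale)
        if vary_mct and mct0.n_layers > 1:
            p.add("d", value=mct0.d_spacing, min=1.0, max=15.0)
            p.add("eta", value=max(mct0.eta, 1e-4), min=0.0, max=1.0)
        return p

    def residual(params):
        edp, mct, scale = _params_from_lmfit(params, rho0, mct0)
        return (model_intensity(edp, mct, q, scale) - I) * w

    # the chi^2 landscape has broadened-step local minima; deterministic
    # multistart (seeded jitters around the initial guess) makes the fit
    # robust to them.  Restarts stop early once chi^2 reaches the level
    # expected from the stated uncertainties.
    restart_rng = np.random.default_rng(1234)
    out = None
    for attempt_idx in range(max(1, n_restarts + 1)):
        if attempt_idx == 0:
            edp_j = edp0
        else:
            # jitter amplitude grows with the attempt number so late restarts
            # can leave the basin of a stubborn local minimum
            amp = 0.1 if attempt_idx <= 3 else 0.25
            f = 1.0 + restart_rng.uniform(-amp, amp, size=9)
            edp_j = EDPParams(
                rho=(rho0,) + tuple(v * f[i] for i, v in enumerate(edp0.rho[1:])),
                R=tuple(np.sort([v * f[3 + i] for i, v in enumerate(edp0.R)])),
                sigma=tuple(np.clip(v * f[6 + i], 0.011, sigma_max * 0.99)
                            for i, v in enumerate(edp0.sigma)),
            )
        attempt = lmfit.minimize(residual, make_params(edp_j, scale0),
                                 method="least_squares", x_scale="jac", max_nfev=20000)
        if out is None or attempt.chisqr < out.chisqr:
            out = attempt
        if out.success and out.chisqr <= 1.15 * len(q):
            break
    edp, mct, scale = _params_from_lmfit(out.params, rho0, mct0)
    stderr = {name: (par.stderr if par.stderr is not None else float("nan")) for name, par in out.params.items()}
    return FitResult(
        edp=edp,
        mct=mct,
        scale=float(scale),
        redchi=float(out.redchi) if out.redchi is not None else float("nan"),
        stderr=stderr,
        q_window=tuple(q_window),
        success=bool(out.success),
        message=str(getattr(out, "message", "")),
        nfev=int(out.nfev),
    )


def edp_descriptors(params: EDPParams, r_max: float = 4.0, n_r: int = 4001) -> dict:
    """Scalar descriptors of a profile: head-peak position/height (argmax over
    r >= 0 on a dense grid), centre density rho(0), and the full width at half
    prominence of the head peak above the solvent baseline."""
    r = np.linspace(0.0, r_max, n_r)
    rho = edp_evaluate(params, r)
    i_pk = int(np.argmax(rho))
    peak_r, peak_rho = float(r[i_pk]), float(rho[i_pk])
    rho0 = params.rho[0]
    half = rho0 + 0.5 * (peak_rho - rho0)
    above = rho >= half
    # contiguous run containing the peak
    lo = i_pk
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_pk
    while hi < n_r - 1 and above[hi + 1]:
        hi += 1
    return {
        "head_peak_position": peak_r,
        "head_peak_density": peak_rho,
        "center_density": float(edp_evaluate(params, 0.0)),
        "head_width": float(r[hi] - r[lo]),
    }


def edp_report(fits: Sequence[FitResult], labels: Sequence[str] | None = None,
               r_max: float = 4.0, n_r: int = 801) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate fitted rho(r) on a common grid plus per-system descriptors.

    Returns ``(profiles, descriptors)``; descriptors carry the sign of the
    change in centre density and head-peak position relative to the first
    system, supporting qualitative between-system contrasts.
    """
    if len(fits) < 1:
        raise ValueError("at least one fit is required")
    labels = list(labels) if labels is not None else [f"system_{i}" for i in range(len(fits))]
    r = np.linspace(-r_max, r_max, n_r)
    profiles = pd.DataFrame({"r_nm": r})
    desc_rows = []
    for lab, fit in zip(labels, fits):
        profiles[lab] = edp_evaluate(fit.edp, r)
        desc_rows.append({"system": lab, **edp_descriptors(fit.edp, r_max=r_max)})
    desc = pd.DataFrame(desc_rows).set_index("system")
    ref = desc.iloc[0]
    desc["center_density_change_vs_first"] = np.sign(desc["center_density"] - ref["center_density"]).astype(int)
    # the head region is a near-plateau, so its argmax carries a few-pm
    # numerical wobble; flag only shifts larger than 0.02 nm
    dpos = desc["head_peak_position"] - ref["head_peak_position"]
    desc["head_position_change_vs_first"] = np.sign(np.where(np.abs(dpos) < 0.02, 0.0, dpos)).astype(int)
    return profiles, desc


# ---------------------------------------------------------------------------
# Curve file I/O: whitespace-separated 3 columns (q, I, sigma_I), '#' comments.

def write_saxs_curve(curve: SAXSCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("# q_nm^-1  I_arb  sigma_I\n")
        for meta_k, meta_v in sorted(curve.metadata.items()):
            fh.write(f"# {meta_k}: {meta_v}\n")
        for q, I, s in zip(curve.q, curve.I, curve.sigma_I):
            fh.write(f"{q:.8e} {I:.8e} {s:.8e}\n")


def read_saxs_curve(path) -> SAXSCurve:
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    if data.shape[1] < 3:
        raise ValueError("curve file must have three columns: q, I, sigma_I")
    return SAXSCurve(q=data[:, 0], I=data[:, 1], sigma_I=data[:, 2])


def save_fit(fit: FitResult, path) -> None:
    payload = {
        "edp": asdict(fit.edp),
        "mct": asdict(fit.mct),
        "scale": fit.scale,
        "redchi": fit.redchi,
        "stderr": fit.stderr,
        "q_window": list(fit.q_window),
        "success": fit.success,
        "message": fit.message,
        "nfev": fit.nfev,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
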