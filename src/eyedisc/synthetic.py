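"""Synthetic data generators with known ground truth.

Everything the estimation and calibration stages consume can be generated
here: bleach-chase intensity pairs with an exponential difference, confocal
FRAP recovery from a finite-difference 2D diffusion oracle, smoothed
expression-profile targets with the qualitative anterior-posterior shapes
of pMad/Hth/Eya, and a fine-grid 1D reference solution of the full
signaling model used as an independent cross-check of the 2D engine.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numpy.typing import NDArray

from . import kinetics
from .errors import InvalidArgument
from .frap import BleachChaseSeries, FrapRecoverySeries
from .params import HOUR, ModelParameters

__all__ = [
    "SyntheticSpec",
    "gen_bleach_chase",
    "gen_frap_recovery",
    "gen_target_profiles",
    "oracle_1d_front",
    "Oracle1DResult",
]


def _apply_noise(values: NDArray, model: str, sigma: float, rng: np.random.Generator) -> NDArray:
    if sigma < 0:
        raise InvalidArgument("noise sigma must be non-negative")
    if sigma == 0:
        return values.copy()
    if model == "lognormal":
        # multiplicative: detector noise scales with intensity
        return values * rng.lognormal(mean=0.0, sigma=sigma, size=values.shape)
    if model == "gaussian":
        return values + rng.normal(scale=sigma, size=values.shape)
    raise InvalidArgument(f"unknown noise model '{model}'")


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic dataset.

    ``generator`` names one of the module generators; ``params`` are its
    keyword arguments. The seed fully determines the output.
    """

    generator: str
    params: dict = field(default_factory=dict)
    noise: str = "lognormal"
    sigma: float = 0.02
    seed: int = 0

    def realize(self):
        fn = {
            "bleach_chase": gen_bleach_chase,
            "frap_recovery": gen_frap_recovery,
            "target_profiles": gen_target_profiles,
            "front_1d": lambda **kw: oracle_1d_front(ModelParameters(), **kw),
        }[self.generator]
        kw = dict(self.params)
        if self.generator in ("bleach_chase", "frap_recovery", "target_profiles"):
            kw.setdefault("sigma", self.sigma)
            kw.setdefault("noise", self.noise)
            kw.setdefault("seed", self.seed)
        return fn(**kw)


# -- bleach-chase -------------------------------------------------------------


def gen_bleach_chase(
    delta_true: float = 6.97e-5,
    d0: float = 0.4,
    baseline: float = 1.0,
    sigma: float = 0.0,
    n_points: int = 25,
    duration: float = 120 * 60.0,
    seed: int = 0,
    noise: str = "lognormal",
) -> BleachChaseSeries:
    """Bleached/unbleached intensity pair with exponential difference decay.

    The unbleached region sits at its visible steady state ``baseline``; the
    bleached region recovers towards it so that the difference follows
    d(t) = d0 * exp(-delta_true * t) exactly before noise. Defaults mirror
    a 120-minute movie with one frame every 5 minutes.
    """
    if delta_true <= 0:
        raise InvalidArgument("delta_true must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    diff = d0 * np.exp(-delta_true * t)
    unb = np.full_like(t, baseline)
    ble = baseline - diff
    return BleachChaseSeries(
        times=t,
        unbleached=_apply_noise(unb, noise, sigma, rng),
        bleached=_apply_noise(ble, noise, sigma, rng),
        meta={"delta_true": delta_true, "d0": d0, "sigma": sigma, "seed": seed},
    )


# -- confocal FRAP ------------------------------------------------------------


def gen_frap_recovery(
    D_true: float = 0.033,
    r_n: float = 5.0,
    K: float = 0.6,
    r_e: float = 7.0,
    domain: float = 60.0,
    dx: float = 0.75,
    duration: float = 3600.0,
    dt_frame: float = 120.0,
    sigma: float = 0.0,
    seed: int = 0,
    noise: str = "lognormal",
) -> FrapRecoverySeries:
    """Pure-2D-diffusion FRAP oracle by explicit finite differences.

    The postbleach state is the Gaussian hole 1 - K exp(-2 r^2 / r_e^2)
    (Kang convention, ``r_e`` its effective radius) on a reflecting square
    of side ``domain``; production and turnover are off, so full recovery to
    the far-field level 1 is the exact long-time limit. The ROI-mean
    recovery curve is sampled every ``dt_frame`` and the initial radial
    profile along the x axis is recorded. Stability is enforced by
    automatic substepping.
    """
    if D_true < 0:
        raise InvalidArgument("diffusion coefficient must be non-negative")
    if domain < 6 * r_e:
        raise InvalidArgument("domain should be >= 6x the bleach width for locality")
    rng = np.random.default_rng(seed)
    x = np.arange(-domain / 2, domain / 2 + dx / 2, dx)
    X, Y = np.meshgrid(x, x, indexing="ij")
    R2 = X**2 + Y**2
    c = 1.0 - K * np.exp(-2.0 * R2 / r_e**2)
    roi = R2 <= r_n**2
    if roi.sum() < 10:
        raise InvalidArgument("grid does not resolve the ROI; reduce dx")

    mid = len(x) // 2
    profile_x = x[mid:] - x[mid]
    profile_I = c[mid:, mid].copy()

    n_frames = int(np.floor(duration / dt_frame)) + 1
    times = np.arange(n_frames) * dt_frame
    F = np.empty(n_frames)
    F[0] = c[roi].mean()

    if D_true > 0:
        dt_stab = 0.2 * dx**2 / D_true
        n_sub = max(1, int(np.ceil(dt_frame / dt_stab)))
        dt_sub = dt_frame / n_sub
        lam = D_true * dt_sub / dx**2
        for k in range(1, n_frames):
            for _ in range(n_sub):
                cp = np.pad(c, 1, mode="edge")  # reflecting boundary
                c = c + lam * (
                    cp[2:, 1:-1] + cp[:-2, 1:-1] + cp[1:-1, 2:] + cp[1:-1, :-2]
                    - 4.0 * c
                )
            F[k] = c[roi].mean()
    else:
        F[1:] = F[0]

    return FrapRecoverySeries(
        times=times,
        recovery=_apply_noise(F, noise, sigma, rng),
        profile_x=profile_x,
        profile_I=_apply_noise(profile_I, noise, sigma, rng),
        r_n=r_n,
        meta={"D_true": D_true, "K": K, "r_e": r_e, "sigma": sigma, "seed": seed},
    )


# -- expression-profile targets ----------------------------------------------


def gen_target_profiles(
    x_min: float = -30.0,
    x_max: float = 90.0,
    dx: float = 1.0,
    amp: dict | None = None,
    pmad_decay: float = 15.0,
    hth_rise_center: float = 12.0,
    hth_rise_width: float = 5.0,
    eya_fall_center: float = 5.0,
    eya_fall_width: float = 5.0,
    sigma: float = 0.0,
    seed: int = 0,
    noise: str = "lognormal",
) -> dict[str, pd.DataFrame]:
    """Furrow-relative expression profiles with the qualitative AP shapes.

    Position is relative to the furrow (x = 0 at the MF, positive anterior).
    pMad peaks at the furrow and decays anteriorly; Hth is low posterior and
    rises sigmoidally into the anterior; Eya is high posterior and falls
    across the furrow. Used as calibration targets and test fixtures.
    """
    rng = np.random.default_rng(seed)
    amps = {"pMad": 1.0, "Hth": 1.0, "Eya": 1.0}
    if amp:
        amps.update(amp)
    x = np.arange(x_min, x_max + dx / 2, dx)
    pmad = amps["pMad"] * np.exp(-np.maximum(x, 0.0) / pmad_decay) / (
        1.0 + np.exp(-(x + 3.0) / 2.0)
    )
    hth = amps["Hth"] / (1.0 + np.exp(-(x - hth_rise_center) / hth_rise_width))
    eya = amps["Eya"] / (1.0 + np.exp((x - eya_fall_center) / eya_fall_width))
    out = {}
    for name, vals in (("pMad", pmad), ("Hth", hth), ("Eya", eya)):
        out[name] = pd.DataFrame(
            {"position_um": x, "intensity": _apply_noise(vals, noise, sigma, rng)}
        )
    return out


# -- fine-grid 1D reference of the signaling model ----------------------------


@dataclass
class Oracle1DResult:
    """Front trajectory (and optional profile snapshots) of the 1D model."""

    times_h: NDArray
    front_um: NDArray
    x: NDArray
    profiles: dict[float, dict[str, NDArray]] = field(default_factory=dict)

    def speed(self, t_lo_h: float, t_hi_h: float) -> float:
        """Linear-fit front speed (um/h) on a time window."""
        m = (self.times_h >= t_lo_h) & (self.times_h <= t_hi_h)
        return float(np.polyfit(self.times_h[m], self.front_um[m], 1)[0])


def _front_position(x: NDArray, c_hth: NDArray, theta: float) -> float:
    """Anterior-most interpolated crossing of c_Hth below theta; 0 if none."""
    below = c_hth <= theta
    if not below.any():
        return 0.0
    i = int(np.nonzero(below)[0][-1])
    if i == len(x) - 1:
        return float(x[-1])
    c0, c1 = c_hth[i], c_hth[i + 1]
    if c1 <= theta or c1 == c0:
        return float(x[i])
    return float(x[i] + (theta - c0) / (c1 - c0) * (x[i + 1] - x[i]))


def oracle_1d_front(
    params: ModelParameters,
    length: float = 250.0,
    n: int = 500,
    t_end_h: float = 70.0,
    dt: float | None = None,
    record_every_h: float = 0.25,
    profiles_at_h: tuple[float, ...] = (),
) -> Oracle1DResult:
    """Fine-grid finite-difference solution of the signaling model in 1D.

    Static anterior-posterior interval (no growth, u = 0), Hh influx at
    x = 0 following the margin time course, zero flux elsewhere. The front
    is the anterior-most position where Hth has dropped below theta_Hth.
    Fully independent of the 2D finite-element engine.

    Warns if the interface is thinner than ~4 grid cells.
    """
    import warnings as _warnings

    p = params
    x = np.linspace(0.0, length, n)
    h = x[1] - x[0]
    if dt is None:
        dt = p.dt_max
    th = p.theta_scheme

    # 1D Laplacian with reflecting (zero-flux) ends
    main = np.full(n, -2.0)
    main[0] = main[-1] = -1.0
    lap = sp.diags([np.ones(n - 1), main, np.ones(n - 1)], [-1, 0, 1]) / h**2

    D = {"Hh": p.D_Hh, "Dpp": p.D_Dpp, "pMad": p.D_intra,
         "Eya": p.D_intra, "Hth": p.D_intra}
    dec = {"Hh": p.delta_Hh, "Dpp": p.delta_Dpp, "pMad": p.delta_pMad,
           "Eya": p.delta_Eya, "Hth": p.delta_Hth}
    I = sp.identity(n, format="csc")
    lhs = {}
    rhs_op = {}
    for s in D:
        # same time discretization as the 2D engine: implicit diffusion,
        # theta-weighted linear decay
        lhs[s] = spla.splu((I - dt * D[s] * lap + dt * th * dec[s] * I).tocsc())
        rhs_op[s] = ((1.0 - dt * (1 - th) * dec[s]) * I).tocsr()

    c = {s: np.zeros(n) for s in D}
    c["Hth"] = np.full(n, p.p_Hth / p.delta_Hth)

    if p.D_Hh / p.delta_Hh < (4 * h) ** 2:
        _warnings.warn("front width under-resolved: fewer than ~4 cells per "
                       "Hh decay length", stacklevel=2)

    n_steps = int(np.ceil(t_end_h * HOUR / dt))
    rec_every = max(1, int(round(record_every_h * HOUR / dt)))
    times, fronts = [0.0], [0.0]
    prof_targets = sorted(profiles_at_h)
    profiles: dict[float, dict[str, NDArray]] = {}

    def production(cc, t_now):
        _, Theta, Phi = kinetics.classify_cells(cc["Hth"], cc["Hh"], p, smooth=True)
        sig_dpp = kinetics.hill_activation(cc["Dpp"], *p.hill("Dpp", "pMad"))
        sig_pm_e = kinetics.hill_activation(cc["pMad"], *p.hill("pMad", "eya"))
        sig_hh_e = kinetics.hill_activation(cc["Hh"], *p.hill("Hh", "eya"))
        sb_pm = kinetics.hill_inhibition(cc["pMad"], *p.hill("pMad", "hth"))
        sb_hh = kinetics.hill_inhibition(cc["Hh"], *p.hill("Hh", "hth"))
        prod = {
            "Hh": p.p_Hh * Phi,
            "Dpp": p.p_Dpp * cc["Hh"] * Theta,
            "pMad": p.p_pMad * sig_dpp,
            "Eya": p.p_Eya * (sig_pm_e + sig_hh_e),
            "Hth": p.p_Hth * sb_pm * sb_hh,
        }
        # margin influx enters the posterior boundary cell (width h/2)
        flux = kinetics.hh_boundary_flux(0.0, t_now, length, p)
        prod["Hh"] = prod["Hh"].copy()
        prod["Hh"][0] += 2.0 * flux / h
        return prod

    t_now = 0.0
    for k in range(1, n_steps + 1):
        prod = production(c, t_now)
        t_now = min(k * dt, t_end_h * HOUR)
        for s in D:
            c[s] = lhs[s].solve(rhs_op[s] @ c[s] + dt * prod[s])
            np.maximum(c[s], 0.0, out=c[s])
        if k % rec_every == 0 or k == n_steps:
            t_h = t_now / HOUR
            times.append(t_h)
            fronts.append(_front_position(x, c["Hth"], p.theta_Hth))
            while prof_targets and t_h >= prof_targets[0] - 1e-9:
                profiles[prof_targets.pop(0)] = {s: c[s].copy() for s in c}
    return Oracle1DResult(
        times_h=np.array(times), front_um=np.array(fronts), x=x, profiles=profiles
    )
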