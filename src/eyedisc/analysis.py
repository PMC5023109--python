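"""Derived quantities: furrow kinetics, area bookkeeping, AP profiles,
gradient-scaling test, parameter sensitivity and profile calibration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from matplotlib.tri import LinearTriInterpolator, Triangulation
from numpy.typing import NDArray
from scipy.optimize import minimize

from .errors import InsufficientData, InvalidArgument
from .kinetics import FieldState
from .mesh import GrowingMesh
from .params import ModelParameters
from .simulator import EyeDiscSimulation, SimulationResult, track_mf

__all__ = [
    "MFKinetics",
    "SensitivityRecord",
    "ScalingReport",
    "fit_mf_kinetics",
    "mf_progression_rate",
    "area_series",
    "profile_along_ap",
    "scaling_test",
    "sensitivity_sweep",
    "calibrate",
]


@dataclass
class MFKinetics:
    """Linear-fit summary of the furrow trajectory.

    ``nonlinearity`` is the root-mean-square error of the ordinary
    least-squares line, the same scalar the sensitivity analysis uses to
    score deviations from linear furrow movement.
    """

    speed: float          # um/h
    intercept: float      # um
    nonlinearity: float   # RMSE, um
    window: tuple[float, float]
    n_points: int


def fit_mf_kinetics(
    times_h: NDArray,
    PL_um: NDArray,
    window: tuple[float, float] | None = None,
) -> MFKinetics:
    """OLS line through the posterior-length series on a time window."""
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(PL_um, dtype=float)
    if window is None:
        window = (float(t[0]), float(t[-1]))
    m = (t >= window[0]) & (t <= window[1])
    if m.sum() < 3:
        raise InsufficientData("need at least 3 points in the fit window")
    coef = np.polyfit(t[m], y[m], 1)
    resid = y[m] - np.polyval(coef, t[m])
    return MFKinetics(
        speed=float(coef[0]),
        intercept=float(coef[1]),
        nonlinearity=float(np.sqrt((resid**2).mean())),
        window=window,
        n_points=int(m.sum()),
    )


def default_fit_window(result: SimulationResult) -> tuple[float, float]:
    """Steady-propagation window: after the Hh-influx era, before the
    furrow nears the anterior pole (85% of its final excursion)."""
    init = result.events.get("mf_initiation_h", 0.0) or 0.0
    t_lo = max(init + 2.0, result.params.t_off / 3600.0 + 1.0 if result.params else 12.0)
    PL_max = float(result.PL_um.max())
    late = result.times_h[result.PL_um >= 0.85 * PL_max]
    t_hi = float(late[0]) if late.size else float(result.times_h[-1])
    return (t_lo, t_hi)


def mf_progression_rate(result: SimulationResult) -> float:
    """Anchored furrow rate: final posterior length divided by the time
    elapsed since furrow initiation (0 if no furrow formed).

    Unlike the free linear fit this readout also registers changes in
    initiation timing and front offset, which is where weak (percent-level)
    parameter perturbations leave their clearest signature.
    """
    init = result.events.get("mf_initiation_h")
    if init is None:
        return 0.0
    t_end = float(result.times_h[-1])
    if t_end <= init:
        return 0.0
    return float(result.PL_um[-1]) / (t_end - init)


def area_series(result: SimulationResult) -> pd.DataFrame:
    """Total/anterior/MF/posterior area table; components sum to total."""
    return pd.DataFrame({
        "time_h": result.times_h,
        "total": result.area_total,
        "anterior": result.area_anterior,
        "mf": result.area_mf,
        "posterior": result.area_posterior,
    })


def growth_termination_time(result: SimulationResult, rate_threshold: float = 0.01) -> float | None:
    """First time from which the relative area growth stays below
    ``rate_threshold`` per hour (the plateau criterion)."""
    t, A = result.times_h, result.area_total
    if len(t) < 3:
        return None
    rate = np.gradient(A, t) / A
    below = rate < rate_threshold
    for i in range(len(t)):
        if below[i:].all():
            return float(t[i])
    return None


def profile_along_ap(
    state: FieldState,
    mesh: GrowingMesh,
    params: ModelParameters,
    band_width: float | None = None,
    n_bins: int = 60,
    relative_to_mf: bool = False,
) -> pd.DataFrame:
    """Band-averaged 1D expression profiles along the AP axis.

    Nodal values within ``band_width`` of the DV midline are binned along
    the AP coordinate (x = 0 at the posterior pole). With
    ``relative_to_mf`` the position axis is shifted by the tracked furrow
    position.
    """
    if band_width is None:
        band_width = 4.0 * mesh.target_edge
    yc = mesh.centroid[1]
    in_band = np.abs(mesh.points[:, 1] - yc) <= band_width / 2.0
    if not in_band.any():
        raise InvalidArgument("empty DV band; increase band_width")
    x_rel = np.asarray(mesh.x_relative(mesh.points[in_band, 0]))
    edges = np.linspace(0.0, mesh.L_AP, n_bins + 1)
    idx = np.clip(np.digitize(x_rel, edges) - 1, 0, n_bins - 1)
    data = {"x_um": 0.5 * (edges[:-1] + edges[1:])}
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    occupied = counts > 0
    for name, c in state.concentrations().items():
        sums = np.bincount(idx, weights=c[in_band], minlength=n_bins)
        prof = np.full(n_bins, np.nan)
        prof[occupied] = sums[occupied] / counts[occupied]
        data[name] = prof
    df = pd.DataFrame(data)[occupied.nonzero()[0][0]:].dropna()
    if relative_to_mf:
        PL = track_mf(state, mesh, params)
        df = df.assign(x_um=df["x_um"] - PL)
    return df.reset_index(drop=True)


@dataclass
class ScalingReport:
    """Anterior-gradient scaling summary at several times.

    For each analyzed time the anterior (furrow-to-anterior-pole) Dpp and
    pMad profiles are extracted, position is rescaled to [0, 1] by the
    anterior length, and a single-exponential decay length lambda (um) is
    fitted per species. Constant lambda with changing anterior length is
    the signature of a NON-scaling gradient.
    """

    times_h: list[float]
    anterior_lengths: dict[float, float]
    decay_lengths: dict[str, dict[float, float]]      # species -> time -> um
    amplitudes: dict[str, dict[float, float]]
    normalized_profiles: dict[str, dict[float, pd.DataFrame]]
    flags: list[str] = field(default_factory=list)


def _fit_decay_length(x: NDArray, y: NDArray) -> tuple[float, float, str | None]:
    """Log-linear decay-length fit on the 10%-90% amplitude segment."""
    amp = float(np.nanmax(y))
    if amp <= 0:
        return np.nan, amp, "zero amplitude"
    lo, hi = 0.1 * amp, 0.9 * amp
    m = (y >= lo) & (y <= hi) & (x >= x[int(np.nanargmax(y))])
    flag = None
    if m.sum() < 3:
        m = y > 0
        flag = "degenerate profile; fit on full positive support"
    if m.sum() < 3:
        return np.nan, amp, "no fittable segment"
    coef = np.polyfit(x[m], np.log(y[m]), 1)
    lam = -1.0 / coef[0] if coef[0] < 0 else np.nan
    if not np.isfinite(lam):
        flag = "non-decaying profile"
    return float(lam), amp, flag


def scaling_test(
    result: SimulationResult,
    times_h: Sequence[float],
    species: Sequence[str] = ("Dpp", "pMad"),
    n_bins: int = 50,
) -> ScalingReport:
    """Test whether anterior Dpp/pMad gradients scale with anterior length.

    Requires field snapshots in ``result`` at (or near) the requested
    times. Profiles are taken from the furrow to the anterior pole,
    normalized per species and per time to unit amplitude, with position
    normalized by the anterior length.
    """
    if not result.snapshots:
        raise InvalidArgument("result has no field snapshots")
    report = ScalingReport(
        times_h=[], anterior_lengths={}, decay_lengths={s: {} for s in species},
        amplitudes={s: {} for s in species}, normalized_profiles={s: {} for s in species},
    )
    snap_times = np.array([t for (t, _, _) in result.snapshots])
    params = result.params or ModelParameters()
    for t_req in times_h:
        k = int(np.argmin(np.abs(snap_times - t_req)))
        t_snap, mesh, state = result.snapshots[k]
        if abs(t_snap - t_req) > 2.0:
            report.flags.append(f"no snapshot within 2 h of t={t_req} h")
            continue
        PL = track_mf(state, mesh, params)
        L_ant = mesh.L_AP - PL
        if L_ant <= 0:
            report.flags.append(f"anterior domain empty at t={t_req} h")
            continue
        prof = profile_along_ap(state, mesh, params, n_bins=max(n_bins, 40))
        m = prof["x_um"] >= PL
        if m.sum() < 4:
            report.flags.append(f"too few anterior bins at t={t_req} h")
            continue
        x_ant = (prof["x_um"][m].to_numpy() - PL)
        report.times_h.append(t_req)
        report.anterior_lengths[t_req] = float(L_ant)
        for s in species:
            y = prof[s][m].to_numpy()
            lam, amp, flag = _fit_decay_length(x_ant, y)
            if flag:
                report.flags.append(f"{s} @ {t_req} h: {flag}")
            report.decay_lengths[s][t_req] = lam
            report.amplitudes[s][t_req] = amp
            report.normalized_profiles[s][t_req] = pd.DataFrame({
                "x_norm": x_ant / L_ant,
                "intensity_norm": y / amp if amp > 0 else y,
            })
    return report


@dataclass
class SensitivityRecord:
    """One row of the +-1% perturbation analysis."""

    parameter: str
    direction: int                # +1 / -1 / 0 (wild-type row)
    speed: float                  # anchored furrow rate, um/h
    slope: float                  # free linear-fit slope, um/h
    nonlinearity: float           # linear-fit RMSE, um
    final_area: float             # total area at run end, um^2
    speed_ratio: float
    nonlinearity_ratio: float
    area_ratio: float
    failed: bool = False


def _run_metrics(params: ModelParameters, t_end_h: float, **engine) -> tuple[float, float, float, float, SimulationResult]:
    res = EyeDiscSimulation(params, **engine).run(t_end_h, output_every_h=1.0)
    rate = mf_progression_rate(res)
    try:
        kin = fit_mf_kinetics(res.times_h, res.PL_um, default_fit_window(res))
        slope, rmse = kin.speed, kin.nonlinearity
    except InsufficientData:
        slope, rmse = np.nan, np.nan
    return rate, slope, rmse, float(res.area_total[-1]), res


DEFAULT_SWEEP_PARAMETERS = (
    "p_Hh", "delta_Hh", "theta_Hh",
    "p_Hth", "delta_Hth", "theta_Hth",
    "p_Dpp", "delta_Dpp", "p_pMad", "delta_pMad",
)


def sensitivity_sweep(
    base: ModelParameters,
    parameters: Sequence[str] = DEFAULT_SWEEP_PARAMETERS,
    fraction: float = 0.01,
    t_end_h: float = 45.0,
    **engine,
) -> list[SensitivityRecord]:
    """Re-run the simulation with each parameter perturbed by +-`fraction`.

    The unperturbed configuration is recorded as the control row with all
    ratios exactly 1. Individual run failures are recorded and the sweep
    continues.
    """
    rate0, slope0, rmse0, area0, _ = _run_metrics(base, t_end_h, **engine)
    records = [SensitivityRecord("wild_type", 0, rate0, slope0, rmse0, area0,
                                 1.0, 1.0, 1.0)]
    for name in parameters:
        for sign in (+1, -1):
            value = getattr(base, name) * (1.0 + sign * fraction)
            try:
                rate, slope, rmse, area, _ = _run_metrics(
                    base.replace(**{name: value}), t_end_h, **engine
                )
                records.append(SensitivityRecord(
                    name, sign, rate, slope, rmse, area,
                    rate / rate0 if rate0 else np.nan,
                    rmse / rmse0 if rmse0 else np.nan,
                    area / area0,
                ))
            except Exception as exc:  # keep sweeping
                warnings.warn(f"sweep run {name} {sign:+d} failed: {exc}",
                              stacklevel=2)
                records.append(SensitivityRecord(
                    name, sign, np.nan, np.nan, np.nan, np.nan,
                    np.nan, np.nan, np.nan, failed=True,
                ))
    return records


def sensitivity_table(records: Sequence[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def calibrate(
    targets: dict[str, pd.DataFrame],
    free_parameters: Sequence[str],
    base: ModelParameters,
    forward: Callable[[ModelParameters], dict[str, pd.DataFrame]] | None = None,
    speed_target: float | None = None,
    speed_weight: float = 0.0,
    max_iterations: int = 60,
) -> tuple[ModelParameters, dict]:
    """Fit free parameters so simulated furrow-relative profiles match targets.

    ``targets`` maps species names to (position_um, intensity) tables on a
    furrow-relative axis; profiles are normalized per species to unit
    maximum before comparison since concentration units are arbitrary. The
    forward model defaults to the fast fine-grid 1D solution of the same
    reaction network (:func:`eyedisc.synthetic.oracle_1d_front`), evaluated
    at 25 h. Returns the fitted parameters and a report with per-species
    residuals; non-convergence returns the best point found, flagged.
    """
    allowed = {"p_Hh", "p_Dpp", "p_pMad", "p_Eya", "p_Hth",
               "K_Hh", "K_Dpp", "K_pMad", "n_Hh", "n_Dpp", "n_pMad",
               "theta_Hth", "theta_Hh", "eta"}
    bad = set(free_parameters) - allowed
    if bad:
        raise InvalidArgument(f"not calibratable: {sorted(bad)}")

    if forward is None:
        from .synthetic import oracle_1d_front

        def forward(p: ModelParameters) -> dict[str, pd.DataFrame]:
            r = oracle_1d_front(p, length=250.0, n=350, t_end_h=25.0,
                                profiles_at_h=(25.0,))
            prof = r.profiles.get(25.0)
            front = r.front_um[-1]
            out = {}
            if prof is None:
                return out
            for s in ("pMad", "Hth", "Eya", "Dpp", "Hh"):
                out[s] = pd.DataFrame({
                    "position_um": r.x - front, "intensity": prof[s],
                })
            out["__front"] = front  # type: ignore[assignment]
            return out

    def residuals(p: ModelParameters) -> float:
        sim = forward(p)
        total = 0.0
        for s, tgt in targets.items():
            if s not in sim:
                return 1e6
            xs = tgt["position_um"].to_numpy()
            ys = tgt["intensity"].to_numpy()
            ys = ys / max(ys.max(), 1e-300)
            mod = np.interp(xs, sim[s]["position_um"], sim[s]["intensity"])
            mod = mod / max(mod.max(), 1e-300)
            total += float(((mod - ys) ** 2).mean())
        if speed_target is not None and speed_weight > 0 and "__front" in sim:
            v = sim["__front"] / 25.0
            total += speed_weight * ((v - speed_target) / speed_target) ** 2
        return total

    x0 = np.log([getattr(base, k) for k in free_parameters])

    def objective(logx: NDArray) -> float:
        try:
            p = base.replace(**{k: float(np.exp(v)) for k, v in zip(free_parameters, logx)})
        except Exception:
            return 1e6
        return residuals(p)

    base_resid = residuals(base)
    if not free_parameters:
        return base, {"residual": base_resid, "converged": True, "n_eval": 1}

    opt = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": max_iterations, "xatol": 1e-3, "fatol": 1e-8})
    fitted = base.replace(
        **{k: float(np.exp(v)) for k, v in zip(free_parameters, opt.x)}
    )
    final_resid = float(opt.fun)
    if final_resid > base_resid:  # optimizer contract: never worse than start
        fitted, final_resid = base, base_resid
    return fitted, {
        "residual": final_resid,
        "base_residual": base_resid,
        "converged": bool(opt.success),
        "n_eval": int(opt.nfev),
        "flag": None if opt.success else "max iterations reached; best-so-far returned",
    }
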