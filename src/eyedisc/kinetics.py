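"""Biochemical core of the eye disc model.

Five species evolve on the disc: the diffusible morphogens Hedgehog (Hh)
and Decapentaplegic (Dpp), the intracellular Dpp-signal transducer pMad,
the retinal determination factor Eya and the progenitor factor Homothorax
(Hth). Regulation is encoded with Hill functions; the three cell states --
proliferating progenitors (Pi), morphogenetic-furrow cells (Theta) and
differentiated cells (Phi) -- are Heaviside classifications of the Hth and
Hh concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import InvalidArgument, InvalidState, ShapeIncompatible, ConfigurationRejected
from .params import ModelParameters

__all__ = [
    "FieldState",
    "hill_activation",
    "hill_inhibition",
    "heaviside",
    "classify_cells",
    "reaction_rates",
    "initial_state",
    "hh_boundary_flux",
]


def hill_activation(c: ArrayLike, K: float, n: float) -> NDArray | float:
    """Activating Hill function sigma = c^n / (c^n + K^n).

    ``K`` is the concentration of half-maximal activity, ``n`` the steepness.
    Monotone non-decreasing in ``c``, with sigma(0) = 0 and sigma(K) = 1/2.
    """
    c_arr = np.asarray(c, dtype=float)
    if K <= 0 or n <= 0:
        raise InvalidArgument("Hill constant K and coefficient n must be positive")
    if np.any(c_arr < 0):
        raise InvalidArgument("concentration must be non-negative")
    # compute in terms of (c/K)^n to avoid overflow for large c
    ratio = np.power(c_arr / K, n)
    out = ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def hill_inhibition(c: ArrayLike, K: float, n: float) -> NDArray | float:
    """Inhibitory Hill function sigma-bar = 1 - sigma = K^n / (c^n + K^n)."""
    out = 1.0 - np.asarray(hill_activation(c, K, n))
    return out if out.ndim else float(out)


def heaviside(x: ArrayLike, eps: float = 0.0) -> NDArray:
    """Heaviside step H(x): 0 for x <= 0, 1 for x > 0.

    With ``eps > 0`` returns the tanh-regularized variant
    0.5*(1 + tanh(x/eps)) used inside PDE right-hand sides; discontinuous
    source terms destabilize the implicit finite-element solves.
    """
    x_arr = np.asarray(x, dtype=float)
    if eps > 0:
        return 0.5 * (1.0 + np.tanh(x_arr / eps))
    return np.where(x_arr > 0, 1.0, 0.0)


@dataclass
class FieldState:
    """Nodal concentration fields plus derived cell-type indicators.

    Indicators satisfy the partition of unity Pi + Theta + Phi = 1 at every
    node (exactly for the sharp Heaviside, within epsilon-tolerance for the
    smoothed variant used in the PDE right-hand sides).
    """

    c_Hh: NDArray
    c_Dpp: NDArray
    c_pMad: NDArray
    c_Eya: NDArray
    c_Hth: NDArray
    Pi: NDArray = field(default=None)  # type: ignore[assignment]
    Theta: NDArray = field(default=None)  # type: ignore[assignment]
    Phi: NDArray = field(default=None)  # type: ignore[assignment]
    t: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.c_Hth)
        for name in ("c_Hh", "c_Dpp", "c_pMad", "c_Eya", "c_Hth"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ShapeIncompatible(f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)

    @property
    def n_nodes(self) -> int:
        return len(self.c_Hth)

    def concentrations(self) -> dict[str, NDArray]:
        return {
            "Hh": self.c_Hh, "Dpp": self.c_Dpp, "pMad": self.c_pMad,
            "Eya": self.c_Eya, "Hth": self.c_Hth,
        }

    def copy(self) -> "FieldState":
        return FieldState(
            c_Hh=self.c_Hh.copy(), c_Dpp=self.c_Dpp.copy(),
            c_pMad=self.c_pMad.copy(), c_Eya=self.c_Eya.copy(),
            c_Hth=self.c_Hth.copy(),
            Pi=None if self.Pi is None else self.Pi.copy(),
            Theta=None if self.Theta is None else self.Theta.copy(),
            Phi=None if self.Phi is None else self.Phi.copy(),
            t=self.t,
        )


def classify_cells(
    c_Hth: ArrayLike,
    c_Hh: ArrayLike,
    params: ModelParameters,
    smooth: bool = False,
) -> tuple[NDArray, NDArray, NDArray]:
    """Cell-type indicator fields (Pi, Theta, Phi) from Hth and Hh levels.

    Pi    = H(c_Hth - theta_Hth)                      progenitors
    Theta = (1 - Pi) * (1 - H(c_Hh - theta_Hh))       furrow cells
    Phi   = (1 - Pi) * H(c_Hh - theta_Hh)             differentiated cells

    With the sharp Heaviside the partition of unity holds exactly; the
    smoothed variant (``smooth=True``, width ``params.eps_for(threshold)``)
    is what enters the PDE right-hand sides.
    """
    c_Hth = np.asarray(c_Hth, dtype=float)
    c_Hh = np.asarray(c_Hh, dtype=float)
    if c_Hth.shape != c_Hh.shape:
        raise ShapeIncompatible(
            f"c_Hth {c_Hth.shape} and c_Hh {c_Hh.shape} live on different meshes"
        )
    eps_hth = params.eps_for(params.theta_Hth) if smooth else 0.0
    eps_hh = params.eps_for(params.theta_Hh) if smooth else 0.0
    H_hth = heaviside(c_Hth - params.theta_Hth, eps_hth)
    H_hh = heaviside(c_Hh - params.theta_Hh, eps_hh)
    Pi = H_hth
    Theta = (1.0 - H_hth) * (1.0 - H_hh)
    Phi = (1.0 - H_hth) * H_hh
    return Pi, Theta, Phi


def reaction_rates(state: FieldState, params: ModelParameters) -> dict[str, NDArray]:
    """Per-species reaction rate fields.

    R_Hh   = p_Hh * Phi - delta_Hh * c_Hh
    R_Dpp  = p_Dpp * c_Hh * Theta - delta_Dpp * c_Dpp
    R_pMad = p_pMad * sigma(Dpp) - delta_pMad * c_pMad
    R_Eya  = p_Eya * (sigma(pMad) + sigma(Hh)) - delta_Eya * c_Eya
    R_Hth  = p_Hth * sigma-bar(pMad) * sigma-bar(Hh) - delta_Hth * c_Hth

    The indicator fields of ``state`` are used as-is; call
    :func:`classify_cells` first so they are consistent with the
    concentrations.
    """
    for name, c in state.concentrations().items():
        if np.any(c < 0):
            raise InvalidState(f"negative {name} concentration")
    if state.Phi is None or state.Theta is None:
        raise InvalidState("indicator fields missing; call classify_cells first")
    p = params
    sig_dpp = hill_activation(state.c_Dpp, *p.hill("Dpp", "pMad"))
    sig_pmad_eya = hill_activation(state.c_pMad, *p.hill("pMad", "eya"))
    sig_hh_eya = hill_activation(state.c_Hh, *p.hill("Hh", "eya"))
    sigbar_pmad = hill_inhibition(state.c_pMad, *p.hill("pMad", "hth"))
    sigbar_hh = hill_inhibition(state.c_Hh, *p.hill("Hh", "hth"))
    return {
        "Hh": p.p_Hh * state.Phi - p.delta_Hh * state.c_Hh,
        "Dpp": p.p_Dpp * state.c_Hh * state.Theta - p.delta_Dpp * state.c_Dpp,
        "pMad": p.p_pMad * sig_dpp - p.delta_pMad * state.c_pMad,
        "Eya": p.p_Eya * (sig_pmad_eya + sig_hh_eya) - p.delta_Eya * state.c_Eya,
        "Hth": p.p_Hth * sigbar_pmad * sigbar_hh - p.delta_Hth * state.c_Hth,
    }


def initial_state(params: ModelParameters, n_nodes: int) -> FieldState:
    """Pre-furrow initial condition.

    Hth sits at its unrepressed steady state p_Hth/delta_Hth everywhere;
    all other species start at zero, so every cell is a progenitor.
    """
    hth0 = params.p_Hth / params.delta_Hth
    if hth0 <= params.theta_Hth:
        raise ConfigurationRejected(
            "initial Hth steady state does not exceed theta_Hth"
        )
    zeros = np.zeros(n_nodes)
    c_Hth = np.full(n_nodes, hth0)
    Pi, Theta, Phi = classify_cells(c_Hth, zeros, params)
    return FieldState(
        c_Hh=zeros.copy(), c_Dpp=zeros.copy(), c_pMad=zeros.copy(),
        c_Eya=zeros.copy(), c_Hth=c_Hth, Pi=Pi, Theta=Theta, Phi=Phi, t=0.0,
    )


def hh_boundary_flux(
    x: ArrayLike, t: float, L_AP: float, params: ModelParameters
) -> NDArray | float:
    """Hh influx density eta * Lambda(x) * tau(t) on the disc boundary.

    ``x`` is the AP coordinate with x = 0 at the posterior pole. Lambda is 1
    on the posterior margin (x within ``margin_fraction`` of the current AP
    length) and 0 elsewhere. tau is 1 before ``t_on``, then declines with
    slope 1 per 2*(t_off - t_on) — reaching 3/4 at the window midpoint and
    1/2 at ``t_off`` — and cuts off to 0 beyond ``t_off`` (the shutdown is
    deliberately discontinuous there, mimicking the margin gradient
    vanishing as the disc fills with Hh).
    """
    if t < 0:
        raise InvalidArgument("time must be non-negative")
    if L_AP <= 0:
        raise InvalidArgument("L_AP must be positive")
    x_arr = np.asarray(x, dtype=float)
    lam = np.where(x_arr <= params.margin_fraction * L_AP, 1.0, 0.0)
    if t < params.t_on:
        tau = 1.0
    elif t <= params.t_off:
        tau = 1.0 - (t - params.t_on) / (2.0 * (params.t_off - params.t_on))
    else:
        tau = 0.0
    out = params.eta * lam * tau
    return out if out.ndim else float(out)
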