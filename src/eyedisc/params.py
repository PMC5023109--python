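"""Model parameters for the eye disc model.

Concentrations are in arbitrary units chosen such that the progenitor
steady state of Homothorax is 1 (``p_Hth / delta_Hth = 1``); thresholds and
Hill constants are therefore interpretable as fractions of maximal Hth.
Times are in seconds and lengths in micrometers throughout the package;
user-facing analysis routines convert to hours where stated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationRejected

SPECIES = ("Hh", "Dpp", "pMad", "Eya", "Hth")

#: Hill-regulated interactions: (ligand, target) pairs that may carry their
#: own (K, n) override, keyed as e.g. ``"K_Hh_hth"`` / ``"n_Hh_hth"``.
HILL_INTERACTIONS = (
    ("Dpp", "pMad"),   # sigma_Dpp activates Mad phosphorylation
    ("pMad", "eya"),   # sigma_pMad activates eya
    ("Hh", "eya"),     # sigma_Hh activates eya
    ("pMad", "hth"),   # sigma-bar_pMad represses hth
    ("Hh", "hth"),     # sigma-bar_Hh represses hth
)

HOUR = 3600.0


@dataclass
class ModelParameters:
    """All rate constants, Hill parameters, thresholds, geometry and numerics.

    Defaults are the packaged wild-type parameterization: directly measured
    constants (diffusion coefficients, degradation rates of Hh, Dpp and Hth)
    are the published values; the remaining constants were calibrated against
    the morphogenetic-furrow speed of 3.4 um/h and the qualitative shapes of
    the pMad/Hth/Eya anterior-posterior profiles.
    """

    # --- production rates (concentration/s; p_Dpp is 1/s since its term is
    #     p_Dpp * c_Hh * Theta). All species share one production rate.
    p_Hh: float = 6.97e-5
    p_Dpp: float = 6.97e-5
    p_pMad: float = 6.97e-5
    p_Eya: float = 6.97e-5
    p_Hth: float = 6.97e-5

    # --- first-order degradation rates (1/s)
    delta_Hh: float = 6.7e-4      # from D_Hh and the 7 um Hh gradient length
    delta_Dpp: float = 2.5e-4     # wing-disc Dpp gradient length
    delta_pMad: float = 1.8e-4    # dephosphorylation; model default
    delta_Eya: float = 6.97e-5    # protein turnover like Hth; model default
    delta_Hth: float = 6.97e-5    # measured by bleach-chase FRAP

    # --- diffusion coefficients (um^2/s)
    D_Hh: float = 0.033           # measured by confocal FRAP
    D_Dpp: float = 0.1
    D_intra: float = 2.5e-4       # nominal intracellular mobility (pMad/Eya/Hth)

    # --- Hill constants (concentration) and coefficients (dimensionless),
    #     shared per ligand; per-interaction overrides go in `hill_overrides`.
    K_Hh: float = 0.01
    n_Hh: float = 2.0
    K_Dpp: float = 3.0e-4
    n_Dpp: float = 2.0
    K_pMad: float = 0.2
    n_pMad: float = 2.0
    hill_overrides: dict[str, float] = field(default_factory=dict)

    # --- cell-transition thresholds (concentration)
    theta_Hth: float = 0.35        # progenitor -> MF when c_Hth falls below
    theta_Hh: float = 0.04        # MF -> differentiated when c_Hh exceeds

    # --- Hh boundary influx
    eta: float = 4.0e-4           # influx amplitude (concentration um/s)
    margin_fraction: float = 0.2  # posterior fraction of L_AP with influx
    t_on: float = 10.0 * HOUR     # influx constant until t_on (s)
    t_off: float = 10.5 * HOUR    # linear ramp to zero on [t_on, t_off]

    # --- growth
    k0: float = 2.8e-5            # initial area growth rate (1/s)
    delta_PL: float = 0.0107      # growth decay constant (1/um)

    # --- mechanics (non-identifiable in quasi-static Stokes; rescale pressure)
    mu: float = 1.0
    rho: float = 1.0

    # --- geometry: initial ellipse semi-axes (um); x is the AP axis
    a: float = 55.0
    b: float = 42.0

    # --- numerics
    eps_H_rel: float = 0.01       # smoothed-Heaviside width, fraction of threshold
    dt_max: float = 250.0         # maximum time step (s)
    target_edge: float = 5.0      # mesh target edge length (um)
    remesh_quality: float = 0.3   # remesh when min element quality drops below
    theta_scheme: float = 0.5     # time-integration theta (0.5 = Crank-Nicolson)

    def __post_init__(self) -> None:
        positive = [
            "p_Hh", "p_Dpp", "p_pMad", "p_Eya", "p_Hth",
            "delta_Hh", "delta_Dpp", "delta_pMad", "delta_Eya", "delta_Hth",
            "D_Hh", "D_Dpp", "D_intra",
            "K_Hh", "K_Dpp", "K_pMad",
            "theta_Hth", "theta_Hh", "eta", "k0", "mu", "rho", "a", "b",
            "dt_max", "target_edge",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigurationRejected(f"{name} must be strictly positive")
        for name in ("n_Hh", "n_Dpp", "n_pMad"):
            if not getattr(self, name) >= 1:
                raise ConfigurationRejected(f"{name} must be >= 1")
        if not 0 < self.margin_fraction < 1:
            raise ConfigurationRejected("margin_fraction must lie in (0, 1)")
        if not self.t_on < self.t_off:
            raise ConfigurationRejected("t_on must precede t_off")
        if not self.p_Hth / self.delta_Hth > self.theta_Hth:
            raise ConfigurationRejected(
                "p_Hth/delta_Hth must exceed theta_Hth, otherwise no "
                "progenitor state exists at t = 0"
            )
        if self.delta_PL < 0:
            raise ConfigurationRejected("delta_PL must be non-negative")

    # -- Hill parameter lookup ------------------------------------------------

    def hill(self, ligand: str, target: str) -> tuple[float, float]:
        """(K, n) for the regulation of `target` by `ligand`.

        Falls back to the shared per-ligand pair unless an override key
        ``K_<ligand>_<target>`` / ``n_<ligand>_<target>`` is present.
        """
        if (ligand, target) not in HILL_INTERACTIONS:
            raise KeyError(f"unknown regulation {ligand} -> {target}")
        K = self.hill_overrides.get(f"K_{ligand}_{target}", getattr(self, f"K_{ligand}"))
        n = self.hill_overrides.get(f"n_{ligand}_{target}", getattr(self, f"n_{ligand}"))
        return float(K), float(n)

    def eps_for(self, threshold: float) -> float:
        """Smoothed-Heaviside width for a given threshold concentration."""
        return self.eps_H_rel * threshold

    # -- (de)serialization ----------------------------------------------------

    def replace(self, **changes: Any) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationRejected(
                f"unknown parameter keys: {sorted(unknown)}"
            )
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationRejected("parameter file must be a flat mapping")
        return cls.from_dict(data)
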