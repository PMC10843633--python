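"""Narrow-escape scaling: mean escape time through partially absorbing
windows and the asymptotic number of escape windows N_w(N_c).

The PSD boundary is replaced by a reflecting sphere pierced by N_w
partially absorbing windows of size a, giving the mean escape time

    tau_bar = |Omega| / (2 pi kappa N_w a^2).

Combining the fitted scaling laws R_g(N_c), zeta(N_c) (window size a ~ zeta)
and tau_e(N_c) yields N_w as an exact ratio and as a three-term large-N_c
expansion.  The absorption constant kappa is not determined by the
simulations; N_w is reported up to the factor 1/kappa (default kappa = 1 in
reduced units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import ScalingFit


@dataclass
class NarrowEscapeParams:
    """Inputs of the narrow-escape formula (reduced units)."""

    volume: float  # |Omega|
    kappa: float  # partial-absorption constant
    n_windows: float  # N_w
    window_size: float  # a

    def __post_init__(self) -> None:
        for name in ("volume", "kappa", "n_windows", "window_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def mean_escape_time(params: NarrowEscapeParams) -> float:
    """tau_bar = |Omega| / (2 pi kappa N_w a^2)."""
    return params.volume / (
        2.0 * np.pi * params.kappa * params.n_windows * params.window_size**2
    )


@dataclass
class WindowScalingResult:
    """N_w(N_c) (times kappa) from the exact ratio and the large-N_c expansion."""

    n_c: np.ndarray
    exact: np.ndarray
    expansion: np.ndarray

    @property
    def relative_difference(self) -> np.ndarray:
        return np.abs(self.exact - self.expansion) / np.abs(self.exact)


def windows_from_scaling(
    rg_fit: ScalingFit,
    zeta_fit: ScalingFit,
    tau_fit: ScalingFit,
    n_c: np.ndarray,
    kappa: float = 1.0,
) -> WindowScalingResult:
    """Number of escape windows vs cross-linker count, exact and expanded.

    Exact ratio (from tau_bar = |Omega|/(2 pi kappa N_w a^2) with
    |Omega| ~ R_g^3, a ~ zeta, tau_bar ~ tau_e):

        N_w = (k_rg N_c^-nu + rg_inf)^3
              / [2 pi kappa (k_z N_c^-gamma + z_inf)^2 (k_t N_c^eta + tau0)]

    Three-term large-N_c expansion (first order in the small quantities
    N_c^-nu, N_c^-gamma, N_c^-eta):

        N_w ~ rg_inf^3 / (2 pi kappa z_inf^2 k_t)
              * [N_c^-eta + 3 (k_rg/rg_inf) N_c^-(nu+eta)
                          - 2 (k_z/z_inf) N_c^-(eta+gamma)]
    """
    if rg_fit.form != "decay" or zeta_fit.form != "decay" or tau_fit.form != "growth":
        raise ValueError("expected decay fits for R_g and zeta and a growth fit for tau_e")
    nc = np.asarray(n_c, dtype=float)
    if np.any(nc <= 0) or kappa <= 0:
        raise ValueError("N_c and kappa must be positive")
    krg, nu, rg_inf = rg_fit.amplitude, rg_fit.exponent, rg_fit.offset
    kz, gam, z_inf = zeta_fit.amplitude, zeta_fit.exponent, zeta_fit.offset
    kt, eta, tau0 = tau_fit.amplitude, tau_fit.exponent, tau_fit.offset

    rg = krg * nc ** (-nu) + rg_inf
    zeta = kz * nc ** (-gam) + z_inf
    tau = kt * nc**eta + tau0
    denom = 2.0 * np.pi * kappa * zeta**2 * tau
    if np.any(denom <= 0) or np.any(rg <= 0):
        raise ValueError("fit parameters produce a nonpositive ratio")
    exact = rg**3 / denom

    pref = rg_inf**3 / (2.0 * np.pi * kappa * z_inf**2 * kt)
    expansion = pref * (
        nc ** (-eta)
        + 3.0 * (krg / rg_inf) * nc ** (-(nu + eta))
        - 2.0 * (kz / z_inf) * nc ** (-(eta + gam))
    )
    return WindowScalingResult(n_c=nc, exact=exact, expansion=expansion)
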