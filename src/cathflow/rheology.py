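"""Shear-rate magnitude and Carreau shear-thinning blood rheology.

Whole blood thins under shear: its apparent viscosity falls from a
zero-shear plateau ``mu_zero`` to an infinite-shear plateau ``mu_inf`` as
the shear rate grows.  The asymptotic Carreau model interpolates between
the plateaus,

    mu(gamma_dot) = mu_inf + (mu_zero - mu_inf) * [1 + (lambda*gamma_dot)**2]**((n-1)/2)

with relaxation time ``lambda`` setting where thinning begins and power-law
index ``n`` < 1 setting how fast it proceeds.  The scalar shear rate fed to
the model is the second-invariant magnitude of the strain-rate tensor,
``gamma_dot = sqrt(2 D:D)`` with ``D = (G + G^T)/2`` for velocity gradient G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CarreauParameters",
    "BLOOD_CARREAU",
    "shear_rate_magnitude",
    "carreau_viscosity",
    "scalar_shear_stress",
]


@dataclass(frozen=True)
class CarreauParameters:
    """Constants of the asymptotic Carreau viscosity law.

    Attributes
    ----------
    mu_inf : float
        Infinite-shear viscosity plateau (Pa·s).
    mu_zero : float
        Zero-shear viscosity plateau (Pa·s); must exceed ``mu_inf``.
    lambda_time : float
        Relaxation time (s) marking the onset of shear thinning.
    n_index : float
        Power-law index (dimensionless), in (0, 1] for shear thinning.
    """

    mu_inf: float
    mu_zero: float
    lambda_time: float
    n_index: float

    def __post_init__(self) -> None:
        if not (self.mu_zero > self.mu_inf > 0.0):
            raise ValueError(
                f"require mu_zero > mu_inf > 0, got mu_zero={self.mu_zero}, "
                f"mu_inf={self.mu_inf}"
            )
        if not self.lambda_time > 0.0:
            raise ValueError(f"lambda_time must be positive, got {self.lambda_time}")
        if not 0.0 < self.n_index <= 1.0:
            raise ValueError(f"n_index must lie in (0, 1], got {self.n_index}")

    def newtonian(self) -> bool:
        """True when the law degenerates to a constant viscosity (n = 1)."""
        return self.n_index == 1.0


#: Whole-blood constants used throughout: mu_inf = 3.45 mPa·s,
#: mu_zero = 25 mPa·s, lambda = 25 s, n = 0.25.
BLOOD_CARREAU = CarreauParameters(
    mu_inf=0.00345, mu_zero=0.025, lambda_time=25.0, n_index=0.25
)


def shear_rate_magnitude(grad: np.ndarray) -> float | np.ndarray:
    """Scalar shear rate ``sqrt(2 D:D)`` from a velocity-gradient tensor.

    Parameters
    ----------
    grad : ndarray
        Velocity gradient ``G[i, j] = du_i/dx_j`` with shape ``(d, d)`` for
        d in {2, 3}, or a stack of gradients with shape ``(..., d, d)``.
        2D gradients embed with zero out-of-plane components.

    Returns
    -------
    float or ndarray
        Non-negative shear rate (1/s).  Antisymmetric (rigid-rotation)
        parts of the gradient do not contribute.
    """
    g = np.asarray(grad, dtype=float)
    if g.ndim < 2 or g.shape[-1] != g.shape[-2] or g.shape[-1] not in (2, 3):
        raise ValueError(f"expected (..., d, d) gradient with d in {{2,3}}, got {g.shape}")
    if not np.all(np.isfinite(g)):
        raise ValueError("velocity gradient contains non-finite entries")
    d = 0.5 * (g + np.swapaxes(g, -1, -2))
    out = np.sqrt(2.0 * np.sum(d * d, axis=(-1, -2)))
    return float(out) if out.ndim == 0 else out


def carreau_viscosity(
    params: CarreauParameters, gamma_dot: float | np.ndarray
) -> float | np.ndarray:
    """Apparent viscosity (Pa·s) at shear rate ``gamma_dot`` (1/s).

    Bounded in [mu_inf, mu_zero]; strictly decreasing in the shear rate for
    n < 1.  Negative shear rates are rejected.
    """
    gd = np.asarray(gamma_dot, dtype=float)
    if np.any(gd < 0.0) or not np.all(np.isfinite(gd)):
        raise ValueError("shear rate must be finite and non-negative")
    p = params
    mu = p.mu_inf + (p.mu_zero - p.mu_inf) * (
        1.0 + (p.lambda_time * gd) ** 2
    ) ** ((p.n_index - 1.0) / 2.0)
    return float(mu) if mu.ndim == 0 else mu


def scalar_shear_stress(
    params: CarreauParameters, gamma_dot: float | np.ndarray
) -> float | np.ndarray:
    """Scalar viscous shear stress ``tau = mu(gamma_dot) * gamma_dot`` (Pa).

    The conventional scalar stress for laminar non-Newtonian reporting:
    zero exactly at zero shear rate and strictly increasing otherwise
    (the viscosity is bounded below by ``mu_inf`` > 0).
    """
    gd = np.asarray(gamma_dot, dtype=float)
    tau = carreau_viscosity(params, gd) * gd
    return float(tau) if np.ndim(tau) == 0 else tau
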