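"""Adaptive fuzzy neuro-controllers, one SISO loop per muscle.

Each muscle carries its own controller whose single input channel is the
lateral (Z) position error of its insertion node and whose output is the
activation alpha in [0, 1].  The controller is a zero-order Takagi-Sugeno
fuzzy network: a fixed grid of Gaussian memberships over the normalised
(error, error-rate) plane, a scalar consequent weight per rule and a
normalised weighted sum as output.

The weights are tuned online by steepest descent on the two-critic cost

    E = 1/2 ke (h1 e + h2 de/dt + h3 int e)^2 + 1/2 k_alpha |alpha|^2

which, with the critic signals r_e = h1 e + h2 de/dt + h3 int e and
r_alpha = |alpha| and the sign-only plant Jacobian j = sign(dZ/dalpha),
gives the per-step update

    dw_i = eta (ke h1 r_e j - k_alpha r_alpha) dalpha/dw_i .

Because the loop is SISO, the sign of the Jacobian suffices: a muscle whose
origin lies on the -Z side pulls its node toward -Z, so j = -1 for it.
The kinematic-error weight ke decreases from L1 down to L5, prioritising
the top of the column where the control authority requirement is largest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actuators import MuscleActuator, MuscleSet
from .geometry import SpineGeometry

__all__ = ["ControllerGains", "FuzzyController", "ControllerState",
           "assign_jacobian_signs", "KE_DEFAULT"]

#: kinematic-error weights for levels L1 .. L5
KE_DEFAULT = {"L1": 15.0, "L2": 7.0, "L3": 2.5, "L4": 1.0, "L5": 0.1}


@dataclass
class ControllerGains:
    """Critic and learning gains.

    ``eta`` is a learning *rate* in 1/s; the per-step increment is
    ``eta * dt``, so refining the integration step does not change the
    learning dynamics.  ``e_norm``/``edot_norm`` normalise the membership
    inputs (mm and mm/s); ``windup`` clamps the error integral (mm s).
    """

    h1: float = 2.0
    h2: float = 2.0
    h3: float = 2.0
    k_alpha: float = 0.2
    k_e: dict = field(default_factory=lambda: dict(KE_DEFAULT))
    eta: float = 0.3
    e_norm: float = 2.0
    edot_norm: float = 20.0
    windup: float = 50.0
    grid: int = 7

    def validate(self):
        vals = [self.h1, self.h2, self.h3, self.k_alpha, self.eta]
        if any(v < 0 for v in vals):
            raise ValueError("controller gains must be nonnegative")
        if self.grid < 2:
            raise ValueError("membership grid must have at least 2 nodes per axis")


@dataclass
class ControllerState:
    """Snapshot of one controller's internal signals (diagnostics)."""

    weights: np.ndarray
    error_integral: float
    last_error: float
    critic_re: float
    critic_ralpha: float
    jacobian_sign: int


class FuzzyController:
    """Zero-order Takagi-Sugeno network with online two-critic learning."""

    def __init__(self, ke: float, jacobian_sign: int, gains: ControllerGains):
        gains.validate()
        if jacobian_sign not in (-1, 1):
            raise ValueError("jacobian sign must be -1 or +1")
        self.gains = gains
        self.ke = float(ke)
        self.j = int(jacobian_sign)
        g = np.linspace(-1.0, 1.0, gains.grid)
        ce, cd = np.meshgrid(g, g, indexing="ij")
        self._ce = ce.ravel()
        self._cd = cd.ravel()
        self._sigma = 2.0 / (gains.grid - 1)
        self._neg_half_inv_sig2 = -1.0 / (2.0 * self._sigma**2)
        self.w = np.zeros(gains.grid * gains.grid)
        self.integ = 0.0
        self.last_error = 0.0
        self.last_re = 0.0
        self.last_alpha = 0.0

    # -- fuzzy network ------------------------------------------------------
    def firing(self, e_mm: float, edot_mms: float) -> np.ndarray:
        """Normalised firing strengths phi_i = mu_i / sum(mu); these are the
        output sensitivities dalpha/dw_i in the unclipped region."""
        g = self.gains
        en = min(1.0, max(-1.0, e_mm / g.e_norm))
        dn = min(1.0, max(-1.0, edot_mms / g.edot_norm))
        mu = np.exp(((en - self._ce) ** 2 + (dn - self._cd) ** 2)
                    * self._neg_half_inv_sig2)
        total = mu.sum()
        if total <= 0.0:
            raise ValueError("membership family does not cover the input")
        return mu / total

    def output(self, e_mm: float, edot_mms: float):
        """Activation (clipped to [0, 1]) and the sensitivity vector."""
        phi = self.firing(e_mm, edot_mms)
        alpha = min(1.0, max(0.0, float(phi @ self.w)))
        return alpha, phi

    # -- critics and learning -----------------------------------------------
    def critics(self, e_mm: float, edot_mms: float, dt: float):
        """Update the error integral (rectangle rule, anti-windup clamp)
        and return the kinematic critic r_e."""
        if dt <= 0.0:
            raise ValueError("dt must be positive")
        g = self.gains
        self.integ = min(g.windup, max(-g.windup, self.integ + e_mm * dt))
        re = g.h1 * e_mm + g.h2 * edot_mms + g.h3 * self.integ
        self.last_error = e_mm
        self.last_re = re
        return re

    def step(self, e_mm: float, edot_mms: float, dt: float) -> float:
        """One control step: compute alpha from the current weights, then
        apply the steepest-descent weight update with the current critics."""
        g = self.gains
        re = self.critics(e_mm, edot_mms, dt)
        alpha, phi = self.output(e_mm, edot_mms)
        gradient = self.ke * g.h1 * re * self.j - g.k_alpha * abs(alpha)
        self.w += (g.eta * dt) * gradient * phi
        self.last_alpha = alpha
        return alpha

    def stationarity_residual(self) -> float:
        """|ke h1 re j - k_alpha alpha|: vanishes at the learned fixed
        point of the weight update for an active muscle."""
        g = self.gains
        return abs(self.ke * g.h1 * self.last_re * self.j
                   - g.k_alpha * abs(self.last_alpha))

    def snapshot(self) -> ControllerState:
        return ControllerState(
            weights=self.w.copy(), error_integral=self.integ,
            last_error=self.last_error, critic_re=self.last_re,
            critic_ralpha=abs(self.last_alpha), jacobian_sign=self.j,
        )


def assign_jacobian_signs(muscles: list[MuscleActuator] | MuscleSet,
                          geometry: SpineGeometry) -> np.ndarray:
    """Sign of dZ/dalpha per muscle from its line of action.

    Increasing the activation pulls the insertion node toward the origin,
    so the sign is that of the Z-component of (origin - insertion).  A line
    of action with no lateral component cannot control Z and is an error.
    """
    acts = muscles.actuators() if isinstance(muscles, MuscleSet) else muscles
    signs = np.empty(len(acts), dtype=int)
    for i, m in enumerate(acts):
        dz = m.origin_m[1] - geometry.coords_m[m.insertion][1]
        if dz == 0.0:
            raise ValueError(f"muscle {m.level}/{m.side}: vertical line of action")
        signs[i] = 1 if dz > 0.0 else -1
    return signs
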