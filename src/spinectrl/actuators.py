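"""Straight-line Hill muscle actuators attached to the spine plant.

Ten muscles: one pair per lumbar level, origins fixed on the pelvis at a
lateral offset +/-D from the level's target position, insertions at the
lumbar nodes.  Each actuator pulls its two attachment points together along
the current straight line of action (no wrapping or via points); the two
nodal force vectors sum to zero exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import hill
from .geometry import PlantState, SpineGeometry

__all__ = ["MuscleActuator", "MuscleSet", "kinematics_from_state"]


@dataclass
class MuscleActuator:
    """One Hill-type line actuator.

    ``side`` is -1 (origin on the -Z side) or +1; ``insertion`` is the node
    index; ``origin_m`` the fixed pelvis attachment in metres; ``l0_m`` the
    resting length (by default the length in the target posture, so the
    posture the controller defends is the muscle's reference);
    ``l_dot_max = l0 / 0.1 s`` exactly.
    """

    level: str
    side: int
    insertion: int
    origin_m: np.ndarray
    l0_m: float
    f_max: float = hill.F_MAX_DEFAULT
    activation: float = 0.0

    @property
    def l_dot_max(self) -> float:
        return self.l0_m / 0.1


def kinematics_from_state(actuator: MuscleActuator, state: PlantState,
                          geometry: SpineGeometry):
    """Length, lengthening rate and unit line of action (origin→insertion)
    in the deformed configuration.  The rate is the analytic projection of
    the insertion-node velocity onto the line of action, not a finite
    difference."""
    p = state.node_positions_m(geometry)[actuator.insertion]
    v = state.node_velocities_m()[actuator.insertion]
    d = p - actuator.origin_m
    l = float(np.linalg.norm(d))
    if l <= 0.0:
        raise ValueError("muscle endpoints coincide")
    unit = d / l
    l_dot = float(unit @ v)
    return l, l_dot, unit


class MuscleSet:
    """Vectorised container for the ten (or 2*n_levels) actuators.

    Provides nodal forces plus consistent stiffness/damping contributions
    for the implicit integrator.  ``passive`` selects the parallel-elastic
    convention ('slack' by default, 'eq' for the exponential as printed,
    'none' to disable).
    """

    def __init__(self, geometry: SpineGeometry, D_mm: float,
                 f_max: float = hill.F_MAX_DEFAULT, passive: str = "slack",
                 l0_scale: float = 1.0):
        if D_mm <= 0.0:
            raise ValueError("muscle origin offset D must be positive")
        self.geometry = geometry
        self.passive = passive
        lumbar = geometry.lumbar_nodes
        nlev = len(lumbar)
        labels = [f"L{nlev - k}" for k in range(nlev)]  # bottom-up L5..L1
        self.node = np.repeat(lumbar, 2)
        self.side = np.tile([-1.0, 1.0], nlev)
        targets = geometry.coords_m[self.node]
        self.origin = np.stack(
            [np.zeros(2 * nlev), targets[:, 1] + self.side * D_mm * 1e-3], axis=1
        )
        self.l0 = np.linalg.norm(self.origin - targets, axis=1) * l0_scale
        self.ld_max = self.l0 / 0.1
        self.f_max = float(f_max)
        self.levels = np.repeat(labels, 2)
        self.n = 2 * nlev
        self._unodes = np.unique(self.node)

    def actuators(self) -> list[MuscleActuator]:
        return [
            MuscleActuator(
                level=str(self.levels[i]), side=int(self.side[i]),
                insertion=int(self.node[i]), origin_m=self.origin[i],
                l0_m=float(self.l0[i]), f_max=self.f_max,
            )
            for i in range(self.n)
        ]

    def state_arrays(self, u: np.ndarray, v: np.ndarray):
        """Lengths, rates and unit vectors (insertion→origin) for all
        muscles given displacement/velocity vectors."""
        d = u.reshape(-1, 3)
        vel = v.reshape(-1, 3)
        p = self.geometry.coords_m[self.node] + d[self.node, :2]
        pv = vel[self.node, :2]
        dvec = self.origin - p
        l = np.linalg.norm(dvec, axis=1)
        unit = dvec / l[:, None]          # points insertion -> origin (pull)
        l_dot = -np.einsum("mi,mi->m", unit, pv)
        return l, l_dot, unit

    def forces(self, u: np.ndarray, v: np.ndarray, alpha: np.ndarray):
        """Per-muscle tension F >= 0, pull direction, and the analytic
        derivatives dF/dl, dF/dl_dot needed for the consistent tangent."""
        l, l_dot, unit = self.state_arrays(u, v)
        alpha = np.clip(alpha, 0.0, 1.0)
        r = l / self.l0
        x = l_dot / self.ld_max
        fl = hill._fl(r)
        fv = hill._fv(x)
        if self.passive == "eq":
            fp = hill._fp(r)
            dfp_dr = 7.675 * fp
        elif self.passive == "slack":
            fp = hill._fps(r)
            dfp_dr = np.where(fp > 0.0, 7.675 * hill._fp(r), 0.0)
        elif self.passive == "none":
            fp = np.zeros_like(l)
            dfp_dr = np.zeros_like(l)
        else:
            raise ValueError(f"unknown passive mode {self.passive!r}")
        F = self.f_max * (alpha * fl * fv + fp)
        dF_dl = self.f_max * (alpha * hill._dfl_dr(r) * fv + dfp_dr) / self.l0
        dF_dld = self.f_max * alpha * fl * hill._dfv_dx(x) / self.ld_max
        return F, unit, l, dF_dl, dF_dld

    def nodal_forces(self, u: np.ndarray, v: np.ndarray, alpha: np.ndarray,
                     ndof: int) -> np.ndarray:
        """Global force vector applied by the muscles on the spine nodes."""
        F, unit, _, _, _ = self.forces(u, v, alpha)
        out = np.zeros(ndof)
        for i in range(self.n):
            i3 = 3 * self.node[i]
            out[i3:i3 + 2] += F[i] * unit[i]
        return out

    def add_system_contributions(self, u, v, alpha, f, K, C):
        """Accumulate muscle forces into ``f`` and their geometric/material
        stiffness and force-velocity damping into ``K`` and ``C`` (signs for
        a residual written as  M a + C v + f_int - f_ext - f_muscle)."""
        F, unit, l, dF_dl, dF_dld = self.forces(u, v, alpha)
        uu = np.einsum("mi,mj->mij", unit, unit)           # (n, 2, 2)
        I2 = np.eye(2)[None, :, :]
        # d(F u)/d p: length change restretches and rotates the line
        Jm = -uu * dF_dl[:, None, None] - (F / l)[:, None, None] * (I2 - uu)
        Cm = uu * dF_dld[:, None, None]
        fm = F[:, None] * unit
        # muscles are stored pairwise per level: 2k and 2k+1 share a node
        nlev = self.n // 2
        fp2 = fm.reshape(nlev, 2, 2).sum(axis=1)
        Jp2 = Jm.reshape(nlev, 2, 2, 2).sum(axis=1)
        Cp2 = Cm.reshape(nlev, 2, 2, 2).sum(axis=1)
        for k in range(nlev):
            i3 = 3 * self.node[2 * k]
            f[i3:i3 + 2] += fp2[k]
            K[i3:i3 + 2, i3:i3 + 2] -= Jp2[k]
            C[i3:i3 + 2, i3:i3 + 2] += Cp2[k]
        return F
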