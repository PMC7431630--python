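"""Follower-load-constrained equilibrium baseline.

The matched inverse model resolves the muscle redundancy by fiat: on the
fixed deformed geometry, the five unilateral muscle intensities are chosen
so that the internal force transmitted across every intervertebral section
is a pure follower load - aligned with the local spine tangent, zero shear.
That is a square 5x5 linear system (one shear constraint per level, one
signed intensity per level; the sign selects the active side, and the
system is re-solved with the selected side's exact line geometry until the
side pattern is consistent).

Muscle attachment geometry matches the control model: origins on the pelvis
at lateral offset +/-D from each vertebra, so the line-of-action direction
ratio is D / X_k.  Section tangents default to the chords of adjacent
nodes (piecewise-linear spine); a cubic-spline tangent option exists since
the source's exact curvature treatment is not documented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import LEVELS, SpineGeometry, build_geometry
from .simulator import LoadingCase, SimulationResult, STUDY_CASES

__all__ = ["EquilibriumSolution", "solve_follower_load", "compare_models"]


@dataclass
class EquilibriumSolution:
    case: LoadingCase
    muscle_forces: np.ndarray      # magnitudes, N, bottom-up (L5..L1)
    sides: np.ndarray              # -1 / +1 active side per level
    compression: np.ndarray        # N, bottom-up (L5-S1 .. L1-L2)
    shear: np.ndarray              # N, same order
    levels: tuple = LEVELS

    @property
    def residual_shear(self) -> float:
        return float(np.abs(self.shear).max())

    def signed_forces(self) -> np.ndarray:
        return self.muscle_forces * self.sides


def _tangents(coords_mm: np.ndarray, mode: str) -> np.ndarray:
    """Unit tangent per section (cut below each lumbar node), bottom-up."""
    n = len(coords_mm) - 1
    t = np.empty((n, 2))
    if mode == "chord":
        d = np.diff(coords_mm, axis=0)
        t = d / np.linalg.norm(d, axis=1, keepdims=True)
    elif mode == "spline":
        cs = CubicSpline(coords_mm[:, 0], coords_mm[:, 1])
        xm = 0.5 * (coords_mm[:-1, 0] + coords_mm[1:, 0])
        dz = cs(xm, 1)
        t = np.stack([np.ones(n), dz], axis=1)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown tangent mode {mode!r}")
    return t


def solve_follower_load(case: LoadingCase | int,
                        geometry: SpineGeometry | None = None,
                        tangent: str = "chord") -> EquilibriumSolution:
    """Solve the zero-shear system on the fixed deformed geometry."""
    if isinstance(case, int):
        case = STUDY_CASES[case]
    geometry = geometry if geometry is not None else build_geometry()
    coords = geometry.node_coords_mm
    nlev = geometry.n_nodes - 1
    if len(geometry.lumbar_nodes) != nlev:
        raise ValueError("equilibrium baseline expects one muscle per node")

    D = case.D_mm
    tvec = _tangents(coords, tangent)
    nvec = np.stack([-tvec[:, 1], tvec[:, 0]], axis=1)

    # external vertical loads per node index (P1 at the top)
    P_node = np.zeros(geometry.n_nodes)
    for k, p in enumerate(case.P[:nlev]):
        P_node[nlev - k] = p

    down = np.array([-1.0, 0.0])
    sides = np.ones(nlev)

    def unit_vectors(s):
        ins = coords[1:]
        org = np.stack([np.zeros(nlev), ins[:, 1] + s * D], axis=1)
        d = org - ins
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    for _ in range(2 * nlev + 2):
        U = unit_vectors(sides)
        A = np.zeros((nlev, nlev))
        b = np.zeros(nlev)
        for j in range(nlev):          # cut below node j+1
            for k in range(j, nlev):   # muscles inserting at/above the cut
                A[j, k] = U[k] @ nvec[j]
            b[j] = -sum(P_node[i] * (down @ nvec[j])
                        for i in range(j + 1, nlev + 1))
        try:
            f = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "degenerate muscle geometry: follower-load system is singular"
            ) from exc
        new_sides = np.where(f < 0.0, -sides, sides)
        if np.all(new_sides == sides):
            break
        sides = new_sides
    f = np.abs(f)

    U = unit_vectors(sides)
    compression = np.empty(nlev)
    shear = np.empty(nlev)
    for j in range(nlev):
        R = sum(P_node[i] * down for i in range(j + 1, nlev + 1))
        R = R + (f[j:, None] * U[j:]).sum(axis=0)
        compression[j] = -(R @ tvec[j])
        shear[j] = R @ nvec[j]
    return EquilibriumSolution(case=case, muscle_forces=f, sides=sides,
                               compression=compression, shear=shear)


def compare_models(control: SimulationResult,
                   equilibrium: EquilibriumSolution) -> dict:
    """Side-by-side comparison of the two models for the same case.

    Active muscle force per level is taken from the control run's steady
    window; RMSE and the sum-of-forces difference are over the five levels.
    """
    if control.case.P != equilibrium.case.P or control.case.D_mm != equilibrium.case.D_mm:
        raise ValueError("control and equilibrium results are for different cases")
    nlev = len(equilibrium.muscle_forces)
    steady = control.steady_muscle_forces()
    ctrl_force = np.empty(nlev)
    ctrl_side = np.empty(nlev)
    for k in range(nlev):              # muscles stored pairwise bottom-up
        pair = steady[2 * k:2 * k + 2]
        i = int(np.argmax(pair))
        ctrl_force[k] = pair[i]
        ctrl_side[k] = control.muscle_sides[2 * k + i]
    eq_force = equilibrium.muscle_forces
    diff = ctrl_force - eq_force
    ctrl_sl = control.section_loads
    return dict(
        levels=list(equilibrium.levels),
        control_forces=ctrl_force,
        control_sides=ctrl_side,
        equilibrium_forces=eq_force,
        equilibrium_sides=equilibrium.sides.astype(float),
        force_diff=diff,
        rmse=float(np.sqrt(np.mean(diff**2))),
        sum_diff=float(ctrl_force.sum() - eq_force.sum()),
        control_compression=np.array([s.compression for s in ctrl_sl]),
        control_shear=np.array([s.shear for s in ctrl_sl]),
        equilibrium_compression=equilibrium.compression.copy(),
        equilibrium_shear=equilibrium.shear.copy(),
    )
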