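"""Geometrically nonlinear 2D frame finite elements.

Corotational Euler-Bernoulli beam: small strains inside each element, large
rotations handled by the corotating frame.  The tangent includes the
material stiffness and the geometric (stress-stiffening) terms from the
current axial force, so buckling of the compressed column is captured.
Slenderness of the lumbar column (~190/35) makes shear deformation
negligible; no Timoshenko correction is applied.
"""

from __future__ import annotations

import numpy as np

from .geometry import LEVELS, PlantState, SectionLoads, SpineGeometry

__all__ = ["BeamModel", "assemble_tangent", "recover_section_loads", "critical_load"]


class StructuralInstabilityError(RuntimeError):
    """Raised when the tangent operator is singular (buckling)."""


class BeamModel:
    """Assembled corotational frame for a given geometry.

    Precomputes connectivity and reference lengths; ``internal_forces``
    returns the global internal force vector and consistent tangent for a
    displacement vector ``u`` (3 DoFs per node, SI units).
    """

    def __init__(self, geometry: SpineGeometry):
        self.geometry = geometry
        self.X = geometry.coords_m
        ne = geometry.n_elements
        self.ndof = 3 * geometry.n_nodes
        self.free = np.arange(3, self.ndof)  # base clamped
        self.L0 = np.linalg.norm(np.diff(self.X, axis=0), axis=1)
        self.beta0 = np.arctan2(
            self.X[1:, 1] - self.X[:-1, 1], self.X[1:, 0] - self.X[:-1, 0]
        )
        idx = np.arange(ne)
        self.edof = np.stack(
            [3 * idx, 3 * idx + 1, 3 * idx + 2,
             3 * (idx + 1), 3 * (idx + 1) + 1, 3 * (idx + 1) + 2], axis=1
        )
        self.EI = geometry.EI
        self.EA = geometry.EA
        self._kix = [np.ix_(self.edof[e], self.edof[e]) for e in range(ne)]

    def element_state(self, u: np.ndarray):
        """Current element chords: lengths, direction cosines, local
        rotations and the axial force / end moments."""
        d = u.reshape(-1, 3)
        x = self.X + d[:, :2]
        dx = x[1:] - x[:-1]
        L = np.linalg.norm(dx, axis=1)
        c = dx[:, 0] / L
        s = dx[:, 1] / L
        beta = np.arctan2(dx[:, 1], dx[:, 0])
        rigid = (beta - self.beta0 + np.pi) % (2.0 * np.pi) - np.pi
        t1 = d[:-1, 2] - rigid
        t2 = d[1:, 2] - rigid
        N = self.EA * (L - self.L0) / self.L0
        M1 = (self.EI / self.L0) * (4.0 * t1 + 2.0 * t2)
        M2 = (self.EI / self.L0) * (2.0 * t1 + 4.0 * t2)
        return L, c, s, N, M1, M2

    def internal_forces(self, u: np.ndarray):
        """Global internal force vector and tangent stiffness at ``u``."""
        ne = self.geometry.n_elements
        L, c, s, N, M1, M2 = self.element_state(u)

        r = np.zeros((ne, 6))
        z = np.zeros((ne, 6))
        r[:, 0] = -c; r[:, 1] = -s; r[:, 3] = c; r[:, 4] = s
        z[:, 0] = s; z[:, 1] = -c; z[:, 3] = -s; z[:, 4] = c
        e3 = np.zeros((ne, 6)); e3[:, 2] = 1.0
        e6 = np.zeros((ne, 6)); e6[:, 5] = 1.0
        zL = z / L[:, None]
        B = np.stack([r, e3 - zL, e6 - zL], axis=1)  # (ne, 3, 6)

        f_local = np.stack([N, M1, M2], axis=1)
        fe = np.einsum("eij,ei->ej", B, f_local)

        kl = np.zeros((ne, 3, 3))
        kl[:, 0, 0] = self.EA / self.L0
        kl[:, 1, 1] = kl[:, 2, 2] = 4.0 * self.EI / self.L0
        kl[:, 1, 2] = kl[:, 2, 1] = 2.0 * self.EI / self.L0
        Ke = np.einsum("eij,eik,ekl->ejl", B, kl, B)
        Ke += (N / L)[:, None, None] * np.einsum("ei,ej->eij", z, z)
        Ke += ((M1 + M2) / L**2)[:, None, None] * (
            np.einsum("ei,ej->eij", r, z) + np.einsum("ei,ej->eij", z, r)
        )

        fint = np.zeros(self.ndof)
        K = np.zeros((self.ndof, self.ndof))
        np.add.at(fint, self.edof, fe)
        for e in range(ne):
            K[self._kix[e]] += Ke[e]
        return fint, K

    def solve_static(self, f_ext: np.ndarray, u0=None, tol=1e-9, max_iter=60):
        """Newton solve of the static problem K(u) = f_ext (free DoFs).

        Raises :class:`StructuralInstabilityError` on a singular tangent;
        this is reported, never regularized away.
        """
        u = np.zeros(self.ndof) if u0 is None else u0.copy()
        scale = max(1.0, float(np.linalg.norm(f_ext)))
        for _ in range(max_iter):
            fint, K = self.internal_forces(u)
            res = fint - f_ext
            if np.linalg.norm(res[self.free]) < tol * scale:
                return u
            Kff = K[np.ix_(self.free, self.free)]
            try:
                du = np.linalg.solve(Kff, -res[self.free])
            except np.linalg.LinAlgError as exc:
                raise StructuralInstabilityError(
                    "singular tangent stiffness during static solve"
                ) from exc
            if not np.all(np.isfinite(du)):
                raise StructuralInstabilityError("non-finite Newton update")
            u[self.free] += du
        raise RuntimeError("static Newton iteration did not converge")


def assemble_tangent(geometry: SpineGeometry, state: PlantState,
                     axial_forces: np.ndarray | None = None) -> np.ndarray:
    """Tangent stiffness of the frame at the given state (free DoFs only).

    ``axial_forces`` optionally overrides the per-element axial force used
    in the geometric terms (otherwise it follows from the displacement
    field).  Symmetric; positive definite only below the buckling load.
    """
    model = BeamModel(geometry)
    u = state.displacements
    if axial_forces is not None:
        # impose the requested axial prestress by shifting reference lengths
        axial = np.asarray(axial_forces, dtype=float)
        model.L0 = model.L0 / (1.0 + axial / model.EA)
    _, K = model.internal_forces(u)
    return K[np.ix_(model.free, model.free)]


def critical_load(geometry: SpineGeometry, unit_load: np.ndarray,
                  f_max: float = 2000.0, tol: float = 1e-3) -> float:
    """Smallest load factor at which the tangent goes singular under the
    given unit load pattern (bisection on the smallest eigenvalue of the
    tangent along the nonlinear equilibrium path)."""
    model = BeamModel(geometry)

    def min_eig(lam: float) -> float:
        try:
            u = model.solve_static(lam * unit_load)
        except (StructuralInstabilityError, RuntimeError):
            return -1.0
        _, K = model.internal_forces(u)
        Kff = K[np.ix_(model.free, model.free)]
        return float(np.linalg.eigvalsh(Kff)[0])

    lo, hi = 0.0, f_max
    if min_eig(hi) > 0.0:
        raise ValueError("load pattern does not buckle below f_max")
    while hi - lo > tol * f_max:
        mid = 0.5 * (lo + hi)
        if min_eig(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def recover_section_loads(geometry: SpineGeometry, state: PlantState,
                          nodal_forces: np.ndarray) -> list[SectionLoads]:
    """Internal section loads at each intervertebral level.

    ``nodal_forces`` is the full vector of external + muscle forces applied
    at the nodes (SI).  For each level the force transmitted across the cut
    is the negated sum over the free body above it, projected onto the local
    deformed chord tangent (compression, positive down the axis) and normal
    (shear, positive toward +Z).  At a converged (quasi-)static state this
    equals the element end force.
    """
    pos = state.node_positions_m(geometry)
    f = nodal_forces.reshape(-1, 3)[:, :2]
    lumbar = geometry.lumbar_nodes
    out = []
    labels = LEVELS if len(lumbar) == 5 else [f"S{i}" for i in range(len(lumbar))]
    for j, node in enumerate(lumbar):
        t = pos[node] - pos[node - 1]
        t = t / np.linalg.norm(t)
        n = np.array([-t[1], t[0]])
        resultant = f[node:].sum(axis=0)
        out.append(SectionLoads(
            level=labels[j],
            compression=float(-(resultant @ t)),
            shear=float(resultant @ n),
        ))
    return out
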