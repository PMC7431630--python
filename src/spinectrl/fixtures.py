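"""Toy models with closed-form expectations, for oracle tests."""

from __future__ import annotations

import numpy as np

from .geometry import SpineGeometry

__all__ = ["make_toy_fixture"]


def make_toy_fixture(kind: str, n_elements: int = 16, L_mm: float = 190.0,
                     EI: float = 1.9, F: float = 1.0):
    """Small model plus its analytic oracle value.

    kinds:
      * ``cantilever`` - straight vertical column, tip lateral load F;
        expectation: tip deflection F L^3 / (3 EI), metres.
      * ``column_buckling`` - straight fixed-free column under axial tip
        load; expectation: Euler load pi^2 EI / (4 L^2), newtons.
      * ``single_muscle`` - one node held by one inclined muscle against a
        lateral load W; expectation: required tension W / sin(phi).
    """
    if kind in ("cantilever", "column_buckling"):
        x = np.linspace(0.0, L_mm, n_elements + 1)
        coords = np.stack([x, np.zeros_like(x)], axis=1)
        geom = SpineGeometry(node_coords_mm=coords, EI=EI)
        L = L_mm * 1e-3
        if kind == "cantilever":
            load = np.zeros(3 * geom.n_nodes)
            load[3 * (geom.n_nodes - 1) + 1] = F     # +Z at the tip
            expect = F * L**3 / (3.0 * EI)
            return geom, load, expect
        load = np.zeros(3 * geom.n_nodes)
        load[3 * (geom.n_nodes - 1)] = -1.0          # unit axial, -X
        expect = np.pi**2 * EI / (4.0 * L**2)
        return geom, load, expect
    if kind == "single_muscle":
        W = F
        phi = np.deg2rad(30.0)
        expect = W / np.sin(phi)
        return dict(W=W, phi=phi), None, expect
    raise ValueError(f"unknown fixture kind {kind!r}")
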