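"""YAML run-configuration parsing.

Schema (all blocks optional; defaults reproduce the reference setup)::

    geometry:
      nodes_mm: [[38, 0.4], [80, 1.7], [105, 3.0], [150, 6.2], [190, 10.0]]
      EI: 1.9            # N m^2
      area_mm2: 1225
    muscles:
      f_max: 800         # N
      passive: slack     # slack | eq | none
    controller:
      h1: 2.0
      h2: 2.0
      h3: 2.0
      k_alpha: 0.2
      k_e: {L1: 15, L2: 7, L3: 2.5, L4: 1, L5: 0.1}
      eta: 0.3           # 1/s
      grid: 7
      windup: 50         # mm s
    simulation:
      dt: 0.001
      t_end: 25
      nodal_mass: 0.1
      rayleigh_beta: 1.0
    loads:
      P: [350, 50, 50, 50, 50]   # N at L1..L5
      D_mm: 50
      ramp_time: 0.2
"""

from __future__ import annotations

import yaml

from .controller import ControllerGains
from .geometry import SpineGeometry, build_geometry
from .simulator import LoadingCase, SimulationConfig

__all__ = ["load_config", "parse_config"]


def parse_config(doc: dict):
    """Turn a configuration mapping into (geometry, case, sim_config)."""
    doc = dict(doc or {})
    geometry = build_geometry(doc.get("geometry") or {})

    ctrl = dict(doc.get("controller") or {})
    gains = ControllerGains(
        h1=float(ctrl.get("h1", 2.0)),
        h2=float(ctrl.get("h2", 2.0)),
        h3=float(ctrl.get("h3", 2.0)),
        k_alpha=float(ctrl.get("k_alpha", 0.2)),
        k_e={str(k): float(v) for k, v in (ctrl.get("k_e") or
             {"L1": 15, "L2": 7, "L3": 2.5, "L4": 1, "L5": 0.1}).items()},
        eta=float(ctrl.get("eta", 0.3)),
        grid=int(ctrl.get("grid", 7)),
        windup=float(ctrl.get("windup", 50.0)),
    )

    mus = dict(doc.get("muscles") or {})
    sim = dict(doc.get("simulation") or {})
    config = SimulationConfig(
        dt=float(sim.get("dt", 1e-3)),
        t_end=float(sim.get("t_end", 25.0)),
        nodal_mass=float(sim.get("nodal_mass", 0.1)),
        rotary_inertia=float(sim.get("rotary_inertia", 1e-4)),
        rayleigh_beta=float(sim.get("rayleigh_beta", 1.0)),
        controller=bool(sim.get("controller", True)),
        passive=str(mus.get("passive", "slack")),
        f_max=float(mus.get("f_max", 800.0)),
        gains=gains,
    )

    loads = dict(doc.get("loads") or {})
    case = LoadingCase(
        P=tuple(loads.get("P", (350, 50, 50, 50, 50))),
        D_mm=float(loads.get("D_mm", 50.0)),
        ramp_time=float(loads.get("ramp_time", 0.2)),
        name=str(loads.get("name", "custom")),
    )
    return geometry, case, config


def load_config(path: str):
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return parse_config(doc)
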