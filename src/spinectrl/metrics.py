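"""Follower-load angle metric and report writers.

All CSV writers emit floats with 17 significant digits so written values
re-parse to the in-memory doubles exactly."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SectionLoads

__all__ = ["FollowerLoadAngle", "follower_load_angle", "write_summary",
           "write_timeseries"]


@dataclass
class FollowerLoadAngle:
    """Absolute angle (degrees) between the resultant internal force and
    the local spine tangent - the hypothetical follower-load direction -
    per level, plus the maximum over levels."""

    levels: list
    per_level: np.ndarray

    @property
    def max_angle(self) -> float:
        return float(self.per_level.max())


def follower_load_angle(section_loads: list[SectionLoads]) -> FollowerLoadAngle:
    """Angle = atan2(|shear|, compression) per level, in degrees.

    The angle is defined in the local deformed frame, so it is invariant
    under rigid rotation of the whole model.  A vanishing resultant has no
    direction and is flagged as an error.
    """
    levels, angles = [], []
    for s in section_loads:
        if np.hypot(s.compression, s.shear) <= 0.0:
            raise ValueError(f"zero resultant force at {s.level}: angle undefined")
        levels.append(s.level)
        angles.append(np.degrees(np.arctan2(abs(s.shear), s.compression)))
    return FollowerLoadAngle(levels=levels, per_level=np.array(angles))


def _section_table(results: dict) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        for s in res.section_loads:
            rows.append(dict(case=name, level=s.level,
                             compression_N=s.compression, shear_N=s.shear,
                             fl_angle_deg=s.follower_angle_deg))
    return pd.DataFrame(rows)


def _force_table(results: dict) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        steady = res.steady_muscle_forces()
        alphas = res.steady_alphas()
        for m in range(len(steady)):
            rows.append(dict(case=name, level=str(res.muscle_levels[m]),
                             side=int(res.muscle_sides[m]),
                             force_N=steady[m], activation=alphas[m]))
    return pd.DataFrame(rows)


def write_summary(results: dict, out_dir: str, sweep: dict | None = None) -> dict:
    """Write the summary CSV tables for a set of converged runs.

    ``results`` maps case names to SimulationResult.  Files written:
    section_loads.csv (level-wise compression/shear), muscle_forces.csv
    (steady forces and activations), fl_angles.csv, and, when a sweep is
    given, sweep.csv with the per-muscle linear fits.  Returns the paths.
    """
    if not results:
        raise ValueError("no results to summarise")
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    df = _section_table(results)
    paths["section_loads"] = os.path.join(out_dir, "section_loads.csv")
    df.to_csv(paths["section_loads"], index=False, float_format="%.17g")

    df = _force_table(results)
    paths["muscle_forces"] = os.path.join(out_dir, "muscle_forces.csv")
    df.to_csv(paths["muscle_forces"], index=False, float_format="%.17g")

    rows = []
    for name, res in results.items():
        fla = follower_load_angle(res.section_loads)
        for lev, ang in zip(fla.levels, fla.per_level):
            rows.append(dict(case=name, level=lev, fl_angle_deg=ang))
        rows.append(dict(case=name, level="max", fl_angle_deg=fla.max_angle))
    paths["fl_angles"] = os.path.join(out_dir, "fl_angles.csv")
    pd.DataFrame(rows).to_csv(paths["fl_angles"], index=False, float_format="%.17g")

    if sweep is not None:
        rows = []
        for i, p1 in enumerate(sweep["loads"]):
            for m in range(sweep["forces"].shape[1]):
                rows.append(dict(L1_load_N=p1, muscle=m,
                                 force_N=sweep["forces"][i, m],
                                 converged=sweep["converged"][i]))
        df = pd.DataFrame(rows)
        fits = pd.DataFrame(sweep["fits"])
        fits.insert(0, "muscle", np.arange(len(sweep["fits"])))
        paths["sweep"] = os.path.join(out_dir, "sweep.csv")
        df.to_csv(paths["sweep"], index=False, float_format="%.17g")
        paths["sweep_fits"] = os.path.join(out_dir, "sweep_fits.csv")
        fits.to_csv(paths["sweep_fits"], index=False, float_format="%.17g")

    report = os.path.join(out_dir, "report.txt")
    with open(report, "w") as fh:
        for name, res in results.items():
            fh.write(f"{name}: converged={res.converged} "
                     f"t_conv={res.t_converged:.2f}s "
                     f"max_err={res.max_tracking_error_mm:.3f}mm "
                     f"steady_err={res.steady_pos_err_mm():.4f}mm\n")
    paths["report"] = report
    return paths


def write_timeseries(result, path: str, every: int = 1) -> str:
    """Full run history as CSV: one row per step (time, lumbar Z
    coordinates, activations, muscle forces)."""
    cols = {"time_s": result.time[::every]}
    for j in range(result.z_lumbar_mm.shape[1]):
        cols[f"z{j}_mm"] = result.z_lumbar_mm[::every, j]
    for m in range(result.alphas.shape[1]):
        tag = f"{result.muscle_levels[m]}{'+' if result.muscle_sides[m] > 0 else '-'}"
        cols[f"alpha_{tag}"] = result.alphas[::every, m]
        cols[f"force_{tag}_N"] = result.muscle_forces[::every, m]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path
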