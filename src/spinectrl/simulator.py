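"""Time-domain driver for the coupled plant-muscle-controller system.

External loads ramp linearly over ``ramp_time`` and are then held; the
plant is integrated implicitly (Newmark average acceleration with Newton
iteration per step) with the muscle forces and their consistent stiffness
and force-velocity damping inside the iteration matrix; the controllers
sample the lateral errors and update their weights once per step.

The loading is quasi-static: inertia and damping only regularise the
transient.  Small surrogate nodal masses and heavy stiffness-proportional
damping put the system in an overdamped creep regime in which the
supercritically compressed column moves slowly enough for the adaptive
controllers to remain stable; the steady state is verified insensitive to
both surrogates (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actuators import MuscleSet
from .beam import BeamModel, recover_section_loads
from .controller import ControllerGains, FuzzyController, KE_DEFAULT, assign_jacobian_signs
from .geometry import PlantState, SectionLoads, SpineGeometry, build_geometry

__all__ = ["LoadingCase", "STUDY_CASES", "SimulationConfig", "SimulationResult",
           "run_case", "run_load_sweep", "run_perturbation", "detect_steady_state"]


@dataclass
class LoadingCase:
    """Vertical nodal loads P1..P5 (N, acting -X at L1..L5) and the lateral
    muscle-origin offset D (mm)."""

    P: tuple
    D_mm: float
    ramp_time: float = 0.2
    name: str = ""

    def __post_init__(self):
        self.P = tuple(float(p) for p in self.P)
        if any(p < 0 for p in self.P):
            raise ValueError("loads must be nonnegative")
        if self.D_mm <= 0:
            raise ValueError("muscle offset D must be positive")


#: the five built-in study loading cases (P1..P5 in N, D in mm)
STUDY_CASES = {
    1: LoadingCase((635, 0, 0, 0, 0), 50.0, name="case1"),
    2: LoadingCase((350, 50, 50, 50, 50), 50.0, name="case2"),
    3: LoadingCase((110, 110, 110, 110, 110), 50.0, name="case3"),
    4: LoadingCase((110, 110, 110, 110, 110), 25.0, name="case4"),
    5: LoadingCase((110, 110, 110, 110, 110), 75.0, name="case5"),
}


@dataclass
class SimulationConfig:
    dt: float = 1e-3                 # s
    t_end: float = 25.0              # s
    nodal_mass: float = 0.1          # kg per free node (transient surrogate)
    rotary_inertia: float = 1e-4     # kg m^2 per free node
    rayleigh_beta: float = 1.0       # s, stiffness-proportional damping
    steady_tol_pos: float = 0.2      # mm
    steady_tol_vel: float = 1.0      # mm/s
    steady_window: float = 1.0       # s
    controller: bool = True
    passive: str = "slack"           # plant passive-muscle convention
    f_max: float = 800.0
    divergence_mm: float = 50.0
    pulse_rise: float = 0.05         # s, rise/fall time of load pulses
    newton_tol: float = 1e-7
    newton_max_iter: int = 25
    gains: ControllerGains = field(default_factory=ControllerGains)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")


@dataclass
class SimulationResult:
    """Histories plus the steady-state snapshot of one run."""

    case: LoadingCase
    config: SimulationConfig
    time: np.ndarray                  # (n_steps,)
    z_lumbar_mm: np.ndarray           # (n_steps, n_levels) lateral positions
    z_target_mm: np.ndarray           # (n_levels,)
    alphas: np.ndarray                # (n_steps, n_muscles)
    muscle_forces: np.ndarray         # (n_steps, n_muscles) N
    pos_err_mm: np.ndarray            # (n_steps,) max |Z - Z_target|
    vel_mms: np.ndarray               # (n_steps,) max lateral speed
    muscle_levels: np.ndarray         # per-muscle level labels
    muscle_sides: np.ndarray          # per-muscle side (-1 / +1)
    state: PlantState                 # final state
    section_loads: list = None        # type: ignore[assignment]
    stationarity: np.ndarray = None   # type: ignore[assignment]
    converged: bool = False
    t_converged: float = float("nan")
    unstable: bool = False

    @property
    def max_tracking_error_mm(self) -> float:
        return float(self.pos_err_mm.max()) if len(self.pos_err_mm) else float("nan")

    def steady_pos_err_mm(self, after: float = 20.0) -> float:
        mask = self.time >= after
        if not mask.any():
            mask = self.time >= self.time[-1] - 1.0
        return float(self.pos_err_mm[mask].max())

    def steady_muscle_forces(self) -> np.ndarray:
        """Muscle forces averaged over the final steady window."""
        window = self.config.steady_window
        mask = self.time >= self.time[-1] - window
        return self.muscle_forces[mask].mean(axis=0)

    def steady_alphas(self) -> np.ndarray:
        window = self.config.steady_window
        mask = self.time >= self.time[-1] - window
        return self.alphas[mask].mean(axis=0)


def detect_steady_state(time: np.ndarray, pos_err_mm: np.ndarray,
                        vel_mms: np.ndarray, tol_pos: float, tol_vel: float,
                        window: float, ramp_time: float = 0.2):
    """Earliest time after the load ramp at which both tolerances hold
    continuously for ``window`` seconds.  Returns (converged, t_conv)."""
    if len(time) < 2:
        return False, float("nan")
    dt = time[1] - time[0]
    need = max(1, int(round(window / dt)))
    ok = (pos_err_mm <= tol_pos) & (vel_mms <= tol_vel) & (time > ramp_time)
    run = 0
    for i, good in enumerate(ok):
        run = run + 1 if good else 0
        if run >= need:
            return True, float(time[i])
    return False, float("nan")


class _CoupledSystem:
    """Assembled plant + muscles + controllers for one loading case."""

    def __init__(self, case: LoadingCase, config: SimulationConfig,
                 geometry: SpineGeometry | None = None):
        self.case = case
        self.config = config
        self.geometry = geometry if geometry is not None else build_geometry()
        self.model = BeamModel(self.geometry)
        self.muscles = MuscleSet(self.geometry, case.D_mm,
                                 f_max=config.f_max, passive=config.passive)
        signs = assign_jacobian_signs(self.muscles, self.geometry)
        nlev = len(self.geometry.lumbar_nodes)
        ke_map = config.gains.k_e if config.gains.k_e else KE_DEFAULT
        self.controllers = []
        for i in range(self.muscles.n):
            label = str(self.muscles.levels[i])
            ke = ke_map.get(label, list(ke_map.values())[-1])
            self.controllers.append(FuzzyController(ke, int(signs[i]), config.gains))
        # external load pattern: P1..P5 at L1..L5, i.e. reversed lumbar order
        ndof = self.model.ndof
        self.load_pattern = np.zeros(ndof)
        lumbar = self.geometry.lumbar_nodes
        for k, p in enumerate(case.P[:nlev]):
            self.load_pattern[3 * lumbar[nlev - 1 - k]] -= p
        # lumped mass and constant Rayleigh damping from the initial tangent
        self.M = np.zeros(ndof)
        for i in range(1, self.geometry.n_nodes):
            self.M[3 * i] = self.M[3 * i + 1] = config.nodal_mass
            self.M[3 * i + 2] = config.rotary_inertia
        _, K0 = self.model.internal_forces(np.zeros(ndof))
        self.C0 = config.rayleigh_beta * K0

    def external_load(self, t: float, extra_P1: float = 0.0) -> np.ndarray:
        f = self.load_pattern * min(t / self.case.ramp_time, 1.0)
        if extra_P1:
            top = self.geometry.lumbar_nodes[-1]
            f = f.copy()
            f[3 * top] -= extra_P1
        return f


def _integrate(system: _CoupledSystem, pulses=None) -> SimulationResult:
    cfg = system.config
    case = system.case
    model = system.model
    muscles = system.muscles
    free = model.free
    ndof = model.ndof
    lumbar = system.geometry.lumbar_nodes
    z_ref_mm = system.geometry.node_coords_mm[lumbar, 1]

    dt = cfg.dt
    nsteps = int(round(cfg.t_end / dt))
    u = np.zeros(ndof)
    v = np.zeros(ndof)
    a = np.zeros(ndof)
    alphas = np.zeros(muscles.n)

    time = np.empty(nsteps)
    z_hist = np.empty((nsteps, len(lumbar)))
    a_hist = np.empty((nsteps, muscles.n))
    f_hist = np.empty((nsteps, muscles.n))
    perr = np.empty(nsteps)
    verr = np.empty(nsteps)

    gamma, beta = 0.5, 0.25
    diverged = False
    n_done = 0

    for step in range(nsteps):
        t = (step + 1) * dt
        extra = 0.0
        if pulses:
            rise = max(cfg.pulse_rise, dt)
            for (t0, t1, dp) in pulses:
                # trapezoidal pulse: a load cannot change instantaneously
                if t0 <= t < t1:
                    extra += dp * min(1.0, (t - t0) / rise)
                elif t1 <= t < t1 + rise:
                    extra += dp * (1.0 - (t - t1) / rise)
        f_ext = system.external_load(t, extra)

        if cfg.controller:
            for mi, ctrl in enumerate(system.controllers):
                node = muscles.node[mi]
                e_mm = -u[3 * node + 1] * 1e3
                edot_mms = -v[3 * node + 1] * 1e3
                alphas[mi] = ctrl.step(e_mm, edot_mms, dt)

        converged_step = False
        for attempt, sub in ((0, 1), (1, 2), (2, 4)):  # step halving fallback
            h = dt / sub
            uu, vv, aa = u.copy(), v.copy(), a.copy()
            ok = True
            for _ in range(sub):
                up = uu + h * vv + h * h * (0.5 - beta) * aa
                vp = vv + h * (1 - gamma) * aa
                unew = uu.copy()
                scale = max(1.0, float(np.linalg.norm(f_ext)))
                for _it in range(cfg.newton_max_iter):
                    anew = (unew - up) / (beta * h * h)
                    vnew = vp + gamma * h * anew
                    fint, K = model.internal_forces(unew)
                    fm = np.zeros(ndof)
                    Km = np.zeros((ndof, ndof))
                    Cm = np.zeros((ndof, ndof))
                    F = muscles.add_system_contributions(unew, vnew, alphas, fm, Km, Cm)
                    res = system.M * anew + system.C0 @ vnew + fint - f_ext - fm
                    if np.linalg.norm(res[free]) < cfg.newton_tol * scale:
                        break
                    K_eff = (np.diag(system.M / (beta * h * h))
                             + (system.C0 + Cm) * (gamma / (beta * h))
                             + K + Km)
                    try:
                        du = np.linalg.solve(K_eff[np.ix_(free, free)], -res[free])
                    except np.linalg.LinAlgError:
                        ok = False
                        break
                    unew[free] += du
                    if not np.all(np.isfinite(unew)):
                        ok = False
                        break
                else:
                    ok = False
                if not ok:
                    break
                aa = (unew - up) / (beta * h * h)
                vv = vp + gamma * h * aa
                uu = unew
            if ok:
                u, v, a = uu, vv, aa
                converged_step = True
                break
        if not converged_step:
            diverged = True
        else:
            F, unit, _, _, _ = muscles.forces(u, v, alphas)
            time[step] = t
            z_hist[step] = z_ref_mm + u[3 * lumbar + 1] * 1e3
            a_hist[step] = alphas
            f_hist[step] = F
            perr[step] = np.abs(u[3 * lumbar + 1]).max() * 1e3
            verr[step] = np.abs(v[1::3]).max() * 1e3
            n_done = step + 1
            if (not np.all(np.isfinite(u))
                    or np.abs(u[1::3]).max() * 1e3 > cfg.divergence_mm):
                diverged = True
        if diverged:
            break

    sl = time[:n_done], z_hist[:n_done], a_hist[:n_done], f_hist[:n_done], \
        perr[:n_done], verr[:n_done]
    time, z_hist, a_hist, f_hist, perr, verr = sl

    state = PlantState(u, v, float(time[-1]) if n_done else 0.0)
    result = SimulationResult(
        case=case, config=cfg, time=time, z_lumbar_mm=z_hist,
        z_target_mm=z_ref_mm.copy(), alphas=a_hist, muscle_forces=f_hist,
        pos_err_mm=perr, vel_mms=verr,
        muscle_levels=muscles.levels.copy(), muscle_sides=muscles.side.copy(),
        state=state, unstable=diverged,
    )
    if diverged:
        return result

    result.converged, result.t_converged = detect_steady_state(
        time, perr, verr, cfg.steady_tol_pos, cfg.steady_tol_vel,
        cfg.steady_window, case.ramp_time)
    f_nodal = system.external_load(float(time[-1]))
    f_nodal = f_nodal + muscles.nodal_forces(u, v, alphas, ndof)
    result.section_loads = recover_section_loads(system.geometry, state, f_nodal)
    result.stationarity = np.array(
        [c.stationarity_residual() for c in system.controllers])
    return result


def run_case(case: LoadingCase | int, config: SimulationConfig | None = None,
             geometry: SpineGeometry | None = None) -> SimulationResult:
    """Integrate one loading case to its horizon and return the histories
    and steady-state snapshot.  ``case`` may be a built-in case number."""
    if isinstance(case, int):
        case = STUDY_CASES[case]
    config = config or SimulationConfig()
    system = _CoupledSystem(case, config, geometry)
    return _integrate(system)


def run_perturbation(case: LoadingCase | int, pulses,
                     config: SimulationConfig | None = None) -> SimulationResult:
    """Run a case with load pulses (t_start, t_end, dP at L1) superimposed
    on the held case load; the controllers stay active.  Pulse edges ramp
    over ``config.pulse_rise`` seconds (a physical load cannot step in zero
    time, and the learning loop has no reflex pathway to absorb a true
    discontinuity)."""
    if isinstance(case, int):
        case = STUDY_CASES[case]
    config = config or SimulationConfig()
    for (t0, t1, _dp) in pulses:
        if not (0.0 <= t0 < t1):
            raise ValueError("pulse interval must satisfy 0 <= t0 < t1")
        if t1 > config.t_end:
            raise ValueError("pulse extends beyond the simulation horizon")
    system = _CoupledSystem(case, config)
    return _integrate(system, pulses=list(pulses))


def run_load_sweep(base_case: LoadingCase | int, L1_loads,
                   config: SimulationConfig | None = None) -> dict:
    """One converged run per L1 load value (other loads from the base case).

    Returns a table with per-load steady muscle forces and linear fits
    (slope, intercept, R^2) of force versus L1 load: one fit per muscle,
    and one per level on the signed level force (active-side force with the
    side encoded in the sign, matching the equilibrium solver's signed
    intensities - the physically continuous variable when the demanded
    lateral force at a level crosses zero inside the sweep range).  A sweep
    of length one cannot be fitted and is flagged degenerate.
    """
    if isinstance(base_case, int):
        base_case = STUDY_CASES[base_case]
    L1_loads = [float(p) for p in L1_loads]
    if any(p < 0 or p > 1000 for p in L1_loads):
        raise ValueError("sweep loads must lie in [0, 1000] N")
    config = config or SimulationConfig()
    results = {}
    forces = []
    flags = []
    for p1 in L1_loads:
        case = LoadingCase((p1,) + base_case.P[1:], base_case.D_mm,
                           base_case.ramp_time, name=f"L1={p1:g}N")
        res = run_case(case, config)
        results[p1] = res
        flags.append(bool(res.converged and not res.unstable))
        forces.append(res.steady_muscle_forces() if not res.unstable
                      else np.full(10, np.nan))
    forces = np.array(forces)
    degenerate = len(L1_loads) < 2

    def fit_column(y):
        good = np.isfinite(y)
        if degenerate or good.sum() < 2:
            return dict(slope=np.nan, intercept=np.nan, r2=np.nan,
                        degenerate=True)
        x = np.asarray(L1_loads)[good]
        yy = y[good]
        slope, intercept = np.polyfit(x, yy, 1)
        resid = yy - (slope * x + intercept)
        ss_tot = float(((yy - yy.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
        return dict(slope=float(slope), intercept=float(intercept),
                    r2=float(r2), degenerate=False)

    fits = [fit_column(forces[:, m]) for m in range(forces.shape[1])]
    # signed level force: F(+side) - F(-side); muscles are stored pairwise
    nlev = forces.shape[1] // 2
    level_forces = forces[:, 1::2] - forces[:, 0::2]
    level_fits = [fit_column(level_forces[:, k]) for k in range(nlev)]
    return dict(loads=L1_loads, results=results, forces=forces,
                level_forces=level_forces, converged=flags, fits=fits,
                level_fits=level_fits)
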