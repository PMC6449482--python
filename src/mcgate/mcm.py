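"""Monte Carlo minimization (MCM) in generalized coordinates.

One MCM cycle perturbs a single randomly chosen flexible coordinate, locally
minimizes the total energy (nonbonded + restraints) with a bounded
quasi-Newton minimizer, and accepts or rejects the minimized point by the
Metropolis criterion against the current point's minimized energy.  A
trajectory terminates when a window of consecutive minimizations fails to
improve the lowest energy found (default window 2000).

The steered driver walks restraint anchors linearly from start to target
positions over a number of stages; during steering each minimization is
capped (default 100 iterations) so consecutive accepted points stay close,
and after the final stage the trajectory runs to the convergence window,
followed by an unconstrained stability run whose C-alpha drift is reported.

Gradients with respect to torsions are analytic (force projection on the
rotation axis); root orientations use matrix-level finite differences of the
Euler rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .energy import NonbondedOptions, nonbonded_energy_forces
from .geometry import euler_to_matrix
from .restraints import PinRestraint, RestraintSet, restraint_energy

KB = 0.0019872041  # kcal/mol/K

__all__ = ["MCMConfig", "MCMTrajectory", "SteerSchedule", "EnergyModel",
           "TorsionPotentialTerm", "local_minimize", "propose_move",
           "run_mcm", "run_steered", "window_converged"]


@dataclass(frozen=True)
class MCMConfig:
    temperature: float = 600.0          # K (Metropolis)
    max_min_iterations: int = 1000      # minimizer iterations per cycle
    steered_min_iterations: int = 100   # cap during steering
    convergence_window: int = 2000      # consecutive cycles w/o new lowest
    max_minimizations: int = 100000     # hard safety cap per trajectory
    rng_seed: int = 0
    # steering protocol
    n_stages: int = 10
    stage_accepts: int = 50             # accepted points per stage
    stage_proposals: int = 500          # proposal cap per stage
    # move amplitudes per coordinate class
    root_pos_sigma: float = 0.5         # Angstrom
    root_euler_sigma: float = 10.0      # degrees
    angle_sigma: float = 5.0            # degrees

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for f in ("convergence_window", "max_minimizations", "n_stages",
                  "stage_accepts", "stage_proposals"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class MCMTrajectory:
    accepted: list = field(default_factory=list)   # (vector, energy)
    lowest: tuple | None = None
    n_minimizations: int = 0
    converged: bool = False
    rng_seed: int | None = None
    log: list = field(default_factory=list)        # JSONL-able records

    @property
    def lowest_energy(self):
        return self.lowest[1] if self.lowest else None


@dataclass
class SteerSchedule:
    targeted_atoms: list                 # [(seg_id, resnum, atom_name), ...]
    start_anchors: np.ndarray            # (n, 3)
    end_anchors: np.ndarray              # (n, 3)
    n_stages: int = 10
    half_width: float = 1.0              # per-stage pin half-width, Angstrom
    force_k: float = 10.0
    companion: RestraintSet = field(default_factory=RestraintSet)

    def __post_init__(self):
        self.start_anchors = np.asarray(self.start_anchors, dtype=float)
        self.end_anchors = np.asarray(self.end_anchors, dtype=float)
        if not (len(self.targeted_atoms) == len(self.start_anchors)
                == len(self.end_anchors)):
            raise ValueError("anchor arrays must match targeted atoms")

    def anchors_at(self, fraction: float) -> np.ndarray:
        return (self.start_anchors
                + fraction * (self.end_anchors - self.start_anchors))

    def stage_pins(self, fraction: float) -> list[PinRestraint]:
        anchors = self.anchors_at(fraction)
        return [PinRestraint(loc, anchors[i], self.half_width, self.force_k)
                for i, loc in enumerate(self.targeted_atoms)]


class TorsionPotentialTerm:
    """Optional intrinsic torsion potential sum_k a_k cos(k theta + phase)."""

    def __init__(self, torsion, terms):
        self.torsion = tuple(torsion)           # (seg_id, resnum, name)
        self.terms = [(float(a), int(n), np.radians(ph))
                      for a, n, ph in terms]

    def energy_grad(self, system):
        vi = system.var_index(*self.torsion)
        th = system.torsion_values[vi]
        e = sum(a * np.cos(n * th + ph) for a, n, ph in self.terms)
        g = sum(-a * n * np.sin(n * th + ph) for a, n, ph in self.terms)
        return float(e), {vi: float(g)}


class EnergyModel:
    """Total-energy objective over a system's flexible coordinates."""

    def __init__(self, system, nb_options: NonbondedOptions | None = None,
                 restraints: RestraintSet | None = None, extra_terms=(),
                 active_residues=None, include_nonbonded: bool = True):
        self.system = system
        self.nb = nb_options or NonbondedOptions()
        self.restraints = restraints or RestraintSet()
        self.extra_terms = list(extra_terms)
        self.active_residues = active_residues
        self.include_nonbonded = include_nonbonded

    def with_restraints(self, restraints) -> "EnergyModel":
        return EnergyModel(self.system, self.nb, restraints,
                           self.extra_terms, self.active_residues,
                           self.include_nonbonded)

    # ---------------------------------------------------------------- energy
    def energy(self, x=None) -> float:
        if x is not None:
            self.system.set_vector(x)
        else:
            self.system.rebuild()
        e = 0.0
        if self.include_nonbonded:
            e_nb, _ = nonbonded_energy_forces(self.system, self.nb,
                                              self.active_residues)
            e += e_nb
        e_r, _ = restraint_energy(self.system, self.restraints)
        e += e_r
        for term in self.extra_terms:
            et, _ = term.energy_grad(self.system)
            e += et
        return e

    def energy_grad(self, x=None):
        """Energy and gradient with respect to the flexible vector."""
        sys = self.system
        if x is not None:
            sys.set_vector(x)
        else:
            sys.rebuild()
        X = sys.cartesian
        gx = np.zeros_like(X)
        e = 0.0
        if self.include_nonbonded:
            e_nb, g_nb = nonbonded_energy_forces(sys, self.nb,
                                                 self.active_residues)
            e += e_nb
            gx += g_nb
        e_r, _, g_r, tg = restraint_energy(sys, self.restraints,
                                           with_gradient=True)
        e += e_r
        gx += g_r
        tgrad = dict(tg)
        for term in self.extra_terms:
            et, tgt = term.energy_grad(sys)
            e += et
            for vi, g in tgt.items():
                tgrad[vi] = tgrad.get(vi, 0.0) + g

        t_idx, a_idx, r_idx = sys.coordinate_layout()
        grad = np.zeros(len(t_idx) + len(a_idx) + 6 * len(r_idx))
        # torsions: force projection on the rotation axis
        for k, vi in enumerate(t_idx):
            v = sys.torsion_vars[vi]
            g = tgrad.get(vi, 0.0)
            if v.axis is not None:
                a2, a3 = v.axis
                u = X[a3] - X[a2]
                nu = np.linalg.norm(u)
                if nu > 1e-12:
                    u = u / nu
                    down = sys.torsion_downstream[vi]
                    if len(down):
                        rel = X[down] - X[a3]
                        g += float(np.einsum(
                            "ij,ij->", gx[down], np.cross(u, rel)))
            grad[k] = g
        off = len(t_idx)
        # flexible bond angles
        for k, ci in enumerate(a_idx):
            entry = sys.entries[sys.angle_var_entries[ci]]
            a2, a3 = entry.refs[1], entry.refs[2]
            child = entry.atom
            nvec = np.cross(X[a2] - X[a3], X[child] - X[a3])
            nn = np.linalg.norm(nvec)
            g = 0.0
            if nn > 1e-12:
                nvec = nvec / nn
                down = sys.angle_downstream[ci]
                rel = X[down] - X[a3]
                g = float(np.einsum("ij,ij->", gx[down],
                                    np.cross(nvec, rel)))
            grad[off + k] = g
        off += len(a_idx)
        # roots: translation is exact; orientation via matrix differences
        for si in r_idx:
            seg = sys.segments[si]
            gseg = gx[seg.atom_slice]
            grad[off:off + 3] = gseg.sum(axis=0)
            local = sys._canon[si]
            e0 = sys.root_orientations[si]
            h = 1e-6
            for k in range(3):
                ep = e0.copy()
                ep[k] += h
                em = e0.copy()
                em[k] -= h
                dR = (euler_to_matrix(ep) - euler_to_matrix(em)) / (2 * h)
                grad[off + 3 + k] = float(np.einsum(
                    "ij,ij->", gseg, local @ dR.T))
            off += 6
        return e, grad


def local_minimize(model: EnergyModel, x0=None, max_iter: int = 1000,
                   gtol: float = 1e-4):
    """Bounded local minimization over the flexible coordinates.

    Returns ``(x, energy)``; the result never has higher energy than the
    start.  ``max_iter == 0`` returns the input unchanged.
    """
    sys = model.system
    if sys.n_flexible == 0:
        raise ValueError("system has no flexible coordinates")
    if x0 is None:
        x0 = sys.get_vector()
    x0 = np.asarray(x0, dtype=float)
    e0 = model.energy(x0)
    if not np.isfinite(e0):
        bad = _offending_pairs(model)
        raise ValueError(f"non-finite starting energy; worst pairs: {bad}")
    if max_iter == 0:
        return x0.copy(), e0

    def fun(x):
        e, g = model.energy_grad(x)
        return e, g

    res = scipy_minimize(fun, x0, jac=True, method="L-BFGS-B",
                         options={"maxiter": max_iter, "gtol": gtol,
                                  "maxcor": 20})
    if np.isfinite(res.fun) and res.fun < e0:
        x, e = res.x, float(res.fun)
    else:
        x, e = x0.copy(), e0
    model.system.set_vector(x)
    return x, e


def _offending_pairs(model, n_report=3):
    from .energy import nonbonded_energy
    try:
        bd = nonbonded_energy(model.system, model.nb,
                              active_residues=model.active_residues)
    except ValueError as exc:
        return str(exc)
    worst = sorted(bd.per_pair.items(),
                   key=lambda kv: -abs(kv[1]["E_total"]))[:n_report]
    return [(k, round(v["E_total"], 2)) for k, v in worst]


def propose_move(system, rng: np.random.Generator,
                 config: MCMConfig = MCMConfig(), x=None) -> np.ndarray:
    """Perturb one randomly selected flexible coordinate.

    Torsions are resampled uniformly in (-180, 180]; root positions receive
    Gaussian steps (sigma 0.5 A), root Euler angles Gaussian steps (sigma
    10 deg), flexible bond angles Gaussian steps (sigma 5 deg).
    """
    if x is None:
        x = system.get_vector()
    x = np.array(x, dtype=float)
    classes = system.coordinate_classes()
    if not classes:
        raise ValueError("system has no flexible coordinates")
    k = int(rng.integers(len(classes)))
    cls = classes[k]
    if cls == "torsion":
        x[k] = rng.uniform(-np.pi, np.pi)
    elif cls == "angle":
        x[k] += rng.normal(0.0, np.radians(config.angle_sigma))
    elif cls == "root_pos":
        x[k] += rng.normal(0.0, config.root_pos_sigma)
    else:  # root_euler
        x[k] += rng.normal(0.0, np.radians(config.root_euler_sigma))
    return x


def window_converged(energies, window: int) -> bool:
    """Convergence rule on an injected sequence of minimized energies.

    The first energy establishes the running lowest; the trajectory is
    converged when the trailing `window` minimizations produced no new
    lowest energy.
    """
    if len(energies) < 1:
        return False
    lowest = energies[0]
    since = 0
    for e in energies[1:]:
        if e < lowest:
            lowest = e
            since = 0
        else:
            since += 1
    return since >= window


def run_mcm(system_or_model, restraints: RestraintSet | None = None,
            config: MCMConfig = MCMConfig(), rng=None,
            min_iterations=None) -> MCMTrajectory:
    """Run one MCM trajectory to the windowed convergence rule.

    Accepts either a :class:`EnergyModel` or a system (then `restraints`
    and default nonbonded options apply).  Fully reproducible for a fixed
    ``config.rng_seed``.
    """
    model = (system_or_model if isinstance(system_or_model, EnergyModel)
             else EnergyModel(system_or_model, restraints=restraints))
    rng = rng or np.random.default_rng(config.rng_seed)
    cap = (min_iterations if min_iterations is not None
           else config.max_min_iterations)
    traj = MCMTrajectory(rng_seed=config.rng_seed)
    x, e = local_minimize(model, max_iter=cap)
    traj.accepted.append((x.copy(), e))
    traj.lowest = (x.copy(), e)
    x_cur, e_cur = x, e
    since_improve = 0
    kT = KB * config.temperature
    while (not traj.converged
           and traj.n_minimizations < config.max_minimizations):
        x_prop = propose_move(model.system, rng, config, x_cur)
        x_new, e_new = local_minimize(model, x0=x_prop, max_iter=cap)
        traj.n_minimizations += 1
        if e_new < traj.lowest[1]:
            traj.lowest = (x_new.copy(), e_new)
            since_improve = 0
        else:
            since_improve += 1
        accept = (e_new <= e_cur
                  or rng.random() < np.exp(-(e_new - e_cur) / kT))
        if accept:
            x_cur, e_cur = x_new, e_new
            traj.accepted.append((x_new.copy(), e_new))
        traj.log.append({"n_min": traj.n_minimizations,
                         "energy": e_new, "accepted": bool(accept),
                         "lowest": traj.lowest[1]})
        if since_improve >= config.convergence_window:
            traj.converged = True
    model.system.set_vector(x_cur)
    return traj


def _stage_mcm(model, config, rng, cap):
    """Short steered stage: limited accepted points / proposals."""
    x_cur = model.system.get_vector()
    x_cur, e_cur = local_minimize(model, x0=x_cur, max_iter=cap)
    n_acc, n_prop = 0, 0
    lowest = (x_cur.copy(), e_cur)
    kT = KB * config.temperature
    while n_acc < config.stage_accepts and n_prop < config.stage_proposals:
        x_prop = propose_move(model.system, rng, config, x_cur)
        x_new, e_new = local_minimize(model, x0=x_prop, max_iter=cap)
        n_prop += 1
        if e_new < lowest[1]:
            lowest = (x_new.copy(), e_new)
        if (e_new <= e_cur
                or rng.random() < np.exp(-(e_new - e_cur) / kT)):
            x_cur, e_cur = x_new, e_new
            n_acc += 1
    model.system.set_vector(x_cur)
    return x_cur, e_cur, lowest, n_prop


def run_steered(system, schedule: SteerSchedule,
                restraints: RestraintSet | None = None,
                config: MCMConfig = MCMConfig(),
                nb_options: NonbondedOptions | None = None,
                stability_run: bool = True):
    """Steered MCM: walk target anchors stepwise, converge, then verify
    stability without constraints.

    Returns ``(system, report)`` where the report carries per-stage logs,
    the final targeted-atom RMSD to the end anchors, and the C-alpha drift
    of the unconstrained stability run.
    """
    for loc in schedule.targeted_atoms:
        system.atom_index(*loc)   # raises on missing targeted atom
    static = (restraints or RestraintSet()).merged_with(schedule.companion)
    rng = np.random.default_rng(config.rng_seed)
    cap = config.steered_min_iterations
    stages = []
    n_stages = schedule.n_stages
    for s in range(1, n_stages + 1):
        frac = s / n_stages
        pins = schedule.stage_pins(frac)
        model = EnergyModel(system, nb_options,
                            RestraintSet(pins=list(pins)).merged_with(static))
        x, e, lowest, n_prop = _stage_mcm(model, config, rng, cap)
        stages.append({"stage": s, "fraction": frac, "energy": e,
                       "proposals": n_prop})
    # final leg: run at the target anchors to the convergence window
    pins = schedule.stage_pins(1.0)
    model = EnergyModel(system, nb_options,
                        RestraintSet(pins=list(pins)).merged_with(static))
    final = run_mcm(model, config=config, rng=rng, min_iterations=cap)
    system.set_vector(final.lowest[0])
    idx = [system.atom_index(*loc) for loc in schedule.targeted_atoms]
    dev = np.linalg.norm(system.cartesian[idx] - schedule.end_anchors, axis=1)
    report = {
        "stages": stages,
        "final_converged": final.converged,
        "final_energy": final.lowest[1],
        "target_deviations": dev,
        "target_rmsd": float(np.sqrt(np.mean(dev ** 2))),
    }
    if stability_run:
        ca = system.calpha_indices()
        before = system.cartesian[ca].copy()
        free_model = EnergyModel(system, nb_options, RestraintSet())
        stab = run_mcm(free_model, config=config, rng=rng,
                       min_iterations=cap)
        system.set_vector(stab.lowest[0])
        drift = np.linalg.norm(system.cartesian[ca] - before, axis=1)
        report["stability_ca_drift"] = float(np.sqrt(np.mean(drift ** 2)))
        report["stability_energy"] = stab.lowest[1]
    return system, report
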