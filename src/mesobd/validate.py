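"""Built-in validation experiments.

These harnesses run complete simulations through the engine and reduce
them to the summary statistics used to check the simulator against its
analytic or numerical references: mean-squared-displacement ratios for
free and membrane diffusion, Poisson statistics of zeroth-order creation,
exponential first-order kinetics, the mass-action time course of the
bimolecular association box, and the time-step halving heuristic (repeat
the run with half the step; results should not change significantly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import engine as _engine
from .dynamics import TAG_MEMBRANE
from .examples import bimolecular_box_model, creation_model, decay_model, free_diffusion_model


@dataclass
class MsdResult:
    ratio: float  # measured MSD / expected MSD at the probe lag
    lag_steps: int
    n_samples: int
    max_abs_y: float  # membrane runs: largest |y displacement| observed


def msd_experiment(
    n: int = 1000,
    D: float = 1e-12,
    dt: float = 1e-4,
    n_iter: int = 1000,
    landscape: str = "unrestricted",
    lag_steps: int = 100,
    seed: int = 1,
) -> MsdResult:
    """Ensemble MSD of inert tracers against 2*d*D*t.

    Positions are collected every iteration; the MSD at the probe lag is
    averaged over non-overlapping windows and all tracers (the standard
    ensemble/time-origin estimator).  ``d`` is 3 for free diffusion and 2
    for membrane diffusion (where the y component must vanish exactly).
    """
    doc = free_diffusion_model(
        n=n, D=D, dt=dt, n_iter=n_iter, landscape=landscape, seed=seed
    )
    frames: list[np.ndarray] = []

    def collect(sim):
        frames.append(np.array([c.com for c in sim.clusters.values()]))

    _engine.run(doc, output_observers=[collect])
    traj = np.stack(frames)  # (n_iter+1, n, 3)
    n_windows = (traj.shape[0] - 1) // lag_steps
    disp = np.stack(
        [
            traj[(w + 1) * lag_steps] - traj[w * lag_steps]
            for w in range(n_windows)
        ]
    )  # (n_windows, n, 3)
    dims = 2 if landscape == TAG_MEMBRANE else 3
    max_abs_y = float(np.max(np.abs(disp[:, :, 1]))) if landscape == TAG_MEMBRANE else float("nan")
    if landscape == TAG_MEMBRANE:
        sq = disp[:, :, 0] ** 2 + disp[:, :, 2] ** 2
    else:
        sq = (disp**2).sum(axis=2)
    expected = 2.0 * dims * D * dt * lag_steps
    return MsdResult(
        ratio=float(sq.mean() / expected),
        lag_steps=lag_steps,
        n_samples=int(sq.size),
        max_abs_y=max_abs_y,
    )


@dataclass
class CreationResult:
    lam: float
    total: int
    expected_total: float
    per_step: np.ndarray
    dispersion: float  # variance / mean of the per-step counts


def creation_experiment(
    k0: float = 1e-6, dt: float = 1e-3, n_iter: int = 10_000, side: float = 1e-6,
    seed: int = 1,
) -> CreationResult:
    """Zeroth-order creation counts vs the Poisson expectation."""
    doc = creation_model(k0=k0, dt=dt, n_iter=n_iter, side=side, seed=seed)
    sim = _engine.Simulation(doc)
    lam = k0 * dt * (side**3 * 1e3) * sim.ctx.N_A
    counts = np.zeros(n_iter + 1, dtype=int)

    class Counter:
        def __call__(self, s):
            counts[s.iteration] = s.entity_count("X")

    sim.output_observers.append(Counter())
    sim.run()
    # counts holds cumulative totals at executed iterations (zeros elsewhere);
    # forward-fill then difference to recover per-step creation counts
    filled = np.maximum.accumulate(counts)
    per_step = np.diff(filled)
    total = int(filled[-1])
    mean = per_step.mean()
    dispersion = float(per_step.var(ddof=1) / mean) if mean > 0 else float("nan")
    return CreationResult(
        lam=lam,
        total=total,
        expected_total=lam * n_iter,
        per_step=per_step,
        dispersion=dispersion,
    )


@dataclass
class DecayResult:
    times: np.ndarray
    fitted_rate: float
    survivors: int


def decay_experiment(
    n: int = 10_000, k1: float = 1.0, dt: float = 1e-4, n_iter: int = 100_000,
    seed: int = 1,
) -> DecayResult:
    """First-order decay: realised reaction times and the MLE rate."""
    doc = decay_model(n=n, k1=k1, dt=dt, n_iter=n_iter, seed=seed)
    times: list[float] = []

    def on_reaction(sim, info):
        times.append(info["iteration"] * sim.cfg.dt)

    sim = _engine.run(doc, reaction_observers=[on_reaction])
    times_arr = np.array(times)
    fitted = 1.0 / times_arr.mean() if len(times_arr) else float("nan")
    return DecayResult(
        times=times_arr, fitted_rate=float(fitted), survivors=sim.entity_count("X")
    )


@dataclass
class AssociationResult:
    times: np.ndarray
    free_a: np.ndarray
    ode_free_a: np.ndarray
    t_half: float
    sim_at_half: float
    ode_at_half: float
    params: dict


def association_experiment(
    seed: int = 1,
    n_a: int = 1000,
    n_b: int = 1000,
    steps_to_half: int = 16000,
    reduced_step: float = 0.1,
    k: float = 3e8,
    D_each: float = 1e-11,
) -> AssociationResult:
    """Irreversible A+B association vs the mass-action ODE.

    For equal initial copy numbers the ODE course is
    ``A(t) = A0 / (1 + k c0 t)``; the simulated free-A count is compared
    at the output timepoint closest to the analytic half-life.
    """
    doc = bimolecular_box_model(
        n_a=n_a, n_b=n_b, k=k, D_each=D_each, reduced_step=reduced_step,
        steps_to_half=steps_to_half, seed=seed,
    )
    times: list[float] = []
    free_a: list[int] = []

    def collect(sim):
        times.append(sim.iteration * sim.cfg.dt)
        n_free = sum(
            1
            for c in sim.clusters.values()
            if len(c.entities) == 1 and c.entities[0].template.id == "A"
        )
        free_a.append(n_free)

    _engine.run(doc, output_observers=[collect])
    times_arr = np.array(times)
    free_arr = np.array(free_a, dtype=float)
    from .reactions import molar_rate_to_si

    k_si = molar_rate_to_si(k)
    c0 = n_a / doc.L**3  # molecules / m^3
    ode = n_a / (1.0 + k_si * c0 * times_arr)
    t_half = 1.0 / (k_si * c0)
    idx = int(np.argmin(np.abs(times_arr - t_half)))
    return AssociationResult(
        times=times_arr,
        free_a=free_arr,
        ode_free_a=ode,
        t_half=t_half,
        sim_at_half=float(free_arr[idx]),
        ode_at_half=float(ode[idx]),
        params={"L": doc.L, "dt": doc.dt, "n_iter": doc.n_iter, "k": k, "D_each": D_each},
    )


def association_ensemble(seeds, **kwargs):
    """Mean and sem of sim/ODE at the half-life over several seeds."""
    ratios = []
    for seed in seeds:
        res = association_experiment(seed=seed, **kwargs)
        ratios.append(res.sim_at_half / res.ode_at_half)
    ratios = np.array(ratios)
    sem = ratios.std(ddof=1) / math.sqrt(len(ratios)) if len(ratios) > 1 else float("nan")
    return float(ratios.mean()), float(sem), ratios


def halving_check(seeds, steps_to_half: int = 16000, **kwargs):
    """Time-step halving heuristic for the association box.

    Runs the ensemble at the trial step and at half the step (same
    physical half-life, twice the iterations) and reports both means with
    95% confidence intervals; overlapping intervals indicate the trial
    step is sufficient.
    """
    m1, s1, r1 = association_ensemble(seeds, steps_to_half=steps_to_half, **kwargs)
    kwargs_half = dict(kwargs)
    rs = kwargs_half.pop("reduced_step", 0.1) / math.sqrt(2.0)
    m2, s2, r2 = association_ensemble(
        seeds, steps_to_half=2 * steps_to_half, reduced_step=rs, **kwargs_half
    )
    ci1 = (m1 - 1.96 * s1, m1 + 1.96 * s1)
    ci2 = (m2 - 1.96 * s2, m2 + 1.96 * s2)
    overlap = ci1[0] <= ci2[1] and ci2[0] <= ci1[1]
    return {
        "mean_dt": m1, "ci_dt": ci1, "ratios_dt": r1,
        "mean_half_dt": m2, "ci_half_dt": ci2, "ratios_half_dt": r2,
        "overlap": overlap,
    }
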