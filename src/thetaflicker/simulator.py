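"""Full-network integration of the two-map attractor model.

The state per unit is (m, u, x) plus an optional colored-noise input eta:

    tau dm/dt = -m + g( sum_j W_ij u_j x_j m_j + I_ext(t) + I0 )
    du/dt     = (U - u)/tau_f + U (1 - u) m
    dx/dt     = (1 - x)/tau_r - u x m
    tau_N d(eta)/dt = -eta + A_n xi(t)

Two integration methods are provided: adaptive Runge-Kutta (scipy RK45,
dense output sampled onto the recording grids) for deterministic runs, and
a fixed-step Euler scheme (numba-compiled, default dt = 0.1 ms) which is the
only method allowed when noise is enabled.  With plasticity disabled the
synaptic variables are frozen at u = U, x = 1.

Recording is two-rate: per-map mean population activity on a fine grid
(default 1 kHz, enough for theta-band filtering and cycle segmentation) and
per-unit rates/synaptic variables on a coarser stride.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from numba import njit
from scipy.integrate import RK45

from .model_core import (ConnectivityParams, NeuronParams, STPParams,
                         SelectivityMap, assign_selectivity,
                         build_connectivity, transfer)
from .stimulus import (LocalizedParams, NoiseParams, TeleportationSchedule,
                       ThetaParams, Trajectory, make_trajectory)

__all__ = [
    "ModelConfig",
    "Network",
    "StimulusSpec",
    "SimConfig",
    "SimResult",
    "build_network",
    "run",
    "population_activity",
    "local_average",
    "teleportation_experiment",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Flat model/stimulus parameter set (the standard simulation regime).

    Defaults are the operating point of the plastic-synapse model; use
    :meth:`no_stp` for the static-synapse regime (stronger recurrence and
    theta drive, plasticity frozen).  ``J0`` may be given signed or not;
    only its magnitude enters (the uniform term is always inhibitory).
    """

    tau: float = 0.01
    U: float = 0.25
    tau_r: float = 0.6
    tau_f: float = 1.9
    A1: float = 0.5
    A2: float = 4.0
    A_theta: float = 13.0
    f_theta: float = 10.0
    V: float = 2.0 * np.pi / 10.0
    J1: float = 14.0
    J0: float = -18.0
    I0: float = -1.0
    alpha: float = 1.0
    f: float = 0.25
    n_per_map: int = 2500
    A_n: float = 0.0
    tau_N: float = 0.01
    seed: int = 0
    stp_enabled: bool = True

    @classmethod
    def no_stp(cls, **overrides) -> "ModelConfig":
        """Static-synapse regime (plasticity frozen at baseline efficacy)."""
        base = dict(tau=0.01, A1=0.75, A2=3.25, A_theta=60.0,
                    J1=35.0, J0=-42.0, stp_enabled=False)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    # split into component parameter objects -------------------------------
    @property
    def neuron(self) -> NeuronParams:
        return NeuronParams(tau=self.tau, alpha=self.alpha, I0=self.I0)

    @property
    def stp(self) -> STPParams:
        return STPParams(U=self.U, tau_r=self.tau_r, tau_f=self.tau_f)

    @property
    def connectivity(self) -> ConnectivityParams:
        return ConnectivityParams(J1=self.J1, J0_magnitude=abs(self.J0))

    @property
    def theta(self) -> ThetaParams:
        return ThetaParams(A_theta=self.A_theta, f_theta=self.f_theta)

    @property
    def localized(self) -> LocalizedParams:
        return LocalizedParams(A1=self.A1, A2=self.A2)

    @property
    def noise(self) -> NoiseParams:
        return NoiseParams(A_n=self.A_n, tau_N=self.tau_N)


@dataclass
class Network:
    """A constructed network: selectivity, weights, and unit/synapse params."""

    sel: SelectivityMap
    W: np.ndarray
    neuron: NeuronParams
    stp: STPParams


@dataclass
class StimulusSpec:
    """The external drive bundle handed to the integrator."""

    theta: ThetaParams
    localized: LocalizedParams
    traj: Trajectory
    noise: NoiseParams = field(default_factory=NoiseParams)


@dataclass(frozen=True)
class SimConfig:
    """Integration settings."""

    method: str = "adaptive_rk"          # "adaptive_rk" | "euler"
    dt: float = 1e-4
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    duration: float = 1.0
    record_stride: float = 0.01          # per-unit recording interval (s)
    pop_stride: float = 0.001            # population-activity interval (s)
    seed: int = 0
    stp_enabled: bool = True
    no_stp_efficacy: str = "adiabatic"   # "adiabatic" | "baseline"
    record_synapses: bool = True
    init_jitter: float = 1e-3

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.method not in ("adaptive_rk", "euler"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.no_stp_efficacy not in ("adiabatic", "baseline"):
            raise ValueError(f"unknown no_stp_efficacy {self.no_stp_efficacy!r}")

    @property
    def stp_mode(self) -> int:
        """Integration mode: 1 = dynamic plasticity, 2 = static synapses at
        their rate-dependent steady state, 0 = frozen at baseline (u=U, x=1;
        numerically unstable at the published static-regime couplings, kept
        for ablation)."""
        if self.stp_enabled:
            return 1
        return 2 if self.no_stp_efficacy == "adiabatic" else 0


@dataclass
class SimResult:
    """Recorded simulation output.

    pop_times / pop_activity : fine-grid per-map mean rates (2, T_pop).
    times / rates / u / x    : strided per-unit state ((T, n); u, x may be None).
    """

    pop_times: np.ndarray
    pop_activity: np.ndarray
    times: np.ndarray
    rates: np.ndarray
    u: np.ndarray | None
    x: np.ndarray | None
    sel: SelectivityMap
    config: SimConfig
    schedule: TeleportationSchedule
    traj: Trajectory

    @property
    def pop_fs(self) -> float:
        return 1.0 / (self.pop_times[1] - self.pop_times[0])


def build_network(cfg: ModelConfig) -> Network:
    sel = assign_selectivity(cfg.n_per_map, cfg.f, seed=cfg.seed)
    W = build_connectivity(sel, cfg.connectivity)
    return Network(sel=sel, W=W, neuron=cfg.neuron, stp=cfg.stp)


# ---------------------------------------------------------------------------
# Euler kernel (numba)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _euler_loop(W, memA, memB, cA1, cA2, cB1, cB2,
                m, u, x, eta,
                tau, alpha, I0,
                U, tau_r, tau_f, stp_mode,
                A_theta, f_theta, A1, A2,
                phi1_steps, phi2_steps, cur_map_steps,
                A_n, tau_N, noise_on, seed,
                dt, n_steps,
                pop_every, unit_every,
                popA, popB, rec_t, rec_m, rec_u, rec_x, rec_syn):
    np.random.seed(seed)
    n = m.shape[0]
    nA = 0.0
    nB = 0.0
    for i in range(n):
        if memA[i]:
            nA += 1.0
        if memB[i]:
            nB += 1.0
    sq_dt = math.sqrt(dt)
    ip = 0
    iu = 0
    for step in range(n_steps + 1):
        # ---- record (state at t = step*dt) ----
        if step % pop_every == 0 and ip < popA.shape[0]:
            sA = 0.0
            sB = 0.0
            for i in range(n):
                if memA[i]:
                    sA += m[i]
                if memB[i]:
                    sB += m[i]
            popA[ip] = sA / nA
            popB[ip] = sB / nB
            ip += 1
        if step % unit_every == 0 and iu < rec_m.shape[0]:
            rec_t[iu] = step * dt
            for i in range(n):
                rec_m[iu, i] = m[i]
                if rec_syn:
                    rec_u[iu, i] = u[i]
                    rec_x[iu, i] = x[i]
            iu += 1
        if step == n_steps:
            break

        t = step * dt
        p1 = phi1_steps[step]
        p2 = phi2_steps[step]
        cur = cur_map_steps[step]
        ampA = A1 + A2 if cur == 0 else A2
        ampB = A1 + A2 if cur == 1 else A2

        # presynaptic drive through the synapses
        if stp_mode == 2:
            # static synapses: efficacy at its steady state for the current
            # rate (no memory, but transmission still saturates with rate)
            w = np.empty(n)
            for i in range(n):
                us = U * (1.0 + tau_f * m[i]) / (1.0 + U * tau_f * m[i])
                xs = 1.0 / (1.0 + us * tau_r * m[i])
                w[i] = us * xs * m[i]
        else:
            w = u * x * m
        h = np.dot(W, w)

        Itheta = A_theta * math.sin(2.0 * math.pi * f_theta * t)
        for i in range(n):
            Iext = Itheta + I0 + eta[i]
            if memA[i]:
                ca = math.cos(cA1[i] - p1)
                cb = math.cos(cA2[i] - p2)
                if ca > 0.0:
                    Iext += ampA * ca
                if cb > 0.0:
                    Iext += ampA * cb
            if memB[i]:
                ca = math.cos(cB1[i] - p1)
                cb = math.cos(cB2[i] - p2)
                if ca > 0.0:
                    Iext += ampB * ca
                if cb > 0.0:
                    Iext += ampB * cb
            z = h[i] + Iext
            za = z / alpha
            if za > 30.0:
                g = z
            else:
                g = alpha * math.log1p(math.exp(za))
            mi = m[i]
            m[i] = mi + (dt / tau) * (g - mi)
            if stp_mode == 1:
                ui = u[i]
                xi = x[i]
                u[i] = ui + dt * ((U - ui) / tau_f + U * (1.0 - ui) * mi)
                x[i] = xi + dt * ((1.0 - xi) / tau_r - ui * xi * mi)
        if noise_on:
            zvec = np.random.standard_normal(n)
            for i in range(n):
                eta[i] = eta[i] + (dt / tau_N) * (-eta[i]) \
                    + (A_n / tau_N) * sq_dt * zvec[i]
    return ip, iu


# ---------------------------------------------------------------------------
# Top-level run
# ---------------------------------------------------------------------------

def _initial_state(net: Network, cfg: SimConfig, rng: np.random.Generator):
    """Baseline fixed point plus a small seeded jitter to break symmetry."""
    n = net.sel.n_units
    m0 = transfer(net.neuron.I0, net.neuron.alpha) * np.ones(n)
    m0 += cfg.init_jitter * rng.random(n)
    u0 = np.full(n, net.stp.U)
    x0 = np.ones(n)
    return m0, u0, x0


def run(net: Network, stim: StimulusSpec, sched: TeleportationSchedule,
        cfg: SimConfig) -> SimResult:
    """Integrate the network under the given drive and cue schedule."""
    noise_on = stim.noise.A_n > 0
    if noise_on and cfg.method != "euler":
        raise ValueError("noisy simulations require method='euler'")
    rng = np.random.default_rng(cfg.seed)
    m0, u0, x0 = _initial_state(net, cfg, rng)
    if cfg.method == "euler":
        res = _run_euler(net, stim, sched, cfg, m0, u0, x0, noise_on)
    else:
        res = _run_adaptive(net, stim, sched, cfg, m0, u0, x0)
    if not np.all(np.isfinite(res.rates)):
        bad = np.flatnonzero(~np.isfinite(res.rates).all(axis=1))[0]
        raise FloatingPointError(
            f"non-finite network state at t={res.times[bad]:.4f} s")
    return res


def _recording_grids(cfg: SimConfig, dt: float):
    n_steps = int(round(cfg.duration / dt))
    pop_every = max(1, int(round(cfg.pop_stride / dt)))
    unit_every = max(1, int(round(cfg.record_stride / dt)))
    n_pop = n_steps // pop_every + 1
    n_unit = n_steps // unit_every + 1
    return n_steps, pop_every, unit_every, n_pop, n_unit


def _run_euler(net, stim, sched, cfg, m0, u0, x0, noise_on) -> SimResult:
    sel = net.sel
    n = sel.n_units
    dt = cfg.dt
    n_steps, pop_every, unit_every, n_pop, n_unit = _recording_grids(cfg, dt)

    step_t = np.arange(n_steps) * dt
    phi1, phi2 = stim.traj.positions(step_t)
    cur = np.array([sched.current_map(t) for t in step_t], dtype=np.int8)

    memA = np.ascontiguousarray(sel.membership[:, 0])
    memB = np.ascontiguousarray(sel.membership[:, 1])
    cA1 = np.nan_to_num(sel.centers[:, 0, 0])
    cA2 = np.nan_to_num(sel.centers[:, 0, 1])
    cB1 = np.nan_to_num(sel.centers[:, 1, 0])
    cB2 = np.nan_to_num(sel.centers[:, 1, 1])

    popA = np.empty(n_pop)
    popB = np.empty(n_pop)
    rec_t = np.empty(n_unit)
    rec_m = np.empty((n_unit, n))
    rec_syn = bool(cfg.record_synapses and cfg.stp_enabled)
    rec_u = np.empty((n_unit, n) if rec_syn else (1, 1))
    rec_x = np.empty_like(rec_u)

    m = m0.copy()
    u = u0.copy() if cfg.stp_enabled else np.full(n, net.stp.U)
    x = x0.copy() if cfg.stp_enabled else np.ones(n)
    eta = np.zeros(n)

    _euler_loop(np.ascontiguousarray(net.W), memA, memB, cA1, cA2, cB1, cB2,
                m, u, x, eta,
                net.neuron.tau, net.neuron.alpha, net.neuron.I0,
                net.stp.U, net.stp.tau_r, net.stp.tau_f, cfg.stp_mode,
                stim.theta.A_theta, stim.theta.f_theta,
                stim.localized.A1, stim.localized.A2,
                phi1, phi2, cur,
                stim.noise.A_n, stim.noise.tau_N, noise_on,
                cfg.seed % (2 ** 31), dt, n_steps,
                pop_every, unit_every,
                popA, popB, rec_t, rec_m, rec_u, rec_x, rec_syn)

    return SimResult(
        pop_times=np.arange(n_pop) * pop_every * dt,
        pop_activity=np.stack([popA, popB]),
        times=rec_t, rates=rec_m,
        u=rec_u if rec_syn else None, x=rec_x if rec_syn else None,
        sel=sel, config=cfg, schedule=sched, traj=stim.traj)


def _run_adaptive(net, stim, sched, cfg, m0, u0, x0) -> SimResult:
    sel = net.sel
    n = sel.n_units
    W = net.W
    nrn, stp = net.neuron, net.stp
    memA = sel.membership[:, 0]
    memB = sel.membership[:, 1]
    idx = [sel.members(k) for k in range(2)]
    cen = [(sel.centers[idx[k], k, 0], sel.centers[idx[k], k, 1]) for k in range(2)]
    A1, A2 = stim.localized.A1, stim.localized.A2
    switch_times = np.array([s[0] for s in sched.switches])

    def ext_input(t):
        out = np.full(n, stim.theta.A_theta * math.sin(2 * math.pi * stim.theta.f_theta * t)
                      + nrn.I0)
        p1, p2 = stim.traj.positions(t)
        cur = sched.current_map(t)
        for k in range(2):
            amp = A1 + A2 if k == cur else A2
            c1, c2 = cen[k]
            out[idx[k]] += amp * (np.maximum(np.cos(c1 - p1), 0.0)
                                  + np.maximum(np.cos(c2 - p2), 0.0))
        return out

    stp_on = cfg.stp_enabled

    if stp_on:
        def rhs(t, y):
            m = y[:n]
            u = y[n:2 * n]
            x = y[2 * n:]
            h = W @ (u * x * m) + ext_input(t)
            dm = (transfer(h, nrn.alpha) - m) / nrn.tau
            du = (stp.U - u) / stp.tau_f + stp.U * (1.0 - u) * m
            dx = (1.0 - x) / stp.tau_r - u * x * m
            return np.concatenate([dm, du, dx])
        y0 = np.concatenate([m0, u0, x0])
    elif cfg.stp_mode == 2:
        from .model_core import stp_steady_state

        def rhs(t, y):
            us, xs = stp_steady_state(np.maximum(y, 0.0), stp)
            h = W @ (us * xs * y) + ext_input(t)
            return (transfer(h, nrn.alpha) - y) / nrn.tau
        y0 = m0.copy()
    else:
        def rhs(t, y):
            h = W @ (stp.U * y) + ext_input(t)
            return (transfer(h, nrn.alpha) - y) / nrn.tau
        y0 = m0.copy()

    n_pop = int(round(cfg.duration / cfg.pop_stride)) + 1
    pop_t = np.arange(n_pop) * cfg.pop_stride
    n_unit = int(cfg.duration / cfg.record_stride) + 1
    unit_t = np.arange(n_unit) * cfg.record_stride

    popA = np.empty(n_pop)
    popB = np.empty(n_pop)
    rec_m = np.empty((n_unit, n))
    rec_syn = bool(cfg.record_synapses and stp_on)
    rec_u = np.empty((n_unit, n)) if rec_syn else None
    rec_x = np.empty((n_unit, n)) if rec_syn else None

    def record(y, ip=None, iu=None):
        m = y[:n]
        if ip is not None:
            popA[ip] = m[memA].mean()
            popB[ip] = m[memB].mean()
        if iu is not None:
            rec_m[iu] = m
            if rec_syn:
                rec_u[iu] = y[n:2 * n]
                rec_x[iu] = y[2 * n:]

    record(y0, ip=0, iu=0)
    ip, iu = 1, 1
    # integrate in segments between cue switches: the drive is discontinuous
    # there and the solver must restart rather than interpolate across
    bounds = [ts for ts in switch_times if 0.0 < ts < cfg.duration]
    segments = list(zip([0.0] + bounds, bounds + [cfg.duration]))
    y = y0
    for t0, t1 in segments:
        solver = RK45(rhs, t0, y, t1, rtol=cfg.rel_tol, atol=cfg.abs_tol,
                      max_step=0.25 / stim.theta.f_theta)
        while solver.status == "running":
            solver.step()
            if solver.status == "failed":
                raise FloatingPointError(
                    f"adaptive integrator failed at t={solver.t:.4f}")
            dense = solver.dense_output()
            while ip < n_pop and pop_t[ip] <= solver.t + 1e-12:
                record(dense(min(pop_t[ip], solver.t)), ip=ip)
                ip += 1
            while iu < n_unit and unit_t[iu] <= solver.t + 1e-12:
                record(dense(min(unit_t[iu], solver.t)), iu=iu)
                iu += 1
        y = solver.y

    return SimResult(
        pop_times=pop_t,
        pop_activity=np.stack([popA, popB]),
        times=unit_t, rates=rec_m,
        u=rec_u, x=rec_x,
        sel=sel, config=cfg, schedule=sched, traj=stim.traj)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def population_activity(res: SimResult, k: int, from_rates: bool = False) -> np.ndarray:
    """Mean rate over map k's member units (dual-map units count in both).

    By default returns the fine-grid series recorded during integration;
    with ``from_rates=True`` recomputes from the strided per-unit rates.
    """
    if from_rates:
        return res.rates[:, res.sel.membership[:, k]].mean(axis=1)
    return res.pop_activity[k]


def local_average(res: SimResult, traj: Trajectory, sel: SelectivityMap,
                  k: int, quantity: str = "rate") -> np.ndarray:
    """Average rate or synaptic efficacy (u*x) of map-k units whose
    place-field centre lies near the animal (both cos(centre - position) > 0.5).
    """
    if quantity not in ("rate", "efficacy"):
        raise ValueError("quantity must be 'rate' or 'efficacy'")
    if quantity == "efficacy" and res.u is None:
        raise ValueError("synaptic variables were not recorded")
    idx = sel.members(k)
    c1 = sel.centers[idx, k, 0]
    c2 = sel.centers[idx, k, 1]
    out = np.empty(len(res.times))
    p1s, p2s = traj.positions(res.times)
    for i, (p1, p2) in enumerate(zip(np.atleast_1d(p1s), np.atleast_1d(p2s))):
        mask = (np.cos(c1 - p1) > 0.5) & (np.cos(c2 - p2) > 0.5)
        assert mask.any(), "empty local selection (grid should preclude this)"
        cols = idx[mask]
        if quantity == "rate":
            out[i] = res.rates[i, cols].mean()
        else:
            out[i] = (res.u[i, cols] * res.x[i, cols]).mean()
    return out


@dataclass
class TeleportationOutcome:
    """A single cue-switch run plus its switch metadata."""

    result: SimResult
    switch_time: float
    transition_time: float | None      # start of first post-switch cycle won by the new map
    switch_position: tuple[float, float] | None
    cycles: "object" = None            # ThetaCycles over the whole run
    events: "object" = None            # per-cycle classification records


def teleportation_experiment(model: ModelConfig, switch_time: float = 10.0,
                             post_window: float = 10.0,
                             sim: SimConfig | None = None,
                             net: Network | None = None) -> TeleportationOutcome:
    """Run a single teleportation protocol and locate the network transition.

    The cue set selects map 0 from t=0 (burn-in; at least 5 s so the
    plasticity variables reach their cruise state) and switches to map 1 at
    ``switch_time``; the run extends ``post_window`` seconds beyond the
    switch.  The transition time is the start of the first post-switch theta
    cycle in which the new map's cycle-mean population activity dominates,
    and the switch position is the animal's location then.
    """
    from . import flicker_detection as fd

    if switch_time < 5.0:
        raise ValueError("switch_time must allow a burn-in of at least 5 s")
    if sim is None:
        method = "euler" if model.A_n > 0 else "adaptive_rk"
        sim = SimConfig(method=method, duration=switch_time + post_window,
                        seed=model.seed, stp_enabled=model.stp_enabled)
    else:
        sim = replace(sim, duration=switch_time + post_window,
                      stp_enabled=model.stp_enabled)
    if net is None:
        net = build_network(model)
    stim = StimulusSpec(theta=model.theta, localized=model.localized,
                        traj=make_trajectory(model.V), noise=model.noise)
    sched = TeleportationSchedule(initial_map=0, switches=[(switch_time, 1)])
    res = run(net, stim, sched, sim)

    total = res.pop_activity.mean(axis=0)
    filt = fd.bandpass_mean_activity(total, res.pop_fs)
    cycles = fd.segment_cycles(filt, res.pop_fs)
    events = fd.classify_cycles(res, cycles, sched)

    transition_time = None
    switch_position = None
    for ev in events:
        start, _ = cycles.intervals[ev.cycle_index]
        if start >= switch_time and not ev.previous_map_dominant:
            transition_time = start
            p1, p2 = stim.traj.positions(start)
            switch_position = (float(p1), float(p2))
            break
    return TeleportationOutcome(result=res, switch_time=switch_time,
                                transition_time=transition_time,
                                switch_position=switch_position,
                                cycles=cycles, events=events)
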