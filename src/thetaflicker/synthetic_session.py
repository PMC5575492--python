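"""Synthetic recording sessions with known ground truth.

Generates the same kind of data bundle a teleportation experiment yields —
per-cell spike trains, a theta-bearing LFP, position tracking and trial
metadata — from a fully specified generative model, so the session-analysis
pipeline can be validated end to end:

* trajectory: Ornstein-Uhlenbeck velocity process with reflecting walls in a
  square arena, giving naturalistic speed variation;
* two environments, each assigning every cell an independent 2D Gaussian
  place field (global remapping);
* LFP: sinusoid at theta frequency plus white noise;
* spikes: inhomogeneous Poisson draws from the active map's tuning curves,
  theta-modulated so the population phase histogram has a clear minimum at
  the LFP trough;
* teleportation trials: after the cue switch every theta cycle expresses the
  new environment except a planted subset that re-expresses the old one
  (ground-truth flickering events).

``from_simulation`` instead converts a network simulation into a bundle by
Poisson-thinning unit rates, so model output can be pushed through the
data-side pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session_analysis import SessionBundle, Trial

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "from_simulation",
           "score_detection", "synthetic_trial_stats"]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for a synthetic teleportation session.

    The arena is 60 cm x 60 cm (30 x 30 bins of 2 cm); place fields are
    isotropic Gaussians.  ``n_planted_flickers`` theta cycles, drawn from
    the window after the cue switch, express the old environment.
    """

    n_cells: int = 40
    arena_side: float = 60.0            # cm
    field_sd: float = 7.0               # cm
    peak_rate: float = 25.0             # Hz
    baseline_rate: float = 0.1          # Hz
    theta_freq: float = 8.0             # Hz
    theta_mod_depth: float = 0.8        # rate modulation within a cycle
    lfp_fs: float = 1250.0              # Hz
    lfp_noise_sd: float = 0.3           # vs unit-amplitude theta
    speed_mean: float = 18.0            # cm/s
    speed_sd: float = 8.0               # cm/s
    speed_tau: float = 1.5              # s, velocity OU time constant
    ref_duration: float = 180.0         # s per reference session
    teleport_duration: float = 40.0     # s
    switch_offset: float = 15.0         # s into the teleport trial
    n_planted_flickers: int = 20
    planted_window: float = 5.0         # s after switch for planted cycles
    tracking_fs: float = 50.0           # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.arena_side, self.field_sd, self.peak_rate,
               self.theta_freq, self.lfp_fs, self.ref_duration,
               self.teleport_duration, self.tracking_fs) <= 0:
            raise ValueError("all generator scales must be positive")
        if self.switch_offset + self.planted_window > self.teleport_duration:
            raise ValueError("planted window extends past the trial end")


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring the analysis."""

    centers: dict[str, np.ndarray]          # (n_cells, 2) cm per environment
    cycle_intervals: np.ndarray             # (n_cycles, 2) s, teleport trial
    cycle_labels: np.ndarray                # per-cycle active env ("A"/"B")
    planted_cycles: np.ndarray              # indices into cycle_intervals
    switch_time: float
    switch_position: tuple[float, float]
    first_new_cycle: int                    # first post-switch cycle index


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

def _ou_walk(duration: float, cfg: GeneratorConfig,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """OU velocity, reflecting walls; returns (t, xy)."""
    dt = 1.0 / cfg.tracking_fs
    n = int(round(duration * cfg.tracking_fs))
    t = np.arange(n) * dt
    xy = np.empty((n, 2))
    v = np.empty(2)
    # start mid-arena with a random heading at the mean speed
    xy[0] = cfg.arena_side / 2.0
    ang = rng.uniform(0, TWO_PI)
    v[:] = cfg.speed_mean * np.array([np.cos(ang), np.sin(ang)])
    a = dt / cfg.speed_tau
    sd_step = cfg.speed_sd * np.sqrt(2.0 * a)
    drift = cfg.speed_mean / np.sqrt(2.0)       # per-component scale
    for i in range(1, n):
        v += a * (np.sign(v) * drift - v) + sd_step * rng.standard_normal(2)
        p = xy[i - 1] + v * dt
        for d in range(2):
            if p[d] < 0:
                p[d] = -p[d]
                v[d] = -v[d]
            elif p[d] > cfg.arena_side:
                p[d] = 2 * cfg.arena_side - p[d]
                v[d] = -v[d]
        xy[i] = p
    return t, xy


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def _field_rate(xy: np.ndarray, centers: np.ndarray,
                cfg: GeneratorConfig) -> np.ndarray:
    """(T, n_cells) Gaussian tuning rates at tracked positions."""
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    return cfg.baseline_rate + cfg.peak_rate * np.exp(-d2 / (2 * cfg.field_sd ** 2))


def _poisson_spikes(t: np.ndarray, rate: np.ndarray,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Inhomogeneous Poisson thinning on the tracking grid, per cell."""
    dt = t[1] - t[0]
    out = []
    for ci in range(rate.shape[1]):
        lam = rate[:, ci] * dt
        counts = rng.poisson(lam)
        times = np.repeat(t, counts) + rng.uniform(0, dt, counts.sum())
        out.append(np.sort(times))
    return out


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate(cfg: GeneratorConfig) -> tuple[SessionBundle, GroundTruth]:
    """Build a (reference A, reference B, teleportation) session.

    The session timeline is the concatenation of both reference trials and
    one teleportation trial.  During the teleportation trial the active
    environment is assigned per theta cycle: "A" before the switch, "B"
    after, except the planted flicker cycles which re-express "A".  Spike
    rates are theta-modulated (cosine of LFP phase, depth
    ``theta_mod_depth``) so population firing dips at the LFP trough.
    """
    rng = np.random.default_rng(cfg.seed)
    centers = {env: rng.uniform(0, cfg.arena_side, (cfg.n_cells, 2))
               for env in ("A", "B")}

    total = 2 * cfg.ref_duration + cfg.teleport_duration
    t, xy = _ou_walk(total, cfg, rng)

    t0A, t0B, t0T = 0.0, cfg.ref_duration, 2 * cfg.ref_duration
    trials = [
        Trial(kind="reference_A", interval=(t0A, t0B), environment="A"),
        Trial(kind="reference_B", interval=(t0B, t0T), environment="B"),
        Trial(kind="teleportation", interval=(t0T, total),
              switch_time=t0T + cfg.switch_offset,
              env_before="A", env_after="B"),
    ]
    switch_time = trials[2].switch_time

    # --- LFP: unit-amplitude theta + white noise -------------------------
    n_lfp = int(round(total * cfg.lfp_fs))
    t_lfp = np.arange(n_lfp) / cfg.lfp_fs
    theta_phase = TWO_PI * cfg.theta_freq * t_lfp          # 0 = LFP peak
    lfp = np.cos(theta_phase) + cfg.lfp_noise_sd * rng.standard_normal(n_lfp)

    # --- theta cycles of the teleport trial (trough-to-trough) -----------
    period = 1.0 / cfg.theta_freq
    first = (np.ceil((t0T - 0.5 * period) / period) + 0.5) * period
    starts = np.arange(first, total - period, period)
    starts = starts[starts >= t0T]
    cycle_intervals = np.column_stack([starts, starts + period])

    labels = np.where(cycle_intervals[:, 0] >= switch_time, "B", "A")
    post = np.flatnonzero(
        (cycle_intervals[:, 0] >= switch_time)
        & (cycle_intervals[:, 0] < switch_time + cfg.planted_window))
    first_new = int(post[0]) if post.size else -1
    # never plant the transition cycle itself
    candidates = post[1:]
    k = min(cfg.n_planted_flickers, len(candidates))
    planted = np.sort(rng.choice(candidates, size=k, replace=False))
    labels[planted] = "A"

    # --- per-sample active environment across the whole session ----------
    env_of_sample = np.empty(t.size, dtype="<U1")
    env_of_sample[:] = "A"
    env_of_sample[(t >= t0B) & (t < t0T)] = "B"
    tele = t >= t0T
    env_of_sample[tele] = "B"
    env_of_sample[tele & (t < switch_time)] = "A"
    for ci in np.flatnonzero(labels == "A"):
        s, e = cycle_intervals[ci]
        if s >= switch_time:
            env_of_sample[(t >= s) & (t < e)] = "A"

    # --- rates and spikes -------------------------------------------------
    rate = np.empty((t.size, cfg.n_cells))
    for env in ("A", "B"):
        rows = env_of_sample == env
        if rows.any():
            rate[rows] = _field_rate(xy[rows], centers[env], cfg)
    mod = 1.0 + cfg.theta_mod_depth * np.cos(TWO_PI * cfg.theta_freq * t)
    rate *= mod[:, None]
    spikes = _poisson_spikes(t, rate, rng)

    bundle = SessionBundle(tracking_t=t, tracking_xy=xy, spikes=spikes,
                           lfp=lfp, lfp_fs=cfg.lfp_fs, trials=trials)
    sw_x = float(np.interp(switch_time, t, xy[:, 0]))
    sw_y = float(np.interp(switch_time, t, xy[:, 1]))
    truth = GroundTruth(centers=centers, cycle_intervals=cycle_intervals,
                        cycle_labels=labels, planted_cycles=planted,
                        switch_time=switch_time,
                        switch_position=(sw_x, sw_y),
                        first_new_cycle=first_new)
    return bundle, truth


# ---------------------------------------------------------------------------
# Trial-statistics generator (for calibrating the partial-correlation test)
# ---------------------------------------------------------------------------

def synthetic_trial_stats(n_trials: int = 30,
                          effect_power: float = 0.0,
                          effect_distance: float = 0.0,
                          confound_corr: float = 0.5,
                          noise_sd: float = 1.0,
                          seed: int = 0):
    """Per-trial summary statistics with a controlled dependence structure.

    Theta power and distance share a latent confound (correlation
    ``confound_corr``), mimicking the slow-behaviour coupling seen in real
    teleportation sessions; the mean firing rate is a further covariate
    weakly tied to power.  The flicker rate is
    ``effect_power * z(power) + effect_distance * z(distance)`` plus skewed
    (exponential) noise, rectified at zero — deliberately non-normal, which
    is why the analysis uses permutation p-values.  With both effects zero
    the flicker rate is independent of power and distance (null model).
    """
    from .session_analysis import TrialStats

    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n_trials)
    a = np.sqrt(confound_corr)
    z_pow = a * latent + np.sqrt(1 - a * a) * rng.standard_normal(n_trials)
    z_dst = a * latent + np.sqrt(1 - a * a) * rng.standard_normal(n_trials)
    z_rate = 0.3 * z_pow + np.sqrt(1 - 0.09) * rng.standard_normal(n_trials)

    power = np.clip(0.25 + 0.08 * z_pow, 0.01, 0.99)
    distance = np.clip(25.0 + 8.0 * z_dst, 1.0, None)
    mean_rate = np.clip(2.0 + 0.5 * z_rate, 0.1, None)
    noise = noise_sd * (rng.exponential(1.0, n_trials) - 1.0)
    flick = np.clip(1.0 + effect_power * z_pow
                    + effect_distance * z_dst + noise, 0.0, None)
    return [TrialStats(flicker_rate=float(flick[i]),
                       theta_power=float(power[i]),
                       mean_distance=float(distance[i]),
                       mean_speed=float(distance[i] / 5.0),
                       mean_rate=float(mean_rate[i]),
                       p_lowV=0.0, excluded=False)
            for i in range(n_trials)]


# ---------------------------------------------------------------------------
# Scoring against ground truth
# ---------------------------------------------------------------------------

def score_detection(vectors, events, truth: GroundTruth,
                    min_overlap: float = 0.05) -> dict:
    """Sensitivity / false discovery of detected flickers vs planted truth.

    Detected and planted cycles are matched by temporal overlap (fraction of
    a cycle, at least ``min_overlap``).  Only post-switch detections count:
    flickering is defined in the window after the cue switch, and the cycle
    that straddles the switch itself has no well-defined map label.  Planted
    cycles whose matching analysis cycle failed the speed/tracking criteria
    are unobservable by construction (the pipeline is required to discard
    them) and are excluded from the sensitivity denominator; their count is
    reported.
    """
    planted = truth.cycle_intervals[truth.planted_cycles]
    period = float(np.median(np.diff(truth.cycle_intervals, axis=1)))

    def overlap(a, b):
        return max(0.0, min(a[1], b[1]) - max(a[0], b[0])) / period

    flagged = [(ev.cycle_index, vectors[ev.cycle_index].interval)
               for ev in events
               if ev.flagged
               and vectors[ev.cycle_index].interval[0] >= truth.switch_time]
    n_hit = 0
    n_unobservable = 0
    for p in planted:
        cands = [(overlap(cv.interval, p), cv) for cv in vectors]
        ov, best = max(cands, key=lambda c: c[0])
        if ov < min_overlap:
            n_unobservable += 1        # no analysis cycle covers it
            continue
        if not best.valid:
            n_unobservable += 1
            continue
        if any(overlap(iv, p) >= min_overlap for _, iv in flagged):
            n_hit += 1
    n_obs = len(planted) - n_unobservable
    n_fp = sum(1 for _, iv in flagged
               if not any(overlap(iv, p) >= min_overlap for p in planted))
    sens = n_hit / n_obs if n_obs else np.nan
    fdr = n_fp / len(flagged) if flagged else 0.0
    return {"sensitivity": sens, "false_discovery": fdr,
            "n_planted": len(planted), "n_observable": n_obs,
            "n_detected": len(flagged), "n_false": n_fp}


# ---------------------------------------------------------------------------
# Model-to-data bridge
# ---------------------------------------------------------------------------

def from_simulation(res, arena_side: float = 60.0, n_cells: int = 40,
                    rate_scale: float = 1.0, lfp_noise_sd: float = 0.05,
                    seed: int = 0) -> tuple[SessionBundle, list[int]]:
    """Convert a network simulation into a session bundle.

    A random subset of ``n_cells`` units (members of either map) is sampled;
    their recorded rates (times ``rate_scale``) drive Poisson spike trains.
    The LFP is the mean network activity (z-scored) plus white noise, and
    the tracking maps the torus diagonal onto the arena diagonal.  Returns
    the bundle plus the sampled unit indices.  The bundle carries a single
    teleportation trial covering the simulated interval; reference trials
    must come from separate simulations or the synthetic generator.
    """
    if res.rates is None or res.rates.size == 0:
        raise ValueError("simulation result has no recorded rates")
    rng = np.random.default_rng(seed)
    sel = res.sel
    any_member = np.flatnonzero(sel.membership.any(axis=1))
    units = rng.choice(any_member, size=min(n_cells, any_member.size),
                       replace=False)

    t = res.times
    dt = t[1] - t[0]
    spikes = []
    for uid in units:
        lam = np.clip(res.rates[:, uid] * rate_scale, 0.0, None) * dt
        counts = rng.poisson(lam)
        times = np.repeat(t, counts) + rng.uniform(0, dt, counts.sum())
        spikes.append(np.sort(times))

    mean_act = res.pop_activity.mean(axis=0)
    z = (mean_act - mean_act.mean()) / (mean_act.std() + 1e-12)
    lfp = z + lfp_noise_sd * rng.standard_normal(z.size)

    p1, p2 = res.traj.positions(t)
    xy = np.column_stack([p1, p2]) * (arena_side / TWO_PI)

    switches = res.schedule.switches
    trial = Trial(kind="teleportation", interval=(float(t[0]), float(t[-1])),
                  switch_time=switches[0][0] if switches else None,
                  env_before="A", env_after="B")
    bundle = SessionBundle(tracking_t=t, tracking_xy=xy, spikes=spikes,
                           lfp=lfp, lfp_fs=res.pop_fs, trials=[trial])
    return bundle, list(map(int, units))
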