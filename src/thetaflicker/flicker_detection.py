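"""Theta-cycle segmentation and flicker classification for model output.

The mean network activity oscillates at theta frequency because of the
uniform sinusoidal drive; cycles are delimited by the local minima of the
theta-band-filtered mean activity.  A cycle is a flickering event when the
cycle-mean population activity of the *non-current* (previously cued) map
exceeds that of the current map.  The sweep helpers re-run the teleportation
protocol over grids of theta amplitude, running speed, plasticity
parameters, and noise levels, and summarize event counts and their time
course relative to the cue switch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .simulator import ModelConfig, SimConfig, SimResult, build_network
from .stimulus import TeleportationSchedule

__all__ = [
    "ThetaCycles",
    "ModelFlickerEvent",
    "bandpass_mean_activity",
    "segment_cycles",
    "classify_cycles",
    "count_flickers",
    "sweep_theta_speed",
    "sweep_stp",
    "transient_profile",
]


@dataclass
class ThetaCycles:
    """Contiguous [start, end) intervals (s) delimiting theta cycles."""

    intervals: np.ndarray        # (n_cycles, 2) seconds
    fs: float

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    def midpoints(self) -> np.ndarray:
        return self.intervals.mean(axis=1)


@dataclass
class ModelFlickerEvent:
    """Per-cycle classification of which map dominated."""

    cycle_index: int
    mean_activity: tuple[float, float]     # per-map cycle-mean rates (Hz)
    current_map: int
    previous_map_dominant: bool


def bandpass_mean_activity(activity: np.ndarray, fs: float,
                           band: tuple[float, float] = (8.0, 12.0)) -> np.ndarray:
    """Zero-phase theta-band (8-12 Hz) filter of the mean network activity."""
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    activity = np.asarray(activity, dtype=np.float64)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    # filtfilt needs a few filter lengths of signal
    if activity.size < 3 * 3 * (2 * 4 + 1):
        raise ValueError("series too short for theta-band filtering")
    return signal.sosfiltfilt(sos, activity)


def segment_cycles(filtered: np.ndarray, fs: float) -> ThetaCycles:
    """Cut cycles at successive local minima of the filtered activity.

    Partial cycles before the first and after the last minimum are dropped.
    Minima closer than half a theta period (at 12 Hz) are merged via a
    minimum-distance constraint, which keeps numerical ripple from splitting
    cycles.
    """
    filtered = np.asarray(filtered, dtype=np.float64)
    if filtered.size == 0 or np.ptp(filtered) == 0:
        return ThetaCycles(intervals=np.empty((0, 2)), fs=fs)
    min_dist = max(1, int(round(fs / 12.0 / 2.0)))
    minima, _ = signal.find_peaks(-filtered, distance=min_dist,
                                  prominence=1e-6 * np.ptp(filtered))
    if len(minima) < 2:
        return ThetaCycles(intervals=np.empty((0, 2)), fs=fs)
    t = minima / fs
    return ThetaCycles(intervals=np.column_stack([t[:-1], t[1:]]), fs=fs)


def classify_cycles(res: SimResult, cycles: ThetaCycles,
                    sched: TeleportationSchedule,
                    statistic: str = "mean") -> list[ModelFlickerEvent]:
    """Decide, per theta cycle, whether the non-current map dominated.

    ``statistic`` selects the within-cycle summary of each map's population
    activity: "mean" (default) or "last_quartile" (mean over the final
    quarter of the cycle, where the competition has resolved).  Ties are not
    events.
    """
    if statistic not in ("mean", "last_quartile"):
        raise ValueError("statistic must be 'mean' or 'last_quartile'")
    t = res.pop_times
    events = []
    for ci, (start, end) in enumerate(cycles.intervals):
        lo = start if statistic == "mean" else end - (end - start) / 4.0
        sl = (t >= lo) & (t < end)
        if not sl.any():
            continue
        mA = float(res.pop_activity[0, sl].mean())
        mB = float(res.pop_activity[1, sl].mean())
        cur = sched.current_map(start)
        means = (mA, mB)
        dominant = means[1 - cur] > means[cur]
        events.append(ModelFlickerEvent(cycle_index=ci, mean_activity=means,
                                        current_map=cur,
                                        previous_map_dominant=dominant))
    return events


def count_flickers(events: list[ModelFlickerEvent], cycles: ThetaCycles,
                   window: tuple[float, float]) -> int:
    """Number of flagged cycles whose start lies in [window[0], window[1])."""
    lo, hi = window
    n = 0
    for ev in events:
        start = cycles.intervals[ev.cycle_index, 0]
        if ev.previous_map_dominant and lo <= start < hi:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Sweep experiments
# ---------------------------------------------------------------------------

def _count_post_switch(model: ModelConfig, switch_time: float,
                       window: tuple[float, float],
                       post_window: float, sim: SimConfig | None,
                       net=None) -> int:
    from .simulator import teleportation_experiment

    out = teleportation_experiment(model, switch_time=switch_time,
                                   post_window=post_window, sim=sim, net=net)
    lo, hi = window
    return count_flickers(out.events, out.cycles,
                          (out.switch_time + lo, out.switch_time + hi))


def sweep_theta_speed(model: ModelConfig, A_theta_grid, V_grid, reps: int = 1,
                      switch_time: float = 10.0, window: tuple[float, float] = (0.0, 5.0),
                      sim: SimConfig | None = None) -> np.ndarray:
    """Mean post-switch flicker counts over a theta-amplitude x speed grid."""
    counts = np.zeros((len(A_theta_grid), len(V_grid)))
    post = window[1] + 1.0
    for i, A in enumerate(A_theta_grid):
        for j, V in enumerate(V_grid):
            for r in range(reps):
                m = replace(model, A_theta=float(A), V=float(V),
                            seed=model.seed + 1000 * r)
                counts[i, j] += _count_post_switch(m, switch_time, window, post, sim)
            counts[i, j] /= reps
    return counts


def sweep_stp(model: ModelConfig, ratio_grid, U_grid=None, A_theta_values=None,
              switch_time: float = 10.0, window: tuple[float, float] = (0.0, 5.0),
              sim: SimConfig | None = None) -> np.ndarray:
    """Post-switch flicker counts over plasticity parameters.

    ``ratio_grid`` sets tau_f / tau_r at the model's tau_r.  If ``U_grid``
    and/or ``A_theta_values`` are given, the result gains those axes:
    shape (len(A_theta_values), len(U_grid), len(ratio_grid)), with singleton
    axes squeezed.
    """
    U_grid = [model.U] if U_grid is None else list(U_grid)
    A_vals = [model.A_theta] if A_theta_values is None else list(A_theta_values)
    out = np.zeros((len(A_vals), len(U_grid), len(ratio_grid)))
    post = window[1] + 1.0
    for a, A in enumerate(A_vals):
        for b, U in enumerate(U_grid):
            for c, ratio in enumerate(ratio_grid):
                m = replace(model, A_theta=float(A), U=float(U),
                            tau_f=float(ratio) * model.tau_r)
                out[a, b, c] = _count_post_switch(m, switch_time, window, post, sim)
    return out.squeeze()


def transient_profile(model: ModelConfig, noise_levels, A_theta_values,
                      reps: int = 5, bins: np.ndarray | None = None,
                      switch_time: float = 10.0, post_window: float = 10.0,
                      sim: SimConfig | None = None) -> dict:
    """Flicker probability vs time since the cue switch, averaged over seeds.

    For each (noise level, theta amplitude, seed) realization the per-cycle
    event stream is binned by cycle start time relative to the switch; the
    profile is the fraction of cycles flagged per bin, averaged across
    realizations.  Returns {"bins": edges, "probability": array, "n_cycles": array}.
    """
    from .simulator import teleportation_experiment

    if bins is None:
        bins = np.arange(0.0, post_window + 0.5, 2.5)
    bins = np.asarray(bins, dtype=np.float64)
    nb = len(bins) - 1
    flagged = np.zeros(nb)
    total = np.zeros(nb)
    for An in noise_levels:
        for A in A_theta_values:
            for r in range(reps):
                m = replace(model, A_n=float(An), A_theta=float(A),
                            seed=model.seed + 7919 * r)
                out = teleportation_experiment(m, switch_time=switch_time,
                                               post_window=post_window, sim=sim)
                for ev in out.events:
                    start = out.cycles.intervals[ev.cycle_index, 0] - switch_time
                    if start < bins[0] or start >= bins[-1]:
                        continue
                    b = int(np.searchsorted(bins, start, side="right")) - 1
                    total[b] += 1
                    flagged[b] += ev.previous_map_dominant
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(total > 0, flagged / np.maximum(total, 1), np.nan)
    return {"bins": bins, "probability": prob, "n_cycles": total,
            "n_flagged": flagged}
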