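"""External drive to the network: theta modulation, place-locked input with
cue switching ("teleportation"), virtual/real trajectories, and colored noise.

The localized (place-specific) input to a unit is a thresholded cosine of the
distance between the unit's place-field centre and the animal position, per
torus dimension.  Its amplitude depends on whether the unit's map is the one
the current cues select: units of the current map receive A1 + A2, units of
the other map only A2 (the cue set splits into a switch-sensitive and a
switch-insensitive part).  Teleportation is an instantaneous change of which
map is "current" while the animal stays in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import SelectivityMap

__all__ = [
    "ThetaParams",
    "LocalizedParams",
    "NoiseParams",
    "Trajectory",
    "TeleportationSchedule",
    "theta_drive",
    "localized_drive",
    "noise_step",
    "make_trajectory",
    "load_trajectory",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ThetaParams:
    """Spatially uniform theta-modulated input A_theta * sin(2*pi*f_theta*t)."""

    A_theta: float = 13.0
    f_theta: float = 10.0

    def __post_init__(self) -> None:
        if self.A_theta < 0 or self.f_theta <= 0:
            raise ValueError("A_theta must be >= 0 and f_theta > 0")


@dataclass(frozen=True)
class LocalizedParams:
    """Amplitudes of the place-locked input: A1 is the switch-sensitive cue
    contribution (only the current map receives it), A2 the switch-insensitive
    one (all maps receive it).  The defaults put most of the drive in the
    stable component, so a cue switch tips the map competition by a small
    margin rather than overwhelming it — the regime in which synaptic
    rebound can transiently flip the winner."""

    A1: float = 0.5
    A2: float = 4.0

    def __post_init__(self) -> None:
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class NoiseParams:
    """Ornstein-Uhlenbeck (colored) noise: tau_N * d(eta)/dt = -eta + A_n * xi(t)
    with xi spatially uncorrelated Gaussian white noise of unit spectral
    density.  Stationary variance is A_n^2 / (2 * tau_N)."""

    A_n: float = 0.0
    tau_N: float = 0.01

    def __post_init__(self) -> None:
        if self.A_n < 0 or self.tau_N <= 0:
            raise ValueError("A_n must be >= 0 and tau_N > 0")


@dataclass
class Trajectory:
    """Animal position on the torus, either as a constant-speed diagonal run
    (phi1 = phi2 = phi0 + V*t) or as sampled angles interpolated in time."""

    V: float | None = None
    phi0: float = 0.0
    t: np.ndarray | None = None
    phi1: np.ndarray | None = None
    phi2: np.ndarray | None = None

    def positions(self, times) -> tuple[np.ndarray, np.ndarray]:
        """Angles (phi1, phi2) in [0, 2*pi) at the given times (s)."""
        times = np.asarray(times, dtype=np.float64)
        if self.V is not None:
            p = np.mod(self.phi0 + self.V * times, TWO_PI)
            return p, p.copy()
        # interpolate each coordinate via its unwrapped angle to avoid
        # spurious jumps at the 0/2*pi seam
        p1 = np.mod(np.interp(times, self.t, np.unwrap(self.phi1)), TWO_PI)
        p2 = np.mod(np.interp(times, self.t, np.unwrap(self.phi2)), TWO_PI)
        return p1, p2


def make_trajectory(V: float, phi0: float = 0.0) -> Trajectory:
    """Constant-speed diagonal trajectory phi1(t) = phi2(t) = phi0 + V*t."""
    if V < 0:
        raise ValueError("V must be non-negative")
    return Trajectory(V=V, phi0=phi0)


def load_trajectory(path, arena_side: float | None = None) -> Trajectory:
    """Load a delimited (t, x, y) table (seconds, cm) and map the arena onto
    the torus by scaling each coordinate of the bounding box to [0, 2*pi).

    A header row naming the columns t, x, y is required.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        t = df[cols["t"]].to_numpy(float)
        x = df[cols["x"]].to_numpy(float)
        y = df[cols["y"]].to_numpy(float)
    except KeyError as e:
        raise ValueError(f"trajectory file must have columns t, x, y (missing {e})")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)) or np.any(~np.isfinite(t)):
        raise ValueError("trajectory contains NaN/inf coordinates")
    if np.any(np.diff(t) <= 0):
        raise ValueError("trajectory timestamps must be strictly increasing")

    def to_angle(v):
        lo, hi = v.min(), v.max()
        side = arena_side if arena_side is not None else (hi - lo)
        if side <= 0:
            return np.zeros_like(v)
        return np.clip((v - lo) / side, 0.0, 1.0 - 1e-12) * TWO_PI

    return Trajectory(t=t, phi1=to_angle(x), phi2=to_angle(y))


@dataclass
class TeleportationSchedule:
    """Which map the cues currently select, as a function of time.

    ``initial_map`` holds before the first switch; ``switches`` is an ordered
    list of (switch_time, new_current_map) with maps indexed 0/1.
    """

    initial_map: int = 0
    switches: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [s[0] for s in self.switches]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("switch times must be strictly increasing")

    def current_map(self, t: float) -> int:
        cur = self.initial_map
        for ts, k in self.switches:
            if t >= ts:
                cur = k
            else:
                break
        return cur

    def previous_map(self, t: float) -> int | None:
        """Map that was current before the most recent switch at or before t."""
        prev = None
        cur = self.initial_map
        for ts, k in self.switches:
            if t >= ts:
                prev, cur = cur, k
            else:
                break
        return prev


# ---------------------------------------------------------------------------
# Drive terms
# ---------------------------------------------------------------------------

def theta_drive(t, p: ThetaParams):
    """Uniform theta input A_theta * sin(2*pi*f_theta*t), identical for all units."""
    return p.A_theta * np.sin(TWO_PI * p.f_theta * np.asarray(t, dtype=np.float64))


def localized_drive(unit: int, t: float, sel: SelectivityMap, traj: Trajectory,
                    sched: TeleportationSchedule, p: LocalizedParams) -> float:
    """Place-locked input to one unit at time t.

    For each map the unit belongs to, adds
    amplitude_k * ([cos(phi_center1 - phi1)]_+ + [cos(phi_center2 - phi2)]_+)
    with amplitude_k = A1 + A2 for the current map and A2 otherwise.  A
    dual-member unit is driven through both of its place fields.
    """
    if not sel.membership[unit].any():
        raise ValueError(f"unit {unit} belongs to no map")
    phi1, phi2 = traj.positions(t)
    cur = sched.current_map(t)
    total = 0.0
    for k in range(sel.membership.shape[1]):
        if not sel.membership[unit, k]:
            continue
        amp = p.A1 + p.A2 if k == cur else p.A2
        c1, c2 = sel.centers[unit, k]
        total += amp * (max(np.cos(c1 - phi1), 0.0) + max(np.cos(c2 - phi2), 0.0))
    return float(total)


def localized_drive_all(t: float, sel: SelectivityMap, traj: Trajectory,
                        sched: TeleportationSchedule, p: LocalizedParams) -> np.ndarray:
    """Vectorized localized input for all units at time t."""
    phi1, phi2 = traj.positions(t)
    cur = sched.current_map(t)
    out = np.zeros(sel.n_units)
    for k in range(sel.membership.shape[1]):
        amp = p.A1 + p.A2 if k == cur else p.A2
        idx = sel.members(k)
        c1 = sel.centers[idx, k, 0]
        c2 = sel.centers[idx, k, 1]
        out[idx] += amp * (np.maximum(np.cos(c1 - phi1), 0.0)
                           + np.maximum(np.cos(c2 - phi2), 0.0))
    return out


def noise_step(eta: np.ndarray, dt: float, p: NoiseParams,
               rng: np.random.Generator) -> np.ndarray:
    """One Euler-Maruyama step of the colored-noise process.

    eta <- eta + (dt/tau_N)(-eta) + (A_n/tau_N) * sqrt(dt) * z, z ~ N(0, 1) iid.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = rng.standard_normal(eta.shape)
    return eta + (dt / p.tau_N) * (-eta) + (p.A_n / p.tau_N) * np.sqrt(dt) * z
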