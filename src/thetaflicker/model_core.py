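"""Network construction and short-term synaptic plasticity primitives.

The model is a continuous attractor neural network (CANN) storing two
independent spatial maps.  Each map is a torus of rate units; a unit's
place-field centre is a pair of angles (one per torus dimension).  Units are
assigned to maps at random, so a fraction of them participate in both maps
(the overlap that makes "flickering" between maps informative).  Recurrent
excitation falls off with the cosine of the angular distance between
place-field centres within each shared map, and a uniform inhibitory term
couples all units, producing a winner-take-all competition between maps.

Synapses are dynamic: the release probability ``u`` facilitates with
presynaptic rate and recovers to its baseline ``U`` with time constant
``tau_f``, while the resource fraction ``x`` depresses and recovers with
``tau_r``.  The momentary efficacy is the product ``u*x``.  Because ``x``
typically recovers faster than ``u`` decays, the efficacy transiently
overshoots its baseline after a burst of activity ends — the synaptic
rebound that lets the previously expressed map win theta-cycle competitions
for a few seconds after a cue switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SelectivityMap",
    "ConnectivityParams",
    "NeuronParams",
    "STPParams",
    "NetworkState",
    "assign_selectivity",
    "build_connectivity",
    "transfer",
    "stp_derivatives",
    "stp_steady_state",
    "integrate_stp",
    "rebound_response",
]

N_MAPS = 2


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectivityParams:
    """Connectivity kernel parameters, in units of the 2*pi/N weight scale.

    ``J1`` multiplies the cosine-shaped excitation for each shared map;
    ``J0_magnitude`` is the strength of the uniform all-to-all inhibition
    (entered as a magnitude; the matrix receives ``-J0_magnitude``).
    ``include_self`` keeps the diagonal, treating each unit as a pool of
    neurons with within-pool recurrence.
    """

    J1: float = 14.0
    J0_magnitude: float = 18.0
    include_self: bool = True

    def __post_init__(self) -> None:
        if self.J1 <= 0 or self.J0_magnitude <= 0:
            raise ValueError("J1 and J0_magnitude must be positive")


@dataclass(frozen=True)
class NeuronParams:
    """Rate-unit parameters: time constant tau (s), transfer smoothness
    alpha (Hz) and background input I0 (Hz)."""

    tau: float = 0.01
    alpha: float = 1.0
    I0: float = -1.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.alpha <= 0:
            raise ValueError("tau and alpha must be positive")


@dataclass(frozen=True)
class STPParams:
    """Short-term plasticity parameters.

    U : baseline release probability, in (0, 1].
    tau_r : recovery time of synaptic resources x (depression), seconds.
    tau_f : decay time of the release probability u (facilitation), seconds.
    """

    U: float = 0.25
    tau_r: float = 0.6
    tau_f: float = 1.9

    def __post_init__(self) -> None:
        if not (0.0 < self.U <= 1.0):
            raise ValueError("U must lie in (0, 1]")
        if self.tau_r <= 0 or self.tau_f <= 0:
            raise ValueError("tau_r and tau_f must be positive")


@dataclass
class NetworkState:
    """Instantaneous state: time, rates m (Hz), release probabilities u and
    resource fractions x per unit."""

    t: float
    m: np.ndarray
    u: np.ndarray
    x: np.ndarray


# ---------------------------------------------------------------------------
# Selectivity assignment
# ---------------------------------------------------------------------------

@dataclass
class SelectivityMap:
    """Map membership and place-field centres for all simulated units.

    membership : (n_units, 2) bool — unit i belongs to map k.
    centers : (n_units, 2, 2) float — angles (phi^k_1, phi^k_2) on [0, 2*pi)
        for each map the unit belongs to; NaN where not a member.
    """

    n_units: int
    membership: np.ndarray
    centers: np.ndarray
    f: float
    grid_size: int = 50

    @property
    def n_per_map(self) -> int:
        return self.grid_size ** 2

    @property
    def n_total(self) -> int:
        """Nominal network size N = 2 * n_per_map used in the weight scale."""
        return N_MAPS * self.n_per_map

    def members(self, k: int) -> np.ndarray:
        """Indices of units belonging to map k (0 or 1)."""
        return np.flatnonzero(self.membership[:, k])

    def dual_fraction(self) -> float:
        return float(self.membership.all(axis=1).mean())


def assign_selectivity(n_per_map: int, f: float = 0.25, seed: int = 0) -> SelectivityMap:
    """Randomly assign units to two maps and place them on each map's grid.

    Units are drawn from a large pool, each joining map k independently with
    probability ``f``; units in neither map are discarded, and draws that
    would overfill an already complete map are discarded, so that each map
    ends with exactly ``n_per_map`` members.  Within a map, members are
    assigned bijectively (seeded shuffle) to the nodes of the regular
    grid_size x grid_size lattice on the torus, independently per map, so a
    dual-member unit's two centres are statistically independent — global
    remapping by construction.
    """
    if not (0.0 < f < 1.0):
        raise ValueError("f must lie strictly between 0 and 1")
    grid_size = math.isqrt(n_per_map)
    if grid_size * grid_size != n_per_map:
        raise ValueError(f"n_per_map={n_per_map} is not a perfect square")

    rng = np.random.default_rng(seed)
    counts = [0, 0]
    rows: list[tuple[bool, bool]] = []
    while min(counts) < n_per_map:
        draws = rng.random((max(256, n_per_map // 4), 2)) < f
        for a, b in draws:
            if not (a or b):
                continue
            if (a and counts[0] >= n_per_map) or (b and counts[1] >= n_per_map):
                continue  # would overfill a complete map
            rows.append((a, b))
            counts[0] += a
            counts[1] += b
            if min(counts) >= n_per_map:
                break

    membership = np.array(rows, dtype=bool)
    n_units = membership.shape[0]
    centers = np.full((n_units, N_MAPS, 2), np.nan)
    node = (np.arange(grid_size) + 0.0) * (2.0 * np.pi / grid_size)
    grid = np.stack(np.meshgrid(node, node, indexing="ij"), axis=-1).reshape(-1, 2)
    for k in range(N_MAPS):
        idx = np.flatnonzero(membership[:, k])
        perm = rng.permutation(n_per_map)
        centers[idx, k, :] = grid[perm]

    return SelectivityMap(n_units=n_units, membership=membership,
                          centers=centers, f=f, grid_size=grid_size)


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def build_connectivity(sel: SelectivityMap, cp: ConnectivityParams) -> np.ndarray:
    """Symmetric weight matrix combining per-map cosine excitation and
    uniform inhibition.

    W[i, j] = (2*pi/N) * [ J1 * sum_{k shared} (cos d1 + cos d2) - J0_magnitude ]

    with N = 2 * n_per_map; the inhibitory term is counted once per unit
    pair regardless of how many maps the pair shares.
    """
    scale = 2.0 * np.pi / sel.n_total
    W = np.full((sel.n_units, sel.n_units), -cp.J0_magnitude, dtype=np.float64)
    for k in range(N_MAPS):
        idx = sel.members(k)
        c1 = sel.centers[idx, k, 0]
        c2 = sel.centers[idx, k, 1]
        block = cp.J1 * (np.cos(c1[:, None] - c1[None, :])
                         + np.cos(c2[:, None] - c2[None, :]))
        W[np.ix_(idx, idx)] += block
    W *= scale
    if not cp.include_self:
        np.fill_diagonal(W, 0.0)
    return W


# ---------------------------------------------------------------------------
# Transfer function
# ---------------------------------------------------------------------------

def transfer(z, alpha: float = 1.0):
    """Smooth threshold-linear transfer g(z) = alpha * log(1 + exp(z/alpha)).

    Exponential for large negative input, linear for large positive input;
    ``alpha`` sets the width of the transition.  Overflow-safe: for
    z/alpha > 30 the linear branch z + alpha*exp(-z/alpha) is used.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    z = np.asarray(z, dtype=np.float64)
    za = z / alpha
    out = np.where(za > 30.0,
                   z + alpha * np.exp(-np.clip(za, 30.0, None)),
                   alpha * np.log1p(np.exp(np.clip(za, None, 30.0))))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Short-term plasticity
# ---------------------------------------------------------------------------

def stp_derivatives(u, x, m, p: STPParams):
    """Time derivatives of the release probability and resource fraction.

    du/dt = (U - u)/tau_f + U * (1 - u) * m
    dx/dt = (1 - x)/tau_r - u * x * m
    """
    du = (p.U - np.asarray(u)) / p.tau_f + p.U * (1.0 - np.asarray(u)) * np.asarray(m)
    dx = (1.0 - np.asarray(x)) / p.tau_r - np.asarray(u) * np.asarray(x) * np.asarray(m)
    return du, dx


def stp_steady_state(m, p: STPParams):
    """Closed-form fixed point of the plasticity dynamics at constant rate m.

    u* = U (1 + tau_f m) / (1 + U tau_f m);  x* = 1 / (1 + u* tau_r m).
    """
    m = np.asarray(m, dtype=np.float64)
    u = p.U * (1.0 + p.tau_f * m) / (1.0 + p.U * p.tau_f * m)
    x = 1.0 / (1.0 + u * p.tau_r * m)
    if m.ndim:
        return u, x
    return float(u), float(x)


def integrate_stp(m_of_t, duration: float, p: STPParams,
                  u0: float | None = None, x0: float = 1.0,
                  rtol: float = 1e-10, atol: float = 1e-12,
                  t_eval: np.ndarray | None = None):
    """Integrate the single-synapse plasticity ODEs under a rate programme.

    ``m_of_t`` is a scalar function of time (Hz).  Returns the solve_ivp
    result with y = [u, x].
    """
    if u0 is None:
        u0 = p.U

    def rhs(t, y):
        du, dx = stp_derivatives(y[0], y[1], m_of_t(t), p)
        return [du, dx]

    return solve_ivp(rhs, (0.0, duration), [u0, x0], rtol=rtol, atol=atol,
                     t_eval=t_eval, dense_output=t_eval is None, max_step=duration / 50)


@dataclass(frozen=True)
class ReboundResult:
    amplitude: float          # max(0, peak post-offset efficacy - U)
    amplitude_unfloored: float
    t_peak: float             # time of the post-offset efficacy peak (s after offset)


def rebound_response(pulse_rate: float, pulse_duration: float, p: STPParams,
                     settle_factor: float = 5.0) -> ReboundResult:
    """Peak post-pulse overshoot of the synaptic efficacy u*x above baseline U.

    The synapse starts at baseline (u=U, x=1), receives a constant rate pulse
    of ``pulse_rate`` Hz for ``pulse_duration`` s, then relaxes at m=0.  The
    relaxation is evaluated in closed form (both variables decay
    exponentially at m=0) on a dense grid spanning at least
    ``settle_factor * max(tau_r, tau_f)``.
    """
    if pulse_rate < 0:
        raise ValueError("pulse_rate must be non-negative")
    if pulse_rate == 0:
        return ReboundResult(0.0, 0.0, 0.0)

    sol = integrate_stp(lambda t: pulse_rate, pulse_duration, p)
    u_off, x_off = sol.y[0, -1], sol.y[1, -1]

    horizon = settle_factor * max(p.tau_r, p.tau_f)
    t = np.linspace(0.0, horizon, 20001)
    u_t = p.U + (u_off - p.U) * np.exp(-t / p.tau_f)
    x_t = 1.0 + (x_off - 1.0) * np.exp(-t / p.tau_r)
    eff = u_t * x_t - p.U
    i = int(np.argmax(eff))
    peak = float(eff[i])
    return ReboundResult(max(0.0, peak), peak, float(t[i]))
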