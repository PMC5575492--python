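"""Theta-cycle analysis of recorded (or synthetic) sessions.

This is the data-side counterpart of the model: given a session bundle of
spike trains, LFP, position tracking and trial metadata, it

1. speed-filters the tracking (valid epochs: 5 cm/s < speed <= 100 cm/s,
   no tracking gaps > 0.05 s),
2. builds occupancy-normalized rate maps (30 x 30 bins of 2 cm, smoothed
   with a fixed 5x5 Gaussian kernel) from the reference sessions,
3. segments teleportation trials into theta cycles using the LFP (hamming
   band-pass 5/6-10/11 Hz, spike phases interpolated peak->trough, cycles
   cut at the phase of minimal population firing),
4. forms per-cycle population vectors of cell firing rates and correlates
   them with each environment's expected rates at the animal's position,
5. classifies flickering events (cycles significantly anti-correlated with
   the current environment and correlated with the other one, thresholds
   from the reference-session correlation distributions), and
6. relates per-trial flicker rates to theta power and distance from the
   switching position via permutation-tested partial correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .flicker_detection import ThetaCycles

__all__ = [
    "SessionBundle",
    "Trial",
    "RateMapSet",
    "CycleVector",
    "DataFlickerEvent",
    "TrialStats",
    "GAUSSIAN_KERNEL",
    "speed_filter",
    "compute_rate_maps",
    "lfp_theta_filter",
    "assign_spike_phases",
    "segment_by_min_phase",
    "cycle_vectors",
    "correlation_thresholds",
    "detect_flickers",
    "trial_statistics",
    "partial_correlation_analysis",
]

# Fixed 5x5 smoothing kernel for rate maps (weights sum to 1 exactly).
GAUSSIAN_KERNEL = np.array([
    [0.0025, 0.0125, 0.0200, 0.0125, 0.0025],
    [0.0125, 0.0625, 0.1000, 0.0625, 0.0125],
    [0.0200, 0.1000, 0.1600, 0.1000, 0.0200],
    [0.0125, 0.0625, 0.1000, 0.0625, 0.0125],
    [0.0025, 0.0125, 0.0200, 0.0125, 0.0025],
])

N_BINS = 30
BIN_SIZE_CM = 2.0

SPEED_MIN_CMS = 5.0
SPEED_MAX_CMS = 100.0
MAX_GAP_S = 0.05


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """One behavioural epoch: a reference session in a single environment or
    a teleportation trial with a cue switch."""

    kind: str                      # "reference_A" | "reference_B" | "teleportation"
    interval: tuple[float, float]  # [start, end) in session time (s)
    environment: str | None = None # env label of a reference trial ("A"/"B")
    switch_time: float | None = None
    env_before: str = "A"
    env_after: str = "B"


@dataclass
class SessionBundle:
    """Spikes + LFP + tracking + trial metadata for one recording session."""

    tracking_t: np.ndarray         # (T,) s, strictly increasing
    tracking_xy: np.ndarray        # (T, 2) cm
    spikes: list[np.ndarray]       # per-cell spike times (s)
    lfp: np.ndarray                # (L,) a.u.
    lfp_fs: float                  # Hz, >= 250
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lfp_fs < 250:
            raise ValueError("LFP sampling rate must be >= 250 Hz")
        if np.any(np.diff(self.tracking_t) <= 0):
            raise ValueError("tracking timestamps must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return len(self.spikes)

    def trials_of(self, kind: str) -> list[Trial]:
        return [tr for tr in self.trials if tr.kind == kind]


@dataclass
class RateMapSet:
    """Per-cell, per-environment smoothed rate maps plus occupancy.

    maps[env] : (n_cells, 30, 30) Hz, NaN in unvisited bins.
    occupancy[env] : (30, 30) seconds of valid dwell time.
    """

    maps: dict[str, np.ndarray]
    occupancy: dict[str, np.ndarray]
    arena_origin: np.ndarray       # lower-left corner (cm) used for binning
    bin_size: float = BIN_SIZE_CM
    _filled: dict = field(default_factory=dict, repr=False)

    def expected_rates(self, env: str, x: float, y: float,
                       fill: str = "nearest") -> np.ndarray:
        """Per-cell rate-map value at the bin containing position (x, y).

        Unvisited bins hold NaN in the canonical maps; with the default
        ``fill='nearest'`` the value of the nearest visited bin is returned
        instead, so cycle vectors recorded over briefly-unvisited spots can
        still be correlated.  ``fill='nan'`` returns the raw values.
        """
        i, j = self.bin_of(x, y)
        if fill == "nearest":
            if env not in self._filled:
                from scipy.ndimage import distance_transform_edt
                m = self.maps[env]
                visited = np.isfinite(m[0])
                _, (ii, jj) = distance_transform_edt(
                    ~visited, return_indices=True)
                self._filled[env] = m[:, ii, jj]
            return self._filled[env][:, i, j]
        return self.maps[env][:, i, j]

    def bin_of(self, x: float, y: float) -> tuple[int, int]:
        i = int(np.clip((x - self.arena_origin[0]) / self.bin_size, 0, N_BINS - 1))
        j = int(np.clip((y - self.arena_origin[1]) / self.bin_size, 0, N_BINS - 1))
        return i, j


@dataclass
class CycleVector:
    """Population vector for one theta cycle."""

    interval: tuple[float, float]
    rates: np.ndarray              # (n_cells,) Hz
    position: tuple[float, float]  # cm, tracking at cycle midpoint
    valid: bool = True             # passes the speed/tracking criteria


@dataclass
class DataFlickerEvent:
    """A teleportation-trial cycle classified as expressing the other map."""

    cycle_index: int
    interval: tuple[float, float]
    corr_current: float
    corr_other: float
    low_threshold: float
    high_threshold: float
    flagged: bool


@dataclass
class TrialStats:
    """Per-teleportation-trial summary statistics."""

    flicker_rate: float            # events/s, normalized by usable time
    theta_power: float             # band power 5-10 Hz / band power 1-125 Hz
    mean_distance: float           # cm from the switching position
    mean_speed: float              # cm/s over valid epochs
    mean_rate: float               # Hz, population mean firing rate (control)
    p_lowV: float                  # fraction of cycles lost to low speed/artifacts
    excluded: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# 1. Speed / artifact filtering
# ---------------------------------------------------------------------------

def speed_filter(tracking_t: np.ndarray, tracking_xy: np.ndarray):
    """Validity mask over tracking samples plus the speed series (cm/s).

    A sample is invalid when the running speed is <= 5 cm/s (immobility),
    > 100 cm/s (tracking artifact), or the sample closes a tracking gap
    longer than 0.05 s.  Speed uses centered finite differences.
    """
    t = np.asarray(tracking_t, dtype=np.float64)
    xy = np.asarray(tracking_xy, dtype=np.float64)
    if t.size < 2:
        raise ValueError("need at least two tracking samples")
    speed = np.empty(t.size)
    d = xy[2:] - xy[:-2]
    speed[1:-1] = np.hypot(d[:, 0], d[:, 1]) / (t[2:] - t[:-2])
    speed[0] = np.hypot(*(xy[1] - xy[0])) / (t[1] - t[0])
    speed[-1] = np.hypot(*(xy[-1] - xy[-2])) / (t[-1] - t[-2])
    valid = (speed > SPEED_MIN_CMS) & (speed <= SPEED_MAX_CMS)
    gap = np.diff(t) > MAX_GAP_S
    # both endpoints of a long gap border missing data
    valid[1:][gap] = False
    valid[:-1][gap] = False
    return valid, speed


def _interp_position(tracking_t, tracking_xy, times):
    x = np.interp(times, tracking_t, tracking_xy[:, 0])
    y = np.interp(times, tracking_t, tracking_xy[:, 1])
    return x, y


def valid_fraction(tracking_t, valid, lo: float, hi: float) -> float:
    """Fraction of [lo, hi) covered by valid tracking samples."""
    sel = (tracking_t >= lo) & (tracking_t < hi)
    if not sel.any():
        return 0.0
    return float(valid[sel].mean())


# ---------------------------------------------------------------------------
# 2. Rate maps
# ---------------------------------------------------------------------------

def smooth_rate_map(rate: np.ndarray, visited: np.ndarray) -> np.ndarray:
    """5x5 Gaussian smoothing with edge/hole renormalization.

    Each output bin is the kernel-weighted mean over *visited* bins only;
    weights falling outside the map or on unvisited bins are renormalized
    away.  Unvisited bins stay NaN.
    """
    filled = np.where(visited, rate, 0.0)
    num = signal.convolve2d(filled, GAUSSIAN_KERNEL, mode="same", boundary="fill")
    den = signal.convolve2d(visited.astype(float), GAUSSIAN_KERNEL,
                            mode="same", boundary="fill")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~visited] = np.nan
    return out


def compute_rate_maps(bundle: SessionBundle,
                      arena_origin: tuple[float, float] | None = None,
                      renormalize_edges: bool = True) -> RateMapSet:
    """Occupancy-normalized, smoothed rate maps from the reference trials.

    The speed filter is applied first: only valid tracking epochs contribute
    occupancy, and only spikes within valid epochs are counted.  With
    ``renormalize_edges`` false the raw kernel is applied everywhere
    (zero-padded), which does not conserve rate mass near edges.
    """
    valid, _ = speed_filter(bundle.tracking_t, bundle.tracking_xy)
    t = bundle.tracking_t
    dt = np.empty_like(t)
    dt[:-1] = np.diff(t)
    dt[-1] = dt[-2] if t.size > 1 else 0.0
    origin = (np.asarray(arena_origin, dtype=np.float64)
              if arena_origin is not None else bundle.tracking_xy.min(axis=0))

    maps: dict[str, np.ndarray] = {}
    occs: dict[str, np.ndarray] = {}
    for env in ("A", "B"):
        trials = [tr for tr in bundle.trials
                  if tr.kind.startswith("reference") and tr.environment == env]
        if not trials:
            continue
        in_trial = np.zeros(t.size, dtype=bool)
        for tr in trials:
            in_trial |= (t >= tr.interval[0]) & (t < tr.interval[1])
        use = in_trial & valid
        if not use.any():
            raise ValueError(f"no valid tracking in reference trials of env {env}")

        ix = np.clip(((bundle.tracking_xy[:, 0] - origin[0]) / BIN_SIZE_CM
                      ).astype(int), 0, N_BINS - 1)
        iy = np.clip(((bundle.tracking_xy[:, 1] - origin[1]) / BIN_SIZE_CM
                      ).astype(int), 0, N_BINS - 1)
        occ = np.zeros((N_BINS, N_BINS))
        np.add.at(occ, (ix[use], iy[use]), dt[use])
        visited = occ > 0

        env_maps = np.empty((bundle.n_cells, N_BINS, N_BINS))
        for ci, st in enumerate(bundle.spikes):
            st = np.asarray(st)
            keep = np.zeros(st.size, dtype=bool)
            for tr in trials:
                keep |= (st >= tr.interval[0]) & (st < tr.interval[1])
            # spikes only count when tracking at spike time is valid
            iv = np.searchsorted(t, st[keep]).clip(0, t.size - 1)
            keep2 = valid[iv]
            sx, sy = _interp_position(t, bundle.tracking_xy, st[keep][keep2])
            sxi = np.clip(((sx - origin[0]) / BIN_SIZE_CM).astype(int), 0, N_BINS - 1)
            syi = np.clip(((sy - origin[1]) / BIN_SIZE_CM).astype(int), 0, N_BINS - 1)
            cnt = np.zeros((N_BINS, N_BINS))
            np.add.at(cnt, (sxi, syi), 1.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(visited, cnt / occ, 0.0)
            if renormalize_edges:
                env_maps[ci] = smooth_rate_map(rate, visited)
            else:
                env_maps[ci] = signal.convolve2d(rate, GAUSSIAN_KERNEL,
                                                 mode="same", boundary="fill")
                env_maps[ci][~visited] = np.nan
        maps[env] = env_maps
        occs[env] = occ
    if not maps:
        raise ValueError("bundle has no reference trials")
    return RateMapSet(maps=maps, occupancy=occs, arena_origin=origin)


# ---------------------------------------------------------------------------
# 3. LFP filtering, spike phases, cycle segmentation
# ---------------------------------------------------------------------------

def lfp_theta_filter(lfp: np.ndarray, fs: float) -> np.ndarray:
    """Linear-phase FIR theta filter (hamming window), zero net delay.

    Transition bands 5-6 Hz (low side) and 10-11 Hz (high side): the 6 dB
    cutoffs sit mid-transition at 5.5 and 10.5 Hz, and the filter length is
    chosen for a ~1 Hz hamming transition width.
    """
    if fs < 250:
        raise ValueError("LFP sampling rate must be >= 250 Hz")
    n_taps = int(np.ceil(3.3 * fs / 1.0))
    n_taps += 1 - n_taps % 2                      # odd length, type-I FIR
    taps = signal.firwin(n_taps, [5.5, 10.5], pass_zero=False,
                         window="hamming", fs=fs)
    return signal.filtfilt(taps, [1.0], np.asarray(lfp, dtype=np.float64),
                           padlen=min(3 * n_taps, len(lfp) - 1))


def _peaks_troughs(filtered: np.ndarray, fs: float):
    """Interleaved peak and trough samples of the theta-filtered LFP."""
    dist = max(1, int(round(fs / 12.0 * 0.5)))
    prom = 0.05 * np.std(filtered)
    peaks, _ = signal.find_peaks(filtered, distance=dist, prominence=prom)
    troughs, _ = signal.find_peaks(-filtered, distance=dist, prominence=prom)
    return peaks, troughs


def assign_spike_phases(filtered: np.ndarray, fs: float,
                        spike_times: np.ndarray,
                        t0: float = 0.0):
    """Linear-interpolated theta phase (degrees) of each spike.

    Phase runs 0 deg at an LFP peak, 180 deg at the next trough, 360 deg at
    the following peak; within each half-cycle the phase is linear in time,
    so every interpolation spans a 180 deg range.  Spikes outside the first/
    last extremum bracket are dropped; returns (phases, kept_mask).
    """
    peaks, troughs = _peaks_troughs(filtered, fs)
    if len(peaks) == 0 or len(troughs) == 0:
        raise ValueError("no identifiable theta peaks/troughs")
    # merged, ordered extrema: (sample, is_peak)
    ext = np.concatenate([peaks, troughs])
    kinds = np.concatenate([np.ones(len(peaks), bool), np.zeros(len(troughs), bool)])
    order = np.argsort(ext)
    ext, kinds = ext[order], kinds[order]
    # enforce alternation: collapse runs of the same kind to their extremum
    keep = np.ones(ext.size, dtype=bool)
    for i in range(1, ext.size):
        if kinds[i] == kinds[i - 1]:
            # keep the more extreme of the two
            a, b = ext[i - 1], ext[i]
            better_prev = (filtered[a] > filtered[b]) == kinds[i]
            keep[i - 1 if not better_prev else i] = False
    ext, kinds = ext[keep], kinds[keep]

    ext_t = t0 + ext / fs
    # cumulative phase: 0 at first peak, +180 deg at each successive extremum
    base = np.arange(ext.size) * 180.0
    base += 0.0 if kinds[0] else 180.0            # start at trough -> offset
    spike_times = np.asarray(spike_times, dtype=np.float64)
    kept = (spike_times >= ext_t[0]) & (spike_times <= ext_t[-1])
    cum = np.interp(spike_times[kept], ext_t, base)
    return np.mod(cum, 360.0), kept


def segment_by_min_phase(filtered: np.ndarray, fs: float,
                         spike_times: np.ndarray,
                         t0: float = 0.0,
                         bin_deg: float = 20.0) -> ThetaCycles:
    """Cut theta cycles at the phase with minimal population firing.

    Builds an 18-bin phase histogram of all spikes, takes the minimal-rate
    bin (ties -> lowest phase) and cuts the signal at every crossing of that
    bin's centre phase.
    """
    spike_times = np.asarray(spike_times, dtype=np.float64)
    if spike_times.size == 0:
        raise ValueError("no spikes to build a phase histogram from")
    phases, kept = assign_spike_phases(filtered, fs, spike_times, t0=t0)
    nb = int(round(360.0 / bin_deg))
    hist, _ = np.histogram(phases, bins=nb, range=(0.0, 360.0))
    cut_phase = (np.argmin(hist) + 0.5) * bin_deg

    peaks, troughs = _peaks_troughs(filtered, fs)
    ext = np.sort(np.concatenate([peaks, troughs]))
    # reconstruct the cumulative-phase timeline as in assign_spike_phases
    ph, _ = assign_spike_phases(filtered, fs, t0 + ext / fs, t0=t0)
    # crossing times of cut_phase: one per 360 deg wrap
    ext_t = t0 + ext / fs
    cum = np.interp(ext_t, ext_t, ext_t)  # placeholder, replaced below
    # simpler: evaluate cumulative phase on the extremum grid directly
    is_peak = np.isin(ext, peaks)
    base = np.arange(ext.size) * 180.0
    base += 0.0 if is_peak[0] else 180.0
    # cumulative phase passes cut_phase + 360*k between consecutive extrema
    cuts = []
    k0 = int(np.floor(base[0] / 360.0))
    for i in range(ext.size - 1):
        lo, hi = base[i], base[i + 1]
        k = np.ceil((lo - cut_phase) / 360.0)
        target = cut_phase + 360.0 * k
        while target < hi:
            frac = (target - lo) / (hi - lo)
            cuts.append(ext_t[i] + frac * (ext_t[i + 1] - ext_t[i]))
            target += 360.0
    cuts = np.asarray(cuts)
    if cuts.size < 2:
        return ThetaCycles(intervals=np.empty((0, 2)), fs=fs)
    return ThetaCycles(intervals=np.column_stack([cuts[:-1], cuts[1:]]), fs=fs)


# ---------------------------------------------------------------------------
# 4. Cycle population vectors
# ---------------------------------------------------------------------------

def cycle_vectors(bundle: SessionBundle, cycles: ThetaCycles,
                  max_invalid_fraction: float = 0.25) -> list[CycleVector]:
    """Per-cycle, per-cell firing rates and the cycle-midpoint position.

    Cycles whose invalid-tracking time fraction exceeds
    ``max_invalid_fraction`` are kept but marked invalid (they still count
    toward p_lowV in trial statistics).
    """
    valid, _ = speed_filter(bundle.tracking_t, bundle.tracking_xy)
    out = []
    spike_arrays = [np.asarray(st) for st in bundle.spikes]
    for ci, (start, end) in enumerate(cycles.intervals):
        dur = end - start
        rates = np.array([
            np.count_nonzero((st >= start) & (st < end)) / dur
            for st in spike_arrays])
        mid = 0.5 * (start + end)
        x, y = _interp_position(bundle.tracking_t, bundle.tracking_xy, [mid])
        ok = valid_fraction(bundle.tracking_t, valid, start, end) \
            >= 1.0 - max_invalid_fraction
        out.append(CycleVector(interval=(start, end), rates=rates,
                               position=(float(x[0]), float(y[0])), valid=ok))
    return out


# ---------------------------------------------------------------------------
# 5. Correlation thresholds and flicker detection
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def correlation_thresholds(ref_vectors: dict[str, list[CycleVector]],
                           maps: RateMapSet):
    """5th/95th percentile thresholds from reference-cycle correlations.

    For each reference cycle of environment e, the population vector is
    correlated with the expected-rate vector of each environment (per-cell
    rate-map values at the cycle's position).  Per environment e this yields
    a same-environment distribution (cycles recorded in e vs map e) and an
    other-environment distribution (cycles of the other environment vs map
    e).  Returns ``(low, high, dists)`` where ``low[e]`` is the 5th
    percentile of the same-environment distribution (the "significantly
    low" bound for map e) and ``high[e]`` the 95th percentile of the
    other-environment distribution; percentiles use linear interpolation.
    Zero-variance cycles are skipped and counted in ``dists['skipped']``.
    """
    envs = list(ref_vectors)
    dists: dict = {e: {"same": [], "other": []} for e in envs}
    skipped = 0
    for e in envs:
        for cv in ref_vectors[e]:
            if not cv.valid:
                continue
            for target in envs:
                expected = maps.expected_rates(target, *cv.position)
                r = _pearson(cv.rates, expected)
                if np.isnan(r):
                    skipped += 1
                    continue
                dists[target]["same" if target == e else "other"].append(r)
    low = {}
    high = {}
    for e in envs:
        same = np.asarray(dists[e]["same"])
        other = np.asarray(dists[e]["other"])
        if same.size < 10 or other.size < 10:
            raise ValueError(f"too few reference cycles for env {e}")
        low[e] = float(np.percentile(same, 5.0))
        high[e] = float(np.percentile(other, 95.0))
    dists["skipped"] = skipped
    return low, high, dists


def detect_flickers(vectors: list[CycleVector], maps: RateMapSet,
                    low: dict[str, float], high: dict[str, float],
                    trial: Trial) -> tuple[list[DataFlickerEvent], int | None]:
    """Classify teleportation-trial cycles; also report the first transition.

    A cycle is a flickering event when its correlation with the current
    environment's map is at or below that map's low threshold AND its
    correlation with the other map is at or above the other map's high
    threshold (both conditions required).  The first network transition is
    the first post-switch cycle whose correlation with the new map exceeds
    that with the old map.
    """
    if trial.switch_time is None:
        raise ValueError("trial has no switch_time")
    events = []
    first_transition = None
    for ci, cv in enumerate(vectors):
        start = cv.interval[0]
        cur = trial.env_after if start >= trial.switch_time else trial.env_before
        oth = trial.env_before if cur == trial.env_after else trial.env_after
        rc = _pearson(cv.rates, maps.expected_rates(cur, *cv.position))
        ro = _pearson(cv.rates, maps.expected_rates(oth, *cv.position))
        flagged = (cv.valid and np.isfinite(rc) and np.isfinite(ro)
                   and rc <= low[cur] and ro >= high[oth])
        events.append(DataFlickerEvent(
            cycle_index=ci, interval=cv.interval, corr_current=rc,
            corr_other=ro, low_threshold=low[cur], high_threshold=high[oth],
            flagged=bool(flagged)))
        if (first_transition is None and start >= trial.switch_time
                and cv.valid and np.isfinite(rc) and np.isfinite(ro)
                and cur == trial.env_after and rc > ro):
            first_transition = ci
    return events, first_transition


# ---------------------------------------------------------------------------
# 6. Trial statistics and partial correlations
# ---------------------------------------------------------------------------

def band_power_ratio(lfp: np.ndarray, fs: float,
                     band=(5.0, 10.0), wide=(1.0, 125.0)) -> float:
    """Theta power normalized by wide-band power (periodogram integrals)."""
    f, p = signal.periodogram(np.asarray(lfp, dtype=np.float64), fs=fs)
    num = p[(f >= band[0]) & (f <= band[1])].sum()
    den = p[(f >= wide[0]) & (f <= min(wide[1], fs / 2))].sum()
    return float(num / den) if den > 0 else np.nan


def trial_statistics(bundle: SessionBundle, trial: Trial,
                     vectors: list[CycleVector],
                     events: list[DataFlickerEvent],
                     first_transition: int | None,
                     window_s: float = 5.0,
                     pre_s: float = 0.25) -> TrialStats:
    """Per-trial flicker rate, theta power, distance and control covariates.

    The analysis window runs from ``pre_s`` before the first network
    transition to ``window_s`` after it (theta power, mean rate), while the
    flicker count and the mean distance from the switching position use the
    ``window_s`` seconds after the transition.  The flicker rate is
    normalized by the usable fraction: n = N / ((1 - p_lowV) * T), with
    p_lowV the fraction of cycles lost to low speed or tracking artifacts.
    Trials with p_lowV > 0.5 are excluded.
    """
    if trial.switch_time is None:
        raise ValueError("trial has no switch_time")
    if first_transition is None:
        return TrialStats(np.nan, np.nan, np.nan, np.nan, np.nan, 1.0,
                          True, "no network transition found")
    t_tr = vectors[first_transition].interval[0]
    lo, hi = t_tr, t_tr + window_s

    in_win = [(cv, ev) for cv, ev in zip(vectors, events)
              if lo <= cv.interval[0] < hi]
    n_cycles = len(in_win)
    if n_cycles == 0:
        return TrialStats(np.nan, np.nan, np.nan, np.nan, np.nan, 1.0,
                          True, "no cycles in analysis window")
    p_lowV = float(np.mean([not cv.valid for cv, _ in in_win]))
    n_flick = sum(ev.flagged for cv, ev in in_win if cv.valid)
    if p_lowV > 0.5:
        return TrialStats(np.nan, np.nan, np.nan, np.nan, np.nan, p_lowV,
                          True, "more than half of cycles low-speed/artifact")
    rate = n_flick / ((1.0 - p_lowV) * window_s)

    # theta power in [t_tr - pre_s, t_tr + window_s] on the raw LFP
    i0 = max(0, int((lo - pre_s) * bundle.lfp_fs))
    i1 = min(len(bundle.lfp), int(hi * bundle.lfp_fs))
    power = band_power_ratio(bundle.lfp[i0:i1], bundle.lfp_fs)

    # mean distance from the switching position over valid epochs
    sw_x, sw_y = _interp_position(bundle.tracking_t, bundle.tracking_xy, [t_tr])
    valid, speed = speed_filter(bundle.tracking_t, bundle.tracking_xy)
    sel = (bundle.tracking_t >= lo) & (bundle.tracking_t < hi) & valid
    if sel.any():
        dx = bundle.tracking_xy[sel, 0] - sw_x[0]
        dy = bundle.tracking_xy[sel, 1] - sw_y[0]
        dist = float(np.hypot(dx, dy).mean())
        spd = float(speed[sel].mean())
    else:
        dist, spd = np.nan, np.nan

    n_sp = sum(int(np.count_nonzero((np.asarray(st) >= lo - pre_s)
                                    & (np.asarray(st) < hi)))
               for st in bundle.spikes)
    mean_rate = n_sp / (bundle.n_cells * (hi - lo + pre_s))

    return TrialStats(flicker_rate=rate, theta_power=power,
                      mean_distance=dist, mean_speed=spd,
                      mean_rate=mean_rate, p_lowV=p_lowV, excluded=False)


# ---------------------------------------------------------------------------
# 7. Whole-session pipeline
# ---------------------------------------------------------------------------

@dataclass
class SessionAnalysis:
    """Everything the pipeline computed for one session."""

    cycles: ThetaCycles                     # all theta cycles of the session
    rate_maps: RateMapSet
    low: dict[str, float]
    high: dict[str, float]
    trial_vectors: list[list[CycleVector]]  # per teleportation trial
    trial_events: list[list[DataFlickerEvent]]
    first_transitions: list[int | None]
    trial_stats: list[TrialStats]


def _cycles_within(cycles: ThetaCycles, interval) -> ThetaCycles:
    sel = ((cycles.intervals[:, 0] >= interval[0])
           & (cycles.intervals[:, 1] <= interval[1]))
    return ThetaCycles(intervals=cycles.intervals[sel], fs=cycles.fs)


def analyze_bundle(bundle: SessionBundle,
                   window_s: float = 5.0) -> SessionAnalysis:
    """Run the complete theta-cycle flicker pipeline on one session."""
    filt = lfp_theta_filter(bundle.lfp, bundle.lfp_fs)
    all_spikes = np.sort(np.concatenate(
        [np.asarray(s) for s in bundle.spikes]))
    cycles = segment_by_min_phase(filt, bundle.lfp_fs, all_spikes)
    maps = compute_rate_maps(bundle)

    refs = {}
    for env in ("A", "B"):
        ivs = [tr.interval for tr in bundle.trials
               if tr.kind.startswith("reference") and tr.environment == env]
        vecs: list[CycleVector] = []
        for iv in ivs:
            vecs.extend(cycle_vectors(bundle, _cycles_within(cycles, iv)))
        refs[env] = vecs
    low, high, _ = correlation_thresholds(refs, maps)

    tvecs, tevents, firsts, stats = [], [], [], []
    for tr in bundle.trials_of("teleportation"):
        vecs = cycle_vectors(bundle, _cycles_within(cycles, tr.interval))
        events, first = detect_flickers(vecs, maps, low, high, tr)
        tvecs.append(vecs)
        tevents.append(events)
        firsts.append(first)
        stats.append(trial_statistics(bundle, tr, vecs, events, first,
                                      window_s=window_s))
    return SessionAnalysis(cycles=cycles, rate_maps=maps, low=low, high=high,
                           trial_vectors=tvecs, trial_events=tevents,
                           first_transitions=firsts, trial_stats=stats)


def _partial_corr(y: np.ndarray, x: np.ndarray, Z: np.ndarray) -> float:
    """Pearson correlation of y and x after regressing out columns of Z."""
    Z1 = np.column_stack([np.ones(len(y)), Z])
    ry = y - Z1 @ np.linalg.lstsq(Z1, y, rcond=None)[0]
    rx = x - Z1 @ np.linalg.lstsq(Z1, x, rcond=None)[0]
    return _pearson(ry, rx)


def partial_correlation_analysis(stats: list[TrialStats],
                                 n_shuffles: int = 1000,
                                 seed: int = 0) -> dict:
    """Partial correlations of flicker rate with theta power and distance.

    Controls: the other predictor and the mean firing rate.  Two-sided
    p-values come from a pair-preserving permutation null: the flicker-rate
    vector is permuted across trials while each trial keeps its
    (power, distance, rate) triple, so the covariate structure is intact;
    p = (1 + #{|r_shuffle| >= |r_obs|}) / (1 + n_shuffles).
    """
    rows = [(s.flicker_rate, s.theta_power, s.mean_distance, s.mean_rate)
            for s in stats if not s.excluded
            and np.isfinite([s.flicker_rate, s.theta_power,
                             s.mean_distance, s.mean_rate]).all()]
    if len(rows) < 10:
        raise ValueError(f"need >= 10 usable trials, got {len(rows)}")
    arr = np.asarray(rows)
    flick, power, dist, mrate = arr.T
    for name, v in [("theta_power", power), ("mean_distance", dist),
                    ("mean_rate", mrate)]:
        if np.std(v) == 0:
            raise ValueError(f"constant covariate: {name}")

    r_power = _partial_corr(flick, power, np.column_stack([dist, mrate]))
    r_dist = _partial_corr(flick, dist, np.column_stack([power, mrate]))

    # permutation null, vectorized: residualize once, then correlate the
    # residualized permuted outcome with each residualized predictor
    rng = np.random.default_rng(seed)
    n = len(flick)

    def _null_corrs(x, Z):
        Z1 = np.column_stack([np.ones(n), Z])
        proj = Z1 @ np.linalg.pinv(Z1)
        rx = x - proj @ x
        rx = rx / np.linalg.norm(rx)
        perms = np.argsort(rng.random((n_shuffles, n)), axis=1)
        Y = flick[perms]                      # (n_shuffles, n)
        RY = Y - Y @ proj.T
        norms = np.linalg.norm(RY, axis=1)
        norms[norms == 0] = np.inf
        return (RY @ rx) / norms

    exceed_p = int(np.sum(np.abs(_null_corrs(
        power, np.column_stack([dist, mrate]))) >= abs(r_power) - 1e-12))
    exceed_d = int(np.sum(np.abs(_null_corrs(
        dist, np.column_stack([power, mrate]))) >= abs(r_dist) - 1e-12))
    p_power = (1 + exceed_p) / (1 + n_shuffles)
    p_dist = (1 + exceed_d) / (1 + n_shuffles)
    return {"r_power": r_power, "p_power": p_power,
            "r_distance": r_dist, "p_distance": p_dist,
            "n_trials": n, "n_shuffles": n_shuffles}
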