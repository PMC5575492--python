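"""HDF5 persistence for simulation results and session bundles."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .session_analysis import SessionBundle, Trial

__all__ = ["save_simulation", "save_bundle", "load_bundle"]


def save_simulation(path, res) -> None:
    """Write a SimResult to an HDF5 file (times, rates, u, x, membership)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("pop_times", data=res.pop_times)
        f.create_dataset("pop_activity", data=res.pop_activity)
        f.create_dataset("times", data=res.times)
        f.create_dataset("rates", data=res.rates, compression="gzip")
        if res.u is not None:
            f.create_dataset("u", data=res.u, compression="gzip")
            f.create_dataset("x", data=res.x, compression="gzip")
        f.create_dataset("membership", data=res.sel.membership)
        f.create_dataset("centers", data=res.sel.centers)
        f.attrs["schedule"] = json.dumps({
            "initial_map": res.schedule.initial_map,
            "switches": res.schedule.switches})
        f.attrs["config"] = json.dumps({
            "method": res.config.method, "dt": res.config.dt,
            "duration": res.config.duration, "seed": res.config.seed,
            "stp_enabled": res.config.stp_enabled})


def save_bundle(path, bundle: SessionBundle, truth=None) -> None:
    """Write a SessionBundle (and optional ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        g = f.create_group("tracking")
        g.create_dataset("t", data=bundle.tracking_t)
        g.create_dataset("xy", data=bundle.tracking_xy)
        g = f.create_group("spikes")
        for i, st in enumerate(bundle.spikes):
            g.create_dataset(f"cell{i:03d}", data=np.asarray(st))
        g = f.create_group("lfp")
        g.create_dataset("samples", data=bundle.lfp)
        g.attrs["fs"] = bundle.lfp_fs
        f.attrs["trials"] = json.dumps([
            {"kind": tr.kind, "interval": list(tr.interval),
             "environment": tr.environment, "switch_time": tr.switch_time,
             "env_before": tr.env_before, "env_after": tr.env_after}
            for tr in bundle.trials])
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("cycle_intervals", data=truth.cycle_intervals)
            g.create_dataset("cycle_labels",
                             data=np.char.encode(truth.cycle_labels))
            g.create_dataset("planted_cycles", data=truth.planted_cycles)
            for env, c in truth.centers.items():
                g.create_dataset(f"centers_{env}", data=c)
            g.attrs["switch_time"] = truth.switch_time
            g.attrs["switch_position"] = list(truth.switch_position)
            g.attrs["first_new_cycle"] = truth.first_new_cycle


def load_bundle(path) -> SessionBundle:
    with h5py.File(path, "r") as f:
        cells = sorted(f["spikes"].keys())
        trials = [Trial(kind=d["kind"], interval=tuple(d["interval"]),
                        environment=d.get("environment"),
                        switch_time=d.get("switch_time"),
                        env_before=d.get("env_before", "A"),
                        env_after=d.get("env_after", "B"))
                  for d in json.loads(f.attrs["trials"])]
        return SessionBundle(
            tracking_t=f["tracking/t"][:],
            tracking_xy=f["tracking/xy"][:],
            spikes=[f[f"spikes/{c}"][:] for c in cells],
            lfp=f["lfp/samples"][:],
            lfp_fs=float(f["lfp"].attrs["fs"]),
            trials=trials)
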