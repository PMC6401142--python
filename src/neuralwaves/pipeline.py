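"""End-to-end orchestration: simulate -> phases -> velocity -> transitions ->
flow scaffold -> statistics, with deterministic seeding and a run manifest.

A run is described by a flat configuration dictionary (typically loaded from
a YAML file).  The global seed fans out to per-stage child seeds through
:class:`numpy.random.SeedSequence` spawning, so toggling one analysis stage
does not change the randomness seen by the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import connectome as cn
from . import dynamics as dyn
from . import flow as fl
from . import phasefield as pf
from . import stats as st
from . import transitions as tr

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "sweep", "DEFAULTS"]

DEFAULTS: dict = {
    # network source: either files or a generator spec
    "coords_file": None,
    "weights_file": None,
    "n_per_hemisphere": 256,
    "extent": [70.0, 130.0, 90.0],
    "midline_gap": 15.0,
    "decay_slope": -0.023,
    "base_weight": 1.0,
    "jitter": 0.0,
    # simulation
    "model": "neural_mass",
    "c": 0.6,
    "tau": 1.0,
    "dt": 0.01,
    "duration": 5000.0,
    "transient_discard": 2000.0,
    "sigma": 0.0,
    "record_interval": 1.0,
    # analyses
    "velocity": True,
    "transitions": True,
    "flow": False,
    "flow_frames": 50,
    "recurrence": False,
    "n_surrogates": 100,
    "fc": False,
    "dwell_fit": False,
    "dwell_cutoff": 100.0,
    "local_radius": 20.0,
    # bookkeeping
    "seed": 0,
    "outdir": "runs/run0",
}


@dataclass
class RunConfig:
    """Validated run configuration (unknown keys are rejected)."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seconds: dict
    files: dict  # name -> sha256
    summary: dict

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "version": self.version,
                 "stage_seconds": self.stage_seconds, "files": self.files,
                 "summary": self.summary}, fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_network(cfg: RunConfig, seed_seq: np.random.SeedSequence) -> cn.SpatialNetwork:
    if cfg["coords_file"] and cfg["weights_file"]:
        return cn.read_network(cfg["coords_file"], cfg["weights_file"])
    rng = np.random.default_rng(seed_seq)
    pos = cn.sample_bilateral_positions(
        cfg["n_per_hemisphere"], tuple(cfg["extent"]), rng,
        midline_gap=cfg["midline_gap"])
    return cn.exponential_network(pos, cfg["decay_slope"], cfg["base_weight"],
                                  rng, cfg["jitter"])


def run_pipeline(cfg: RunConfig | dict) -> RunManifest:
    """Execute all enabled stages in dependency order; write outputs and a
    manifest into the configured output directory."""
    if isinstance(cfg, dict):
        cfg = RunConfig(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg["seed"])
    net_seq, sim_seq, surr_seq = root.spawn(3)
    stage_seconds: dict = {}
    files: dict = {}
    summary: dict = {}

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                stage_seconds[name] = round(time.perf_counter() - self.t0, 3)

        return _T()

    def register(name, path):
        files[name] = _sha256(path)

    with timed("network"):
        net = build_network(cfg, net_seq)
        cn.write_network(net, outdir / "coords.csv", outdir / "weights.txt")
    register("coords.csv", outdir / "coords.csv")
    register("weights.txt", outdir / "weights.txt")

    with timed("simulate"):
        sim_cfg = dyn.SimConfig(
            c=cfg["c"], tau=cfg["tau"], dt=cfg["dt"], duration=cfg["duration"],
            transient_discard=cfg["transient_discard"], sigma=cfg["sigma"],
            seed=int(np.random.default_rng(sim_seq).integers(2**31 - 1)),
            record_interval=cfg["record_interval"], model=cfg["model"])
        traj = dyn.integrate(net, sim_cfg)
        traj.save(outdir / "trajectory.h5")
    register("trajectory.h5", outdir / "trajectory.h5")

    field = pf.hilbert_phase(traj)
    r_local, r_global = pf.local_global_synchrony(
        field, net.positions, radius=cfg["local_radius"])
    summary["R_local"] = r_local
    summary["R_global"] = r_global

    vel = None
    if cfg["velocity"]:
        with timed("velocity"):
            vel = pf.velocity_field(field, net.positions)
            sp = pf.speed_summary(vel)
            summary["median_speed_mm_per_ms"] = sp.median
            np.savetxt(outdir / "nodal_mean_speed.csv", sp.nodal_mean,
                       header="mean_speed_mm_per_ms", comments="")
        register("nodal_mean_speed.csv", outdir / "nodal_mean_speed.csv")

    ts = None
    if cfg["transitions"]:
        with timed("transitions"):
            labels = tr.axis_partition(net.positions, "x")
            ra, rb = tr.partition_coherence(field, labels)
            cc = tr.windowed_lagged_xcorr(ra, rb, dt=field.dt)
            ts = tr.detect_transitions(cc)
            summary["n_transitions"] = int(ts.times.size)
            np.savetxt(outdir / "transitions.csv", ts.times,
                       header="time_ms", comments="")
            if ts.times.size >= 2:
                dw = tr.dwell_times(ts)
                summary["median_dwell_ms"] = float(np.median(dw.durations))
                np.savetxt(outdir / "dwell_times.csv", dw.durations,
                           header="dwell_ms", comments="")
                register("dwell_times.csv", outdir / "dwell_times.csv")
        register("transitions.csv", outdir / "transitions.csv")

    if cfg["flow"] and vel is not None:
        with timed("flow"):
            n_frames = min(cfg["flow_frames"], vel.v.shape[0])
            frames = np.linspace(0, vel.v.shape[0] - 1, n_frames).astype(int)
            snaps = [fl.find_sources_sinks(vel, f) for f in frames]
            record = fl.track_and_count(snaps, net.n_nodes)
            rows = []
            for snap in snaps:
                for kind, cs in (("source", snap.sources), ("sink", snap.sinks)):
                    for cen, node in zip(cs.centroids, cs.nodes):
                        rows.append((snap.time, kind, *cen, node))
            import pandas as pd

            pd.DataFrame(rows, columns=["t_ms", "type", "x", "y", "z", "node"]
                         ).to_csv(outdir / "flow_clusters.csv", index=False)
            summary["mean_sinks_per_frame"] = float(
                np.mean([s.sinks.nodes.size for s in snaps]))
            summary["mean_sources_per_frame"] = float(
                np.mean([s.sources.nodes.size for s in snaps]))
        register("flow_clusters.csv", outdir / "flow_clusters.csv")

    if cfg["recurrence"] and vel is not None:
        with timed("recurrence"):
            emp = st.alignment_recurrence(vel, frame_stride=10)
            child = surr_seq.spawn(cfg["n_surrogates"])
            surrogates = []
            for i in range(cfg["n_surrogates"]):
                s_traj = st.aaft_surrogate(traj, child[i])
                s_field = pf.hilbert_phase(s_traj)
                s_vel = pf.velocity_field(s_field, net.positions)
                surrogates.append(st.alignment_recurrence(s_vel, frame_stride=10))
            mask = st.recurrence_significance(emp, surrogates)
            np.savetxt(outdir / "recurrence_mask.csv", mask, fmt="%d",
                       delimiter=",")
            summary["recurrence_exceedance_fraction"] = float(
                np.mean(mask != 0))
        register("recurrence_mask.csv", outdir / "recurrence_mask.csv")

    if cfg["fc"]:
        with timed("fc"):
            fc = st.fc_matrix(traj, "raw")
            np.savetxt(outdir / "fc_raw.csv", fc, delimiter=",")
        register("fc_raw.csv", outdir / "fc_raw.csv")

    if cfg["dwell_fit"] and ts is not None and ts.times.size >= 2:
        with timed("dwell_fit"):
            dw = tr.dwell_times(ts)
            lines = []
            for family in st.TAIL_FAMILIES:
                try:
                    fit = st.fit_tail(dw, family, cutoff=cfg["dwell_cutoff"])
                    lines.append(fit.report())
                except ValueError as err:
                    lines.append(f"family={family} failed: {err}")
            (outdir / "dwell_fits.txt").write_text("\n".join(lines) + "\n")
        register("dwell_fits.txt", outdir / "dwell_fits.txt")

    from . import __version__

    manifest = RunManifest(dict(cfg.values), __version__, stage_seconds,
                           files, summary)
    manifest.save(outdir / "manifest.json")
    return manifest


def sweep(base: RunConfig | dict, grid: dict) -> list:
    """Run the pipeline over a parameter grid (e.g. c x tau).

    ``grid`` maps config keys to lists of values; the Cartesian product is
    executed with per-cell output directories and an aggregate summary table
    (R_local, R_global, transition count per cell).  Failures are recorded
    and the sweep continues.
    """
    import itertools

    if isinstance(base, RunConfig):
        base = dict(base.values)
    if not grid:
        raise ValueError("grid must be nonempty")
    keys = sorted(grid)
    manifests = []
    rows = []
    outroot = Path(base.get("outdir", DEFAULTS["outdir"]))
    for combo in itertools.product(*(grid[k] for k in keys)):
        cell = dict(base)
        cell.update(dict(zip(keys, combo)))
        tag = "_".join(f"{k}{v}" for k, v in zip(keys, combo))
        cell["outdir"] = str(outroot / f"cell_{tag}")
        try:
            m = run_pipeline(cell)
            manifests.append(m)
            rows.append({**dict(zip(keys, combo)), **m.summary})
        except Exception as err:  # noqa: BLE001 - sweep must continue
            logger.error("sweep cell %s failed: %s", tag, err)
            rows.append({**dict(zip(keys, combo)), "error": str(err)})
    import pandas as pd

    outroot.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(outroot / "sweep_summary.csv", index=False)
    return manifests
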