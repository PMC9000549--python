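"""Orchestrate every analysis stage over one or more trajectory conditions.

One :class:`RunConfig` names a set of labelled trajectories (typically the
same channel under different membrane potentials), the channel geometry
and the criteria blocks.  :func:`run_pipeline` emits, per condition:

* ``occupancy.csv`` + ``occupancy_summary.json`` — the water-wire stripe,
* ``helix_z.csv`` — per-helix displacement vs the four-helix center,
* ``sidechain_z_<res>.csv`` — sidechain z-tracks (S4 arginines),
* ``hbond_<pair>.csv`` and ``partner_table.csv`` — contact series,
* ``gate_gap_<res>.csv`` — gate-vs-anchor z-gaps,
* ``pore_profile.csv`` (first analyzed frame) and ``pore_mean.csv``,
* ``field.json`` — E = V/z bookkeeping,

plus a machine-readable ``index.json`` across conditions.  All floats are
written with fixed 6-decimal formatting and no timestamps, so re-running
an identical configuration reproduces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .hydration import WaterWireCriteria, occupancy_series
from .interactions import HBondCriteria, hbond_count_series, \
    partner_occupancy_table
from .kinematics import gate_z_gap, helix_z_series, sidechain_z_series
from .model_io import (ChannelDefinition, Trajectory, detect_equilibration,
                       field_magnitude, load_channel_definition,
                       read_trajectory)
from .geometry import rmsd_series
from .pore import min_radius_and_passability, pore_profile

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "TrajectorySource", "run_pipeline", "load_run_config"]

FMT = "%.6f"


@dataclass
class TrajectorySource:
    label: str
    path: str
    potential_mV: float = 0.0
    format: str = "pdb_multimodel"


@dataclass
class RunConfig:
    trajectories: list[TrajectorySource]
    channel: ChannelDefinition = field(default_factory=ChannelDefinition)
    wire: WaterWireCriteria = field(default_factory=WaterWireCriteria)
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    membrane_thickness_A: float = 36.0
    equilibration: str | int = 0        # "auto" or a frame index
    hbond_pairs: list[tuple] = field(default_factory=list)
    arg_residues: list[int] = field(default_factory=list)
    gate_pairs: list[tuple] = field(default_factory=list)  # (gate, anchor)
    basic_residues: list[tuple] = field(default_factory=list)
    acidic_residues: list[tuple] = field(default_factory=list)
    pore_params: dict = field(default_factory=dict)
    output_dir: str = "channelgate_out"

    def __post_init__(self) -> None:
        labels = [t.label for t in self.trajectories]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")


def _residue_key(value) -> tuple | int:
    if isinstance(value, (list, tuple)):
        return int(value[0]), str(value[1])
    return int(value)


def load_run_config(source: str | Path | Mapping) -> RunConfig:
    """Read a YAML run configuration."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    d = dict(source)
    trajs = [TrajectorySource(label=str(t["label"]), path=str(t["path"]),
                              potential_mV=float(t.get("potential_mV", 0.0)),
                              format=str(t.get("format", "pdb_multimodel")))
             for t in d["trajectories"]]
    kwargs: dict = {"trajectories": trajs}
    if "channel" in d:
        kwargs["channel"] = load_channel_definition(d["channel"])
    if "wire" in d:
        kwargs["wire"] = WaterWireCriteria(**d["wire"])
    if "hbond" in d:
        kwargs["hbond"] = HBondCriteria(**d["hbond"])
    for key in ("membrane_thickness_A", "equilibration", "output_dir",
                "pore_params"):
        if key in d:
            kwargs[key] = d[key]
    for key in ("hbond_pairs", "gate_pairs"):
        if key in d:
            kwargs[key] = [tuple(_residue_key(r) for r in pair)
                           for pair in d[key]]
    for key in ("basic_residues", "acidic_residues"):
        if key in d:
            kwargs[key] = [_residue_key(r) for r in d[key]]
    if "arg_residues" in d:
        kwargs["arg_residues"] = [int(r) for r in d["arg_residues"]]
    return RunConfig(**kwargs)


def _write_csv(path: Path, header: list[str], columns: list[np.ndarray],
               formats: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in zip(*columns):
            fh.write(",".join(f % v for f, v in zip(formats, row)) + "\n")


def _series_csv(path: Path, series) -> None:
    _write_csv(path, ["frame", "time_ns", "z_A"],
               [series.frame_indices, series.times, series.z_values],
               ["%d", FMT, FMT])


def _res_tag(residue) -> str:
    if isinstance(residue, tuple):
        return f"{residue[0]}{residue[1]}"
    return str(residue)


def _analyze_condition(traj: Trajectory, source: TrajectorySource,
                       config: RunConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    entry: dict = {"label": source.label,
                   "potential_mV": source.potential_mV,
                   "n_frames": traj.n_frames}

    fs = field_magnitude(source.potential_mV, config.membrane_thickness_A)
    (outdir / "field.json").write_text(json.dumps({
        "potential_mV": fs.potential_mV,
        "thickness_A": fs.thickness_A,
        "magnitude_mV_per_A": round(fs.magnitude_mV_per_A, 6)}, indent=1))
    entry["field_mV_per_A"] = round(fs.magnitude_mV_per_A, 6)

    if config.equilibration == "auto":
        logger.info("[%s] detecting equilibration from RMSD", source.label)
        series = rmsd_series(traj, 0, mode="all_heavy")
        equil = detect_equilibration(series)
    else:
        equil = int(config.equilibration)
    entry["equil_start"] = equil

    logger.info("[%s] water-wire occupancy", source.label)
    wire = occupancy_series(traj, config.channel, config.wire, equil)
    _write_csv(outdir / "occupancy.csv", ["frame", "time_ns", "continuous"],
               [wire.frame_indices, wire.times,
                wire.per_frame.astype(int)], ["%d", FMT, "%d"])
    summary = {
        "occupancy": round(wire.occupancy, 6),
        "n_frames": int(wire.per_frame.size),
        "n_continuous": int(wire.per_frame.sum()),
        "run_lengths": wire.run_lengths,
        "longest_run": max(wire.run_lengths, default=0),
    }
    (outdir / "occupancy_summary.json").write_text(
        json.dumps(summary, indent=1))
    entry["occupancy"] = summary["occupancy"]

    logger.info("[%s] helix kinematics", source.label)
    helices = helix_z_series(traj, config.channel, equil)
    first = next(iter(helices.values()))
    _write_csv(outdir / "helix_z.csv",
               ["frame", "time_ns"] + list(helices),
               [first.frame_indices, first.times]
               + [s.z_values for s in helices.values()],
               ["%d", FMT] + [FMT] * len(helices))
    entry["helix_final_dz"] = {k: round(s.final_mean(), 6)
                               for k, s in helices.items()}

    for res in config.arg_residues:
        s = sidechain_z_series(traj, res, equil_start=equil, rezero=True)
        _series_csv(outdir / f"sidechain_z_{res}.csv", s)

    for pair in config.hbond_pairs:
        logger.info("[%s] H-bonds %s", source.label, pair)
        cs = hbond_count_series(traj, pair[0], pair[1], config.hbond, equil)
        _write_csv(outdir / f"hbond_{_res_tag(pair[0])}_{_res_tag(pair[1])}.csv",
                   ["frame", "time_ns", "count"],
                   [cs.frame_indices, cs.times, cs.counts], ["%d", FMT, "%d"])

    if config.basic_residues and config.acidic_residues:
        table = partner_occupancy_table(
            traj, config.basic_residues, config.acidic_residues,
            config.hbond, equil)
        table = table.copy()
        table["occupancy"] = table["occupancy"].map(lambda v: FMT % v)
        table.to_csv(outdir / "partner_table.csv", index=False)

    for gate, anchor in config.gate_pairs:
        s = gate_z_gap(traj, gate, anchor, equil)
        _series_csv(outdir / f"gate_gap_{_res_tag(gate)}.csv", s)

    logger.info("[%s] pore profile", source.label)
    prof0 = pore_profile(traj.frame(equil), config.channel,
                         **config.pore_params)
    _write_csv(outdir / "pore_profile.csv", ["z_A", "radius_A", "cx", "cy"],
               [prof0.z_grid, prof0.radii, prof0.centers[:, 0],
                prof0.centers[:, 1]], [FMT] * 4)
    # mean profile over a handful of evenly spaced analyzed frames
    picks = np.unique(np.linspace(equil, traj.n_frames - 1, 5).astype(int))
    stack = [prof0.radii] + [
        pore_profile(traj.frame(i), config.channel,
                     **config.pore_params).radii
        for i in picks if i != equil]
    mean_radii = np.mean(stack, axis=0)
    _write_csv(outdir / "pore_mean.csv", ["z_A", "radius_A"],
               [prof0.z_grid, mean_radii], [FMT, FMT])
    rmin, zmin, passable = min_radius_and_passability(prof0)
    entry["pore_min_radius"] = round(rmin, 6)
    entry["pore_min_z"] = round(zmin, 6)
    entry["pore_passable"] = passable
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every condition; returns the report index.

    Writes one output directory per condition plus ``index.json``.  A
    stage failure raises after logging which condition and stage failed;
    outputs written so far are retained.
    """
    root = Path(config.output_dir)
    root.mkdir(parents=True, exist_ok=True)
    index: dict = {"conditions": []}
    for source in config.trajectories:
        logger.info("condition %s: reading %s", source.label, source.path)
        try:
            traj = read_trajectory(source.path, source.format)
            entry = _analyze_condition(traj, source, config,
                                       root / source.label)
        except Exception:
            logger.exception("condition %s failed", source.label)
            raise
        index["conditions"].append(entry)
    (root / "index.json").write_text(json.dumps(index, indent=1))
    return index
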