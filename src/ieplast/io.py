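"""Readers and writers for sweep containers, place sessions and
published source-data tables.

Two sweep dialects are supported: an HDF5 layout
(``/cells/<cell_id>/<timepoint>/sweep###`` with ``voltage_mV`` and
``current_pA`` datasets and ``dt_ms``/``step_amp_pA``/``step_onset_ms``/
``step_dur_ms`` attributes) for volume, and a long-format CSV
(cell_id, timepoint, sweep, t_ms, v_mV, i_pA, step_amp_pA, step_onset_ms,
step_dur_ms) for small human-inspectable fixtures.  Units are encoded in
the column names.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .sweep import Sweep


class SweepParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------- HDF5

def save_sweeps_hdf(path: str | Path, cells: Mapping[str, Mapping[str, list[Sweep]]]) -> None:
    """Write nested {cell_id: {timepoint: [Sweep, ...]}} to HDF5."""
    with h5py.File(path, "w") as f:
        root = f.create_group("cells")
        for cid, tps in cells.items():
            gc = root.create_group(str(cid))
            for tp, sweeps in tps.items():
                gt = gc.create_group(str(tp))
                for k, s in enumerate(sweeps):
                    gs = gt.create_group(f"sweep{k:03d}")
                    gs.create_dataset("voltage_mV", data=s.v)
                    gs.create_dataset("current_pA", data=s.i)
                    gs.attrs["dt_ms"] = s.dt
                    gs.attrs["step_amp_pA"] = s.step_amp
                    gs.attrs["step_onset_ms"] = s.step_onset * s.dt
                    gs.attrs["step_dur_ms"] = (s.step_offset - s.step_onset) * s.dt


def load_sweeps_hdf(path: str | Path) -> dict[str, dict[str, list[Sweep]]]:
    out: dict[str, dict[str, list[Sweep]]] = {}
    with h5py.File(path, "r") as f:
        for cid, gc in f["cells"].items():
            out[cid] = {}
            for tp, gt in gc.items():
                sweeps = []
                for name in sorted(gt):
                    gs = gt[name]
                    v = gs["voltage_mV"][:]
                    i = gs["current_pA"][:]
                    if v.shape != i.shape:
                        raise SweepParseError(
                            f"voltage/current length mismatch in {cid}/{tp}/{name}"
                        )
                    dt = float(gs.attrs["dt_ms"])
                    onset = int(round(float(gs.attrs["step_onset_ms"]) / dt))
                    dur = int(round(float(gs.attrs["step_dur_ms"]) / dt))
                    sweeps.append(
                        Sweep(
                            dt=dt,
                            v=v,
                            i=i,
                            step_onset=onset,
                            step_offset=onset + dur,
                            step_amp=float(gs.attrs["step_amp_pA"]),
                        )
                    )
                out[cid][tp] = sweeps
    return out


# ------------------------------------------------------------- long CSV

_CSV_COLUMNS = [
    "cell_id",
    "timepoint",
    "sweep",
    "t_ms",
    "v_mV",
    "i_pA",
    "step_amp_pA",
    "step_onset_ms",
    "step_dur_ms",
]


def save_sweeps_csv(path: str | Path, cells: Mapping[str, Mapping[str, list[Sweep]]]) -> None:
    frames = []
    for cid, tps in cells.items():
        for tp, sweeps in tps.items():
            for k, s in enumerate(sweeps):
                frames.append(
                    pd.DataFrame(
                        {
                            "cell_id": cid,
                            "timepoint": tp,
                            "sweep": k,
                            "t_ms": s.t,
                            "v_mV": s.v,
                            "i_pA": s.i,
                            "step_amp_pA": s.step_amp,
                            "step_onset_ms": s.step_onset * s.dt,
                            "step_dur_ms": (s.step_offset - s.step_onset) * s.dt,
                        }
                    )
                )
    pd.concat(frames, ignore_index=True)[_CSV_COLUMNS].to_csv(path, index=False)


def load_sweeps_csv(path: str | Path) -> dict[str, dict[str, list[Sweep]]]:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SweepParseError(f"missing columns in sweep CSV: {missing}")
    out: dict[str, dict[str, list[Sweep]]] = {}
    for (cid, tp, k), grp in df.groupby(["cell_id", "timepoint", "sweep"], sort=True):
        grp = grp.sort_values("t_ms")
        t = grp["t_ms"].to_numpy()
        if len(t) < 2:
            raise SweepParseError(f"sweep {cid}/{tp}/{k} has fewer than 2 samples")
        dt = float(t[1] - t[0])
        onset = int(round(float(grp["step_onset_ms"].iloc[0]) / dt))
        dur = int(round(float(grp["step_dur_ms"].iloc[0]) / dt))
        sw = Sweep(
            dt=dt,
            v=grp["v_mV"].to_numpy(),
            i=grp["i_pA"].to_numpy(),
            step_onset=onset,
            step_offset=onset + dur,
            step_amp=float(grp["step_amp_pA"].iloc[0]),
        )
        out.setdefault(str(cid), {}).setdefault(str(tp), []).append(sw)
    return out


def load_sweeps(path: str | Path, dialect: str | None = None) -> dict[str, dict[str, list[Sweep]]]:
    """Load a sweep container, inferring the dialect from the suffix
    (.h5/.hdf5 vs .csv) unless given explicitly."""
    path = Path(path)
    if dialect is None:
        dialect = "hdf" if path.suffix in (".h5", ".hdf5", ".hdf") else "long-csv"
    if dialect == "hdf":
        return load_sweeps_hdf(path)
    if dialect == "long-csv":
        return load_sweeps_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# -------------------------------------------------------- place sessions

def save_place_session(spikes_path: str | Path, pos_path: str | Path, session) -> None:
    pd.DataFrame({"cell_id": "cell", "t_s": session.spike_times}).to_csv(
        spikes_path, index=False
    )
    lap_idx = np.full(len(session.t), -1)
    direction = np.zeros(len(session.t), dtype=int)
    for li, (a, b, d) in enumerate(session.laps):
        m = (session.t >= a) & (session.t < b)
        lap_idx[m] = li
        direction[m] = d
    pd.DataFrame(
        {"t_s": session.t, "x_cm": session.x, "lap": lap_idx, "direction": direction}
    ).to_csv(pos_path, index=False)


def load_place_session(spikes_path: str | Path, pos_path: str | Path, track_length: float,
                       condition: str = "novel"):
    from .placesim import PlaceSession

    sp = pd.read_csv(spikes_path)
    pos = pd.read_csv(pos_path)
    for col, df, name in (("t_s", sp, "spikes"), ("t_s", pos, "position"), ("x_cm", pos, "position")):
        if col not in df.columns:
            raise SweepParseError(f"missing column {col!r} in {name} CSV")
    laps = []
    if "lap" in pos.columns:
        for li in sorted(pos["lap"].unique()):
            if li < 0:
                continue
            seg = pos[pos["lap"] == li]
            d = int(seg["direction"].iloc[0]) if "direction" in pos.columns else 1
            laps.append((float(seg["t_s"].min()), float(seg["t_s"].max()), d))
    return PlaceSession(
        spike_times=sp["t_s"].to_numpy(),
        t=pos["t_s"].to_numpy(),
        x=pos["x_cm"].to_numpy(),
        laps=laps,
        track_length=track_length,
        condition=condition,
    )


# ------------------------------------------------------ source-data tables

#: expected value columns per published figure table (long format after load)
SOURCE_SCHEMAS: dict[str, list[str]] = {
    "fig1": ["cell_id", "condition", "timepoint", "spike_count"],
    "fig2": ["cell_id", "condition", "timepoint", "rin_mohm", "latency_ms"],
    "fig3": ["cell_id", "condition", "timepoint", "spike_count", "rin_mohm", "latency_ms"],
    "fig4": ["cell_id", "condition", "timepoint", "spike_count", "rin_mohm", "latency_ms"],
    "fig5": ["cell_id", "condition", "timepoint", "sag_ratio"],
    "fig6": ["cell_id", "condition", "timepoint", "spike_count", "rin_mohm", "latency_ms"],
    "fig7": ["cell_id", "condition", "timepoint", "spike_count", "rin_mohm", "latency_ms"],
    "fig8": ["cell_id", "condition", "lap", "in_rate_hz", "out_rate_hz"],
}


def load_source_data(path: str | Path, figure_id: str) -> pd.DataFrame:
    """Load a published per-figure source-data table into tidy long format.

    The table must be a delimited file with the columns declared for the
    figure; value columns are melted into (metric, value) pairs so the
    group-statistics routines can consume any figure uniformly.
    """
    if figure_id not in SOURCE_SCHEMAS:
        raise SchemaError(
            f"unknown figure id {figure_id!r}; known: {sorted(SOURCE_SCHEMAS)}"
        )
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    expected = SOURCE_SCHEMAS[figure_id]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(
            f"source table for {figure_id} is missing columns {missing}; expected {expected}"
        )
    id_cols = [c for c in expected if c in ("cell_id", "condition", "timepoint", "lap")]
    value_cols = [c for c in expected if c not in id_cols]
    return df.melt(id_vars=id_cols, value_vars=value_cols, var_name="metric", value_name="value")
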