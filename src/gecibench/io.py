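"""Tidy CSV contracts and run manifests.

Population recordings travel as two CSVs — a trace table with columns
(cell_id, frame, time_s, F_meas, F_np) and a sidecar annotation table
(cell_id, event_type, time_s, value) holding spikes and the stimulus
schedule — plus a plain key=value manifest recording the generator
parameters and seed. Depth profiles and screen plates use flat tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .depth import DepthProfile
from .screen import WellRecord
from .synth import Population
from .traceproc import Trace


def write_manifest(path, params: dict) -> None:
    lines = [f"{k}={v}" for k, v in params.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            k, _, v = line.partition("=")
            out[k] = v
    return out


def population_to_frames(pop: Population) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a Population into (traces, annotations) tidy tables."""
    trace_rows = []
    for cell in pop.cells:
        n = len(cell.f_meas)
        trace_rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell.cell_id,
                    "frame": np.arange(n),
                    "time_s": cell.f_meas.times,
                    "F_meas": cell.f_meas.samples,
                    "F_np": cell.f_np.samples,
                }
            )
        )
    traces = pd.concat(trace_rows, ignore_index=True)

    ann_rows = []
    for cell in pop.cells:
        for t in cell.spikes.times:
            ann_rows.append((cell.cell_id, "spike", t, 1.0))
    for rec in pop.schedule.itertuples():
        ann_rows.append((-1, "blank_start", rec.blank_start, rec.direction))
        ann_rows.append((-1, "stim_start", rec.stim_start, rec.direction))
        ann_rows.append((-1, "stim_end", rec.stim_end, rec.direction))
    annotations = pd.DataFrame(
        ann_rows, columns=["cell_id", "event_type", "time_s", "value"]
    )
    return traces, annotations


def save_population(outdir, pop: Population) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces, annotations = population_to_frames(pop)
    traces.to_csv(outdir / "traces.csv", index=False)
    annotations.to_csv(outdir / "annotations.csv", index=False)
    pop.schedule.to_csv(outdir / "schedule.csv", index=False)
    write_manifest(
        outdir / "manifest.txt",
        {
            "indicator": pop.kinetics.name,
            "fs": pop.config.fs,
            "f0": pop.config.f0,
            "noise_sd": pop.config.noise_sd,
            "r_true": pop.config.r_true,
            "neuropil_amp": pop.config.neuropil_amp,
            "seed": pop.config.seed,
            "n_cells": len(pop.cells),
        },
    )


def load_traces(path, fs: float) -> dict[int, tuple[Trace, Trace]]:
    """Read a tidy trace CSV into per-cell (F_meas, F_np) Trace pairs."""
    df = pd.read_csv(path)
    out = {}
    for cid, grp in df.groupby("cell_id"):
        grp = grp.sort_values("frame")
        out[int(cid)] = (
            Trace(grp.F_meas.to_numpy(), fs=fs),
            Trace(grp.F_np.to_numpy(), fs=fs),
        )
    return out


def depth_profiles_to_frame(profiles: list[DepthProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for z, f in zip(p.depths, p.fluorescence):
            rows.append((p.dendrite_id, p.indicator, z, f))
    return pd.DataFrame(rows, columns=["dendrite_id", "indicator", "depth_um", "F"])


def frame_to_depth_profiles(df: pd.DataFrame) -> list[DepthProfile]:
    profiles = []
    for (did, ind), grp in df.groupby(["dendrite_id", "indicator"], sort=False):
        grp = grp.sort_values("depth_um")
        profiles.append(
            DepthProfile(
                grp.depth_um.to_numpy(), grp.F.to_numpy(), dendrite_id=did, indicator=ind
            )
        )
    return profiles


def plate_to_frame(wells: list[WellRecord]) -> pd.DataFrame:
    rows = []
    for w in wells:
        for n_ap, block in sorted(w.traces.items()):
            n_cells, n_frames = block.shape
            for c in range(n_cells):
                rows.append(
                    pd.DataFrame(
                        {
                            "plate": w.plate,
                            "well": w.well,
                            "variant": w.variant,
                            "cell_id": c,
                            "train_APs": n_ap,
                            "frame": np.arange(n_frames),
                            "F": block[c],
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def frame_to_plate(
    df: pd.DataFrame, fs: float, stim_time_s: float, train_hz: float = 83.0
) -> list[WellRecord]:
    wells = []
    for (plate, well, variant), grp in df.groupby(
        ["plate", "well", "variant"], sort=False
    ):
        traces = {}
        for n_ap, sub in grp.groupby("train_APs"):
            pivot = sub.pivot(index="cell_id", columns="frame", values="F")
            traces[int(n_ap)] = pivot.to_numpy()
        wells.append(
            WellRecord(
                variant=variant,
                traces=traces,
                fs=fs,
                stim_time_s=stim_time_s,
                plate=plate,
                well=well,
                train_hz=train_hz,
            )
        )
    return wells
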