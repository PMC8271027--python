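"""Readers and writers for the plain-text formats the pipeline consumes.

Formats
-------
FP plate data : long CSV with columns ``time, value, well`` plus a layout
    TSV mapping ``well`` to ``allotype, catalyst, replicate, role``
    (role is ``sample`` or ``baseline``).  Time units default to seconds;
    minutes and hours are converted on read.
CPMG tables : TSV with columns ``methyl_id, nu_hz, intensity``; ``nu_hz = 0``
    rows mark the reference scan.
Peak lists : TSV with columns ``assignment_id, h_ppm, n_ppm, intensity``.
Melt curves : tidy CSV with ``temperature, fluorescence, condition,
    replicate`` (wide form: a ``temperature`` column plus one column per
    well, given a layout map).
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import pandas as pd

from .cpmg import DispersionFit, DispersionProfile
from .fpkinetics import FPTrace, KineticsFit
from .hsqcratio import PeakList, RatioTable
from .thermoshift import MeltCurve, TmFit

__all__ = [
    "TIME_FACTORS",
    "read_fp_csv", "write_fp_csv",
    "read_cpmg_tsv", "write_cpmg_tsv",
    "read_peaklist_tsv", "write_peaklist_tsv",
    "read_melt_csv", "write_melt_csv",
    "write_fits_csv", "write_dispersion_fits_csv",
    "write_ratio_csv", "write_tm_csv",
    "append_manifest",
]

TIME_FACTORS: Mapping[str, float] = {"s": 1.0, "min": 60.0, "h": 3600.0}

_FLOAT_FMT = "%.10g"   # deterministic, locale-free float formatting


def read_fp_csv(data_path, layout_path, time_unit: str = "s") -> list[FPTrace]:
    """Read long-format FP data plus a plate layout into traces."""
    if time_unit not in TIME_FACTORS:
        raise ValueError(f"unknown time unit {time_unit!r}; "
                         f"use one of {sorted(TIME_FACTORS)}")
    data = pd.read_csv(data_path)
    layout = pd.read_csv(layout_path, sep="\t")
    for col in ("time", "value", "well"):
        if col not in data.columns:
            raise ValueError(f"FP data is missing column {col!r}")
    for col in ("well", "allotype", "catalyst", "replicate", "role"):
        if col not in layout.columns:
            raise ValueError(f"plate layout is missing column {col!r}")
    meta = layout.set_index("well")
    traces = []
    factor = TIME_FACTORS[time_unit]
    for well, grp in data.groupby("well", sort=True):
        if well not in meta.index:
            raise ValueError(f"well {well!r} not present in the layout")
        m = meta.loc[well]
        grp = grp.sort_values("time")
        traces.append(FPTrace(
            time=grp["time"].to_numpy() * factor,
            fp=grp["value"].to_numpy(),
            allotype=str(m["allotype"]), catalyst=str(m["catalyst"]),
            replicate=int(m["replicate"]), role=str(m["role"])))
    return traces


def write_fp_csv(traces: Sequence[FPTrace], data_path, layout_path) -> None:
    """Write traces as long CSV + layout TSV (inverse of :func:`read_fp_csv`)."""
    rows, layout = [], []
    for i, tr in enumerate(traces):
        well = f"W{i:03d}"
        layout.append({"well": well, "allotype": tr.allotype,
                       "catalyst": tr.catalyst, "replicate": tr.replicate,
                       "role": tr.role})
        for t, v in zip(tr.time, tr.fp):
            rows.append({"time": t, "value": v, "well": well})
    pd.DataFrame(rows).to_csv(data_path, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(layout).to_csv(layout_path, sep="\t", index=False)


def read_cpmg_tsv(path, t_cpmg: float = 0.040) -> list[DispersionProfile]:
    """Read a per-methyl CPMG intensity table."""
    df = pd.read_csv(path, sep="\t")
    for col in ("methyl_id", "nu_hz", "intensity"):
        if col not in df.columns:
            raise ValueError(f"CPMG table is missing column {col!r}")
    return [DispersionProfile(methyl_id=str(mid),
                              nu=grp["nu_hz"].to_numpy(),
                              intensity=grp["intensity"].to_numpy(),
                              t_cpmg=t_cpmg)
            for mid, grp in df.groupby("methyl_id", sort=True)]


def write_cpmg_tsv(profiles: Sequence[DispersionProfile], path) -> None:
    rows = [{"methyl_id": p.methyl_id, "nu_hz": nu, "intensity": i}
            for p in profiles for nu, i in zip(p.nu, p.intensity)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=_FLOAT_FMT)


def read_peaklist_tsv(path, label: str = "") -> PeakList:
    df = pd.read_csv(path, sep="\t")
    return PeakList(df, label=label or str(path))


def write_peaklist_tsv(peaks: PeakList, path) -> None:
    peaks.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_melt_csv(path) -> list[MeltCurve]:
    """Read tidy melt curves (temperature, fluorescence, condition, replicate)."""
    df = pd.read_csv(path)
    for col in ("temperature", "fluorescence"):
        if col not in df.columns:
            raise ValueError(f"melt table is missing column {col!r}")
    if "condition" not in df.columns:
        df["condition"] = ""
    if "replicate" not in df.columns:
        df["replicate"] = 0
    curves = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("temperature")
        curves.append(MeltCurve(temperature=grp["temperature"].to_numpy(),
                                fluorescence=grp["fluorescence"].to_numpy(),
                                condition=str(cond), replicate=int(rep)))
    return curves


def write_melt_csv(curves: Sequence[MeltCurve], path) -> None:
    rows = [{"temperature": t, "fluorescence": f, "condition": c.condition,
             "replicate": c.replicate}
            for c in curves for t, f in zip(c.temperature, c.fluorescence)]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_fits_csv(fits: Sequence[KineticsFit], path) -> None:
    rows = [{"allotype": f.condition[0], "catalyst": f.condition[1],
             "replicate": f.condition[2], "y0": f.y0, "a": f.a,
             "k_on": f.k_on, "k_on_stderr": f.k_on_stderr, "rss": f.rss,
             "converged": f.converged} for f in fits]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_dispersion_fits_csv(fits: Sequence[DispersionFit], path) -> None:
    rows = [{"methyl_id": f.methyl_id, "model": f.model, "r2_0": f.r2_0,
             "kex": f.kex, "phi": f.phi, "sigma": f.sigma,
             "amplitude": f.dispersion_amplitude, "dispersing": f.dispersing}
            for f in fits]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_ratio_csv(rt: RatioTable, path) -> None:
    table = rt.table.copy()
    table["mean"] = rt.mean
    table["delta"] = rt.delta
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_tm_csv(fits: Sequence[TmFit], path) -> None:
    rows = [{"condition": f.condition, "tm": f.tm, "slope": f.slope,
             "tm_stderr": f.tm_stderr, "converged": f.converged}
            for f in fits]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def append_manifest(path, stage: str, seed: int | None, **info) -> None:
    """Append one JSON-lines manifest record for a pipeline stage."""
    rec = {"stage": stage, "seed": seed, **info}
    with open(path, "a") as fh:
        fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")
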