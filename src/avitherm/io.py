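"""CSV serialization for the package's tabular objects.

Schemas (column name -> unit):

individuals.csv
    id, sex (M/F), mb_g, bl_mm, bw_mm, bd_mm, tl_mm, tw_mm, td_mm,
    wing_mm, bill_area_mm2, tarsi_area_mm2, bill_index, tarsi_index,
    plus true_* generator columns when present.

profiles.csv (long)
    id, ta_c, vo2_ml_min, ewl_mg_h

steady_state.csv
    id, ta_c, vo2_ml_min, ewl_mg_h, window_start_s, window_end_s,
    window_sd, flags

trace CSV
    header comment lines ``# key=value`` carrying flow_rate_ml_min,
    barometric_pressure_kpa, ta_c, fio2, incurrent_wvp_kpa,
    chamber_volume_l, individual_id; then columns
    time_s, o2_frac, wvp_kpa, segment_id, is_baseline.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .morphometrics import IndividualRecord
from .respirometry import RespirometryTrace, SteadyStateMeasure, ThermalProfile

__all__ = [
    "individuals_to_frame", "frame_to_individuals",
    "write_individuals", "read_individuals",
    "profiles_to_frame", "frame_to_profiles",
    "write_profiles", "read_profiles",
    "measures_to_frame", "write_trace", "read_trace",
]

_IND_COLUMNS = {
    "id": "id", "sex": "sex", "mb": "mb_g", "bl": "bl_mm", "bw": "bw_mm",
    "bd": "bd_mm", "tl": "tl_mm", "tw": "tw_mm", "td": "td_mm",
    "wing": "wing_mm", "bill_area": "bill_area_mm2",
    "tarsi_area": "tarsi_area_mm2", "bill_index": "bill_index",
    "tarsi_index": "tarsi_index", "true_tlc": "true_tlc_c",
    "true_tuc": "true_tuc_c", "true_bmr": "true_bmr_ml_min",
    "true_ewl_inflection": "true_ewl_inflection_c",
    "true_ewl_baseline": "true_ewl_baseline_mg_h",
}


def individuals_to_frame(population: Sequence[IndividualRecord]) -> pd.DataFrame:
    rows = []
    for ind in population:
        rows.append({col: getattr(ind, attr)
                     for attr, col in _IND_COLUMNS.items()})
    return pd.DataFrame(rows)


def frame_to_individuals(frame: pd.DataFrame) -> list[IndividualRecord]:
    population = []
    for _, row in frame.iterrows():
        kwargs = {}
        for attr, col in _IND_COLUMNS.items():
            if col in frame.columns and not pd.isna(row[col]):
                kwargs[attr] = row[col]
        population.append(IndividualRecord(**kwargs))
    return population


def write_individuals(population: Sequence[IndividualRecord],
                      path: str | Path) -> None:
    individuals_to_frame(population).to_csv(path, index=False)


def read_individuals(path: str | Path) -> list[IndividualRecord]:
    return frame_to_individuals(pd.read_csv(path))


def profiles_to_frame(profiles: Sequence[ThermalProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for ta, vo2, ewl in zip(p.temps, p.vo2, p.ewl):
            rows.append({"id": p.individual_id, "ta_c": ta,
                         "vo2_ml_min": vo2, "ewl_mg_h": ewl})
    return pd.DataFrame(rows)


def frame_to_profiles(frame: pd.DataFrame) -> list[ThermalProfile]:
    profiles = []
    for ind_id, grp in frame.groupby("id", sort=False):
        grp = grp.sort_values("ta_c")
        profiles.append(ThermalProfile(
            str(ind_id), grp["ta_c"].to_numpy(),
            grp["vo2_ml_min"].to_numpy(), grp["ewl_mg_h"].to_numpy()))
    return profiles


def write_profiles(profiles: Sequence[ThermalProfile],
                   path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[ThermalProfile]:
    return frame_to_profiles(pd.read_csv(path))


def measures_to_frame(measures: Sequence[SteadyStateMeasure]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": m.individual_id, "ta_c": m.ta, "vo2_ml_min": m.vo2,
        "ewl_mg_h": m.ewl, "window_start_s": m.window_start,
        "window_end_s": m.window_end, "window_sd": m.window_sd,
        "flags": ";".join(m.flags),
    } for m in measures])


_TRACE_META = {
    "flow_rate_ml_min": ("flow_rate", float),
    "barometric_pressure_kpa": ("barometric_pressure", float),
    "ta_c": ("ta", float),
    "fio2": ("fio2", float),
    "incurrent_wvp_kpa": ("incurrent_wvp", float),
    "chamber_volume_l": ("chamber_volume_l", float),
    "individual_id": ("individual_id", str),
}


def write_trace(trace: RespirometryTrace, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, (attr, _) in _TRACE_META.items():
            fh.write(f"# {key}={getattr(trace, attr)}\n")
        pd.DataFrame({
            "time_s": trace.time,
            "o2_frac": trace.o2,
            "wvp_kpa": trace.wvp,
            "segment_id": trace.segment_id,
            "is_baseline": trace.is_baseline.astype(int),
        }).to_csv(fh, index=False)


def read_trace(path: str | Path) -> RespirometryTrace:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    kwargs = {}
    for key, (attr, cast) in _TRACE_META.items():
        if key in meta:
            kwargs[attr] = cast(meta[key])
    return RespirometryTrace(
        time=frame["time_s"].to_numpy(),
        o2=frame["o2_frac"].to_numpy(),
        wvp=frame["wvp_kpa"].to_numpy(),
        segment_id=frame["segment_id"].to_numpy(),
        is_baseline=frame["is_baseline"].to_numpy().astype(bool),
        **kwargs,
    )
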