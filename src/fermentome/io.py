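"""Readers and writers for the plain-text interchange formats.

Kinetic series travel as long-format CSV (time, variable, compartment,
replicate, value); trajectories as long-format TSV (taxon, kingdom,
replicate, time, abundance); feature and sensory tables as TSV with the
instance id in the first column.  Networks use the JSON format defined
in :mod:`fermentome.metnet`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import KineticSeries
from .trajectory import AbundanceTrajectory

__all__ = [
    "series_to_long",
    "series_from_long",
    "trajectories_to_long",
    "trajectories_from_long",
    "write_table",
    "read_table",
]

SERIES_COLUMNS = ["time", "variable", "compartment", "replicate", "value"]
TRAJ_COLUMNS = ["taxon", "kingdom", "replicate", "time", "abundance"]


def series_to_long(series_list, path=None) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for t, v in zip(s.times, s.values):
            rows.append((t, s.variable, s.compartment, s.replicate, v))
    df = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def series_from_long(source) -> list:
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"series table missing columns {sorted(missing)}")
    out = []
    for (var, comp, rep), grp in df.groupby(
        ["variable", "compartment", "replicate"], sort=True
    ):
        grp = grp.sort_values("time")
        out.append(
            KineticSeries(
                times=grp["time"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
                variable=str(var), compartment=str(comp), replicate=str(rep),
            )
        )
    return out


def trajectories_to_long(trajectories, path=None) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        for t, a in zip(tr.times, tr.abundances):
            rows.append((tr.taxon, tr.kingdom, tr.replicate, t, a))
    df = pd.DataFrame(rows, columns=TRAJ_COLUMNS)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def trajectories_from_long(source) -> list:
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    out = []
    for (taxon, kingdom, rep), grp in df.groupby(
        ["taxon", "kingdom", "replicate"], sort=True
    ):
        grp = grp.sort_values("time")
        out.append(
            AbundanceTrajectory(
                taxon=str(taxon), kingdom=str(kingdom), replicate=str(rep),
                times=grp["time"].to_numpy(dtype=float),
                abundances=np.clip(grp["abundance"].to_numpy(dtype=float), 0.0, 1.0),
            )
        )
    return out


def write_table(df: pd.DataFrame, path, index_label="instance") -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_label)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
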