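"""Delimited-table interfaces for experimental HX data and rate tables.

HX-MS CSV: peptide_id, chain, start, end, sequence, time_s, uptake_fraction
           [, replicate] — long format, one row per peptide/time(/replicate);
           replicates are averaged per time point on load.
HX-NMR CSV: chain, residue, value, value_type in {lnP, deltaG_kcal_mol}.
kint CSV:  chain, residue, kint_per_s.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import BiasMap, FitReport
from .forward import HxModelParams, PeptideCurve, lnP_from_deltaG

__all__ = [
    "read_hxms_csv", "write_hxms_csv",
    "read_hxnmr_csv", "read_kint_csv",
    "write_fit_report_csv", "write_bias_map_csv",
]


def read_hxms_csv(path) -> list[PeptideCurve]:
    """Load peptide uptake curves; replicate rows are averaged per time
    point before anything else happens."""
    df = pd.read_csv(path)
    required = {"peptide_id", "chain", "start", "end", "time_s", "uptake_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for pid, grp in df.groupby("peptide_id", sort=False):
        mean = grp.groupby("time_s", sort=True)["uptake_fraction"].mean()
        row = grp.iloc[0]
        curves.append(PeptideCurve(
            str(pid), str(row["chain"]), int(row["start"]), int(row["end"]),
            mean.index.to_numpy(dtype=float), mean.to_numpy(dtype=float),
            str(row.get("sequence", "") or "")))
    return curves


def write_hxms_csv(curves, path) -> None:
    rows = []
    for c in curves:
        for t, d in zip(c.times, c.uptake):
            rows.append({"peptide_id": c.peptide_id, "chain": c.chain,
                         "start": c.start, "end": c.end, "sequence": c.sequence,
                         "time_s": t, "uptake_fraction": d})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_hxnmr_csv(path, params: HxModelParams | None = None) -> pd.DataFrame:
    """Load per-residue observations; Delta-G values (kcal/mol) are converted
    to lnP on the fly. Returns columns chain, residue, lnP."""
    params = params or HxModelParams()
    df = pd.read_csv(path)
    required = {"chain", "residue", "value", "value_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["value_type"]) - {"lnP", "deltaG_kcal_mol"}
    if bad:
        raise ValueError(f"{path}: unknown value_type {sorted(bad)}")
    lnp = np.where(df["value_type"] == "lnP", df["value"],
                   [lnP_from_deltaG(v, params) for v in df["value"]])
    return pd.DataFrame({"chain": df["chain"].astype(str),
                         "residue": df["residue"].astype(int), "lnP": lnp})


def read_kint_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"chain", "residue", "kint_per_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["kint_per_s"] <= 0).any():
        raise ValueError(f"{path}: non-positive intrinsic rate")
    return df[["chain", "residue", "kint_per_s"]].assign(
        chain=df["chain"].astype(str), residue=df["residue"].astype(int))


def write_fit_report_csv(report: FitReport, path) -> None:
    """Per-item errors plus a trailing summary row (item_id='AVERAGE')."""
    df = report.to_frame()
    summary = pd.DataFrame([{"item_id": "AVERAGE", "error": report.average}])
    pd.concat([df, summary], ignore_index=True).to_csv(path, index=False)


def write_bias_map_csv(bias: BiasMap, path) -> None:
    bias.to_frame().to_csv(path, index=False)
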