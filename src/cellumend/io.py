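"""Readers and writers for the pipeline's plain-text formats.

Tables are TSV with taxa or probes as rows and samples as columns;
annotation columns are prefixed ``#`` so they cannot collide with
sample ids.  Forcing and observation series are CSV with an ISO-8601
date column.  Loaders validate invariants and name the offending
row/column in error messages.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mend import ForcingSeries
from .synthetic import CommunityTable, ObservationSet, ProbeTable, TraitReference

__all__ = [
    "write_community_table", "read_community_table",
    "write_trait_reference", "read_trait_reference",
    "write_probe_table", "read_probe_table",
    "write_forcing", "read_forcing",
    "write_observations", "read_observations",
]


def _check_nonnegative(df: pd.DataFrame, what: str) -> None:
    arr = df.to_numpy()
    bad = np.argwhere(arr < 0)
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"negative {what} at row {df.index[r]!r}, column {df.columns[c]!r}")


def write_community_table(table: CommunityTable, path, metadata_path=None) -> None:
    out = table.counts.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")
    if metadata_path is None:
        metadata_path = Path(path).with_suffix(".metadata.tsv")
    meta = table.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


def read_community_table(path, metadata_path=None) -> CommunityTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"duplicated sample ids: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_nonnegative(df, "abundance")
    counts = df.T
    counts.index.name = "sample_id"
    if metadata_path is None:
        metadata_path = Path(path).with_suffix(".metadata.tsv")
    if Path(metadata_path).exists():
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        meta = meta.loc[counts.index]
    else:
        meta = pd.DataFrame(index=counts.index)
        meta["group"] = [s.split("_")[0] for s in counts.index]
    return CommunityTable(counts=counts, metadata=meta)


def write_trait_reference(ref: TraitReference, path) -> None:
    t = ref.table.copy()
    t.index.name = "taxon_id"
    full = t.reindex(list(t.index) + list(ref.unmatched))
    full["matched"] = [True] * len(t) + [False] * len(ref.unmatched)
    full.to_csv(path, sep="\t")


def read_trait_reference(path) -> TraitReference:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "matched" in df.columns:
        matched = df[df["matched"].astype(bool)]
        unmatched = tuple(df.index[~df["matched"].astype(bool)])
        matched = matched.drop(columns=["matched"])
    else:
        matched, unmatched = df, ()
    return TraitReference(table=matched, unmatched=unmatched)


def write_probe_table(table: ProbeTable, path) -> None:
    out = table.intensities.copy()
    out.insert(0, "#gene", table.annotations["gene"])
    out.insert(1, "#category", table.annotations["category"])
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_probe_table(path) -> ProbeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    annot_cols = [c for c in df.columns if c.startswith("#")]
    annotations = df[annot_cols].rename(
        columns={c: c.lstrip("#") for c in annot_cols})
    intens = df.drop(columns=annot_cols).astype(float)
    _check_nonnegative(intens, "intensity")
    return ProbeTable(intensities=intens, annotations=annotations)


def write_forcing(forcing: ForcingSeries, path) -> None:
    dates = pd.date_range(forcing.start_date, periods=len(forcing), freq="D")
    pd.DataFrame({
        "date": dates.strftime("%Y-%m-%d"),
        "temperature_C": forcing.temperature,
        "moisture_vv": forcing.moisture,
        "litter_input": forcing.litter_input,
    }).to_csv(path, index=False)


def read_forcing(path) -> ForcingSeries:
    df = pd.read_csv(path)
    required = {"date", "temperature_C", "moisture_vv", "litter_input"}
    if not required.issubset(df.columns):
        raise ValueError(f"forcing CSV needs columns {sorted(required)}")
    dates = pd.to_datetime(df["date"])
    gaps = dates.diff().dropna()
    if (gaps != pd.Timedelta(days=1)).any():
        where = dates[1:][gaps != pd.Timedelta(days=1)].iloc[0].date()
        raise ValueError(
            f"forcing has a gap before {where}; supply a cleaned, gap-filled "
            "daily series")
    return ForcingSeries(temperature=df["temperature_C"].to_numpy(),
                         moisture=df["moisture_vv"].to_numpy(),
                         litter_input=df["litter_input"].to_numpy(),
                         start_date=str(dates.iloc[0].date()))


def write_observations(obs: ObservationSet, path, start_date="2016-01-01") -> None:
    base = pd.Timestamp(start_date)
    rows = []
    for name, days, vals in (("rh", obs.rh_days, obs.rh),
                             ("mbc", obs.mbc_days, obs.mbc),
                             ("gene", obs.gene_days, obs.gene)):
        for d, v in zip(days, vals):
            rows.append({"date": (base + pd.Timedelta(days=int(d))).date(),
                         "day": int(d), "variable": name, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_observations(path) -> ObservationSet:
    df = pd.read_csv(path)
    parts = {}
    for name in ("rh", "mbc", "gene"):
        sub = df[df["variable"] == name].sort_values("day")
        parts[name] = (sub["day"].to_numpy(dtype=int),
                       sub["value"].to_numpy(dtype=float))
    return ObservationSet(rh_days=parts["rh"][0], rh=parts["rh"][1],
                          mbc_days=parts["mbc"][0], mbc=parts["mbc"][1],
                          gene_days=parts["gene"][0], gene=parts["gene"][1])
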