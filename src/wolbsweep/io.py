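"""Readers, writers and run provenance.

Canonical tabular dialect is TSV (tab-separated, UTF-8, header row); CSV is
accepted on input via delimiter sniffing.  Coordinates are decimal degrees,
positions km, frequencies unitless in [0, 1]; percentages appear only in
reports.  Every pipeline run can drop a JSON provenance record (parameters,
seed, package version) next to its outputs; records contain no timestamps
so reruns are byte-identical.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .association import validate_records
from .model import Trajectory
from .wave import PopulationSite

__all__ = [
    "read_table",
    "write_table",
    "read_survey",
    "write_survey",
    "read_sites",
    "write_sites",
    "write_trajectory",
    "read_config",
    "write_provenance",
    "write_fasta",
]

_SITE_COLUMNS = ("site", "lat", "lon", "period", "n", "n_double")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV table, sniffing the delimiter."""
    return pd.read_csv(path, sep=None, engine="python")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_survey(path: str | Path) -> pd.DataFrame:
    """Individual-level survey records, validated against the schema."""
    df = read_table(path)
    if "haplotype" in df.columns:
        df["haplotype"] = df["haplotype"].fillna("untyped")
    for col in ("population", "period", "zone", "host_plant", "infection", "haplotype"):
        if col in df.columns:
            df[col] = df[col].astype(str)  # bare years must stay categorical
    return validate_records(df)


def write_survey(records: pd.DataFrame, path: str | Path) -> None:
    write_table(validate_records(records), path)


def read_sites(path: str | Path) -> list[PopulationSite]:
    df = read_table(path)
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table is missing columns: {missing}")
    return [
        PopulationSite(
            site=str(r.site), lat=float(r.lat), lon=float(r.lon),
            period=str(r.period), n=int(r.n), n_double=int(r.n_double),
        )
        for r in df.itertuples()
    ]


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    write_table(sites, path)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Trajectory TSV: generation, heritable and observed frequencies,
    invading-strain frequency and mismatch."""
    write_table(traj.to_dataframe(), path)


def read_config(path: str | Path) -> dict:
    """Flat key-value run configuration (YAML mapping, one level deep)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a key-value mapping")
    for key, value in cfg.items():
        if isinstance(value, (dict, list)):
            raise ValueError(f"config key {key!r} is nested; flat values only")
    return cfg


def package_version() -> str:
    try:
        return version("wolbsweep")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def write_provenance(path: str | Path, subcommand: str, params: dict,
                     seed: int | None = None) -> None:
    """Machine-readable run record; deterministic for identical runs."""
    record = {
        "tool": "wolbsweep",
        "version": package_version(),
        "subcommand": subcommand,
        "seed": seed,
        "params": params,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_fasta(records, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")
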