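"""Readers and writers for the artifact formats.

The per-sample mutation table is a TSV with one row per unique mutation
and columns ``clone`` (clone type label, 0 for unlabelled), ``alt``
(variant read count), ``depth`` (sequencing depth) and ``id`` (unique
mutation id); this is also the target-data input format for the inference
entry points.
"""

from __future__ import annotations

import pathlib

import pandas as pd
import yaml

from .params import SimulationParams
from .sequencing import VAFSpectrum

MUTATION_TABLE_COLUMNS = ["clone", "alt", "depth", "id"]


class SchemaError(ValueError):
    pass


def write_mutation_table(spectrum: VAFSpectrum, path) -> None:
    df = spectrum.df
    out = pd.DataFrame(
        {
            "clone": df["clone"] if "clone" in df else 0,
            "alt": df["alt"].astype(int),
            "depth": df["depth"].astype(int),
            "id": df["id"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_mutation_table(path, depth_nominal: float = 100.0) -> VAFSpectrum:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MUTATION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; expected {MUTATION_TABLE_COLUMNS}"
        )
    bad = df.index[(df["alt"] < 0) | (df["depth"] < 1) | (df["alt"] > df["depth"])]
    if len(bad):
        raise SchemaError(
            f"{path}: row {int(bad[0])} invalid (need 0 <= alt <= depth, depth >= 1)"
        )
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicated mutation id {dup!r}")
    spec = df.copy()
    spec["vaf"] = spec["alt"] / spec["depth"]
    spec = spec[["id", "alt", "depth", "vaf", "clone"]]
    return VAFSpectrum(spec, sample_id=pathlib.Path(str(path)).stem,
                       depth_nominal=depth_nominal)


def load_config(path) -> SimulationParams:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return SimulationParams.from_dict(cfg)


def save_config(params: SimulationParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
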