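"""Fragment table schema and I/O.

A fragment set is a pandas DataFrame with one simulated cfDNA molecule per
row — the universal currency between the simulator, the treatment operators
and the analysis statistics.

Columns
-------
contig : str            placement contig (spike-ins live on ``lambda_spikein``)
start, end : int        0-based half-open genomic span; ``length = end - start``
length : int            observed molecule length (nt for single strands, bp for duplexes);
                        for nicked duplexes this is the post-denaturation ladder length
duplex_length : int     full duplex length (== length except for nicked duplexes)
strand : {"+", "-"}
state : {"ss", "ds_intact", "ds_nicked"}
nicks : str             comma-joined within-fragment nick offsets, "" if none
umi : str               unique molecular identifier (8-mer by default)
population : {"uscf", "mncf", "spikein"}
treatment_history : str semicolon-joined operator labels, "" if untouched
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "SPIKEIN_CONTIG",
    "empty_fragments",
    "validate_fragments",
    "read_fragments_tsv",
    "write_fragments_tsv",
    "write_fragments_bed",
    "append_history",
    "parse_nicks",
    "format_nicks",
]

COLUMNS = (
    "contig",
    "start",
    "end",
    "length",
    "duplex_length",
    "strand",
    "state",
    "nicks",
    "umi",
    "population",
    "treatment_history",
)

SPIKEIN_CONTIG = "lambda_spikein"

_STATES = {"ss", "ds_intact", "ds_nicked"}
_POPULATIONS = {"uscf", "mncf", "spikein"}


class SchemaError(ValueError):
    """Fragment table violates the documented schema."""


def empty_fragments() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        COLUMNS,
        [str, np.int64, np.int64, np.int64, np.int64, str, str, str, str, str, str],
    )})
    return df


def validate_fragments(df: pd.DataFrame, require_umi: bool = False) -> pd.DataFrame:
    """Check schema and core invariants; returns ``df`` unchanged."""
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"fragment table is missing column {col!r}")
    if len(df) == 0:
        return df
    if (df["start"] < 0).any():
        raise SchemaError("negative fragment start")
    length = df["end"].to_numpy() - df["start"].to_numpy()
    if (length < 1).any():
        raise SchemaError("fragment with length < 1")
    if not np.array_equal(length, df["length"].to_numpy()):
        raise SchemaError("length column inconsistent with end - start")
    if (df["duplex_length"].to_numpy() < length).any():
        raise SchemaError("duplex_length smaller than observed length")
    bad_state = set(df["state"].unique()) - _STATES
    if bad_state:
        raise SchemaError(f"unknown strandedness state(s): {sorted(bad_state)}")
    bad_pop = set(df["population"].unique()) - _POPULATIONS
    if bad_pop:
        raise SchemaError(f"unknown population label(s): {sorted(bad_pop)}")
    nicked = df["state"] == "ds_nicked"
    if (nicked & (df["nicks"].fillna("") == "")).any():
        raise SchemaError("ds_nicked fragment without nick offsets")
    if require_umi and (df["umi"].fillna("") == "").any():
        raise SchemaError("fragment without UMI")
    return df


def parse_nicks(value: str) -> list[int]:
    if not value:
        return []
    return [int(x) for x in value.split(",")]


def format_nicks(offsets) -> str:
    return ",".join(str(int(x)) for x in offsets)


def append_history(df: pd.DataFrame, label: str) -> pd.DataFrame:
    """Append an operator label to every row's treatment_history (in place)."""
    hist = df["treatment_history"].fillna("")
    df["treatment_history"] = np.where(hist == "", label, hist + ";" + label)
    return df


def write_fragments_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, COLUMNS].to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "contig": str,
            "start": np.int64,
            "end": np.int64,
            "length": np.int64,
            "duplex_length": np.int64,
            "strand": str,
            "state": str,
            "nicks": str,
            "umi": str,
            "population": str,
            "treatment_history": str,
        },
        keep_default_na=False,
    )
    return validate_fragments(df)


def write_fragments_bed(df: pd.DataFrame, path: str | Path) -> None:
    """BED6+ export: name = population, score = length, plus schema extras."""
    out = pd.DataFrame(
        {
            "contig": df["contig"],
            "start": df["start"],
            "end": df["end"],
            "name": df["population"],
            "score": df["length"],
            "strand": df["strand"],
            "state": df["state"],
            "umi": df["umi"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
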