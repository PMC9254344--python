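"""In-silico enzyme digestions, library preparation and trace synthesis.

Enzyme susceptibility model
---------------------------
* ``dsDNase``  removes double-stranded molecules (intact or nicked);
* ``S1`` / ``P1`` / ``ExoI`` remove single-stranded molecules; S1 in addition
  trims jagged duplex ends (a narrow law centred on 10 bp total, split
  binomially between the two ends) and cleaves nicked duplexes at their nick
  offsets into intact sub-duplexes that re-enter the set;
* ``DNaseI`` removes everything; ``nick_repair`` converts nicked duplexes to
  intact ones at their full duplex length; ``RNase`` is the identity (every
  molecule here is DNA).

"Removes with probability efficiency" is an independent Bernoulli draw per
susceptible molecule.  No operator ever increases a molecule's length, and
total bp never increases (S1 cleavage conserves bp before trimming).

Library preparation
-------------------
The double-stranded kit accepts only duplexes (nicked ones, at their full
duplex length, unless disabled).  The single-stranded kit with heat
denaturation accepts everything, nicked duplexes entering as their
post-denaturation ladder pieces; without heat, duplexes enter only with a
small leak probability.  Every accepted molecule gets
``library_size = insert + adapter_total_bp`` (150 bp of adapters by default).

The synthesized electropherogram trace places a Gaussian kernel (σ = 5 bp)
at each molecule's library size on a 1 bp axis spanning [35, 1000] bp, so
the integrated area is proportional to molecule count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .fixtures import ConfigurationError
from .fragments import (
    append_history,
    format_nicks,
    parse_nicks,
    validate_fragments,
)

__all__ = [
    "ENZYMES",
    "TreatmentSpec",
    "LibraryPrep",
    "Trace",
    "digest",
    "prepare_library",
    "synthesize_trace",
]

ENZYMES = ("dsDNase", "S1", "P1", "ExoI", "DNaseI", "nick_repair", "RNase")
_SS_NUCLEASES = {"S1", "P1", "ExoI"}


@dataclass(frozen=True)
class TreatmentSpec:
    """One enzymatic treatment: which enzyme, how completely it acts."""

    enzyme: str
    efficiency: float = 0.95
    s1_trim_total: int = 10  # mean total jagged-end trim in bp (S1 only)

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ConfigurationError(f"unknown enzyme {self.enzyme!r}; known: {ENZYMES}")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ConfigurationError("efficiency must lie in [0, 1]")
        if self.s1_trim_total < 0:
            raise ConfigurationError("s1_trim_total must be non-negative")


@dataclass(frozen=True)
class LibraryPrep:
    """Library-preparation chemistry: kit type, denaturation, adapter mass."""

    kit: str = "ss"
    heat_denaturation: bool = True
    adapter_total_bp: int = 150
    ds_without_heat_efficiency: float = 0.05
    include_nicked_in_ds: bool = True

    def __post_init__(self) -> None:
        if self.kit not in ("ss", "ds"):
            raise ConfigurationError("kit must be 'ss' or 'ds'")
        if not 0.0 <= self.ds_without_heat_efficiency <= 1.0:
            raise ConfigurationError("ds_without_heat_efficiency must lie in [0, 1]")

    @property
    def label(self) -> str:
        if self.kit == "ds":
            return "lib:ds"
        return "lib:ss+heat" if self.heat_denaturation else "lib:ss-no-heat"


def _draw_trim_totals(rng: np.random.Generator, n: int, mean: int) -> np.ndarray:
    """Narrow symmetric law on {mean-1, mean, mean+1} with weights (.25, .5, .25)."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    t = mean + rng.choice(np.array([-1, 0, 1]), size=n, p=[0.25, 0.5, 0.25])
    return np.maximum(t, 0)


def _cleave_nicked(
    rows: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Cut each nicked duplex at its nick offsets into intact sub-duplexes."""
    pieces = []
    for _, row in rows.iterrows():
        offsets = [0] + parse_nicks(row["nicks"]) + [int(row["length"])]
        for a, b in zip(offsets[:-1], offsets[1:]):
            if b <= a:
                continue
            piece = row.copy()
            piece["start"] = row["start"] + a
            piece["end"] = row["start"] + b
            piece["length"] = b - a
            piece["duplex_length"] = b - a
            piece["state"] = "ds_intact"
            piece["nicks"] = ""
            pieces.append(piece)
    if not pieces:
        return rows.iloc[0:0]
    out = pd.DataFrame(pieces).reset_index(drop=True)
    # cleavage products are new molecules; give them fresh UMIs
    codes = rng.integers(0, 4, size=(len(out), 8))
    alphabet = np.array(list("ACGT"))
    out["umi"] = ["".join(alphabet[c]) for c in codes]
    return out


def digest(fragments: pd.DataFrame, spec: TreatmentSpec, seed: int = 0) -> pd.DataFrame:
    """Apply one enzymatic treatment; returns the surviving fragment set."""
    validate_fragments(fragments)
    rng = np.random.default_rng(seed)
    df = fragments.reset_index(drop=True).copy()
    state = df["state"].to_numpy()
    eff = spec.efficiency

    if spec.enzyme == "RNase":
        out = df
    elif spec.enzyme == "DNaseI":
        keep = rng.random(len(df)) >= eff
        out = df.loc[keep]
    elif spec.enzyme == "dsDNase":
        susceptible = np.isin(state, ["ds_intact", "ds_nicked"])
        removed = susceptible & (rng.random(len(df)) < eff)
        out = df.loc[~removed]
    elif spec.enzyme == "nick_repair":
        nicked = state == "ds_nicked"
        acted = nicked & (rng.random(len(df)) < eff)
        df.loc[acted, "end"] = df.loc[acted, "start"] + df.loc[acted, "duplex_length"]
        df.loc[acted, "length"] = df.loc[acted, "duplex_length"]
        df.loc[acted, "state"] = "ds_intact"
        df.loc[acted, "nicks"] = ""
        out = df
    elif spec.enzyme in _SS_NUCLEASES:
        removed = (state == "ss") & (rng.random(len(df)) < eff)
        out = df.loc[~removed].reset_index(drop=True)
        if spec.enzyme == "S1":
            # cleave nicked duplexes at their nicks (per-molecule efficiency)
            nicked = out["state"].to_numpy() == "ds_nicked"
            cleave = nicked & (rng.random(len(out)) < eff)
            pieces = _cleave_nicked(out.loc[cleave], rng)
            out = pd.concat([out.loc[~cleave], pieces], ignore_index=True)
            # jagged-end trimming of all surviving duplexes
            is_ds = np.isin(out["state"].to_numpy(), ["ds_intact", "ds_nicked"])
            idx = np.flatnonzero(is_ds)
            totals = _draw_trim_totals(rng, idx.size, spec.s1_trim_total)
            lengths = out["length"].to_numpy()
            totals = np.minimum(totals, lengths[idx] - 1)  # keep length >= 1
            left = rng.binomial(totals, 0.5)
            right = totals - left
            starts = out["start"].to_numpy().copy()
            ends = out["end"].to_numpy().copy()
            starts[idx] += left
            ends[idx] -= right
            out["start"] = starts
            out["end"] = ends
            out["length"] = ends - starts
            trimmed_duplex = out["duplex_length"].to_numpy().copy()
            trimmed_duplex[idx] -= totals
            out["duplex_length"] = np.maximum(trimmed_duplex, out["length"].to_numpy())
            # trimming a still-nicked duplex shifts/culls its nick offsets
            still_nicked = np.flatnonzero(out["state"].to_numpy() == "ds_nicked")
            trim_left = np.zeros(len(out), dtype=np.int64)
            trim_left[idx] = left
            for j in still_nicked:
                L = int(out.at[j, "length"])
                offs = [o - int(trim_left[j]) for o in parse_nicks(out.at[j, "nicks"])]
                offs = [o for o in offs if 0 < o < L]
                if offs:
                    out.at[j, "nicks"] = format_nicks(offs)
                else:
                    out.at[j, "state"] = "ds_intact"
                    out.at[j, "nicks"] = ""
                    out.at[j, "duplex_length"] = L
    else:  # pragma: no cover - ENZYMES is closed
        raise ConfigurationError(f"unknown enzyme {spec.enzyme!r}")

    out = out.reset_index(drop=True).copy()
    label = spec.enzyme if spec.enzyme != "S1" else f"S1(trim~{spec.s1_trim_total})"
    append_history(out, f"{label}@{eff:g}")
    return validate_fragments(out)


def prepare_library(
    fragments: pd.DataFrame, prep: LibraryPrep | None = None, seed: int = 0
) -> pd.DataFrame:
    """Convert molecules to library products with a ``library_size`` column."""
    prep = prep or LibraryPrep()
    validate_fragments(fragments)
    rng = np.random.default_rng(seed)
    df = fragments.reset_index(drop=True).copy()
    state = df["state"].to_numpy()
    insert = df["length"].to_numpy().copy()

    if prep.kit == "ds":
        accept = state == "ds_intact"
        if prep.include_nicked_in_ds:
            accept |= state == "ds_nicked"
        # a nicked duplex ligates as the full (un-denatured) duplex
        insert = np.where(state == "ds_nicked", df["duplex_length"].to_numpy(), insert)
    elif prep.heat_denaturation:
        # everything enters; nicked duplexes contribute their ladder pieces,
        # which is exactly the generated `length`
        accept = np.ones(len(df), dtype=bool)
    else:
        leak = rng.random(len(df)) < prep.ds_without_heat_efficiency
        accept = (state == "ss") | (np.isin(state, ["ds_intact", "ds_nicked"]) & leak)
        insert = np.where(state == "ds_nicked", df["duplex_length"].to_numpy(), insert)

    out = df.loc[accept].reset_index(drop=True).copy()
    out["library_size"] = insert[accept] + prep.adapter_total_bp
    append_history(out, prep.label)
    return out


# ---------------------------------------------------------------------------
# Electropherogram traces
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """Capillary-electrophoresis-like trace: size axis (bp) vs intensity (FU)."""

    sizes: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sizes.shape != self.intensity.shape:
            raise ValueError("sizes and intensity must have equal shapes")
        if (np.diff(self.sizes) <= 0).any():
            raise ValueError("size axis must be strictly increasing")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"size": self.sizes, "intensity": self.intensity}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Trace":
        df = pd.read_csv(path, sep="\t")
        return cls(df["size"].to_numpy(), df["intensity"].to_numpy())


def synthesize_trace(
    library: pd.DataFrame,
    kernel_sigma: float = 5.0,
    axis: tuple[int, int] = (35, 1000),
) -> Trace:
    """Render a library as a smooth trace (one unit of area per molecule)."""
    if len(library) == 0:
        raise ValueError("cannot synthesize a trace from an empty library")
    if "library_size" not in library.columns:
        raise ValueError("library table lacks a library_size column (run prepare_library)")
    lo, hi = axis
    sizes = np.arange(lo, hi + 1)
    counts = np.bincount(
        np.clip(library["library_size"].to_numpy(), lo, hi) - lo, minlength=sizes.size
    ).astype(float)
    intensity = gaussian_filter1d(counts, sigma=kernel_sigma, mode="constant")
    return Trace(sizes=sizes, intensity=intensity)
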