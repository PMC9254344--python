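"""Size-partitioned fragmentomics statistics.

Implements the read-level statistics of an ultrashort-vs-mononucleosomal
cfDNA study: size filtering into the ultrashort (25-100 nt) and
mononucleosomal (101-250 bp) classes with everything else excluded,
exact-match UMI deduplication, 1 bp length histograms with modal length and
10 bp periodicity detection, chromosome distribution, 100 bp binned genome
coverage with Pearson correlation, midpoint-based functional-element
profiles normalized to the genomic bp baseline (overall and per 10 bp size
bin), and electropherogram quantification of the ultrashort fraction.

Fragments are assigned to loci by their midpoint, ``floor((start+end)/2)``
— fragment-level annotation stands in for the peak-call-then-annotate route
used on deep real data sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fixtures import CLASSES, ElementAnnotation, GenomeModel
from .fragments import validate_fragments
from .treatments import Trace

__all__ = [
    "SizeClassConfig",
    "LengthHistogram",
    "ElementProfile",
    "BinnedCoverage",
    "size_filter_classify",
    "deduplicate",
    "modal_length",
    "periodicity",
    "PeriodicityResult",
    "chrom_distribution",
    "bin_coverage",
    "pearson_matrix",
    "annotate_fragments",
    "element_profile",
    "size_binned_profile",
    "default_size_bins",
    "quantify_trace",
    "library_to_insert",
]


@dataclass(frozen=True)
class SizeClassConfig:
    """Inclusive length ranges of the two analyte classes."""

    uscf_range: tuple[int, int] = (25, 100)
    mncf_range: tuple[int, int] = (101, 250)

    def __post_init__(self) -> None:
        u_lo, u_hi = self.uscf_range
        m_lo, m_hi = self.mncf_range
        if not (u_lo <= u_hi < m_lo <= m_hi):
            raise ValueError("size ranges must be ordered, disjoint and contiguous-compatible")


def size_filter_classify(
    fragments: pd.DataFrame, cfg: SizeClassConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Partition fragments by length into uscf / mncf / excluded (exhaustive, disjoint)."""
    cfg = cfg or SizeClassConfig()
    length = fragments["length"].to_numpy()
    uscf = (length >= cfg.uscf_range[0]) & (length <= cfg.uscf_range[1])
    mncf = (length >= cfg.mncf_range[0]) & (length <= cfg.mncf_range[1])
    return {
        "uscf": fragments.loc[uscf].reset_index(drop=True),
        "mncf": fragments.loc[mncf].reset_index(drop=True),
        "excluded": fragments.loc[~(uscf | mncf)].reset_index(drop=True),
    }


def deduplicate(fragments: pd.DataFrame) -> pd.DataFrame:
    """Exact-match UMI deduplication on (contig, start, end, strand, umi).

    The first occurrence of each key is retained.  Error-tolerant UMI
    clustering is deliberately not modelled.
    """
    validate_fragments(fragments, require_umi=True)
    return fragments.drop_duplicates(
        subset=["contig", "start", "end", "strand", "umi"], keep="first"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Length histograms: modality and periodicity
# ---------------------------------------------------------------------------


@dataclass
class LengthHistogram:
    """1 bp-resolution fragment-length histogram."""

    lengths: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.lengths.shape != self.counts.shape:
            raise ValueError("lengths and counts must have equal shapes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_lengths(cls, values: Sequence[int] | np.ndarray) -> "LengthHistogram":
        values = np.asarray(values, dtype=np.int64)
        if values.size == 0:
            raise ValueError("cannot build a histogram from zero fragments")
        lo, hi = int(values.min()), int(values.max())
        lengths = np.arange(lo, hi + 1)
        counts = np.bincount(values - lo, minlength=lengths.size)
        return cls(lengths=lengths, counts=counts)

    @classmethod
    def from_fragments(cls, fragments: pd.DataFrame) -> "LengthHistogram":
        return cls.from_lengths(fragments["length"].to_numpy())

    @classmethod
    def from_counts(cls, counts: Mapping[int, int]) -> "LengthHistogram":
        if not counts:
            raise ValueError("cannot build a histogram from an empty mapping")
        lo, hi = min(counts), max(counts)
        lengths = np.arange(lo, hi + 1)
        arr = np.array([counts.get(int(l), 0) for l in lengths], dtype=np.int64)
        return cls(lengths=lengths, counts=arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def window(self, lo: int, hi: int) -> np.ndarray:
        """Counts on the inclusive window [lo, hi] (zero-filled outside support)."""
        out = np.zeros(hi - lo + 1, dtype=np.int64)
        mask = (self.lengths >= lo) & (self.lengths <= hi)
        out[self.lengths[mask] - lo] = self.counts[mask]
        return out

    def to_tsv(self, path) -> None:
        pd.DataFrame({"length": self.lengths, "count": self.counts}).to_csv(
            path, sep="\t", index=False
        )


def modal_length(hist: LengthHistogram) -> int:
    """Argmax length of the histogram; ties break toward the smallest length."""
    if hist.total == 0:
        raise ValueError("empty histogram has no mode")
    return int(hist.lengths[int(np.argmax(hist.counts))])


@dataclass(frozen=True)
class PeriodicityResult:
    period: int
    contrast: float


def periodicity(
    hist: LengthHistogram,
    window: tuple[int, int] = (100, 160),
    periods: Sequence[int] = tuple(range(2, 21)),
    smoothing_half_width: int = 5,
) -> PeriodicityResult:
    """Dominant oscillation period of the histogram inside ``window``.

    Counts are detrended by subtracting a centered moving average
    (half-width ``smoothing_half_width``, edge windows shrink to available
    support); the dominant period is the lag maximizing the normalized
    autocorrelation of the detrended signal, ties toward the smaller lag.
    The contrast score is that autocorrelation value.  Deterministic given
    the histogram.
    """
    lo, hi = window
    span = hi - lo + 1
    max_p = max(periods)
    if span < 2 * max_p:
        raise ValueError(
            f"window [{lo}, {hi}] is shorter than twice the maximum candidate period {max_p}"
        )
    if hi < hist.lengths[0] or lo > hist.lengths[-1]:
        raise ValueError("window does not overlap the histogram range")
    y = hist.window(lo, hi).astype(float)
    h = smoothing_half_width
    kernel = np.ones(2 * h + 1)
    trend = np.convolve(y, kernel, mode="same") / np.convolve(np.ones_like(y), kernel, mode="same")
    z = y - trend
    denom = float(np.sum(z * z))
    if denom == 0.0:
        return PeriodicityResult(period=int(min(periods)), contrast=0.0)
    best_p, best_r = None, -np.inf
    for p in periods:
        r = float(np.sum(z[:-p] * z[p:]) / denom)
        if r > best_r:
            best_p, best_r = int(p), r
    return PeriodicityResult(period=best_p, contrast=best_r)


# ---------------------------------------------------------------------------
# Genomic distribution
# ---------------------------------------------------------------------------


def chrom_distribution(fragments: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    """Per-contig fragment fraction and per-Mb density (fractions sum to 1)."""
    if len(fragments) == 0:
        raise ValueError("no fragments")
    counts = fragments["contig"].value_counts()
    unknown = set(counts.index) - set(genome.names)
    if unknown:
        raise ValueError(f"fragments on contig(s) unknown to the genome: {sorted(unknown)}")
    n = len(fragments)
    rows = []
    for name, length in genome.contigs:
        c = int(counts.get(name, 0))
        frac = c / n
        rows.append((name, length, c, frac, frac / (length / 1e6)))
    return pd.DataFrame(rows, columns=["contig", "length", "n", "fraction", "per_mb"]).set_index(
        "contig"
    )


def _midpoints(fragments: pd.DataFrame) -> np.ndarray:
    return (fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2


@dataclass
class BinnedCoverage:
    """Fragment counts per fixed-size genomic bin, concatenated in contig order.

    Bins tile each contig independently (last bin truncated); a fragment is
    assigned to the bin containing its midpoint under half-open bin edges.
    """

    genome: GenomeModel
    bin_size: int
    vector: np.ndarray

    @property
    def total(self) -> int:
        return int(self.vector.sum())


def _bin_offsets(genome: GenomeModel, bin_size: int) -> dict[str, int]:
    offsets, acc = {}, 0
    for name, length in genome.contigs:
        offsets[name] = acc
        acc += -(-length // bin_size)  # ceil
    offsets["__total__"] = acc
    return offsets


def bin_coverage(
    fragments: pd.DataFrame, genome: GenomeModel, bin_size: int = 100
) -> BinnedCoverage:
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    offsets = _bin_offsets(genome, bin_size)
    total_bins = offsets.pop("__total__")
    vector = np.zeros(total_bins, dtype=np.int64)
    mids = _midpoints(fragments)
    for contig, sub_idx in fragments.groupby("contig", sort=False).indices.items():
        if contig not in offsets:
            raise ValueError(f"fragments on contig {contig!r} unknown to the genome")
        bins = mids[sub_idx] // bin_size + offsets[contig]
        np.add.at(vector, bins, 1)
    return BinnedCoverage(genome=genome, bin_size=bin_size, vector=vector)


def pearson_matrix(
    coverages: Sequence[BinnedCoverage | np.ndarray],
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation matrix of binned-coverage vectors (raw counts)."""
    vectors = [c.vector if isinstance(c, BinnedCoverage) else np.asarray(c, float) for c in coverages]
    if names is None:
        names = [f"sample{i}" for i in range(len(vectors))]
    n = {len(v) for v in vectors}
    if len(n) != 1:
        raise ValueError("coverage vectors have unequal lengths")
    for name, v in zip(names, vectors):
        if np.std(v) == 0:
            raise ValueError(f"coverage vector {name!r} has zero variance")
    mat = np.corrcoef(np.vstack([np.asarray(v, float) for v in vectors]))
    mat = np.atleast_2d(mat)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=list(names), columns=list(names))


# ---------------------------------------------------------------------------
# Functional-element profiles
# ---------------------------------------------------------------------------


def annotate_fragments(fragments: pd.DataFrame, annotation: ElementAnnotation) -> pd.Series:
    """Functional class of each fragment's midpoint bp."""
    classes = np.empty(len(fragments), dtype=object)
    mids = _midpoints(fragments)
    for contig, sub_idx in fragments.groupby("contig", sort=False).indices.items():
        codes = annotation.class_codes_at(contig, mids[sub_idx])
        classes[sub_idx] = np.asarray(CLASSES, dtype=object)[codes]
    return pd.Series(classes, index=fragments.index, name="klass")


@dataclass
class ElementProfile:
    """Fragment proportions per functional class and their ratio to the genome baseline."""

    proportions: dict[str, float]
    n: int
    ratio_to_baseline: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(CLASSES),
                "proportion": [self.proportions.get(c, 0.0) for c in CLASSES],
                "ratio_to_baseline": [self.ratio_to_baseline.get(c, np.nan) for c in CLASSES],
            }
        )


def element_profile(
    classes: pd.Series | Sequence[str], baseline: Mapping[str, float]
) -> ElementProfile:
    """Summarize per-fragment classes against the genomic bp baseline."""
    classes = pd.Series(classes)
    n = len(classes)
    if n == 0:
        raise ValueError("element profile of zero fragments is undefined")
    counts = classes.value_counts()
    proportions = {c: float(counts.get(c, 0) / n) for c in CLASSES}
    ratios = {
        c: proportions[c] / baseline[c] for c in CLASSES if baseline.get(c, 0.0) > 0
    }
    return ElementProfile(proportions=proportions, n=n, ratio_to_baseline=ratios)


def default_size_bins(lo: int = 25, hi: int = 100, width: int = 10) -> list[tuple[int, int]]:
    """Half-open 10 bp bins tiling [lo, hi]; the last bin is closed at ``hi``."""
    edges = list(range(lo, hi, width)) + [hi + 1]
    return [(a, b) for a, b in zip(edges[:-1], edges[1:])]


def size_binned_profile(
    fragments: pd.DataFrame,
    annotation: ElementAnnotation,
    baseline: Mapping[str, float] | None = None,
    bins: Sequence[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Element profile per fragment-length bin.

    Returns a tidy frame (bin_lo, bin_hi, class, n, proportion, ratio); bins
    with zero fragments carry NaN proportions/ratios rather than zeros.
    """
    baseline = baseline if baseline is not None else annotation.baseline
    bins = list(bins) if bins is not None else default_size_bins()
    classes = annotate_fragments(fragments, annotation)
    length = fragments["length"].to_numpy()
    rows = []
    for lo, hi in bins:
        mask = (length >= lo) & (length < hi)
        n = int(mask.sum())
        if n == 0:
            for c in CLASSES:
                rows.append((lo, hi, c, 0, np.nan, np.nan))
            continue
        prof = element_profile(classes[mask], baseline)
        for c in CLASSES:
            rows.append(
                (lo, hi, c, n, prof.proportions[c], prof.ratio_to_baseline.get(c, np.nan))
            )
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "class", "n", "proportion", "ratio"])


# ---------------------------------------------------------------------------
# Electropherogram quantification
# ---------------------------------------------------------------------------


def quantify_trace(
    trace: Trace,
    region_a: tuple[int, int] = (180, 250),
    region_b: tuple[int, int] = (251, 350),
) -> float:
    """Ultrashort fraction area(A) / (area(A) + area(B)) by trapezoidal integration.

    Region A spans the ultrashort library band (inclusive 180-250 bp by
    default) and region B the mononucleosomal band (251-350 bp); a 250-350 bp
    variant of region B can be passed explicitly.
    """
    for lo, hi in (region_a, region_b):
        if lo < trace.sizes[0] or hi > trace.sizes[-1]:
            raise ValueError(f"region [{lo}, {hi}] outside the trace axis")

    def area(lo: int, hi: int) -> float:
        mask = (trace.sizes >= lo) & (trace.sizes <= hi)
        return float(np.trapezoid(trace.intensity[mask], trace.sizes[mask]))

    a, b = area(*region_a), area(*region_b)
    if a + b == 0:
        raise ValueError("zero total intensity in the quantification regions")
    return a / (a + b)


def library_to_insert(library_size: int, adapter_total: int = 150) -> int:
    """Insert size of a library molecule (library size minus adapter mass)."""
    if library_size <= adapter_total:
        raise ValueError(
            f"library size {library_size} is within the adapter-dimer regime (<= {adapter_total})"
        )
    return int(library_size) - int(adapter_total)
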