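"""Deterministic synthetic fixtures: genome, functional-element annotation, oligos.

The genome is a small stand-in for a mammalian reference: a handful of
autosome-like contigs plus one mitochondrial contig whose default length is
the canonical 16,569 bp of the human mitochondrial genome.  Gene models are
placed at random (non-overlapping, including their promoter/terminator
margins) and resolved into a single functional class per base pair with the
precedence promoter > TTS > exon > intron > intergenic, mirroring how
annotatePeaks-style tools assign one label per locus.

Coordinates are 0-based half-open throughout; BED output is therefore
written natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "CLASSES",
    "PRECEDENCE",
    "GenomeModel",
    "AnnotationParams",
    "ElementAnnotation",
    "default_genome_spec",
    "build_genome",
    "read_genome_fasta",
    "annotate_elements",
]

#: Functional classes, listed in precedence order (highest first).
CLASSES = ("promoter", "TTS", "exon", "intron", "intergenic")
PRECEDENCE = CLASSES

_CLASS_CODE = {c: i for i, c in enumerate(CLASSES)}
_INTERGENIC = _CLASS_CODE["intergenic"]

_DEFAULT_CONTIGS = (("chrA", 10_000_000), ("chrB", 10_000_000), ("chrM", 16_569))


class ConfigurationError(ValueError):
    """Invalid genome/annotation configuration."""


class PlacementError(RuntimeError):
    """Gene models could not be placed without overlap."""


@dataclass(frozen=True)
class GenomeModel:
    """Ordered contigs plus the identity of the mitochondrial contig."""

    contigs: tuple[tuple[str, int], ...] = _DEFAULT_CONTIGS
    mito_name: str = "chrM"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate contig name(s): {', '.join(dup)}")
        for name, length in self.contigs:
            if length < 1:
                raise ConfigurationError(f"contig {name!r} has non-positive length {length}")
        if self.mito_name not in names:
            raise ConfigurationError(
                f"mitochondrial contig {self.mito_name!r} not among contigs"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.contigs)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.contigs)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.contigs)

    @property
    def mito_fraction(self) -> float:
        """bp fraction of the mitochondrial contig (≈8.28e-4 for the default build)."""
        return self.lengths[self.mito_name] / self.total_bp

    def nuclear_contigs(self) -> tuple[tuple[str, int], ...]:
        return tuple((n, l) for n, l in self.contigs if n != self.mito_name)


def default_genome_spec() -> GenomeModel:
    """Two 10 Mb autosome-like contigs plus a 16,569 bp mitochondrial contig."""
    return GenomeModel()


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> bytes:
    return _BASES[rng.integers(0, 4, size=length)].tobytes()


def build_genome(
    spec: GenomeModel | Sequence[tuple[str, int]] | None = None,
    seed: int = 0,
    fasta_path: str | Path | None = None,
    mito_name: str = "chrM",
    line_width: int = 80,
) -> GenomeModel:
    """Materialize a :class:`GenomeModel`, optionally writing a uniform-random FASTA.

    Identical ``seed`` (and spec) yields byte-identical FASTA output.
    """
    if spec is None:
        genome = GenomeModel()
    elif isinstance(spec, GenomeModel):
        genome = spec
    else:
        genome = GenomeModel(tuple((str(n), int(l)) for n, l in spec), mito_name=mito_name)
    if fasta_path is not None:
        rng = np.random.default_rng(seed)
        with open(fasta_path, "wb") as fh:
            for name, length in genome.contigs:
                fh.write(f">{name}\n".encode())
                seq = _random_sequence(rng, length)
                for i in range(0, length, line_width):
                    fh.write(seq[i : i + line_width])
                    fh.write(b"\n")
    return genome


def read_genome_fasta(path: str | Path, mito_name: str = "chrM") -> GenomeModel:
    """Recover a :class:`GenomeModel` (names and lengths) from a FASTA file."""
    fa = Fasta(str(path), build_index=True, rebuild=True)
    contigs = tuple((name, len(fa[name])) for name in fa.keys())
    fa.close()
    return GenomeModel(contigs, mito_name=mito_name)


# ---------------------------------------------------------------------------
# Element annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationParams:
    """Geometry of the synthetic gene models.

    Defaults are sized so that on the default 20 Mb genome the baseline is
    intergenic-dominated (>60% of bp), with promoters/TTS a percent or two and
    introns dominating the genic fraction — the qualitative shape of a
    mammalian functional-element profile.
    """

    n_genes: int = 300
    exons_per_gene: int = 5
    exon_length: int = 200
    intron_length: int = 4_500
    promoter_upstream: int = 1_000
    promoter_downstream: int = 100
    tts_upstream: int = 100
    tts_downstream: int = 1_000
    max_attempts: int = 10_000

    @property
    def gene_body_length(self) -> int:
        return (
            self.exons_per_gene * self.exon_length
            + (self.exons_per_gene - 1) * self.intron_length
        )


@dataclass
class ElementAnnotation:
    """Precedence-resolved single-class labelling of every genomic bp.

    ``raw_features`` keeps the unresolved per-feature intervals (promoter/TTS
    windows, exons, introns) exactly as generated; ``intervals`` holds the
    resolved, non-overlapping, genome-covering segments.  Intergenic is the
    complement and never appears in ``raw_features``.
    """

    genome: GenomeModel
    #: unresolved features: DataFrame(contig, start, end, klass, strand)
    raw_features: pd.DataFrame
    #: resolved per-contig segmentation: contig -> (starts, ends, class codes)
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(repr=False)

    def __post_init__(self) -> None:
        self._baseline_bp: dict[str, int] | None = None

    # -- resolution ---------------------------------------------------------

    @classmethod
    def from_features(
        cls, genome: GenomeModel, features: pd.DataFrame
    ) -> "ElementAnnotation":
        """Resolve possibly-overlapping features into one class per bp.

        Features are painted onto a per-contig array in increasing precedence
        order so the highest-precedence class wins; unpainted bp are
        intergenic.  Resolution is idempotent by construction.
        """
        intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        lengths = genome.lengths
        for contig, length in genome.contigs:
            arr = np.full(length, _INTERGENIC, dtype=np.uint8)
            sub = features[features["contig"] == contig]
            # paint lowest precedence first so higher precedence overwrites
            for klass in reversed(PRECEDENCE[:-1]):
                for _, row in sub[sub["klass"] == klass].iterrows():
                    s = max(0, int(row["start"]))
                    e = min(length, int(row["end"]))
                    if e > s:
                        arr[s:e] = _CLASS_CODE[klass]
            intervals[contig] = _run_length_encode(arr)
        for contig in set(features["contig"]) - set(lengths):
            raise ConfigurationError(f"feature on unknown contig {contig!r}")
        return cls(genome=genome, raw_features=features.reset_index(drop=True), intervals=intervals)

    # -- queries ------------------------------------------------------------

    def class_codes_at(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Class code of each genomic position (vectorized)."""
        if contig not in self.intervals:
            raise ConfigurationError(f"unknown contig {contig!r}")
        starts, ends, codes = self.intervals[contig]
        positions = np.asarray(positions)
        if positions.size and (positions.min() < 0 or positions.max() >= ends[-1]):
            raise ValueError(f"position outside contig {contig!r}")
        idx = np.searchsorted(starts, positions, side="right") - 1
        return codes[idx]

    def class_at(self, contig: str, position: int) -> str:
        return CLASSES[int(self.class_codes_at(contig, np.array([position]))[0])]

    @property
    def baseline_bp(self) -> dict[str, int]:
        """Exact bp count per class over the whole genome."""
        if self._baseline_bp is None:
            counts = dict.fromkeys(CLASSES, 0)
            for starts, ends, codes in self.intervals.values():
                widths = ends - starts
                for code in np.unique(codes):
                    counts[CLASSES[code]] += int(widths[codes == code].sum())
            self._baseline_bp = counts
        return dict(self._baseline_bp)

    @property
    def baseline(self) -> dict[str, float]:
        """Genome-wide bp fraction per class (sums to 1)."""
        bp = self.baseline_bp
        total = sum(bp.values())
        return {c: bp[c] / total for c in CLASSES}

    # -- I/O ----------------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        """Write resolved non-intergenic intervals as BED6 (name = class)."""
        rows = []
        for contig, _ in self.genome.contigs:
            starts, ends, codes = self.intervals[contig]
            for s, e, c in zip(starts, ends, codes):
                if c != _INTERGENIC:
                    rows.append((contig, int(s), int(e), CLASSES[c], 0, "."))
        pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score", "strand"]).to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bed(cls, genome: GenomeModel, path: str | Path) -> "ElementAnnotation":
        """Rebuild an annotation from a resolved BED6 (intergenic recomputed)."""
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["contig", "start", "end", "name", "score", "strand"],
            dtype={"contig": str, "name": str},
        )
        feats = bed.rename(columns={"name": "klass"})[["contig", "start", "end", "klass"]]
        feats["strand"] = "."
        return cls.from_features(genome, feats)

    def baseline_to_tsv(self, path: str | Path) -> None:
        bp = self.baseline_bp
        frac = self.baseline
        pd.DataFrame(
            {"class": list(CLASSES), "bp": [bp[c] for c in CLASSES], "fraction": [frac[c] for c in CLASSES]}
        ).to_csv(path, sep="\t", index=False)


def _run_length_encode(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment a per-bp class array into (starts, ends, codes)."""
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [arr.size]))
    return starts.astype(np.int64), ends.astype(np.int64), arr[starts]


def _gene_features(
    contig: str, start: int, strand: str, params: AnnotationParams
) -> list[tuple[str, int, int, str, str]]:
    """Feature intervals of one gene whose body occupies [start, start+body)."""
    body = params.gene_body_length
    end = start + body
    feats: list[tuple[str, int, int, str, str]] = []
    # exon/intron ladder along the body, orientation-independent geometry
    pos = start
    for i in range(params.exons_per_gene):
        feats.append((contig, pos, pos + params.exon_length, "exon", strand))
        pos += params.exon_length
        if i < params.exons_per_gene - 1:
            feats.append((contig, pos, pos + params.intron_length, "intron", strand))
            pos += params.intron_length
    if strand == "+":
        tss, tes = start, end
        feats.append((contig, tss - params.promoter_upstream, tss + params.promoter_downstream, "promoter", strand))
        feats.append((contig, tes - params.tts_upstream, tes + params.tts_downstream, "TTS", strand))
    else:
        tss, tes = end, start  # TSS at the right edge on the minus strand
        feats.append((contig, tss - params.promoter_downstream, tss + params.promoter_upstream, "promoter", strand))
        feats.append((contig, tes - params.tts_downstream, tes + params.tts_upstream, "TTS", strand))
    return feats


def annotate_elements(
    genome: GenomeModel,
    params: AnnotationParams | None = None,
    seed: int = 0,
) -> ElementAnnotation:
    """Place non-overlapping gene models on the nuclear contigs and resolve classes.

    The mitochondrial contig carries no gene models (it is entirely
    intergenic).  Placement is rejection sampling over uniform positions; a
    gene's footprint includes its promoter and TTS windows so neighbouring
    genes never share bp even before precedence resolution.
    """
    params = params or AnnotationParams()
    rng = np.random.default_rng(seed)
    nuclear = genome.nuclear_contigs()
    if not nuclear:
        raise ConfigurationError("genome has no nuclear contigs to carry genes")
    body = params.gene_body_length
    # flank margin covering promoter/TTS windows in either orientation
    margin = max(
        params.promoter_upstream, params.promoter_downstream,
        params.tts_upstream, params.tts_downstream,
    )
    weights = np.array([l for _, l in nuclear], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n, _ in nuclear}
    features: list[tuple[str, int, int, str, str]] = []
    attempts = 0
    n_placed = 0
    while n_placed < params.n_genes:
        if attempts >= params.max_attempts:
            raise PlacementError(
                f"placed {n_placed}/{params.n_genes} genes after {attempts} attempts"
            )
        attempts += 1
        ci = rng.choice(len(nuclear), p=weights)
        contig, clen = nuclear[ci]
        lo, hi = margin, clen - body - margin
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        span = (start - margin, start + body + margin)
        if any(not (span[1] <= s or span[0] >= e) for s, e in placed[contig]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        placed[contig].append(span)
        features.extend(_gene_features(contig, start, strand, params))
        n_placed += 1
    feats = pd.DataFrame(features, columns=["contig", "start", "end", "klass", "strand"])
    return ElementAnnotation.from_features(genome, feats)
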