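"""Synthetic cell-free DNA fragmentome sampling.

The generator draws a bimodal mixture of two molecule populations:

* ``uscf`` — ultrashort, single-stranded molecules with a sharp modal length
  of 50 nt on the support [25, 100] nt, placed with enrichment over
  promoters/exons/introns (and a size-conditioned promoter peak around
  45-55 nt);
* ``mncf`` — mononucleosomal duplexes with a sharp modal length of 160 bp on
  [101, 250] bp, placed with intergenic enrichment.  A configurable fraction
  carries single-strand nicks; such molecules are generated at a
  post-denaturation "ladder" length drawn from {150, 140, 130, 120, 110} bp
  (geometric weights, ±1 bp jitter), producing the 10 bp periodicity on the
  left shoulder of the nucleosomal peak, while their full duplex length is
  retained in ``duplex_length``.

Placement: a functional class is chosen with probability proportional to
(class bp) × (per-population enrichment multiplier) × (size-conditioned
multiplier, ultrashort only); then a resolved interval of that class is
chosen proportional to its bp, and the fragment midpoint is uniform within
the interval.  With all multipliers at 1 placement is uniform per bp over
the genome, so the mitochondrial contig receives its bp share
(16,569 / 20,016,569 ≈ 8.3e-4 of fragments under the default genome).

Length-dependent extraction retention is modelled as a logistic curve per
method (QiaC / QiaM / SPRI); the low-molecular-weight-retaining methods have
strictly higher retention below 100 nt, with SPRI above QiaM at 30-50 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixtures import CLASSES, ElementAnnotation, GenomeModel, ConfigurationError
from .fragments import COLUMNS, SPIKEIN_CONTIG, format_nicks, validate_fragments
from .oligos import LADDER_SIZES, OligoCatalog

__all__ = [
    "PopulationConfig",
    "ExtractionModel",
    "simulate_population",
    "add_spikeins",
    "apply_extraction",
    "spikein_recovery",
]

_UMI_ALPHABET = np.array(list("ACGT"))


def _default_element_weights() -> dict[str, dict[str, float]]:
    # Directionality mirrors the observed element profiles: ultrashort
    # molecules enriched over promoters/exons/introns, nucleosomal molecules
    # enriched intergenic.
    return {
        "uscf": {"promoter": 2.5, "TTS": 1.0, "exon": 1.6, "intron": 1.3, "intergenic": 0.85},
        "mncf": {"promoter": 0.5, "TTS": 0.9, "exon": 0.6, "intron": 0.8, "intergenic": 1.25},
    }


def _default_size_curves() -> dict[str, tuple[float, float, float, float]]:
    # Multiplier values at the knots (25, 45, 55, 100) nt; linear in between.
    # Promoter enrichment peaks in the 45-55 nt window; intergenic weight
    # rises toward 100 nt.
    return {
        "promoter": (0.6, 2.2, 2.2, 0.4),
        "intergenic": (1.0, 0.9, 0.9, 1.8),
    }


@dataclass
class PopulationConfig:
    """Generative parameters of the two-population fragmentome mixture."""

    n_total: int = 50_000
    uscf_fraction: float = 0.45

    # ultrashort length law: sharp two-sided-exponential peak + uniform background
    uscf_support: tuple[int, int] = (25, 100)
    uscf_mode: int = 50
    uscf_scale_left: float = 4.0
    uscf_scale_right: float = 7.0
    uscf_background: float = 0.25

    # mononucleosomal length law: discretized two-sided exponential
    mncf_support: tuple[int, int] = (101, 250)
    mncf_mode: int = 160
    mncf_scale: float = 4.0

    # nicked-duplex ladder
    nick_fraction: float = 0.25
    ladder_modes: tuple[int, ...] = (150, 140, 130, 120, 110)
    ladder_decay: float = 0.8
    ladder_jitter: int = 1

    # placement enrichment
    element_weights: dict[str, dict[str, float]] = field(default_factory=_default_element_weights)
    size_curve_knots: tuple[int, int, int, int] = (25, 45, 55, 100)
    size_curves: dict[str, tuple[float, float, float, float]] = field(default_factory=_default_size_curves)
    mito_weight: float = 1.0

    umi_length: int = 8
    seed: int | None = None
    max_placement_rounds: int = 1_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.uscf_fraction <= 1.0:
            raise ConfigurationError("uscf_fraction must lie in [0, 1]")
        if self.n_total < 0:
            raise ConfigurationError("n_total must be non-negative")
        for pop, weights in self.element_weights.items():
            for klass, w in weights.items():
                if w <= 0:
                    raise ConfigurationError(f"non-positive multiplier for {pop}/{klass}")
        if self.mito_weight <= 0:
            raise ConfigurationError("mito_weight must be positive")

    # -- length distributions ----------------------------------------------

    def uscf_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.uscf_support
        lengths = np.arange(lo, hi + 1)
        sharp = np.where(
            lengths <= self.uscf_mode,
            np.exp(-(self.uscf_mode - lengths) / self.uscf_scale_left),
            np.exp(-(lengths - self.uscf_mode) / self.uscf_scale_right),
        )
        sharp /= sharp.sum()
        background = np.full(lengths.size, 1.0 / lengths.size)
        pmf = (1 - self.uscf_background) * sharp + self.uscf_background * background
        return lengths, pmf / pmf.sum()

    def mncf_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.mncf_support
        lengths = np.arange(lo, hi + 1)
        pmf = np.exp(-np.abs(lengths - self.mncf_mode) / self.mncf_scale)
        return lengths, pmf / pmf.sum()

    def ladder_weights(self) -> np.ndarray:
        w = self.ladder_decay ** np.arange(len(self.ladder_modes))
        return w / w.sum()

    def size_multiplier(self, klass: str, lengths: np.ndarray) -> np.ndarray:
        """Piecewise-linear size-conditioned multiplier for ultrashort placement."""
        if klass not in self.size_curves:
            return np.ones(np.asarray(lengths).shape)
        return np.interp(lengths, self.size_curve_knots, self.size_curves[klass])


# ---------------------------------------------------------------------------
# Extraction retention
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtractionModel:
    """Logistic length-dependent retention probability for one extraction method."""

    method: str
    floor: float
    ceiling: float
    midpoint: float
    slope: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.floor <= self.ceiling <= 1.0):
            raise ConfigurationError("retention floor/ceiling must satisfy 0 <= floor <= ceiling <= 1")
        if self.slope <= 0:
            raise ConfigurationError("slope must be positive")

    def retention(self, lengths) -> np.ndarray:
        lengths = np.asarray(lengths, dtype=float)
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + np.exp(-(lengths - self.midpoint) / self.slope)
        )

    PRESETS = {
        # The standard silica-column protocol loses most sub-100 nt material;
        # the miRNA-protocol and bead-based methods retain it, with the
        # bead-based method strongest at 30-50 nt.
        "QiaC": dict(floor=0.02, ceiling=0.90, midpoint=120.0, slope=20.0),
        "QiaM": dict(floor=0.25, ceiling=0.90, midpoint=70.0, slope=25.0),
        "SPRI": dict(floor=0.35, ceiling=0.90, midpoint=60.0, slope=25.0),
    }

    @classmethod
    def preset(cls, method: str) -> "ExtractionModel":
        if method not in cls.PRESETS:
            raise ConfigurationError(f"unknown extraction method {method!r}")
        return cls(method=method, **cls.PRESETS[method])


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------


def _random_umis(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    if n == 0:
        return np.array([], dtype=object)
    codes = rng.integers(0, 4, size=(n, k))
    chars = _UMI_ALPHABET[codes]
    return np.array(["".join(row) for row in chars], dtype=object)


def _class_interval_tables(
    annotation: ElementAnnotation, mito_weight: float
) -> dict[str, dict[str, np.ndarray]]:
    """Per-class flattened interval arrays with bp weights (mito contig scaled)."""
    genome = annotation.genome
    contig_index = {name: i for i, name in enumerate(genome.names)}
    tables: dict[str, dict[str, list]] = {
        c: {"contig": [], "start": [], "end": [], "weight": []} for c in CLASSES
    }
    for contig, _ in genome.contigs:
        starts, ends, codes = annotation.intervals[contig]
        scale = mito_weight if contig == genome.mito_name else 1.0
        for s, e, c in zip(starts, ends, codes):
            klass = CLASSES[c]
            tables[klass]["contig"].append(contig_index[contig])
            tables[klass]["start"].append(int(s))
            tables[klass]["end"].append(int(e))
            tables[klass]["weight"].append((e - s) * scale)
    out: dict[str, dict[str, np.ndarray]] = {}
    for klass, t in tables.items():
        if not t["start"]:
            continue
        w = np.asarray(t["weight"], dtype=float)
        out[klass] = {
            "contig": np.asarray(t["contig"]),
            "start": np.asarray(t["start"], dtype=np.int64),
            "end": np.asarray(t["end"], dtype=np.int64),
            "cumw": np.cumsum(w),
        }
    return out


def simulate_population(
    genome: GenomeModel,
    annotation: ElementAnnotation,
    config: PopulationConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample ``config.n_total`` fragments from the two-population mixture.

    Sampling order per fragment: population by mixture fraction → length from
    that population's law (nicked nucleosomal molecules draw a ladder length
    and keep their duplex length separately) → placement class by
    baseline × enrichment → interval and midpoint within the class → strand
    and UMI.  A fixed seed reproduces the set exactly.
    """
    config = config or PopulationConfig()
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    n = config.n_total
    contig_lengths = np.array([l for _, l in genome.contigs], dtype=np.int64)
    contig_names = np.array(genome.names, dtype=object)

    # populations
    is_uscf = rng.random(n) < config.uscf_fraction
    population = np.where(is_uscf, "uscf", "mncf").astype(object)

    # lengths and strandedness states
    lengths = np.zeros(n, dtype=np.int64)
    duplex = np.zeros(n, dtype=np.int64)
    state = np.empty(n, dtype=object)
    n_uscf = int(is_uscf.sum())
    u_lengths, u_pmf = config.uscf_pmf()
    lengths[is_uscf] = rng.choice(u_lengths, size=n_uscf, p=u_pmf)
    duplex[is_uscf] = lengths[is_uscf]
    state[is_uscf] = "ss"

    mncf_idx = np.flatnonzero(~is_uscf)
    n_mncf = mncf_idx.size
    m_lengths, m_pmf = config.mncf_pmf()
    nicked_mask = rng.random(n_mncf) < config.nick_fraction
    intact_idx = mncf_idx[~nicked_mask]
    nicked_idx = mncf_idx[nicked_mask]
    lengths[intact_idx] = rng.choice(m_lengths, size=intact_idx.size, p=m_pmf)
    duplex[intact_idx] = lengths[intact_idx]
    state[intact_idx] = "ds_intact"
    if nicked_idx.size:
        ladder = rng.choice(
            np.asarray(config.ladder_modes), size=nicked_idx.size, p=config.ladder_weights()
        )
        if config.ladder_jitter:
            ladder = ladder + rng.integers(
                -config.ladder_jitter, config.ladder_jitter + 1, size=nicked_idx.size
            )
        full = rng.choice(m_lengths, size=nicked_idx.size, p=m_pmf)
        full = np.maximum(full, ladder + 2)  # duplex strictly longer than its ladder piece
        lengths[nicked_idx] = ladder
        duplex[nicked_idx] = full
        state[nicked_idx] = "ds_nicked"

    # placement class per fragment: probs ∝ class bp-weight × enrichment × size curve
    class_bp = np.zeros(len(CLASSES))
    tables = _class_interval_tables(annotation, config.mito_weight)
    for i, klass in enumerate(CLASSES):
        if klass in tables:
            class_bp[i] = tables[klass]["cumw"][-1]
    probs = np.zeros((n, len(CLASSES)))
    ew = config.element_weights
    for i, klass in enumerate(CLASSES):
        w = np.full(n, class_bp[i])
        for pop in ("uscf", "mncf"):
            mask = population == pop
            w[mask] *= ew.get(pop, {}).get(klass, 1.0)
        if class_bp[i] > 0:
            w[is_uscf] *= config.size_multiplier(klass, lengths[is_uscf])
        probs[:, i] = w
    row_sum = probs.sum(axis=1)
    if (row_sum <= 0).any():
        raise ConfigurationError("no placeable class for some fragments")
    cum = np.cumsum(probs / row_sum[:, None], axis=1)
    u = rng.random(n)
    klass_idx = (u[:, None] > cum).sum(axis=1)

    # place fragments: interval by bp weight, midpoint uniform, bounded retries
    start = np.zeros(n, dtype=np.int64)
    contig_of = np.zeros(n, dtype=np.int64)
    for i, klass in enumerate(CLASSES):
        rows = np.flatnonzero(klass_idx == i)
        if rows.size == 0:
            continue
        if klass not in tables:
            raise ConfigurationError(f"class {klass!r} absent from the genome")
        t = tables[klass]
        cumw = t["cumw"]
        total = cumw[-1]
        pending = rows
        for _ in range(config.max_placement_rounds):
            if pending.size == 0:
                break
            iv = np.searchsorted(cumw, rng.random(pending.size) * total, side="right")
            s_iv, e_iv = t["start"][iv], t["end"][iv]
            mid = s_iv + (rng.random(pending.size) * (e_iv - s_iv)).astype(np.int64)
            cand_start = mid - lengths[pending] // 2
            cand_end = cand_start + lengths[pending]
            clen = contig_lengths[t["contig"][iv]]
            ok = (
                (cand_start >= 0)
                & (cand_end <= clen)
                & (cand_start + duplex[pending] <= clen)
            )
            good = pending[ok]
            start[good] = cand_start[ok]
            contig_of[good] = t["contig"][iv[ok]]
            pending = pending[~ok]
        if pending.size:
            raise ConfigurationError(
                f"could not place {pending.size} fragments of class {klass!r} "
                f"within {config.max_placement_rounds} rounds"
            )

    strand = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
    umi = _random_umis(rng, n, config.umi_length)

    # nick offsets, strictly inside (0, length)
    nicks = np.full(n, "", dtype=object)
    for j in np.flatnonzero(state == "ds_nicked"):
        L = int(lengths[j])
        k = 1 if (L <= 2 or rng.random() < 0.7) else 2
        offs = rng.choice(np.arange(1, L), size=min(k, L - 1), replace=False)
        nicks[j] = format_nicks(np.sort(offs))

    df = pd.DataFrame(
        {
            "contig": contig_names[contig_of],
            "start": start,
            "end": start + lengths,
            "length": lengths,
            "duplex_length": duplex,
            "strand": strand,
            "state": state,
            "nicks": nicks,
            "umi": umi,
            "population": population,
            "treatment_history": "",
        },
        columns=list(COLUMNS),
    )
    return validate_fragments(df)


# ---------------------------------------------------------------------------
# Spike-ins and extraction
# ---------------------------------------------------------------------------


def add_spikeins(
    fragments: pd.DataFrame,
    catalog: OligoCatalog,
    copies_per_size: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Append single-stranded ladder spike-ins on a dedicated lambda contig.

    Lengths are the catalog's actual string lengths (which may deviate from
    the nominal ladder sizes by a nucleotide or two).  The input table is not
    modified.
    """
    if copies_per_size < 0:
        raise ValueError("copies_per_size must be non-negative")
    if copies_per_size == 0:
        return fragments.copy()
    rng = np.random.default_rng(seed)
    rows = []
    for name in LADDER_SIZES:
        L = len(catalog.records[name])
        rows.append(
            pd.DataFrame(
                {
                    "contig": SPIKEIN_CONTIG,
                    "start": 0,
                    "end": L,
                    "length": L,
                    "duplex_length": L,
                    "strand": "+",
                    "state": "ss",
                    "nicks": "",
                    "umi": _random_umis(rng, copies_per_size, 8),
                    "population": "spikein",
                    "treatment_history": "",
                }
            )
        )
    out = pd.concat([fragments, *rows], ignore_index=True)
    return validate_fragments(out)


def apply_extraction(
    fragments: pd.DataFrame, model: ExtractionModel, seed: int = 0
) -> pd.DataFrame:
    """Thin the set by length-dependent retention (independent Bernoulli draws)."""
    rng = np.random.default_rng(seed)
    p = model.retention(fragments["length"].to_numpy())
    keep = rng.random(len(fragments)) < p
    from .fragments import append_history

    out = fragments.loc[keep].reset_index(drop=True).copy()
    return append_history(out, f"extract:{model.method}")


def spikein_recovery(pre: pd.DataFrame, post: pd.DataFrame) -> dict[int, float]:
    """Recovered fraction per spike-in ladder size (survivors / input).

    Sizes absent from the input are not reported (undefined rather than 0);
    a size present only in the output is a consistency error.
    """
    pre_s = pre.loc[pre["population"] == "spikein", "length"].value_counts()
    post_s = post.loc[post["population"] == "spikein", "length"].value_counts()
    extra = set(post_s.index) - set(pre_s.index)
    if extra:
        raise ValueError(f"spike-in size(s) {sorted(extra)} present after but not before")
    return {int(size): float(post_s.get(size, 0) / n_in) for size, n_in in pre_s.items()}
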