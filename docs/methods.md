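# Methods

This note documents the generative model, the statistics, the default
parameter choices and their rationale, and what the synthetic data does and
does not emulate.

## Coordinate and schema conventions

All coordinates are 0-based half-open; BED output is therefore written
without conversion. A fragment table row is one molecule with `length =
end − start`. For nicked duplexes (`ds_nicked`) the coordinate span and
`length` are the molecule's *post-denaturation ladder length* — the length
at which it appears in single-stranded libraries and aligned-insert
histograms — while the full duplex length is kept in `duplex_length`
(always ≥ `length`). Generation guarantees `start + duplex_length ≤ contig
length`, so nick repair (which rewrites `end = start + duplex_length`) can
never leave the contig.

## Synthetic genome and annotation

The default genome is two 10 Mb autosome-like contigs plus one 16,569 bp
mitochondrial contig, so the mitochondrial bp share is 16,569/20,016,569 ≈
8.28×10⁻⁴ — under uniform per-bp placement the expected mitochondrial
fragment fraction is below 0.1%. Sequence content is uniform random and is
only needed when a FASTA file is requested; every downstream statistic
works on coordinates.

Gene models (default 300) are placed by rejection sampling on the nuclear
contigs, with a flank margin so that no two genes share bp even before
precedence resolution; the mitochondrial contig carries none. Each gene is
an exon/intron ladder (5 exons × 200 bp, 4 introns × 4,500 bp by default)
with a promoter window `[TSS−1000, TSS+100)` and a TTS window
`[TES−100, TES+1000)` on the gene strand. These windows follow the common
annotatePeaks-style defaults; no standard window definition exists for a
synthetic genome, so both are exposed as parameters. Classes are resolved
to one label per bp by painting features in increasing precedence order
(`promoter > TTS > exon > intron > intergenic`, UTRs folded into exon);
intergenic is the complement and is never stored as gene intervals. The
default geometry yields a baseline of roughly 1.7% promoter, 1.7% TTS,
1.2% exon, 27% intron and 69% intergenic — intergenic-dominated (≥60%), as
in a mammalian functional-element profile.

## Length laws

**Ultrashort (uscf), support 25–100 nt, mode 50 nt.** A discretized
two-sided exponential peak (scale 4 nt left of the mode, 7 nt right) mixed
with a 25% uniform background over the support. The sharp component makes
the printed mode statistically identifiable at desk scale (the peak bin
exceeds its neighbours by ≈4σ at n = 50,000); the background populates the
60–100 nt range so that size-resolved element profiles near 100 nt are
measurable. Only the mode and support are externally constrained; the
shape is this package's choice and fully parameterized.

**Mononucleosomal (mncf), support 101–250 bp, mode 160 bp.** A discretized
two-sided exponential with scale 4 bp. A Gaussian with σ ≈ 15 bp was
considered and rejected: its top is so flat (adjacent-bp probability ratio
≈ 0.998) that the sample mode at n = 50,000 is an essentially uniform draw
among several lengths near 160, making the modal length meaningless as a
statistic. The sharp peak is also the more realistic description of the
nucleosomal maximum riding on the fragment-length distribution.

**Nicked ladder.** A fraction (default 0.25) of mncf molecules are
`ds_nicked`: they draw a ladder length from {150, 140, 130, 120, 110} bp
with geometric weights (ratio 0.8) and ±1 bp uniform jitter, and keep a
full duplex length drawn from the mncf law (forced > ladder length). The
nick offsets (1–2 per molecule) are uniform strictly inside the fragment.
The decay ratio and nick fraction were chosen once so the ladder is clearly
detectable while the 160 bp mode still dominates the class histogram; both
are exposed in `PopulationConfig`.

## Placement model

Per fragment: a functional class is drawn with probability ∝ (class bp
weight) × (per-population enrichment multiplier) × (size-conditioned
multiplier, uscf only); an interval of that class is drawn ∝ its bp (the
mitochondrial contig's intervals can be re-weighted via `mito_weight`,
default 1 = length-proportional); the fragment midpoint is uniform within
the interval and the start is `midpoint − length//2`. Out-of-bounds
candidates are re-drawn (bounded retries). With all multipliers at 1 this
is exactly uniform per-bp placement.

Default multipliers encode the observed directionality — ultrashort
molecules enriched over promoters (2.5), exons (1.6) and introns (1.3) and
depleted intergenic (0.85); nucleosomal molecules the opposite (intergenic
1.25, promoter 0.5, exon 0.6, intron 0.8). The uscf size-conditioned
curves are piecewise linear with knots at 25/45/55/100 nt: the promoter
multiplier peaks on 45–55 nt (0.6 → 2.2 → 2.2 → 0.4) and the intergenic
multiplier rises toward 100 nt (1.0 → 0.9 → 0.9 → 1.8). Only the
qualitative shape is externally constrained; the values are this package's
defaults and are configurable.

UMIs are uniform 8-mers (4⁸ = 65,536 keys). At desk-scale depths the
probability that two *distinct* molecules share both coordinates and UMI
is negligible; exact-match deduplication is therefore unbiased here,
unlike on deep real libraries where error-tolerant UMI clustering matters.

## Extraction retention

Retention is a logistic in length, `floor + (ceiling − floor) / (1 +
exp(−(L − midpoint)/slope))`, applied as an independent Bernoulli per
molecule. Presets: QiaC (floor 0.02, midpoint 120, slope 20) loses most
sub-100 nt material; QiaM (floor 0.25, midpoint 70, slope 25) and SPRI
(floor 0.35, midpoint 60, slope 25) retain it, with SPRI above QiaM at
30–50 nt. The curves are monotone non-decreasing and satisfy the stated
orderings at every length ≤ 100 nt; absolute values are not externally
constrained and were fixed once at plausible magnitudes. Spike-in recovery
(survivors/input per ladder size) reports sizes with zero input as
undefined rather than zero.

## Treatments

Susceptibility: dsDNase removes duplexes (intact or nicked); S1/P1/Exo I
remove single strands; DNase I removes everything; RNase is the identity;
nick repair converts `ds_nicked` to `ds_intact` at the full duplex length,
clearing the nick offsets. "Removes with probability `efficiency`"
(default 0.95, unconstrained externally) is an independent Bernoulli draw.

S1 additionally (i) cleaves surviving nicked duplexes at their nick
offsets into intact sub-duplexes that re-enter the set (bp-conserving) and
(ii) trims jagged duplex ends. The total trim per molecule is drawn from a
narrow symmetric law on {mean−1, mean, mean+1} with weights (0.25, 0.5,
0.25), mean 10 bp, split binomially between the two ends. A Poisson(10)
total trim was considered and rejected: its spread smears the modal
downshift so that the 160 → 150 bp shift is not reliably detectable at
n = 50,000, whereas jagged single-stranded overhangs are short and tightly
distributed, which the narrow law captures while preserving the 10 bp
mean. No treatment increases any molecule's length, and total bp never
increases.

Library preparation: the ds kit accepts only duplexes — nicked ones at
their full duplex length (physically ligatable; excludable via
`include_nicked_in_ds`). The ss kit with heat denaturation accepts
everything, nicked duplexes entering as their ladder pieces; a denatured
intact duplex contributes one library molecule (not two strands) to keep
count conservation simple — a deliberate deviation from physical
stoichiometry. Without heat, duplexes leak in with probability 0.05.
`library_size = insert + 150 bp` of adapters.

Traces: each library molecule contributes a Gaussian kernel (σ = 5 bp,
matching typical band widths) at its library size on a 1 bp axis spanning
35–1000 bp, so integrated area ∝ molecule count. `%uscfDNA` integrates
the 180–250 bp region against 251–350 bp (trapezoidal, inclusive integer
bounds); a 250–350 bp variant of the second region is selectable.

## Statistics

* **Size classes**: uscf = [25, 100], mncf = [101, 250], inclusive;
  lengths outside [25, 250] are excluded. The partition is exhaustive and
  disjoint.
* **Modal length**: histogram argmax, ties toward the smaller length.
* **Periodicity**: counts in the window (default 100–160 bp, zero-filled
  where the window extends past the histogram support) are detrended by a
  centered moving average and the dominant period is the lag (2–20 bp)
  maximizing the normalized autocorrelation `Σ z_t z_{t+p} / Σ z_t²`; the
  contrast score is that value. The smoothing half-width default is 5
  (11-bin window): a 21-bin moving average contains two full 10 bp periods
  and nearly cancels the oscillation it is supposed to expose, which —
  together with the nucleosomal-peak flank at the window edge — made the
  lag-10/lag-20 argmax unstable; with half-width 5 the period-10 margin is
  wide at desk scale. The half-width remains a parameter.
* **Fragment → locus assignment** is by midpoint bp, `floor((start+end)/2)`,
  for element classes and for 100 bp coverage bins (half-open bins tiling
  each contig independently, last bin truncated). Direct fragment
  annotation stands in for peak calling plus peak annotation, which needs
  read depths far beyond desk scale.
* **Element profiles** report per-class fragment proportions and their
  ratio to the genomic bp baseline (defined only where the baseline is
  positive). The size-binned variant uses half-open 10 bp bins over
  [25, 100] with the final bin closed at 100; empty bins are undefined
  (NaN), not zero.
* **Pearson correlation** of binned coverages is computed on raw counts
  (no log transform); zero-variance vectors are an error naming the
  sample.

## Problem sizes and determinism

Default problem sizes — 20 Mb genome, 300 genes, n = 50,000 fragments
(100,000 for the uniform-placement run) — were chosen so that every
statistic above has the power to resolve its expected value (peak-bin
separations of ≥3–4σ, binomial SEs a few 10⁻³) while a full replay runs in
seconds. Every stochastic operation takes an explicit seed and reproduces
byte-identical output for the same seed.

## Oligo catalog

The ladder and control oligo strings are stored verbatim as printed,
including degenerate N positions. Counted lengths: lambda 30 → 30 nt
(23 fixed + 7 N), lambda 50 → 51, lambda 75 → 75, lambda 100 → 100,
lambda 150 → 150, lambda 200 → 198 — all within ±2 nt of the nominal
ladder sizes. The dsDNA control string is 459 nt (nominally 460) and the
ssDNA control 349 nt (stated variously as 350 or 356). The catalog does
not silently correct these; spike-in fragments use the actual string
lengths.

## What the synthetic data does not emulate

No base-level sequence content effects (GC bias, mappability), no
sequencing errors or FASTQ generation, no PCR amplification bias, no
adapter-dimer artifacts beyond exclusion by size, no enzyme kinetics
(efficiencies are single Bernoulli probabilities), no real genome builds
or tissue-specific annotations. Passing tests therefore demonstrate that
the statistics correctly measure the generative model's properties — not
that real plasma libraries will show these exact numbers. The relative
abundance of the two populations in plasma is unknown; the default mixture
fraction (45% ultrashort) is an arbitrary, configurable choice, and every
mixture-recovery test treats it as a free parameter.
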