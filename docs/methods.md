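# Methods

`lhekit` models the computational side of characterizing a re-targeted
LAGLIDADG homing endonuclease (LHE) and its megaTAL fusion: how specific
the enzyme is around its ~20 bp recognition site, where in a genome it
might cut besides the intended locus, how much editing it achieved at a
sequenced locus, and how tightly it binds its substrate. This note records
the models, the defaults, and the design choices that were genuinely open.

## Coordinate system and mismatch nomenclature

An LHE site of even length L (canonically 20) is indexed by signed labels
−L/2 … −1, +1 … +L/2 with no zero; the cleavage point sits between −1 and
+1. Label ↔ index conversion is the bijection `idx = label + L/2` (label <
0) / `idx = label + L/2 − 1` (label > 0), so −10 → 0 and +10 → 19 for
L = 20. All genomic intervals are 0-based half-open.

Differences between sites are written as concatenated `position+base`
tokens (`-10G-8A`, `+4T+8G`), naming the *variant's* base at each
differing position. The parser accepts ASCII `-`, the typographic minus
`−`, explicit `+`, and bare digits (positive); output is always ASCII with
explicit signs, so label files are grep-safe.

The four mismatch *clusters* used during interface engineering
(`-10A-8T`, `-6C-5C-4T`, `+6T+7G`, `+9C+10T`) are structure-informed: a
purely positional rule (e.g. "merge labels separated by one position")
would merge the −10…−4 run into one cluster. They are therefore accepted
as configuration and validated against the computed mismatch labels, never
derived.

## Specificity profiles and the tolerance rule

A one-off profile records the cleavage of all 3L single-base variants of
the site, normalized so the on-target sequence is exactly 1 (`r = raw /
on_target`; normalization fails loudly when on-target cleavage is zero).
With tolerance threshold θ (default 0.5, i.e. 50% of on-target):

* cell `(position, base)` is **tolerated** iff `r > θ` (strictly; `r = θ`
  is not tolerated — the classification prose is consistent only with a
  strict cut);
* a position is **degenerate** iff at least one of its three alternative
  cells is tolerated, otherwise **specific**;
* a multi-mismatch candidate site is predicted **tolerated** iff *every*
  constituent single mismatch is individually tolerated. This binary
  combination rule is the prediction used for genomic hits; a quantitative
  product-of-r score under an independence assumption is available
  (`combined_score`) but is reporting-only, never part of the call.

When per-cell standard errors are present they are carried through and
reported; classification always uses the point estimate (profiles are
measured in small replicate numbers, and propagating SEs through a strict
threshold would only manufacture false confidence).

## Off-target scanning

`scan` slides the target over every window of every genome sequence on
both strands and reports each window with Hamming distance ≤ k_max (default
2, matching the 1–2 bp near-match search that motivates it). The
implementation is a vectorized exact comparison (numpy, one pass per
target position), so completeness is structural rather than heuristic; the
test suite checks it bit-for-bit against a position-by-position Python
oracle. Ambiguity codes (N, R, …) never match and thus count as
mismatches — conservative for discovery. Palindromic windows matching on
both strands are reported once per strand, since each orientation is a
distinct binding mode; overlapping windows are all reported. An upstream
TALE half-site is deliberately *not* used to filter hits: in the
motivating data the absence of homologous TALE boxes at near-match loci
was an observation, not a selection criterion.

## Read classification

Reads are aligned globally (affine gaps) against the reference amplicon in
both orientations, keeping the better score. Gap parameters are fixed at
match/mismatch/open/extend = +2/−4/−6/−1; nothing in the modelled assays
constrains them, so they are configuration constants chosen once and
logged, not tunables. A read fails when shorter than 50 bases or when the
mean per-base alignment score is below 0 (a random 25%-identity read
scores ≈ −2.5/base; a read with a few percent of edits stays well
positive).

Indels are reported at their left-aligned placement. For cut-window
intersection, however, the *full equivalence footprint* (leftmost through
rightmost equivalent placement) is used: a deletion inside a homopolymer
that spans the cut window would otherwise canonicalize out of it, and the
classification would depend on an arbitrary placement choice. This makes
the call invariant to where the sequencer or aligner happened to put the
gap.

Classes: **HDR** (all donor-signature bases converted, no cut-window
indel), else **NHEJ** (any indel footprint intersecting the cut window —
by default the central four bases of the site, configurable up to the full
site span), else **intact**. Substitutions alone never count as
disruption, because PCR/sequencing error would inflate rates. Disruption
rate = NHEJ / non-failed reads, with Wilson 95% intervals (well-behaved at
the n = 28–53 clone counts these assays produce, where Wald intervals are
not). Percentages are displayed at one decimal place. Rate ratios between
loci are reported as fold changes; a zero denominator yields a flagged
infinity rather than an exception.

## Assay quantification

* **Yeast-surface cleavage index**: `1 − median(substrate channel, Mg²⁺) /
  median(substrate channel, Ca²⁺)`, clamped to [0, 1]. Ca²⁺ supports
  binding but not catalysis, so it is the uncleaved control; a zero
  control median is a control failure, not a zero. Medians are used for
  all flow summaries — fluorescence distributions are heavy-tailed.
* **TLR fractions**: NHEJ = mCherry⁺/BFP⁺, HDR = GFP⁺/BFP⁺ inside the
  nuclease-expression gate; mock mode computes over the whole population.
  Default gates are thresholds placed at the 99.5th percentile of a
  negative control; an expression band capturing ~10% of events around the
  median is available for expression-matched comparisons.
* **Gel fraction**: cleaved / (cleaved + uncut).
* **Binding**: 1:1 saturation isotherm `F(c) = F0 + Fmax·c/(Kd + c)`,
  without ligand depletion — surface sites (~10⁴–10⁵ per cell) are far
  below ligand at 1–500 nM. The F0 offset absorbs background staining.
  Fitting is Levenberg–Marquardt least squares with seven Kd starts
  log-spaced over [c_min/10, c_max·10]; unphysical (Kd ≤ 0) optima are
  rejected. The fit is flagged, not silently trusted, when the titration
  is flat (Fmax ≈ 0), the Kd lands far outside the sampled range, or the
  design spans less than a decade of concentration.

## Synthetic data

Generators are pure functions of (parameters, seed); a master seed is
split per component via `SeedSequence([master, crc32(name)])`. Every
generator returns a `GroundTruth` record that serializes with the dataset.

* **Genomes**: iid background at specified GC (default 0.5), planted
  variants at non-overlapping loci ≥ 2L apart; the background is
  rejection-sampled until it contains no extra window within the scan's
  k_max, so planted-recovery tests are exact. For a 20 bp site the chance
  of a spurious ≤ 2-mismatch window in 100 kb is ~10⁻⁴, so rejection
  almost never triggers; a bounded attempt budget raises a
  retry-with-new-seed error rather than looping.
* **Profiles**: tolerated cells draw r ~ U(θ+0.05, 1.2), others
  U(0, θ−0.05) — an unambiguous margin around the threshold.
* **Reads**: planted counts are deterministic (`round(n·p)`) because
  observed clone counts are fixed numbers, with a binomial mode for
  CI-coverage studies; NHEJ events are deletions of 1–10 bp centered at
  the cut point (90%) or insertions of 1–3 bp (10%); substitution errors
  are iid per base. Default amplicons in tests/examples put the site
  between 50 bp flanks (120 bp total) — long enough for unambiguous
  global alignment, small enough to keep simulations fast.
* **Titrations**: 8 log-spaced concentrations over 1–500 nM, Gaussian
  noise σ·Fmax.
* **Flow events**: mixtures of lognormal populations with deterministic
  per-population counts.

What the generators do *not* emulate: real indel spectra (microhomology
bias), PCR duplicates and chimeras, base-quality-dependent errors,
spillover between flow channels, or ligand depletion. Tests passing on
this synthetic data therefore demonstrate the *bookkeeping and inference*
are correct under the stated models, not that the models capture every
artifact of real instruments.

## Problem sizes

Defaults keep any single check in seconds-to-a-minute on one core: 100 kb
planted genomes for scan/oracle comparisons, 1 000 random profile/mismatch
pairs for the tolerance truth table, 100 replicate titrations for Kd
recovery, and 500 replicates × 100 reads for CI-coverage — sizes at which
the binomial and simulation margins are already tight.

## Known limitations

* The scan is exhaustive, not indexed; it is meant for desk-scale genomes
  (≲ 100 Mb is still only seconds, but a mammalian genome at k > 3 would
  warrant pigeonhole seeding — any accelerated path must match the naive
  scan bit-for-bit).
* The read classifier assumes one locus per amplicon and no large
  rearrangements; chimeric reads will usually fail alignment rather than
  be detected.
* Tolerance predictions inherit the independence assumption of the
  combination rule; epistasis between mismatches (known to exist for
  adjacent positions) is outside the model.
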