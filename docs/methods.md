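# Methods

## Coordinate and distance conventions

All intervals are 0-based, half-open (BED-native); GTF input (1-based,
inclusive) is converted once on read, so a plus-strand transcript
starting at GTF coordinate 1000 has its TSS at 999 and a minus-strand
transcript ending at 2000 has its TSS at 1999. TSS records identical in
(chrom, position, strand) are merged — coordinate-identical isoforms
would otherwise multiply-count one data point in density estimation —
with the merged TPM taken as the sum of member transcripts (total
promoter output; `max` is available). Chromosome names are never
normalized; a peak/TSS name-set mismatch raises a warning (or an error
under `--strict`), because silent zero-overlap from `chr1` vs `1` is
the classic failure mode here.

Every distance in the pipeline is **center-to-point**: the peak center
is `floor((start+end)/2)` and the signed distance to a TSS is oriented
by the gene (negative = upstream). This applies uniformly, including
the 500 bp "active" criterion; an interval-edge variant of that
criterion exists behind `active_criterion="edge"` but is not the
default.

Nearest queries use per-chromosome sorted arrays with binary search and
are contract-tested against an O(n·m) linear scan, ties included.
Tie-breaking at equal |d| is deterministic but direction-specific: a
TSS→peak query prefers the upstream (negative-distance) peak, then the
smaller center coordinate, then the lexicographically smaller name; a
peak→TSS query prefers the smaller TSS coordinate, then the smaller
transcript id. (The two directions use different first keys because
"upstream" is well-defined for a peak relative to an oriented gene,
but ambiguous for choosing between two oppositely-oriented genes.)

## Density profiles and the shape summary

The profile is the plain Gaussian kernel sum
`f(x) = (n·h·√2π)⁻¹ Σ exp(−(x−dᵢ)²/2h²)` evaluated on a regular grid,
default −2000…+2000 bp in 10 bp steps with bandwidth h = 15 bp. The
bandwidth is fixed, never Silverman-estimated; there is no boundary
correction — mass beyond the grid is simply not plotted. Distances
entering a profile are those of peaks whose nearest (optionally
filtered) TSS lies within the window; peaks without one are excluded
*before* smoothing and their count is reported, so genome-wide distal
peaks cannot flatten the promoter signal.

The unimodal/bimodal contrast is summarized without a formal dip test:
`center_fraction` is the empirical share of |d| < 300 bp,
`flank_fraction` the share of 300 ≤ |d| ≤ 1000 bp (the band where
flanking H3K4me1 concentrates), and `bimodality_ratio` their quotient
with ε = 1e−9 guarding the denominator.

## Classification rules

Poised regions are H3K4me3 peaks overlapping any H3K27me3 peak by
≥ 1 bp, reported once with original coordinates (`-wa` semantics,
implemented over an interval tree). Rule `by_k4me3` labels a TSS poised
iff its nearest H3K4me3 (within 2 kb) is such a peak, active iff a
nearest H3K4me3 exists but is not, `other` otherwise. Rule `by_k4me1`
evaluates poised first — nearest H3K4me1 overlapping a poised region —
and only then active (nearest H3K4me3 center within 500 bp); a TSS can
never be both. TSS without a TPM record keep their state call but are
excluded from expression-binned analyses: unquantified is not zero.
TPM = 0 falls in bin B1; there is no separate silent bin.

## Rank test

The Kruskal–Wallis statistic is computed from pooled mid-ranks with the
standard tie correction and referred to the chi-square upper tail with
k−1 degrees of freedom, evaluated through the regularized incomplete
gamma function. The test is applied to **absolute** distances |d|: both
the unimodal and the bimodal shape are near-symmetric about zero, so
signed distances would cancel the very contrast of interest (a signed
option exists). No exact small-sample null is attempted; any group
below n = 5 triggers a warning. All identical values is rejected as
degenerate input rather than returning H = 0/0.

## The synthetic landscape

The simulator emulates the observed promoter geometry on one linear
chromosome (`chrS`): `n_genes` TSS at a fixed spacing (default
10 000 bp, 2 000 genes), strands alternating by index so strand-aware
code is always exercised. States are assigned in exact counts
(round(fraction·n), default 30 % poised, 10 % silent) by a seeded
shuffle. Per state:

* **active** — one H3K4me3 peak centered at TSS + N(100, 50) bp in gene
  orientation, two H3K4me1 peaks at ±U(300, 1000) bp, one H3K27ac peak
  at TSS + N(0, 50), no H3K27me3;
* **poised** — the same H3K4me3 placement, an H3K27me3 peak whose
  center is drawn uniformly *inside* the H3K4me3 interval (≥ 1 bp
  overlap by construction), and one H3K4me1 peak at TSS +
  N(0, 100);
* **silent** — no peaks.

1 000 background H3K4me1 peaks land uniformly, constrained ≥ 2 kb from
every TSS, so they enter no promoter window. Peak widths are uniform
per mark — H3K4me3 500–900 bp, H3K4me1 400–800 bp, H3K27me3
800–2 000 bp, H3K27ac 300–700 bp — chosen as typical MACS2 output
scales; the wide promoter-mark widths also make the poised H3K4me1 ∩
poised-H3K4me3 overlap essentially certain given the 100 bp jitter. A
config validator enforces spacing > 2·(max offset + max width) so
neighboring genes cannot interfere, which makes "the nearest TSS of
every promoter peak is its own TSS" a provable property rather than a
probabilistic one.

TPM is drawn per state — active: LogNormal(μ=2, σ=1); poised: 0 with
probability 0.7, else LogNormal(μ=0.5, σ=1); silent: 0 — deliberately
overlapping so expression alone cannot separate the states and
naturally discordant promoters exist. `make_discordant_subset`
additionally forces chosen counts of poised TSS to high TPM and active
TSS to low TPM, touching only the expression table, for the
poising-vs-expression analysis. All draws come from per-component
substreams (`default_rng([seed, k])` with fixed component indices k) in
a documented order, so adding a mark never perturbs earlier draws and
outputs are byte-identical per seed.

What the simulator does *not* model: read-level noise, peak-calling
artifacts, copy-number or mappability biases, multiple chromosomes,
overlapping/nested genes, CpG-island width effects, or any correlation
structure between neighboring promoters. Passing tests therefore
demonstrate that the pipeline's geometry, classification logic and
statistics are correct under the stated generative model — not that
real ChIP-seq data will show equally clean separation.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 2000 bp | inclusion radius for nearest-mark hits and the map |
| `bandwidth` | 15 bp | Gaussian kernel width of the density profile |
| `active_radius` | 500 bp | max |d(TSS, nearest H3K4me3 center)| for "active" under `by_k4me1` |
| grid step | 10 bp | density evaluation resolution over ±window |
| `nbins` | 30 | bins per axis of the 2D distance map over [−2000, 2000] |
| TPM edges | 1, 5, 10 | expression bins, upper-inclusive |

## Problem sizes

The default simulated study uses 2 000 genes (≈ 5 200 peaks across the
four marks), which the full chain processes in seconds; the
oracle-equivalence and reference-implementation checks use 200 and 100
random instances respectively, and the permutation calibration of the
rank test uses 1 000 label shuffles of 120 pooled observations.

## Known limitations

* Only k = 1 nearest queries; no signal-weighted distances.
* The chi-square null is inaccurate for very small groups (warned, not
  corrected).
* Density profiles are not boundary-corrected, so a profile whose mass
  abuts ±window underestimates total mass near the edges.
* The two classification rules are both exposed because the underlying
  procedure can be read either way; on cleanly separated landscapes
  they agree, but on real data they need not.
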