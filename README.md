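# promdens

Promoter classification from the *shape* of histone-mark ChIP-seq peak
density around transcription start sites.

## The problem

H3K4me1 is classically an enhancer mark, but around promoters its peaks
take one of two configurations: a single peak centered on the TSS
(unimodal), or two peaks displaced ~300–1000 bp on either side
(bimodal), as if the mark had "cleared" from a promoter occupied by
H3K4me3. The unimodal, TSS-centered configuration tracks the **poised
(bivalent)** chromatin state — promoters carrying both H3K4me3 and the
Polycomb mark H3K27me3 — rather than low expression per se, while the
bimodal, flanking configuration marks epigenetically **active**
(H3K4me3-only) promoters regardless of their transcript level.

`promdens` implements that analysis as a reusable pipeline for anyone
with peak calls (MACS2 narrowPeak/broadPeak or plain BED), a TSS
annotation (GTF or bed6) and a kallisto-style TPM table:

* **geometry** — signed, gene-oriented distance `d` from each peak
  center to the nearest TSS (negative = upstream), and the reverse
  per-TSS nearest-peak query, exact including ties;
* **density profiles** — the Gaussian-smoothed density
  `f(x) = (n·h·√(2π))⁻¹ Σᵢ exp(−(x−dᵢ)²/2h²)` with bandwidth
  `h = 15` bp, plus a center/flank mass summary of unimodal vs bimodal
  shape;
* **promoter states** — poised-region lists by ≥1 bp overlap
  (`bedtools -wa` semantics) and two per-TSS classification rules: by
  the bivalency of the nearest H3K4me3 peak, or by whether the nearest
  H3K4me1 peak overlaps a poised region (with "active" requiring the
  nearest H3K4me3 center within 500 bp of the TSS);
* **statistics** — expression binning (TPM ≤ 1, 1–5, 5–10, > 10) and
  the tie-corrected Kruskal–Wallis rank-sum test
  `H = [12/(N(N+1)) Σ Rᵢ²/nᵢ − 3(N+1)] / [1 − ΣT/(N³−N)]` on absolute
  distances |d|;
* **synthetic landscapes** — a seeded simulator that writes every input
  format the pipeline reads plus per-TSS ground truth, so the whole
  chain is testable end to end without any external data.

## Worked example

```sh
promdens simulate --out sim --n-genes 300 --seed 3
promdens run-all \
    --k4me1 sim/H3K4me1.bed --k4me3 sim/H3K4me3.bed \
    --k27me3 sim/H3K27me3.bed --k27ac sim/H3K27ac.bed \
    --tss sim/tss.bed --tpm sim/tpm.tsv --out out
```

`out/shape_summary.tsv` then contains (300 genes: 180 active, 90
poised, 30 silent):

```
mark      n_distances  n_excluded  center_fraction  flank_fraction  bimodality_ratio
H3K27ac   180          0           1.000000         0.000000        0.000000
H3K27me3  90           0           0.755556         0.244444        0.323529
H3K4me1   450          1000        0.200000         0.800000        4.000000
H3K4me3   270          0           1.000000         0.000000        0.000000
```

Only H3K4me1 is flank-dominated (`bimodality_ratio` 4.0: its 360
active-promoter flank peaks sit 300–1000 bp from the TSS, while the 90
poised-promoter peaks sit on it; the 1000 excluded peaks are distal
background with no TSS within 2 kb). `out/kw_tests.tsv` holds the rank
tests on |d(TSS, nearest H3K4me1)|:

```
analysis                            k  group_sizes     H        df  p_value
abs_d_k4me1_across_expression_bins  4  74,84,53,59     120.867  3   5.01977e-26
abs_d_k4me1_poised_vs_active        2  90,180          179.339  1   6.7568e-41
```

i.e. H3K4me1 placement differs strongly across expression bins and,
even more sharply, between poised and active promoters.
`out/promoter_calls.tsv` lists every TSS with its state under both
rules, the signed distances that produced the call, and its expression
bin; `out/joint_map.tsv` is the 2D bin-count map of per-TSS
(d_H3K4me1, d_H3K4me3).

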