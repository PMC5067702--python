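# Methods

`ncontext` associates differentially expressed (DE) non-coding RNAs with
putative protein-coding targets through three genomic-context procedures,
and builds target-driven interaction networks.  This note records the model,
the defaults and why they are what they are, what the synthetic generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Differential expression

The design is a two-tissue (SN, DRG), five-timepoint (days 0, 1, 4, 7, 14)
study with three replicates per (tissue, day) group.  Each post-baseline day
defines a contrast (I1..I4) of that tissue's group against its day-0 group.
Per feature and contrast:

* **Fold change** — ratio of linear-scale group means of the normalised
  intensities, reported signed: `r` if `r ≥ 1`, else `−1/r`, so |FC| ≥ 1 and
  the sign encodes direction.  The DE threshold |FC| > 1.5 is strict.
* **t-test** — two-sided, on log2 intensities, pooled-variance (classical
  Student) by default.  With n = 3 per arm the Welch–Satterthwaite degrees
  of freedom collapse to ≈2–3 and the test loses most of its power, so the
  pooled test with its full 2n−2 = 4 df is the default; `test="welch"`
  selects the unequal-variance form, and both share a variance floor
  (ε = 1e−8 on the log2 scale) so that degenerate zero-variance groups —
  routine on noiseless synthetic fixtures — yield a finite statistic.
  Identical groups still return p = 1.
* **Multiple testing** — Benjamini–Hochberg step-up across all features
  *within* each (tissue, interval) contrast, matching per-contrast DEG
  tables; q < 0.05.

Probe-level rows collapse to genes by keeping, per (gene, tissue, interval),
the probe with the smallest q (ties: largest |FC|, then lexicographic probe
id).  A probe mapping to several genes contributes to each and is logged;
unmapped probes are excluded with a warning and counted.

Replicates are treated as independent groups across days (no pairing).

## Contextual target association

* **lincRNA neighbours.**  Candidate targets are DE protein-coding genes on
  the lincRNA's chromosome with boundary gap ≤ 3,000,000 bp.  The gap is
  `downstream.start − upstream.end` in 1-based inclusive coordinates
  (adjacent loci → 1, overlapping loci → 0); the window boundary is
  inclusive.  Output is sorted closest-first per lincRNA and each link
  carries a per-side megabase bin (≤1 MB/≤2 MB/≤3 MB).  The published
  evidence this mirrors never states its distance convention; the boundary
  gap is the common choice and `distance_mode="start_to_start"` is provided
  to chase alternative reproductions.
* **Antisense RNAs.**  A link requires same chromosome, opposite strands and
  ≥ `min_overlap` bp of genomic overlap (default 1).  Opposite-strand
  *proximity without overlap* is deliberately not sufficient — overlap is
  the standard definition of antisense pairing — but `min_overlap` is
  configurable.
* **Pseudogene parents.**  Pseudogene cDNAs are locally aligned
  (Smith–Waterman, affine gaps; match +2, mismatch −3, a gap of length k
  costing 5 + 2k — BLASTN-like) against coding cDNAs, either in-process or
  from a pre-computed 12-column tabular hit file.  Per pseudogene only the
  top hit is kept (score, then identity, then lexicographic subject id);
  hits must reach score ≥ 50 and identity ≥ 0.7.  E-values are not computed;
  the score/identity gate substitutes for an E-value cut.  If the two best
  hits across different subjects tie on both score and identity the
  pseudogene is ambiguous and excluded from the unique list (reported
  separately); `tie_policy="first"` instead keeps the lexicographically
  first subject.

Associations are then annotated with the (tissue, interval) contrasts in
which the target is DE; the retained set keeps only DE targets.

## Networks and over-representation

Edge tables (protein1/protein2/combined_score) are read with scores on the
0–999 integer scale divided by 1000 (auto-detected; files already in [0, 1]
pass through).  Node identity is the upper-cased gene symbol.  Interaction
edges are filtered at confidence ≥ 0.7 (inclusive); association edges —
ncRNA→target links, the dotted edges of the published network figures — are
exempt from the filter and excluded from connectivity and shortest paths
(configurable), since they represent a different relation.  Shortest paths
are fewest-edge with deterministic lexicographic tie-breaking.

Pathway annotation in the original analysis used a proprietary knowledge
base; the package instead provides a generic upper-tail hypergeometric
over-representation test against user-supplied GMT gene sets, BH-corrected
across sets.  This is a substitute, not a reproduction, of the original
pathway figures.

## Synthetic data

The generator emulates the motivating study's shape: 30 samples (2 tissues ×
5 days × 3 replicates), log-normal intensities (log2 ~ Normal; the standard
microarray assumption — the original raw-data distribution is not
documented), one probe per feature by default with `probes_per_feature`
available to exercise probe collapse.  Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| chromosomes | 6 × 25 Mb | room for ±3 Mb neighbourhoods with separation |
| coding / lincRNA / antisense / pseudogene | 40 / 6 / 6 / 8 | every relation class exercised at small cost |
| planted neighbour gaps | published worked-example distances (274,577 bp, ...) | realistic cis-distances |
| antisense overlap fraction | 0.5 of the shorter locus | mid-range overlap |
| mutation / indel rate | 0.05 / 0.005 per site | young-pseudogene divergence |
| cDNA length | 300–900 nt | desk-scale alignment cost |
| log2 effect / noise SD | 2.0 / 0.25 | clear but not trivial effects at n = 3 |
| baseline log2 | Normal(8, 1.5) | typical array intensity range |

Planted DE effects persist across all post-baseline intervals of the chosen
tissue by default (`de_span="course"`): the emulated injury response lasts
over the 14-day course, as in the published interval-spanning expression
heatmaps.  `de_span="single"` confines each effect to one interval.

Placement is rejection sampling with a fixed attempt budget and raises an
explicit placement error when the chromosomes cannot host the request —
never silent truncation.  Two structural guarantees matter for testing:
features never overlap except planted antisense pairs, and every DE coding
gene that is not a planted lincRNA target is kept more than 3 Mb (the
`guard_window`) from every lincRNA locus, with lincRNA blocks mutually
separated likewise.  The second guarantee is what makes zero-noise
end-to-end recovery *exact*: without it, incidental DE neighbours would
legitimately appear in the neighbour output and set equality against the
truth manifest could not hold.

What the generator does **not** emulate: dye and batch effects, spatial
array artifacts, probe cross-hybridisation, background correction,
correlated biological replicates, realistic transcript structure (gene-level
loci only) and realistic sequence composition (i.i.d. uniform bases,
expected pairwise identity 0.25).  Passing recovery tests therefore show the
pipeline's correctness under its own model assumptions, not robustness to
real-array artifacts.

## Verification problem sizes

The test suite's oracle-equivalence checks run each primitive against an
independent brute-force implementation (all-pairs scans, hand step-up BH, a
three-state Gotoh DP, exact combinatorial hypergeometric tails, BFS) on
≥100 random instances each.  Recovery checks use: a 40-feature zero-noise
study recovered exactly; a 1,050-feature single-tissue time course (1,000
null + 50 planted) for noisy DE recovery; and 8 pseudogenes at mutation
rate 0.10/indel 0.01 against 28 coding genes (20 distractors) for parental
assignment.  The worked-example fixture encodes all 30 published
lincRNA–target pairs at their printed offsets with distractors beyond the
window.

## Known limitations

* Gene-level only; transcript isoforms and probe remapping to genomes are
  out of scope (the probe→gene map is an input).
* Neighbour search operates within one source's coordinate system; no
  cross-species liftover.
* Trans-acting (distal) target inference, RNA–protein interaction and miRNA
  target prediction are out of scope.
* The statistics are intentionally plain (two-group t-tests per interval);
  no moderated/empirical-Bayes variance sharing and no time-series trend
  tests.
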