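# Methods

## Hash-read model and parsing

A hashing oligo read is modelled as the fixed layout
`anchor5 · UMI1 · barcode · UMI2 · anchor3`. Parsing proceeds in layout
order and a read's status records the first failing stage, so the status
tallies (`valid`, `no_anchor`, `ambiguous_cell`, `unknown_cell`,
`ambiguous_hash`, `unknown_hash`) always partition the input.

- **Anchor.** `anchor5` may start 0–3 bases into the read (sequencers
  occasionally prepend untemplated bases) and must match within
  `anchor_mismatch_tol` substitutions (default 2). When present, `anchor3`
  is verified at the expected offset with the same tolerance. Empty anchors
  are allowed for pre-extracted hash reads; the layout then starts at
  offset 0.
- **Cell barcode.** The index read is corrected against the valid-cell
  whitelist by the *nearest unique winner* rule: an exact member is kept;
  otherwise the unique member at minimal Hamming distance within
  `cell_mismatch_tol` (default 1) wins, and a tie at the minimal distance is
  ambiguous rather than guessed. The nearest-winner form (instead of
  "unique within tolerance") makes the number of valid reads monotone
  non-decreasing in the tolerance. For tolerance 1 the lookup uses
  single-position wildcard keys, O(L) per read.
- **Sample barcode.** Matched by the same nearest-unique-winner rule with
  `hash_mismatch_tol` (default 1). A design is only accepted when the
  minimum pairwise Hamming distance among barcodes is ≥ 2·tol + 1, which
  provably excludes ties within tolerance.
- **Both mates.** The oligo carries sequencing adapters at both ends, so
  the layout can arrive on either mate. Read 1 is parsed as sequenced;
  failing that, the reverse complement of read 2 is tried, and the first
  valid parse wins (a failed record keeps read 1's status). This also makes
  parsing robust to independent errors on the two mates.

## UMI collapse

The two UMIs are concatenated into one molecule key per read. Within each
(cell, sample) group, collapse is *directional*: UMIs are visited in
decreasing read count (lexicographic tie-break, so the procedure is fully
deterministic), and UMI `b` is absorbed into cluster member `a` when
Hamming(a, b) = 1 and reads(a) ≥ 2·reads(b) − 1; the molecule count is the
number of clusters. The count-ratio condition distinguishes PCR/sequencing
errors (rare neighbours of an abundant UMI) from genuinely distinct
molecules that happen to be neighbours. Exact-match collapse is available
(`method="exact"`), equivalent to tolerance 0. Neighbour candidates are
generated by enumeration (3L per UMI) rather than all-pairs comparison, so
groups scale linearly in distinct UMIs.

## Demultiplexing

Classification follows the quadrant rule on the count matrix: per nucleus,
count the samples whose hash count reaches their cutoff — exactly one gives
a singlet of that sample, two or more a multiplet, zero a negative.
Cutoffs are one of:

- **fixed** (default fallback 10 counts);
- **fitted** (`auto_cutoff`): per sample, a two-component Gaussian mixture
  is fitted by EM to log1p(counts) with deterministic initialization
  (component means at the 25th and 75th percentiles, equal weights, unit
  precisions), and the cutoff is the smallest integer count at which the
  high component's posterior exceeds 0.5. If the fitted means are separated
  by < 1 log-unit the distribution is treated as unimodal and the fixed
  fallback applies. At least 50 nuclei are required. Fitting after the
  read-depth filter (the analysis order of the examples) is recommended:
  filtering truncates the low-quality tail that otherwise blurs the ambient
  and signal modes together;
- **CLR/quantile** (`clr_quantile_cutoff`), the droplet-hashing convention:
  log counts are split into background and positive clusters by
  deterministic 2-means, and the cutoff is one count above the 0.99
  quantile of the background cluster.

The nucleus prefilter keeps cells with ≥ 10,000 total reads (inclusive);
"total reads" means total sequenced read pairs assigned to the barcode, with
the caller free to substitute aligned-fragment totals. The QC filter drops
a nucleus when *any* enabled predicate fires: reads-in-peaks < 15%,
fragments-in-peaks < 2,000, blacklist ratio > 0.05, or nucleosome signal
outside (0.2, 4); each predicate toggles independently and a missing metric
under an enabled predicate is a hard error rather than a silent pass.

## Species assignment and concordance

In a two-genome (barnyard) pool, per-genome fragment counts classify each
nucleus: singlet of the dominant genome when its fraction ≥ `purity`
(default 0.9), doublet when below purity with ≥ `min_minor` (default 100)
minor-genome fragments, otherwise undetermined. The purity and minor-count
defaults are this package's own choices — the underlying idea (aligned to
one genome vs. both) does not fix numeric thresholds — and both are
configurable.

Concordance restricts to nuclei that are singlets under both schemes,
builds the genome × hash-sample confusion matrix, and calls a nucleus
concordant when its hash sample's species label matches its genome.
The test statistic is Pearson's chi-squared without continuity correction,
Σ(O−E)²/E; when any expected cell is below 5 the report flags the statistic
as unreliable instead of switching tests. Reported percentages round
half-up to two decimals (one decimal for doublet summaries), matching the
presentation convention of the field's tables.

## Cnum analysis

Intervals are 0-based half-open; two intervals overlap when they share at
least `min_overlap` bases (default 1, the common default of overlap
tooling). A union peak's Cnum is the number of clusters whose peak sets
contain at least one overlapping peak. Bulk intensity attachment uses the
maximum score among overlapping bulk peaks — robust when a union peak spans
two bulk peaks; peaks without a bulk overlap are excluded from intensity
analysis rather than imputed.

The maximal-Cnum (constitutive) group's bulk intensities are dichotomized
by the same deterministic log-scale mixture machinery as `auto_cutoff`:
threshold at the posterior crossover between the two fitted components
(the dip between the densities), labels by threshold comparison. At least
100 scores are required for a fit; smaller or degenerate (all-equal) inputs
need a manual threshold. Because the fit acts on log scores, labels are
invariant under positive scaling and the threshold scales linearly.

Feature annotation classifies the peak midpoint with precedence
promoter > 5'UTR > 3'UTR > exon > intron > intergenic. Promoters are
TSS ± `promoter_window` (default 2,000 bases), strand-aware; introns are
transcript bases not covered by any exon; a chromosome absent from the gene
model yields intergenic with a warning. Sub-146-base peak removal (a
convention of enhancer-identification pipelines) is exposed as
`filter_min_width` but not applied by default.

## Synthetic data generator

The generator emulates the observables of a pooled barnyard hashing run,
not chromatin biology: no genomic read sequences, fragment-length structure,
or Tn5 insertion model. Per nucleus, two latent factors with mean 1 set the
scale: capture quality `q ~ Gamma(read_depth_dispersion)` multiplies both
total reads (`q · read_depth_mean`) and hash yield, and staining efficiency
`s ~ Gamma(hash_depth_dispersion)` multiplies hash yield only
(`hash reads ~ Poisson(q·s·hash_depth_mean)`). Hash counts are therefore
negative-binomially overdispersed, correlate with read depth (nuclei failing
a depth filter are also prone to insufficient hash counts), and a small
tail of well-sequenced nuclei still stains poorly — producing the
insufficient-count "negative" class among filtered nuclei.

Doublets (probability `doublet_rate`) draw hash reads from both constituent
samples and split genome fragments binomially between the constituent
species; ambient contamination rewrites each read's sample barcode with
probability `ambient_fraction` to a uniformly chosen other sample;
substitution errors hit every written base i.i.d. at `base_error_rate`;
`cross_species_noise` reassigns aligned fragments between genomes. Cell
barcodes are drawn without replacement from a generated whitelist of 10×
the nucleus count, and a run errors out when the requested nuclei exceed
1/100 of the barcode space (collision risk). All outputs, including the
gzip streams (fixed mtime), are byte-identical functions of
(config, design, seed).

Preset defaults (`barnyard_config`): 2 samples (one human, one mouse
line), doublet_rate 0.12, hash_depth_mean 300, hash_depth_dispersion 8,
ambient_fraction 0.05, base_error_rate 0.01, genome_depth_mean 2,500,
cross_species_noise 0.01, read_depth_mean 25,000, read_depth_dispersion 2.
These were calibrated once so that the demultiplexed label proportions among
filter-passing nuclei land near the canonical ≈86% singlet / ≈12% multiplet
/ ≈2% negative split of real hashing runs; at 1,000 nuclei (seed 1) the
pipeline measures 87.6 / 11.0 / 1.4. This is a realism target, not a claim
of distributional fidelity — real data add unmodelled structure (barcode
swapping, ambient profiles that track nuclei density, per-sample staining
batch effects), so passing tests demonstrate correctness of the
computational contracts, not performance guarantees on arbitrary libraries.

The Cnum fixture lays non-overlapping union peaks along one chromosome,
assigns each a true cluster-presence count (default weights 0.22 / 0.15 /
0.16 / 0.47 for Cnum 1–4, echoing the strongly constitutive-skewed
composition of real peak sets), gives 90% of peaks an overlapping bulk peak
whose log-mean score rises with Cnum, and draws the maximal-Cnum group from
an explicit log-normal mixture (log-means 1 and 4, log-sd 0.4, equal
weights) so dichotomization has exact component truth.

## Problem sizes and determinism

Test and acceptance runs use 400–1,000 simulated nuclei (≈10⁵–3·10⁵ hash
reads) and 500–2,000 peaks — sizes at which every pipeline stage, including
the quadratic reference oracles in the test suite, runs in seconds while
leaving the statistical checks well-powered. All stochastic components
(generator, mixture fits, k-means) are either seeded or deterministically
initialized; nothing depends on hash ordering or wall-clock state.

## Known limitations

- Hash-read parsing assumes substitution errors only; indels inside the
  layout shift the frame and surface as `no_anchor`/`unknown_hash`.
- `auto_cutoff` assumes a two-mode count distribution per sample; heavily
  skewed pools (one sample dominating the run) may need the CLR/quantile
  mode or a fixed cutoff.
- Midpoint-based feature annotation assigns exactly one class per peak;
  broad peaks spanning several features are represented by their centre.
- The generator's negatives arise from low staining alone; it does not
  model nuclei that lose their hash for biological reasons (membrane
  damage) independently of yield.
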