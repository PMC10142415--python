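# nuhash

A Python toolkit for demultiplexing antibody-hashed single-nucleus ATAC-seq
(snATAC-seq) experiments and for relating single-cell peaks to bulk ATAC-seq
intensities.

## The problem

Nucleus hashing tags each sample's nuclei with an oligonucleotide-conjugated
antibody before pooling, so several samples can share one droplet run and be
separated computationally afterwards. Each hashing oligo carries a
sample-specific barcode flanked by two unique molecular identifiers (UMIs)
and constant adapter remnants, laid out along the read as

```
anchor5 · UMI1 · sample barcode · UMI2 · anchor3
```

while the droplet's 16-nt cell barcode arrives on the index read. This
package implements everything downstream of sequencing:

- **hash counting** — locate the 5' anchor (bounded mismatches, small offset
  window), slice the layout, error-correct the cell barcode against the
  valid-cell whitelist (unique nearest neighbour within Hamming tolerance),
  match the sample barcode (nearest unique winner), and collapse UMIs with
  the directional rule (`b` merges into `a` when Hamming(a,b) = 1 and
  reads(a) ≥ 2·reads(b) − 1), yielding a valid-cell × sample count matrix;
- **demultiplexing** — per-sample count cutoffs (fixed, fitted, or
  CLR/quantile); a nucleus with exactly one sample at or above cutoff is a
  *singlet*, two or more a *multiplet*, none a *negative*. Fitted cutoffs
  come from a deterministic two-component Gaussian mixture on log1p counts
  (components seeded at the 25th/75th percentiles), thresholding where the
  high component's posterior crosses 0.5;
- **barnyard concordance** — in a human+mouse mixture, each nucleus is also
  classified from per-genome fragment counts (singlet when the dominant
  genome holds ≥ 90% of fragments, doublet when the minor genome contributes
  ≥ 100). Agreement between hash and genome singlets is reported as a
  confusion matrix with discordance rate and Pearson chi-squared statistic
  (no continuity correction);
- **Cnum analysis** — a peak's *Cnum* is the number of cell clusters whose
  peak sets overlap it (≥ 1 base, BED half-open convention). Peaks are
  matched to bulk ATAC peaks (max signal among overlaps), the constitutive
  (maximal-Cnum) group's bimodal intensities are dichotomized at the
  posterior crossover of a log-scale mixture, and peaks are annotated by
  midpoint with precedence promoter > 5'UTR > 3'UTR > exon > intron >
  intergenic;
- **simulation** — a generator producing FASTQ triplets, whitelists,
  genome counts, and cluster/bulk peak sets with full ground truth, so every
  stage is testable without sequencing data.

## Worked example

`examples/03_demux_and_concordance.py` simulates a 600-nucleus 2-plex
barnyard run, counts hash molecules, and demultiplexes. It prints:

```
499 of 600 nuclei pass the 10,000-read filter
per-sample cutoffs: {'NuHash-1': 57.0, 'NuHash-2': 64.0}
           count    pct
label
singlet      445  89.18
multiplet     46   9.22
negative       8   1.60
discordant: 0 of 444 (0.0%), chi2 p = 1.46e-98
```

Reading: 83% of simulated nuclei pass the read-depth filter; the fitted
cutoffs fall in the gap between ambient contamination (~5% of a nucleus's
hash reads carry another sample's barcode) and true signal; 89% of passing
nuclei are confidently assigned to one sample, 9% are multiplets (pooled
doublets), and 1.6% lack sufficient hash counts. Every nucleus that is a
singlet under both the hash and the genome classification is assigned to
the same species by both — zero discordance on this run.

The other examples cover design/parsing (`01`), counting internals (`02`),
and the Cnum/bulk-intensity analysis (`04`). A thin CLI mirrors the
workflow: `nuhash simulate | count | demux | species | concord | cnum`.

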