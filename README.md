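# archintro

Toolkit for testing whether a divergent haplotype in a phased panel is
archaic-introgressed rather than a relic of incomplete lineage sorting
(ILS), plus the companion enzyme-kinetics analysis. It provides:

- **core_io** — data model (haplotype panel, genetic map, region mask) and
  readers/writers for phased VCF, BED masks, TSV genetic maps and fragment
  lists, FASTA export, and the merged-panel site filters (biallelic,
  mask-restricted, missing-free, segregating, archaic-het removal).
- **synthetic_data** — a deterministic mosaic simulator that generates a
  phased panel with a planted introgressed tract (per-side tract length
  Exponential with mean 100/g cM for gene flow g generations ago), archaic
  pseudo-genomes, a recombination map, a mask, ground truth, and noisy
  dose-response tables — so every stage is testable offline.
- **ld_blocks** — haplotypic r² and LD-defined block calling: boundaries
  are the outermost variants within a search window whose r² with the
  focal variant exceeds a threshold; genetic length by map interpolation.
- **ils** — survival probability that a shared haplotype of genetic length
  m persisted since lineage divergence: P(L ≥ m) = (1 + Gm)·exp(−Gm) with
  G the summed branch lengths (two-sided recombination-clock model), plus
  fragment-length percentile ranking.
- **archaic_affinity** — Hamming distances, allele-sharing tracks,
  haplotype deduplication, nearest-archaic assignment, and a rooted
  neighbor-joining tree with site-resampling bootstrap support.
- **selection** — Tajima's D (1989 constants) and sliding windows with
  per-step averaging of overlapping windows.
- **kinetics** — Michaelis–Menten and substrate-inhibition dose-response
  models, linear standard-curve calibration, and global nonlinear fits
  with shared, fixed, or free Km and asymptotic confidence intervals.
- **cli / pipeline** — a `click` CLI orchestrating the full synthetic run.

## CLI

```sh
archintro --help
archintro ils --cm 0.018 --branch-a 21500 --branch-b 19500
archintro simulate --seed 0 --outdir sim/
archintro block --vcf sim/panel.vcf --focal chr8:18222492 --r2 0.8 --map sim/map.tsv
archintro tajima --vcf sim/panel.vcf --window 10000 --step 100 --out tajima.tsv
archintro tree --vcf sim/panel.vcf --outgroup ancestral --boot 1000 --seed 7 --out tree.nwk
archintro kinfit --data assays.tsv --model substrate_inhibition --km shared
archintro run --seed 0 --outdir run/        # full synthetic end-to-end run
```

`archintro run` writes `panel.vcf`, `map.tsv`, `mask.bed`, `truth.tsv`,
block/ILS summaries, `tree.nwk`, `sharing.tsv`, `tajima.tsv`, and a
deterministic `report.json` (identical config + seeds ⇒ byte-identical
report).

## Conventions

Variant positions are 1-based (VCF); masks are 0-based half-open (BED).
Archaic genotypes are unphased: each archaic contributes one
pseudo-haplotype and sites heterozygous in any archaic are dropped by the
default filters. r² is haplotypic (phased), computed on modern haplotypes.
Tree branch lengths are differences per retained site; trees are rooted on
the inferred ancestral sequence (sites with unknown ancestral state are
excluded from rooting).
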