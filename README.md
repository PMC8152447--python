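# stallsites

Detection and cross-species conservation analysis of ribosome stall sites
from ribosome-profiling codon coverage.

## The problem

During elongation, ribosomes pause or stall at specific codons. Ribosome
profiling detects these as codons with footprint coverage far above the
transcript background, but single-library peak calls are riddled with
protocol- and library-specific artifacts. A stall site that appears at the
*same aligned codon* in homologous transcripts of several species, however,
is very unlikely to be an artifact: under a simple combinatorial null the
chance that one of k random peaks in a second homolog lands within one
codon of a given peak on an n-codon gene is

```
p = 1 − C(n−m, k) / C(n, k)
```

with m the number of codons that count as a match (the peak codon and its
two neighbours). At the scale typical of well-expressed genes — n = 500
codons, k = 3 peaks per gene, m = 3 — this gives p = 0.018 for two
homologs, and p^(j−1) for j organisms: 3.2e-04 for three, 5.8e-06 for
four, 1e-07 for five. Observed conservation far above these rates
(one-tailed binomial test) marks stalling as functional rather than
accidental.

This package implements the full pipeline around that idea, at desk scale:

- **`stallsites.simulate`** — synthetic cohorts of homologous transcripts
  (2–5 pseudo-organisms, substitutions + whole-codon indels), planted stall
  sites with configurable P-/A-site amino-acid context, and
  negative-binomial footprint counts with elevated dwell at stalls, plus
  full ground truth (positions, categories, the true alignment).
- **`stallsites.profiles`** — P-site assignment from (5' position, length)
  footprint records via a per-length offset table, a frame-periodicity
  gate, per-codon coverage, and ribosome meta-profiles.
- **`stallsites.calling`** — stall-peak calling: median-coverage expression
  gate, z-scores over the trimmed CDS (first codon and last two removed),
  z > 5 cutoff, first-five-codon exclusion.
- **`stallsites.conservation`** — peak matching across homologs in
  alignment-column space with ±3-nt tolerance, starting from the maximal
  organism set and iterating over smaller subsets; built-in center-star
  aligner or an external MSA tool.
- **`stallsites.nullmodel`** — the chance-conservation formula (exact
  integer binomials), its Monte-Carlo cross-check, the binomial test, the
  codon-motif resampling null, SNP-overlap expectation, and matched
  control-set construction (Mann–Whitney-verified).
- **`stallsites.seqfeatures`** — amino-acid/k-mer enrichment around sites,
  exit-tunnel charge profiles with resampled background bands, nucleotide
  PFMs (MEME export), and hierarchical mechanistic attribution (P-site
  Pro/Gly/Asp → A-site Glu → lysine stretches → negative charge at −2).
- **`stallsites.contextfeatures`** — 51-nt sliding-window MFE around sites
  with random-position and codon-permutation controls (built-in Nussinov
  stub or RNAfold), exon/domain/disorder/TM positioning, premature
  termination ratios, fragment-length metaplots.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
synthetic cohort (60 genes × 3 organisms, seed 11) and write their tables
under `results/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_call_stall_sites.py
python analysis/03_map_conservation.py
python analysis/04_null_model.py
python analysis/05_sequence_features.py
python analysis/06_context_features.py
```

Output of the calling and conservation steps:

```
called peaks: 584 (median z = 11.4)
planted member sites recovered: 584/600 (97.3%); false calls: 0
peak recall 97.3%, empirical FDR 0.0%
conserved-group recovery (true alignments): 99.4%
conserved-group recovery (built-in aligner): 99.4%
conserved stall sites: 179
```

i.e. at dwell factor 20 over a mean expression of 10 footprints per codon,
the z > 5 rule recovers 97% of planted stalls with no false calls, and the
alignment-based matching reassembles 99% of the planted conserved groups.
The null model step prints the chance rates the observed conservation is
tested against:

```
two-homolog chance match probability: p = 0.018
  3 organisms: 3.2e-04
  4 organisms: 5.8e-06
  5 organisms: 1.0e-07
observed conserved sites: 179 on 60 genes; expected by chance 1.08;
one-tailed binomial p = 1.63e-105
```

and the sequence step attributes the conserved sites to mechanisms,
recovering the planted category mix (15% P-site Pro, 12% Gly, 17% Asp, 10%
A-site Glu, 2% lysine stretches, 7% negative charge at −2):

```
mechanistic attribution:
         ProP: 14.9%   GlyP: 11.3%   AspP: 12.4%
         GluA: 10.3%  polyK:  3.4%  NegMinus2: 7.6%
explained by sequence features: 59.9%
```

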