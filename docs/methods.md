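# Methods

## Stall-peak calling

Footprint records carry a transcript id, a 0-based 5' position, a length
and a count. A per-length offset table maps each record to its P-site
nucleotide (`five_prime_pos + offset[length]`); lengths whose
offset-shifted 5' ends are not frame-0 periodic over the CDS (modal frame
≠ 0, or frame-0 fraction ≤ 0.5) are rejected by a quality gate. The gate's
0.5 threshold is this package's choice; offsets themselves are an input,
not inferred here. Coordinates are 0-based half-open throughout and codon
index 0 is the start codon.

Per-codon coverage is the 3-nt binned P-site coverage over the CDS. A
transcript qualifies for calling when the median of its codon coverage is
strictly above zero (the median is taken over the full CDS). z-scores are
computed over the codon set with the first codon and the last two codons
removed — those positions carry initiation/termination pile-ups — using
the population (1/N) standard deviation; at N ≈ 500 the 1/N vs 1/(N−1)
difference is negligible but the convention is fixed for exactness. Codons
with z strictly greater than 5.0 are peaks; peaks at codon indices 0–4 are
discarded (reporting-level exclusion only — those codons still contribute
to the mean and sd). A profile with zero variance yields no peaks rather
than an error. Adjacent codons both above threshold are both reported; the
downstream conservation matching tolerates ±1 codon, so merging would only
lose information.

## Conservation matching

Homologous transcripts are compared through a nucleotide multiple
alignment. Each peak's codon first-nucleotide position is mapped to an
alignment column; peaks across organisms are clustered by single linkage
and a cluster is a candidate conserved site when its column diameter is at
most 3 (columns, i.e. gaps count — the alignment is the shared coordinate
system) and it spans ≥ 2 organisms. Matching starts from the alignment of
the full organism set; peaks matched there are settled, and the remainder
is re-evaluated under all subsets of decreasing size (within a size, in
lexicographic organism order), so that one divergent homolog cannot mask
conservation among the others. Clusters from different subsets that share
a peak are merged and the conservation level is the number of distinct
organisms in the union; each peak belongs to at most one conserved site.
Subset order and tie-breaks (nearest column, then smaller column) are
fixed so the procedure is deterministic and invariant to input organism
order.

Two alignment backends are provided. The built-in backend is a center-star
progressive aligner: the center is the sequence with the highest total
pairwise identity, the others are globally aligned to it
(match +2, mismatch −1, gap open −5, gap extend −1, via Biopython's
PairwiseAligner) and merged on center coordinates (once a gap, always a
gap). This is adequate at the low divergence the cohort simulates; at ≤ 5%
substitution divergence it reproduces ground-truth conservation groups as
well as the true alignments do. An external MSA tool (mafft) can be
substituted through an aligned-FASTA round trip.

## The chance-conservation null model

The probability that any of k random peaks in a second homolog lands in
the m-codon window matching a given peak on an n-codon gene is
p = 1 − C(n−m, k)/C(n, k), evaluated with exact integer binomial
coefficients and a single final division (C(a, b) = 0 when b > a). With
n = 500, k = 3, m = 3 this is 0.018; for j organisms the chance rate is
p^(j−1). Observed conservation is tested with the upper-tail exact
binomial test P(X ≥ observed | trials, p0 = 0.018). The expected number of
chance overlaps is reported as the literal product p × n_genes.

The Monte-Carlo cross-check estimates exactly the event the formula
describes: one anchor peak placed so its ±1-codon window lies inside the
gene, k = 3 distinct uniform peaks in the second homolog, a match when any
peak falls within the window. Over 10^6 simulated genes the estimate
agrees with the analytic value to within Monte-Carlo error. Note that the
related event "any pair among 3 + 3 peaks within one codon" has a larger
probability (≈ 0.05); the formula's event conditions on one anchor peak.

Motif significance uses a resampling null: per site, 11 codons are drawn
from the same gene per round; 1000 rounds give the expected match count
(rescaled to the per-site scale), compared to the observed count by a
chi-square test with 1 df. Control sets matched to a reference
distribution (coverage, translational efficiency, alignment score, peak
count — one generic matcher covers all four) are built by stratified
decile sampling, accepted when a two-sample Mann–Whitney U test against
the reference gives p ≥ 0.5, and returned flagged otherwise.

## Sequence characterisation

Windows around a site use the ribosome convention: 0 = P-site, +1 =
A-site, −1 = E-site; the exit tunnel spans positions −30…−1 (the P-site is
reported separately, since "upstream" excludes it). Charge classes:
positive {K, R, H}, negative {D, E}, special {P, G}; histidine's
protonation is pH-dependent, so the positive set is configurable.
Windows are truncated, and flagged as such, at CDS boundaries.

Mechanistic attribution is hierarchical, first match wins: P-site Pro →
P-site Gly → P-site Asp → A-site Glu → a lysine pair adjacent to the peak
(−1…0 or −2…−1) → Asp/Glu at −2 → unexplained. The precedence makes the
category percentages disjoint so they sum to the explained fraction;
"lysine stretch" is operationalised as ≥ 2 consecutive K because the
stretch length that matters is not sharply defined. Sites with truncated
windows at the inspected positions are unexplained.

## Structure and positional context

Secondary-structure stability is the minimum free energy of a 51-nt
window slid over the CDS. Two folding backends: RNAfold (ViennaRNA),
giving thermodynamic MFEs in kcal/mol, and a built-in Nussinov
base-pair-maximisation stub (−1 per AU/GC/GU pair, hairpin loop ≥ 3 nt)
which is *not* thermodynamic and is intended for relative comparisons and
tests; the default is the stub so nothing outside Python is required. The
structure metaplot uses sites > 30 nt from the start codon and > 60 nt
from the stop; the random control re-anchors each site at a random
eligible position outside its own window (reading the precomputed track,
so the repetition count is cheap), and the permutation control keeps the
stall codon fixed while permuting the codons in the −30…−1 and +1…+60
codon windows before refolding — the permutation window is interpreted in
codons, the eligibility filter in nucleotides, and both are exposed as
parameters.

Exon positioning excludes sites in the first 45 and last 3 nt of the CDS
(mirroring the 15-codon/1-codon trims used elsewhere; applying the
exclusion per exon instead is a defensible alternative reading). Domain
distances are measured in amino acids to the nearest upstream C-terminal
domain boundary, with a random same-gene paired control; disorder
meta-profiles use per-residue scores supplied as input (a disorder
predictor is out of scope), a 0.516 coil threshold, and random
same-protein controls excluding the first 15 residues, the last 2, and
the sites themselves. The premature-termination statistic is the log2
ratio of mean coverage over the 15 codons upstream vs downstream of a
site, requiring both flanks inside the gene body; zero downstream
coverage reports +inf, which counts as ratio > 2.

## The synthetic cohort

The generator is the package's study system. Per gene, an ancestor CDS of
random sense codons (ATG start, single stop, no internal stops) is drawn;
each organism derives from it by point substitutions and at most one
whole-codon indel per gene. Substitution counts are Binomial(#mutable nt,
rate) with positions drawn without replacement, third codon positions
weighted 4:1 — biasing toward synonymous change while keeping the per-nt
rate exact over mutable positions; a substitution never creates an
in-frame stop. Indels are whole codons only and never fall within ±10
codons of a planted site, so frames stay comparable while alignment-gap
mapping is still exercised. The true alignment is reconstructed from the
recorded edit operations and retained for oracle tests.

Planted sites (default 3 conserved groups and 1 organism-private site per
gene, matching the null model's k ≈ 3 peaks per gene on ~500-codon genes)
receive a mechanistic context drawn from a configurable category mix
(default: Pro .15 / Gly .12 / Asp .17 / Glu-A .10 / polyK .02 /
neg-at-−2 .07 / none .37). Planting first sets codons −2…+1 to neutral
amino acids (Ala/Leu/Ser/Val) and then applies the category's minimal
edit using the most frequent human codon per amino acid — without the
sanitisation, a "Glu-A" site with a chance P-site proline would be
attributed to the higher-precedence rule and category proportions would
not be recoverable. Context codons are exempt from substitution so
conservation survives divergence.

Footprint counts per codon are negative binomial with mean
`expression_mean` (× `dwell_factor` at stalls) and size `nb_dispersion`;
Poisson is the dispersion → ∞ limit. Counts are split multinomially over
a footprint-length distribution (default 28/29/30 nt at 0.5/0.3/0.2) and
each record's 5' position is the P-site nucleotide minus the length's
offset, so the offset table inverts the generator exactly — the profile
pipeline recovers the per-codon draws bit for bit, which the tests
assert. `dwell_factor` defaults to 20 and `nb_dispersion` to 10; the
dispersion was fixed by a design-time power calculation so that a
dwell-20 stall over a mean of 10 clears the z > 5 cutoff with ~95%
probability per site, making ≥ 90% site recovery and ≥ 95% conserved-group
recovery the expected operating point of the default conditions. One
top-level seed drives everything; per-gene substreams are derived by a
stable hash (CRC-32) of the gene id, so outputs are byte-identical across
runs and independent of gene iteration order.

What the generator does *not* emulate: sequencing error, rRNA
contamination, alignment bias and multimapping, codon-usage structure,
expression heterogeneity across genes, transient (sub-threshold) pausing,
and coverage autocorrelation along transcripts. Recovery rates measured
here therefore characterise the method under its own assumptions — clean
P-site assignment and independent overdispersed counts — not performance
on real libraries.

## Problem sizes

Default analysis cohort: 60 genes × 3 organisms (~500 codons per gene);
the recovery benchmarks in the test suite use 500 genes × 3 organisms.
The Monte-Carlo cross-check of the null model uses 10^6 simulated genes;
structure metaplots in the analyses fold 40 sites with 200 random-control
repetitions and 20 permutations (the 10 000 / 100 defaults remain the
function defaults). These sizes are the package's chosen desk-scale
operating points.

## Known limitations

- The center-star aligner degrades above ~10% divergence or with long or
  clustered indels; use the external backend there.
- The Nussinov stub's scores are pair counts, not free energies; only the
  RNAfold backend produces kcal/mol.
- The expected-overlap product p × n_genes treats genes as exchangeable
  single-peak units; it is a first-order expectation, not a calibrated
  count.
- Attribution categories are sequence rules only; they cannot separate
  co-occurring mechanisms (e.g. a proline that is also preceded by
  negative charge is counted as proline by precedence).
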