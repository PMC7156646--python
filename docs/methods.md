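# Methods

This document records the statistical models, parameter defaults, and
numerical choices implemented in `isoribo`, together with the scope of
the synthetic-data generator and known limitations. All empirical numbers
quoted here were produced by the package's own test suite or the
`scripts/acceptance.py` run described in the README.

## Abundance quantification

For ORF (or transcript) *i* with estimated counts `n_i` and effective
length `l_i`,

    value_i = 1e6 * (n_i / l_i) / sum_j (n_j / l_j)

This is TPM when the counts come from RNA-seq and OPM when they are
fractionally assigned ribosome footprints. Columns sum to one million by
construction; the implementation guarantees a relative error below 1e-6
(`test_quantify.py`). Effective length is the ORF length minus (mean read
length − 1), floored at 1 nt, which equals the number of distinct
positions a read of the mean length can occupy.

**Footprint assignment.** Reads shorter than 26 nt are discarded
(footprints below this length are not reliably ribosomal). Uniquely
mapping reads get weight 1. Multi-mapping reads are grouped into
equivalence classes by their compatible transcript set and split
proportionally to the RNA-space abundance of those transcripts (the RNA
prior), optionally refined by EM iterations on the ribosome-space
abundances (counts per effective length) until the maximum weight change
falls below 1e-6 or 100 iterations. With 90 reads unique to A, 10 unique
to B, and 100 shared at equal lengths, the EM fixed point assigns the
shared class 0.9 to A — recovered to 1e-3 in the tests. Reads whose
compatible transcripts all have zero prior mass are split uniformly and
counted.

## P-site offsets

For each read length, 5' end positions of assigned reads are aggregated
relative to annotated ATGs over all ORFs (window −40..−1 nt). The offset
is the distance from the leftmost *covered* position to the ATG, where
coverage requires at least 2.0 of read weight (guarding against stray
alignments). The leftmost-covered rule is used instead of the modal
distance because it is invariant to the coverage profile inside the ORF:
the most 5' footprint whose P site is the start codon defines the
boundary, whereas a mode can be shifted by coverage unevenness. Under ±1
nt positional noise at a 20% rate the leftmost covered position moves by
at most 1 nt, matching the tested tolerance. Length classes with fewer
than 50 supporting in-window reads fall back to the conventional offset
of 12 nt, with a warning and a `defaulted` flag.

## Translation calling

Two metrics per ORF, computed from pooled P-site profiles:

- **Periodicity** = f0 / (f0 + f1 + f2), the fraction of P-site weight in
  the annotated frame.
- **PME** = H / H_max, the Shannon entropy of the read distribution over
  codons divided by the entropy of the uniform distribution over the same
  codons. PME is 1 for perfectly even coverage, 0 for a single-codon
  pile-up, and defined as 1 for degenerate single-region ORFs.

ORFs with fewer than 10 pooled reads or mean RNA abundance ≤ 0.1 TPM are
labeled `not_evaluated`: below these floors neither metric is meaningful.
Otherwise the ORF is `translated` iff both metrics are at or above
thresholds calibrated on positive controls: each threshold is the
empirical `1 − coverage_fraction` quantile (linear interpolation,
numpy's default) of the control distribution, with
`coverage_fraction = 0.90` so that 90% of controls pass each metric
marginally. Calibration refuses to run with fewer than 20 controls.

**Structural sensitivity ceiling.** Because the two thresholds are each
set at the 10th percentile of the positive class, the joint AND rule
passes about 0.9² ≈ 81% of true positives when the metrics are weakly
correlated (measured: 81.8% sensitivity, 100% specificity on 500
simulated ORFs at the default generator settings). Raising sensitivity
above this requires raising `coverage_fraction`, trading specificity.
This ceiling is a property of the calibration design, not of the
implementation, and is deliberately left visible in the acceptance suite.

## Splicing events and differential inclusion

Events of the seven classical types are enumerated from genomic exon
chains per gene: skipped exon (SE), alternative 3'/5' splice sites
(A3/A5, strand-resolved), mutually exclusive exons (MX), retained intron
(RI), and alternative first/last exons (AF/AL, strand-resolved). Each
event names the isoforms realizing the inclusion form and the total set
of isoforms involved; events whose differential region does not overlap
any involved ORF are discarded by default. Detector output is verified
against an independently written brute-force exon-chain oracle on random
genes. SE events with alternative exons ≤ 51 nt are flagged as
microexons (strictly < 28 nt as "short" microexons).

Inclusion in any abundance space is
`sum(abundance of inclusion isoforms) / sum(abundance of all event
isoforms)`; with TPM this is PSI, with OPM it is the translation-level
relative abundance RA. Values are undefined (NaN) when the denominator is
below 0.1, where the ratio is dominated by noise.

**Differential test.** The statistic is `dpsi = mean(cond2) −
mean(cond1)` over replicates. The null distribution pools absolute
between-replicate differences within each condition across events of
similar total abundance (10 equal-width bins of log10 abundance,
borrowing neighbors below 100 points per bin). Replicate differences are
scaled by `sqrt((1/n1 + 1/n2)/2)` so the null matches the sampling law of
a difference of replicate means under homoscedastic noise; without this
scaling the test is conservative by a factor of sqrt(3) at 3+3
replicates. The p-value is the fraction of null points ≥ |dpsi|;
significance additionally requires |dpsi| > 0.1. Measured on 1,000 null
events at 3+3 replicates the empirical type-I error at α = 0.05 is
0.049, inside the binomial 95% band, and a planted ΔPSI of 0.4 is
recovered with absolute error below 0.01 and p ≈ 0.

## Ortholog isoform pairing

For a 1-to-1 orthologous gene pair, all protein isoform pairs are
globally aligned (Needleman–Wunsch via Biopython's `PairwiseAligner`,
BLOSUM62, gap open −10, gap extend −0.5) and scored as identical aligned
columns divided by total alignment columns (gaps included), so scores lie
in [0, 1]. Pairs scoring below 0.8 are never emitted. The one-to-one
assignment repeatedly fixes the globally best-scoring remaining pair
(ties broken lexicographically). With strict symmetric preferences this
greedy rule produces the unique stable matching — verified in the tests
against both exhaustive enumeration of stable matchings (instances up to
5×5) and a textbook Gale–Shapley implementation (up to 6×6), with an
explicit blocking-pair check on every instance.

## Validation evidence

- **Isoform-specific sequence regions**: maximal ORF intervals whose
  genomic bases belong to no sibling ORF; validated by ≥ 10 uniquely
  mapping reads, where a read counts if it overlaps the region by ≥ 1 nt
  (crediting junction-spanning reads).
- **Frame-aware ORF regions**: additionally include shared bases read in
  a shifted codon frame by every sibling; validated by ≥ 1 summed P-site
  weight. By construction these regions contain the sequence-kind
  regions.
- **Peptides**: a peptide supports an ORF only if it matches exactly one
  ORF perfectly and no other ORF within 2 amino-acid mismatches over any
  equal-length window (gap-free Hamming distance; optional I/L
  collapsing). Verified against a naive reference implementation.
- **Polysome fractions**: per transcript, each fraction's TPM divided by
  the three-fraction sum (high-polysome, low-polysome, monosome); rows
  sum to 1, zero rows are NaN.

## Synthetic-data generator

The simulator builds gene models from segment templates: 5' UTR, an ATG
plus coding body, alternative internal segments realizing one event kind
per gene (cycling through SE, A3, A5, MX, RI, AF, AL plus microexon and
frame-shift variants), a stop, and a 3' UTR. Coding bodies are drawn from
a T-free alphabet {A, C, G}, so no spurious ATG or stop codons can arise
in any frame, and every ORF ends in `TAA` followed by a pad containing
stops in all three frames — this guarantees complete ORFs in every
isoform even when an alternative exon shifts the downstream frame. Minus
strand genes are generated by mirroring templates (A3↔A5, AF↔AL swap).

Footprints from translated ORFs have frame-0 probability 0.9 and
near-even codon coverage (Dirichlet concentration 50); untranslated ORFs
emit frame-uniform, bursty coverage (concentration 0.15). Read lengths
follow {28: 0.3, 29: 0.4, 30: 0.3} with planted P-site offsets
{28: 12, 29: 12, 30: 13}. Multi-mapping records are emitted for every
sibling isoform containing the read's genomic bases contiguously.
Single-isoform genes (every 4th gene by default) are forced translated
and serve as calibration controls. Two-condition designs plant inclusion
changes on selected genes with Gaussian replicate noise on the inclusion
share; ribosome-space abundances are proportional to RNA
(`proportional`), independently noisy (`coupled_noise`), or flat across
conditions (`decoupled`).

**Scope.** The generator covers what the pipeline needs to be tested
against planted truth: isoform structure, frame and coverage signal,
multi-mapping, replicate designs. It does not model sequencing errors,
alignment ambiguity beyond exact multi-mapping, nucleotide biases,
uORFs/dORFs, or overlapping genes.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds stay below 2^31.
- Output tables are written with `%.6g` floating-point formatting, sorted
  rows, and content-hash headers, so identical configurations produce
  byte-identical files (verified by running the full pipeline twice).
- Quantile calibration uses numpy's default linear interpolation.
- Empirical p-values use `searchsorted` on the sorted null pool
  (fraction of null points ≥ the observed statistic).

## Limitations

- In genes mixing translated and untranslated isoforms, reads from
  shared exons are fractionally split by the abundance prior, which
  dilutes the periodicity of the translated isoform and inflates that of
  the untranslated one; calling accuracy on such genes is below that of
  isolated ORFs. Frame-aware specific regions exist precisely to provide
  independent evidence in these cases.
- The sensitivity of translation calling is bounded by the calibration
  coverage (see above).
- The differential-inclusion null assumes approximately homoscedastic
  replicate noise within abundance bins; strongly heteroscedastic designs
  would need a different pooling rule.
- Ortholog pairing assumes strict preferences; exact score ties are
  resolved lexicographically, which is deterministic but arbitrary.
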