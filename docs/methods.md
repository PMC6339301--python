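# Methods

`capkit` implements the computational core of a target-capture ("hyb-seq")
panel workflow for tree species identification: selecting low-copy gene
targets from a transcriptome by genomic-read coverage, tiling hybridization
probes over them, quantifying how well the resulting probe set enriches
libraries across taxa, ranking species-diagnostic SNPs by per-site
Weir–Cockerham F_ST, and building reference-guided organelle consensus
genomes. This note records the models, the parameters that matter, and the
design choices made where the procedure was genuinely open.

## Coverage-based target selection (RPK)

When shotgun genomic reads are mapped against a transcriptome, the mapped
read count of a transcript scales with the genomic copy number of the
underlying gene. Normalising by transcript length gives reads per kilobase,

    RPK_t = (reads_plus + reads_minus) / (L_t / 1000),

a copy-number proxy that is comparable across transcripts of different
length. Sorting transcripts by ascending RPK produces a characteristic
profile: contaminants and unmappable models at RPK ≈ 0, a broad plateau of
single-copy genes, and a heavy upper tail of multi-copy families. A rank
window over this ordering — defaults 5000..15000, inclusive on both ends —
selects the low-copy plateau while skipping the zero-coverage bottom.
Inclusivity matters: a window of 5000..15000 selects exactly 10,001
targets. Ties in RPK are broken by lexicographic target id so the selection
is reproducible; the upstream mapper's multi-mapping policy is taken at
face value (the coverage table is not re-deduplicated). Repeat masking is
an external step; the module only offers a convenience filter that drops
targets whose soft/hard-masked fraction exceeds a threshold (default 0.5).

## Probe tiling

Probes are fixed-length tiles (default 100 bp, two per target) laid
end-to-end from the 5′ end: intervals [0, 100), [100, 200), ... in 0-based
half-open coordinates. Only full-length tiles are emitted — synthesis
vendors produce fixed-length oligos, and the behaviour for sub-length
remainders is otherwise unconstrained — so a 150-bp target yields one
probe. Probes containing N or soft-masked bases are flagged rather than
dropped by default, since vendor-side QC rules vary; `--drop-ambiguous`
removes them.

## Enrichment QC

Per-specimen enrichment is summarised by on-target yield (sum of plus- and
minus-strand reads mapped to the targets), its percentage of the library,
and per-target depth

    depth = read_length × mapped_reads / covered_bases,

with `read_length = 101` bp by default. Percentages are rounded
half-away-from-zero to one decimal and depths to the nearest integer,
matching conventional panel-metric tables.

"Reliably enriched" targets per species are those whose depth **strictly
exceeds** the threshold (default 10X) in *every* specimen of the species —
boundary equality is excluded, and the set is therefore monotone: raising
the threshold or adding a specimen can only shrink it.

Cross-taxon efficiency comparisons are normalised by first removing
organelle-labelled reads (organelle classification is upstream labelling;
no aligner is reimplemented here) and then drawing a fixed-size uniform
subsample without replacement (default 10^6 reads). Libraries with fewer
non-organelle reads than the subsample size raise a named shortfall error
rather than silently proceeding, mirroring the exclusion of under-sequenced
libraries from such comparisons.

Group comparisons use Welch's unequal-variance t-test with Satterthwaite
degrees of freedom (via `scipy.stats.ttest_ind(equal_var=False)`). The
"unpaired Student's t-test" reported for such panels with non-integer df
(e.g. df = 23.86 for a 24-vs-19 comparison) is only consistent with the
Welch form, so that is what the module implements; the test suite checks
parity with an independently coded textbook computation to 1e-10.

The package ships a 43-row table of published sequencing metrics for a
Meliaceae capture diversity panel (24 in-genus, 19 out-genus libraries) as
a plain TSV. It serves as a desk-scale regression anchor: every percentage
column recomputes from the count columns to the printed decimal, and the
group statistics above reproduce from it exactly. The in-genus/out-genus
t-test is computed over all 24 in-genus rows, including the one
under-sequenced library — that roster is what reproduces the published
statistic, although the same library is excluded from subsampled
comparisons by the shortfall rule; callers choose the roster.

## Variant filtering and Weir–Cockerham F_ST

Variant records are classified as biallelic SNPs, indels (any
length-changing allele), or multiallelic SNPs. The stringent filter retains
sites that are biallelic SNPs with **no missing genotypes**, minor allele
frequency ≥ 0.05, and site quality > 500. Boundary conventions are a
documented choice — sources for such pipelines conflict between "MAF > 5%"
and "MAF ≥ 5%", and between "quality > 500" and "≥ 500" — so the MAF bound
is inclusive, the quality bound strict, and both are configurable.

For each surviving site the per-locus estimator of Weir & Cockerham (1984)
partitions allelic variance using population sample sizes n_i (called
diploid genotypes), ALT-allele frequencies p_i, and observed heterozygote
proportions h_i, with r populations, n̄ the mean sample size, n_c the
variance-corrected mean, p̄ the weighted mean frequency, s² the weighted
frequency variance, and h̄ the weighted mean heterozygosity:

    a = (n̄/n_c) [ s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4) / (n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄) ]
    c = h̄/2
    θ = a / (a + b + c).

θ is undefined exactly when a+b+c = 0 (monomorphic sites) and is then
reported as undefined, never silently dropped. Negative estimates —
expected for weakly differentiated sites — are reported as computed, never
clamped. Genotypes are used exactly as coded in the VCF (diploid), even
where the organism is polyploid, because that is what upstream diploid
callers emit. Populations with fewer called genotypes than a minimum
(default 2) are excluded from the estimate with a logged warning: a
single-specimen population contributes no within-population variance and
inflates the θ = 1 count. The distribution summary excludes undefined
values, counts θ ≥ 0.5 and θ = 1 (tolerance 1e-9), and histograms with bin
width 0.05 clipped to [−0.05, 1]. Candidate diagnostic SNPs are the defined
sites at or above a θ threshold, sorted by θ descending then site key.

The estimator is tested against an independent exact-fraction oracle coded
directly from the component definitions, including the hand-derived
configuration pop1 = {AA, AA, Aa}, pop2 = {aa, Aa, aa}, where a = 7/36,
b = 0, c = 1/6, θ = 7/13.

## Organelle consensus

Reference-guided consensus calling applies a plurality rule per position:
the most frequent base when total depth ≥ 2 (configurable), otherwise N.
Ties at the top count also resolve to N — a tied plurality carries no
evidence for either base, and N is the conservative, testable choice.
Coverage statistics report mean depth over the full reference length and
percent of positions covered at ≥ 1X. Assembly contigs are joined with
100-N spacers. Alignment variable-site counting treats a column as a SNP
only when it contains ≥ 2 distinct unambiguous bases (A/C/G/T,
case-insensitive) among the selected taxa; N and gaps are ignored
entirely. Pileups and reports use 1-based coordinates (VCF convention);
internal arrays are 0-based.

## Synthetic data: what it emulates and what it does not

The generator module produces every input format with planted truth, under
one master seed fanned out to per-operation child seeds by stable hashing
(reproducible, independent streams; byte-identical reruns).

* **Coverage**: mapped-read counts are negative-binomial with mean
  rate × (L/1000) × copy_number and dispersion 5 by default (Poisson in the
  dispersion → ∞ limit). The overdispersion reflects the heavy-tailed RPK
  ranges real mappings show (spanning zero to thousands). The default rate
  of 0.8 reads/kbp/copy makes the low-copy plateau's mean RPK 0.8, the
  regime a rank-window selection targets. Covered bases follow the
  random-coverage saturation curve L(1 − e^(−reads·len/L)).
* **Capture**: per-read categories are multinomial with
  P(organelle) = organelle_fraction and P(on-target) = (1 − organelle
  fraction) × group bias, out-genus bias ≤ in-genus bias by construction.
* **Genotypes**: Hardy–Weinberg diploid draws at planted per-species ALT
  frequencies; "fixed" sites put every species at frequency 0 or 1 (both
  present), "private" sites are polymorphic in one species, "shared" sites
  share one intermediate frequency. Shared/private sites are redrawn
  (bounded retries) if sampling noise happens to realise a complete fixed
  difference, so planted class labels remain truthful for recovery scoring.
  Missingness is per-genotype Bernoulli; site qualities are drawn from a
  two-component uniform mixture (a low-quality fraction below the filter
  threshold, the rest above).
* **Organelle pileups**: per-position depths are Poisson around a given
  profile; planted substitutions replace the reference base in all reads.
  The recorded truth consensus applies the 2X/N rule to the *realised*
  depths, so recovery checks are exact.

The generators do not simulate read sequences, sequencing error profiles,
alignment artefacts, paralog collapse, linkage between sites, or
within-species population structure. Passing recovery tests therefore
demonstrates correctness of the selection/filtering/estimation logic under
the stated generative model, not robustness to upstream artefacts in real
libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: the 43-row metrics table
for panel statistics; a 52,181-entry ranking for the window-cardinality
check; 500-site, 16-specimen genotype panels for F_ST recovery; 1200
transcripts × 20 seeds for selection purity; 3-kb references for consensus
recovery. These sizes make the full suite run in seconds while leaving all
statistical checks comfortably powered. Floating-point tolerances: 1e-12
for estimator component comparisons against the exact-fraction oracle,
1e-10 for t-test parity, 1e-9 for θ = 1 counting. Rounding is
half-away-from-zero via `decimal` to avoid binary-float round-half-even
surprises in reported percentages.

## Known limitations

* Organelle read classification, read mapping, repeat masking, variant
  calling, and multiple alignment are consumed, not implemented.
* The probe-tiling rule reproduces the stated design (two 100-bp tiles per
  target); vendor-side probe QC that removes a small fraction of tiles is
  not modelled.
* F_ST is the global multi-population estimator; pairwise F_ST and
  assignment methods are out of scope.
* Diploid genotype handling of polyploid organisms inherits whatever bias
  the upstream caller introduced.
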