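# Methods

This note documents the models, conventions and numerical choices behind
the toolkit, in the spirit of a statistical methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and binning

All internal coordinates are 0-based half-open (BED convention); GTF input
is converted on read. The genome is tiled with fixed-width bins (default
25 kb, the resolution at which interactions are called; 5 kb for binary
binding profiles), with the last bin of each chromosome truncated. A
fragment is represented by the single nucleotide at its center,
`start + floor((len − 1)/2)`; for even lengths this is the left-of-middle
base. The center convention keeps every tag in exactly one bin and one
gene, which makes all count partitions exact. Distance between the two
tags of a pair is measured center-to-center, consistent with center-point
feature assignment; the alternative (nearest-edge) differs by at most one
tag length (≤ 27 bp) and never moves a pair across the class boundaries
used here (10 kb, 100 kb, 1 Mb, 10 Mb), which sit orders of magnitude
above that.

## Read anatomy and extraction

The chimeric construct is, 5′→3′: RNA tag (25–27 nt, transcript sense),
the 50-nt bridge-adapter top strand, DNA tag (25–27 nt), a sequencing-
linker stub, a 6-nt multiplexing barcode, then filler to the read length
(150 nt); the whole construct appears in either sequencing orientation
with probability ½. The 25–27-nt tag window is EcoP15I geometry: the
adapter carries one CAGCAG recognition site per strand, and the enzyme
cleaves 25–27 nt away from each.

The extractor finds the adapter by best Hamming-distance placement of the
top strand and its reverse complement over all offsets (default budget
2 mismatches; two placements tying at the best distance are rejected as
ambiguous). Substitution-only matching is a deliberate simplification:
substitution errors dominate Illumina data, and exact Hamming search makes
the extractor's behaviour fully enumerable in tests. This diverges from
the HMM-based extraction used historically for this assay; the mismatch
budgets are explicit knobs because the original tolerances are not
published.

Reads found in reverse orientation are reverse-complemented before the
flanks are taken, so the RNA tag is always reported in transcript sense
and the RNA strand is recovered from construct orientation alone. The
upstream flank is the RNA tag; flanks shorter than 25 nt are rejected
(`short_flank`), flanks longer than 27 nt keep only the adapter-proximal
27 bases (a DNase fragment can extend past the cleavage read-through).
The DNA-tag length (25, 26 or 27) is delimited by the best Hamming
placement of the linker stub at the three candidate offsets, ties
preferring the longer tag; the stub is a pure delimiter, so no placement
is "rejected" — a garbage read instead fails the barcode check. The
barcode is read immediately after the stub and matched to the whitelist
within 1 mismatch; ties and distance > 1 give `bad_barcode`. Whitelist
barcodes default to four 6-mers with pairwise Hamming distance ≥ 3, so a
single error is always uniquely correctable.

rRNA contaminants are screened on the RNA tag only, by exact shared
k-mers (k = 21) with the rDNA repeating unit on either strand. For
25–27-nt tags a 21-mer seed makes false positives against a ~5-kb
reference essentially impossible (expected rate ≈ 2·L·7/4²¹ ≈ 10⁻⁸) while
any true substring hits by construction. PCR duplicates are collapsed on
the exact (RNA seq, DNA seq, barcode) triple, keeping the first
occurrence; this is sequence-level dedup, performed before alignment.

## Mapping and pairing

On fixture genomes tags are mapped by exact search (forward-strand seed
dictionary, verified full-length on both strands). A unique hit receives
MAPQ 37 — the conventional "unique" code of BWA-backtrack, which real
libraries are aligned with — multi-hits receive MAPQ 0, and both tags of
a pair must reach MAPQ ≥ 37 to survive. The threshold is exposed because
the uniqueness rule is stated both as "= 37" and "≥ 37" in the
literature; ≥ is the weaker and adopted form. Real data enters as a
tab-separated aligned-tags table (one documented header, 0-based
half-open); SAM/BAM conversion is a one-line external step, which keeps
the core dependency-light. RNA strand is taken from the alignment; DNA
strand is stored but ignored downstream.

## Significance model

For RNA *r* with counts k(r,b) over bins *b*: N(r) = Σ_b k(r,b) and
U(r) = #{b : k(r,b) > 0}, both genome-wide (cis and trans bins alike).
Each observed (r,b) is tested one-sided against Binomial(N(r), 1/U(r)):
the null says the RNA scatters its contacts indifferently over the bins
it is seen in. An RNA observed in a single bin has P = 1 and p = 1 — the
model cannot call it, which is the correct degenerate behaviour.

The tail probability is computed through the binomial survival function;
values below 1e-50 are recomputed by direct log-space pmf summation with
geometric early termination, because the incomplete-beta route loses
relative accuracy (~1e-7) very deep in the tail. Above the mode the term
ratio is < 1, so the summation converges in a few dozen terms.

Benjamini–Hochberg correction is applied once, jointly over the full
interaction list (all RNAs together). The correction scope is genuinely
open — per-RNA correction is defensible — but a single adjustment over
the pooled list is the most literal reading of "adjust the p-values of
the interaction list" and is the default here. Interactions with adjusted
p < 0.05 are significant. Blacklist filtering is applied *after*
correction, to the significant set: by default a significant interaction
is removed when its DNA bin interval intersects a blacklist interval; a
`blacklist_on="centers"` toggle instead keys on the raw tag centers.

## Synthetic data: what it emulates and what it does not

The generator is the study-conditions definition for every test. Defaults:
two 300-kb chromosomes, 40 non-overlapping genes (2–6 kb, 3 exons) with a
biotype mix of 50% protein-coding / 20% long-ncRNA / 15% small-ncRNA /
15% other; log-normal (σ = 1) expression weights, giving realistic
heavy-tailed quartile structure; 25-kb bins. Contacts mix three
components: a nascent fraction (25%) within 1 kb of the RNA's own
position, a trans fraction (5%) uniform on another chromosome, and the
remainder following the canonical chromatin contact decay
P(d) ∝ (d + d0)^(−α) with α = 1, d0 = 1 kb, sampled by inverse CDF and
redrawn while out of range. Per-bin enrichment multiplies a target bin's
background mass by a fold factor and renormalizes
(p* = f·q/(1 + (f−1)q)); the bin's background mass q is estimated from
the gene's own base draws, so the construction is exact in expectation
for any background shape. A 500-bp repeat is planted verbatim at two
intergenic loci to create honest multi-mappers; TADs, peaks, blacklist
intervals and alternating 50-kb A/B compartments are laid down as BED
tables.

Reads carry the full construct with random-base filler, optional
substitution errors applied uniformly over the read (duplicates are exact
copies made *after* error injection, as PCR copies of one molecule), and
rRNA contaminants whose RNA tag is a random substring of a synthetic 5-kb
rDNA stand-in. The truth table stores both the genomic intervals and the
*emitted* (post-error) tag sequences, so extractor accuracy can be scored
under noise.

Deliberately not modelled: indels and quality-score structure, GC and
mappability bias, chromatin-state-dependent contact probability,
transcript isoforms (tags sample the gene span uniformly), and the
GRID-seq/MARGI anatomies. Tests passing on this generator therefore
demonstrate correctness of the *computational* contract — boundary
conventions, deconvolution, statistics — not robustness to every artefact
of real libraries.

## Downstream statistics

- **Replicate correlation** is Pearson's r on (RNA, bin) units observed
  with positive counts in *all* replicates ("complete observations").
- **Expression correlation**: interaction counts → RPK (count / kb of
  gene span); genes need RPK ≥ 1 and TPM ≥ 1; r² on log10 values.
- **Distance decay** measures DNA-center-to-nearest-gene-edge distance
  (0 inside the gene body), aggregates on log-spaced bins, and normalizes
  each expression quartile's curve to unit mass (quartile I = lowest).
- **Metaprofiles**: each region of width L is extended by L on both
  sides and the 3L window is chopped into 300 bins (the region proper is
  bins 100–199 exactly); per-bin counts are scaled to per-bp rates and
  averaged over regions; regions whose window leaves the chromosome are
  dropped. The inside/outside split is computed TAD-by-TAD: for each TAD,
  pairs whose RNA center lies in the half-open TAD interval feed the
  inside profile, all others the outside profile — an RNA outside one TAD
  may well be inside a neighbouring one.
- **Peak density**: per-bp counts in ±5 kb around peak centers, divided
  by the window mean to align baselines ("mean of ±5000 bp" is ambiguous
  between window mean and edge mean; window mean is the default, an
  edge-mean toggle is provided). A matched random-region generator
  supplies the control.
- **Repeat enrichment**: with self-interactions removed, the percentage
  for family F in distance interval I divides F's interactions in I by
  F's total tag count; the test is two-sided equal-variance Student's t
  across replicate-level proportions, F vs the non-repeat class (NR).
  The degenerate all-identical case returns t = 0, p = 1 rather than NaN.
- **Cross-library comparisons**: per-gene Jaccard distance
  1 − |A∩B|/|A∪B| on binary 5-kb binding profiles (both empty → 0)
  against capture-rate difference |a−b|/max(a,b)·100 (both zero → 0);
  promoter (TSS ± 2 kb) log2 ratios on library-size-normalized counts
  with a pseudocount of 1 on the normalized scale (zeros are common at
  promoters; the pseudocount is the package's choice); shared-trans
  percentage uses the union of the two significant sets as denominator
  (the symmetric choice among the undocumented alternatives); top-k
  overlaps rank by normalized count with ties at rank k broken by gene
  id, making the sets deterministic.
- **Dominant region/class matrices** take the per-bin-pair mode with
  fixed tie orders (exon < intron < intergenic;
  protein_coding < long_ncRNA < ncRNA < other).

## Problem sizes and determinism

Every stochastic routine takes a seed or Generator and is fully
deterministic given it. The shipped verification uses problem sizes
chosen to make the statistical assertions sharp while staying desk-scale:
50,000-read round trips, N = 10,000 contacts over 1,000 bins × 20 seeds
for null calibration and × 50 seeds for planted-enrichment power,
200 random triples against the exact rational binomial oracle, and
100 random vectors against the definitional BH step-up oracle. The
synthetic genome (2 × 300 kb) is small enough that exact mapping indexes
build in seconds yet large enough that 25-mers are unique away from the
planted repeat.

## Known limitations

- The exact mapper tolerates no mismatches; tags with sequencing errors
  are dropped rather than rescued, so recovery under noise is bounded by
  the error-free fraction of tags (a real aligner rescues most of these).
- Gene assignment is gene-level, not isoform-level; exon/intron labels
  use the union of exons.
- The significance model is background-uniform per RNA; it does not
  stratify by distance, so strong distance decay inflates local-bin
  significance — mirroring the original model's behaviour, not fixing it.
- Hi-C processing, CAGE normalization, peak calling, liftover and triplex
  prediction are out of scope; their outputs are consumed as plain
  tables/BED when needed.
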