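# Methods

`compbias` re-implements, as a tested pipeline, the bespoke computations
behind a comparative analysis of two extremely AT-rich parasitoid wasp
genomes (*Aphidius ervi* and *Lysiphlebus fabarum*-type data): nucleotide
and codon composition, expression-stratified composition comparisons,
haploid linkage mapping with scaffold anchoring, and bisulfite methylation
summarization. Because the deposited assemblies, annotation and read data
are large downloads, a synthetic-data module generates inputs with the
statistical structure each analysis assumes; every claim the test suite
makes is therefore a claim about the method, validated on data whose truth
is known by construction.

## Composition statistics

GC content is (G+C)/(A+C+G+T); IUPAC ambiguity codes are excluded from the
denominator by default (`count_as_non_gc` keeps them). GC3 restricts the
numerator and denominator to third codon positions of sense codons: each
gene's terminal stop codon is excluded and a trailing partial codon is
truncated with a warning. Relative synonymous codon usage for codon *c* in
a synonymous family of size *k* is

    RSCU_c = k · n_c / Σ_{c'∈family} n_{c'}

so RSCU = 1 means unbiased usage; within each family the values sum to *k*
whenever the family is observed. Codon counts are pooled over the whole
CDS set (concatenated pooling, not per-gene averaging); per-gene profiles
remain available by passing single-element lists. Stop codons are excluded
from RSCU and GC3 — the convention of standard codon-usage tooling —
and the exclusion is stated in output metadata. Single-codon families
(Met, Trp) are reported as RSCU 1 when observed.

Nitrogen cost is offered on three scales because "nitrogen content" is
genuinely ambiguous: per single-strand base (A=5, G=5, C=3, T=2 atoms,
from the molecular formulas of the bases), per duplex pair (G:C = 8,
A:T = 7 — the reason GC and nitrogen cannot be fully disentangled), and
per amino-acid residue (total N including the backbone amide: Arg 4,
His 3, Lys/Asn/Gln/Trp 2, all others 1; `sidechain_only=True` subtracts
the backbone). The residue scale is the default for gene-set comparisons.

Profiles are compared by pairwise Euclidean distance on RSCU vectors
(undefined entries dropped pairwise) and a principal-component projection
via SVD of the column-centered RSCU matrix, with per-component explained
variance. Gene-set composition differences use Welch's two-sample
two-sided t-test with Welch–Satterthwaite degrees of freedom, implemented
from first principles (only the t distribution function comes from scipy)
and checked against `scipy.stats.ttest_ind` to 1e-10 in the tests.

## Expression strata

Libraries are normalized with median-of-ratios size factors: the
reference is the per-gene geometric mean over libraries (genes with any
zero excluded); each library's factor is the median ratio to that
reference. Size factors are identified only up to a global constant, which
is irrelevant downstream. The "most highly expressed 10%" stratum per life
stage takes ⌈0.10·G⌉ genes ranked by mean normalized expression over that
stage's libraries, ties broken by gene id (a tie at the boundary is
logged).

The differential-expression test is a deliberate stand-in for a
negative-binomial GLM: Welch's t on log2(normalized count + 1) per gene,
Benjamini–Hochberg q-values, significance at q < 0.05. It is simple,
well-calibrated under an NB null (verified: discovery fraction ≤ 1% at
nominal 0.05 over 10 × 2000-gene null replicates) and powerful at the
panel sizes involved (≥ 90% recall of 4-fold changes at 20 libraries per
stage), but it is not the NB model: shrinkage, dispersion sharing and
covariate adjustment (host, replicate) are absent, so DE-stratum
membership on real data would differ at the margin while top-decile strata
(no model involved) transfer directly. The pseudocount (default 1) and the
normalized-vs-raw ranking choice are recorded in output metadata. BH is
implemented in-package (step-up with enforced monotonicity) and checked
against statsmodels to 1e-12.

The strata report runs four Welch comparisons between the adult and larva
strata: top-decile GC, DE GC, top-decile nitrogen, DE nitrogen — GC in
percent, nitrogen per residue.

## Linkage mapping

Haplodiploid males are haploid, so sons of one female form a
doubled-haploid-like mapping panel with one informative parent — except
the maternal phase is unknown. The pipeline:

1. **Filter**: drop markers with > 20% missing data or minor-allele
   frequency < 15%. The boundaries are inclusive on the keep side
   (exactly 20% / exactly 15% are kept), since the stated rule removes
   strictly-greater / strictly-smaller values.
2. **Phase-mirror**: duplicate every marker with flipped alleles. Groups
   then form among co-phased copies; one group of each mirrored pair is
   discarded afterwards (the one kept contains the lexicographically
   smallest original id — but both partners carry the same original
   markers, so the choice is presentational).
3. **Group**: single-linkage transitive closure over pairs with a
   two-sided Fisher exact p < 1e-6 on the 2×2 haplotype table **and**
   r̂ < 0.5 (coupling phase). The r̂ < 0.5 condition is essential: a
   marker and its own mirror are perfectly negatively associated and
   would otherwise always link, collapsing the mirror construction.
   A group containing a marker and its own mirror is an error (data
   inconsistency). Groups below 2 markers are reported unplaced.
   All-pairs Fisher p-values use a vectorized hypergeometric enumeration
   with a log-gamma lookup table, validated against
   `scipy.stats.fisher_exact` to 1e-9; the scipy routine is far too slow
   for the ~260k mirrored pairs of a realistic panel.
4. **Order**: within a group, minimum-spanning-tree backbone on the
   complete r̂ graph, a depth-first path from one end of the tree
   diameter, then local search (2-opt segment reversals plus
   single-marker relocations — relocations matter because a lone
   misplaced marker is unreachable by reversals) minimizing the summed
   adjacent r̂. The phase-free estimate min(r̂, 1−r̂) is used throughout,
   so ordering is well-defined on raw unknown-phase input too. Ties break
   by marker id; orientation is fixed so the first id sorts before the
   last. This MST + local-search order is this package's defined
   equivalent of the external MSTmap objective; it is validated by
   simulation recovery (6/6 groups, within-group Kendall τ ≥ 0.95 at 90
   sons), not by output-identity with that tool.
5. **Distances**: cumulative Kosambi centimorgans over adjacent pairs,
   d = 25·ln((1+2r)/(1−2r)), inverse r = tanh(d/50)/2. Multipoint
   likelihood is not used; summed adjacent distances overestimate long
   spans slightly under noise (a documented limitation). An adjacent
   estimate of exactly 0.5 is clamped just below with a warning.
6. **Gap split**: any adjacent gap > 70 cM splits its group (a gap that
   large at n = 90 indicates a false fusion of two chromosomes);
   positions re-zero per new group.
7. **Anchor**: each scaffold goes to the group holding the majority of
   its markers, at its mean cM; orientation is the sign of the Spearman
   correlation of bp vs cM (|ρ| ≥ 0.5, at least 3 distinct markers, else
   unknown). A chimera is flagged when ≥ 5 minority-group markers are
   positionally contiguous at one scaffold end; the suggested split is the
   bp midpoint between the two blocks.

The whole map is invariant to flipping the phase of any subset of markers
(verified exactly in the tests): mirroring makes the doubled marker set
phase-symmetric, and every tie-break keys on mirror-stripped ids.

VCF input takes haploid GT calls; heterozygous calls in a haploid
individual are set missing and logged.

## Methylation

Every genomic cytosine (both strands) is classified by its two downstream
bases on its own strand: CG, CHG, CHH (H ∈ {A, C, T}); sites within two
bases of their strand's 3' end, or with an ambiguity code in the window,
are context-undefined and excluded from rate tables (but still counted
for coverage). CG sites are counted per strand, not collapsed to
symmetric dyads, matching a per-cytosine accounting; dyad collapsing can
be layered on the per-site table. Calls from alignments: forward-strand
reads show C (methylated) or T (unmethylated) at forward cytosines;
reverse-strand alignments show G or A in reference orientation; anything
else tallies as a mismatch. Rates are raw fractions of methylated calls —
incomplete conversion is simulated but deliberately not corrected, since
the reported quantities are raw. Covered sites are classed never
(no methylated call), always (no unmethylated call), or variable.

The built-in mapper is a three-letter (C→T / G→A collapsed) exact
matcher that discards multi-hit reads as ambiguous. It exists so the
module is exercisable end to end on synthetic reads; real data would come
from a dedicated bisulfite aligner's SAM, which `count_calls` accepts
unchanged.

## Synthetic data

All generators are pure functions of a `SimulationSpec`; one seed
determines every byte of output, and each generator emits a truth table
the tests consume. Defaults are the study conditions:

* genome: iid bases, 25% GC target (the AT-richness regime of these
  genomes), 250 kb at desk scale;
* genes: ATG + codons from an AT-skewed table (weight 0.15 per G/C in the
  codon) + stop, mean 150 codons, half on the minus strand, two exons with
  60 bp introns; no internal stop can arise by construction;
* expression: NB counts (dispersion 0.1, mean ≈ 200) for two stages × 10
  libraries, planted log2 fold changes, optional GC-coupled larval shift;
* cross: 6 chromosomes × 30 markers, adjacent r = 0.05, 90 sons (the
  post-filter panel size of the real cross), 5% missing, 0.5% genotype
  error; phase labels are randomized per marker at generation time so the
  mapping pipeline's phase invariance is genuinely exercised;
* bisulfite: CG/CHG/CHH methylation probabilities 0.01/0.002/0.002,
  drawn once per site (so never/always/variable classes are meaningful),
  99.5% conversion, 80 bp reads at depth 5.

Recombination is a marker-to-marker Markov walk with the specified r — no
interference model — because the consumers need pairwise r̂ and order
recovery, not a chiasma process. What the generators do **not** emulate:
repeat and TE landscapes, read errors and quality scores, isoform
structure, library-composition biases, segregation distortion, or
dispersion trends across expression levels. Tests passing on this data
therefore validate the algorithms' correctness and calibration, not their
robustness to every artifact of real sequencing data.

## Numerical and edge-case choices

* Welch with zero variance in both groups: t = 0, p = 1 on equal means,
  p = 0 otherwise.
* Fisher two-sided p sums hypergeometric probabilities ≤ the observed one
  with a 1e-7 relative tolerance for float ties (scipy's gate).
* RSCU of an unobserved family is undefined (absent), not zero; profile
  distances drop undefined entries pairwise.
* Empty strata, all-ambiguous sequences, disconnected r̂ graphs, and
  all-markers-filtered matrices raise with explanatory messages rather
  than returning degenerate numbers.
* Percentages are rounded to one decimal in summary outputs only; full
  precision is kept in tables.

## Problem sizes

Default test and acceptance sizes — 250 kb genomes, 200 genes, 2000-gene
expression matrices, 20-seed × 180-marker crosses, 20 kb bisulfite
genomes at depth 5 — were chosen so the full suite exercises every
statistical claim at meaningful power while remaining quick to run on a
laptop. Scaling the spec fields up is supported and changes no code path.
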