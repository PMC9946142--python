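# Methods

## Coverage-deviation karyotyping

Per-window mapped-read counts (post duplicate removal) are normalized by
each sample's total mapped reads, making the statistic invariant to
sequencing depth. For every window, the line/parent rate ratio is computed
against each wheat parent in the line's crossing history and the ratio
closest to 1 is kept, on the assumption that the parent whose coverage best
matches the line is the parental donor of that window. The selection is per
window, not per chromosome. When two parents are exactly equidistant the
lower ratio is kept — a deterministic tie-break that is conservative toward
detecting loss events. Windows where no parent has coverage are *undefined*;
they are excluded from block statistics rather than imputed, because no
principled imputation exists for zero-coverage windows at these scales.

The resulting deviation proxies the copy number of wheat DNA relative to
the parent: windows in [0.8, 1.2] are *normal*; values near 0 indicate
homozygous introgression or deletion; ~0.5 heterozygous or monosomic state;
~2 duplication. The band edges and all thresholds below are configuration
values (one `Thresholds` block), not constants.

## Block calling

On the 1 Mbp track, maximal runs of windows with deviation < 0.7 are found
per chromosome. A run beginning within 5 Mbp of the previous block is merged
into it, and the intervening gap windows *count as constituents*: a merged
block is discarded when fewer than 80% of its constituent (defined) windows
are below threshold. Counting gap windows makes the rule self-limiting —
aggressive merging dilutes the below-threshold fraction and the block
discards itself. The discard rule is applied after merging. Duplications
use the same run/merge/fraction machinery with the predicate deviation
≥ 1.8.

Block zygosity comes from the mean deviation of its below-threshold
windows: below 0.3 the wheat DNA is essentially absent (homozygous event);
otherwise the block is heterozygous/monosomic. Only the homozygous case is
characterized quantitatively in published work; the 0.3 cut sits between
the residual-coverage level of homozygous events (~0.05) and the
heterozygous band (0.4–0.6).

## Donor assignment

A donor-specific SNP is an alternate allele called homozygous in the donor
accession and absent — as an allele, not merely as a position — from every
wheat parent. Heterozygous donor calls are excluded by default because the
donor is a single diploid individual, making such calls ambiguous evidence
for a species-specific allele (`include_het_donor` and
`strict_position_exclusion` flags cover the alternatives). Line SNPs
matching the donor set in position and allele are retained, sites above 3×
the line's mean coverage are removed as collapsed repeats (the mean depth is
per-sample manifest data, since published per-line thresholds demonstrate it
is not a constant), and matches are binned into 1 Mbp windows split by
genotype class.

A homozygous reduced block is assigned as a donor introgression when at
least 50% of its windows carry ≥ 5 homozygous donor matches per Mbp **and**
the block-wide hom:het ratio is ≥ 2.0; otherwise it is a deletion. The
rationale: donor reads from an introgressed segment that aberrantly map
elsewhere produce *heterozygous* donor-allele calls (donor and wheat alleles
at the same site), so a low hom:het ratio marks a mapping artefact, not
donor DNA. These three numbers are **calibration defaults**, not published
values — no quantitative thresholds for this assignment are available — and
are exposed in the configuration. Heterozygous blocks carry their donor
evidence as heterozygous matches, so they are assigned by total donor-match
density instead (default ≥ 50/Mbp, calibrated well above the ~10/Mbp scatter
level of aberrant mapping yet far below the ~3000/Mbp signal of a real
heterozygous introgression).

## Border refinement

Borders called on the 1 Mbp grid are refined on a 100 kbp track: each border
moves outward to the outermost contiguous fine window satisfying the calling
predicate, searching at most one coarse window beyond the edge ("either side
of the larger block"); when the windows just inside an edge fail the
predicate the border retracts inward to the first window that passes.
Refinement is skipped with a warning when the fine track does not cover the
block.

## Downsampling

`downsample_counts` thins each window count with a Binomial(count, f) draw
and scales the sample total by f, which is exactly the count distribution
obtained by keeping each read independently with probability f. Recovery is
then assessed from the deviation track alone (blocks left origin-unassigned,
matched against truth by ≥ 50% reciprocal overlap regardless of origin),
since at very low depth no usable SNP evidence remains.

## Gene-level classification

Orthologue pairs require reciprocal best hits (filtered at ≥ 90% identity
and alignment length ≥ 80% of the query; best hit = highest bitscore, ties
broken by lowest e-value then lexicographic subject id — the tie-break is a
fixed convention) *and* shared orthogroup membership. Donor genes are novel
when their orthogroup has no wheat member or they are unassigned; an
orthogroup is donor-expanded with ≥ 4 donor proteins and more than twice the
wheat count. A donor gene is introgressed in a line when its mean mapping
depth is at least the line's threshold (default 0.6× mean depth) and it
lies on a contig anchored by an orthologue pair whose wheat partner starts
inside a called introgression — depth alone cannot distinguish an
introgressed gene from a conserved paralogue attracting cross-mapped reads,
so the contig condition is deliberately conservative. Resistance-candidate
filtering keeps genes of the supplied classes (NLR, protein kinase, ABC
transporter, WAK) with ≥ 2× depth in every phenotype-positive line and
< 2× in every negative line, flagged for manual review rather than asserted
unique. Novelty cut-offs are 85% identity for NB-ARC domains and 80% for
whole proteins, with no hit counting as identity 0.

## Expression analyses

A gene is expressed when its mean TPM across replicates exceeds 1.0
(strictly). Identity binning of expressed fractions uses edges <90 / [90,95)
/ [95,99) / ≥99 — a reconstruction, since exact published bin edges are not
available; the edges are configurable. For differential expression, wheat
genes inside introgression blocks are dropped (no donor orthologue) or have
their counts summed with the introgressed orthologue under the wheat gene
id; retained totals are conserved exactly. A gene is DE when |log2FC| ≥ 1
and adjusted p < 0.05 against *both* wheat parents with agreeing sign
(disagreeing significant signs are logged and returned `not_de`).

Triad test sets require: D homoeologue introgressed or deleted and
downregulated (a deleted homoeologue is not expressed, so deletion counts as
downregulation); A and B in normal copy-number regions; and every
homoeologue with normalized expression count ≥ 1, taken as the mean across
samples ("across samples" is ambiguous between mean and every-sample; mean
is the default, `--per-sample` provided). Controls substitute "D normal and
not DE". Upregulation of a homoeologue means a full dual-comparison `up`
call. The 2×2 upregulation table is tested with a two-tailed Fisher's exact
test (two-sided p = sum of hypergeometric probabilities of all tables with
the observed margins no more probable than the observed one); homoeologue
log2 fold changes are compared with a two-tailed t test, Welch by default
since equal variances have no justification here (configurable). Windowed
expression profiles use mean per-gene log2FC in 10 Mbp windows with a 0.5
pseudocount.

## Synthetic data

The simulator operates at the window-count and SNP-record level — the exact
summaries the method consumes — because read-level simulation adds cost but
no test power at these scales. Default study conditions: three 50 Mbp
chromosomes (one per subgenome), 5× depth with 150 bp read-length
equivalents, Poisson counting noise, two wheat parents, a donor diverged at
5e-3 SNPs/bp (chosen so homozygous matches per 1 Mbp window are comfortably
nonzero even after downsampling), parents carrying 1e-3 SNPs/bp of which 5%
collide with donor alleles. Planted defaults cover every event class at
≥ 5 Mbp: a 20 Mbp homozygous introgression (large enough for the
downsampling analysis), an 8 Mbp homozygous deletion, a 6 Mbp monosomic
deletion and an 8 Mbp duplication — a copy-number load that keeps the
genomic background inside the 0.8–1.2 normal band, as in real lines where
most of the genome is unaffected. Inside introgressions, residual
cross-mapping retains 5% of parental coverage (deviation near, not at,
zero) and donor sites are recovered as homozygous line calls at rate 0.9;
outside, heterozygous false matches occur at scatter rate 0.002 per donor
site, and 1% of line SNP sites receive ~8× depth to exercise the 3× repeat
filter. Sub-window event boundaries are supported and recorded in truth.
One global seed drives a named random stream per output type, so adding
outputs never perturbs existing ones and equal seeds give byte-identical
files.

The expression simulator plants triads with negative-binomial counts
(dispersion 0.05, log-normal triad means), replaces introgressed D
homoeologues with donor orthologues (25% of them carrying a planted log2FC
of magnitude 1.5–3, 70% downregulated), zeroes deleted D homoeologues, and
never perturbs A/B homoeologues — the balancing null holds by construction,
matching the empirical finding that no compensation occurs. Its DE tables
are computed with a per-gene Wald test on the log2 fold change using the
generative dispersion (a per-gene t test at 3 replicates has essentially no
power after multiple-testing correction), playing the role of an external
DE engine.

What the simulator does *not* emulate: GC and mappability bias (the method
applies no such correction), recombination and linkage structure, repeat
families beyond the high-depth site fraction, correlated noise between
neighbouring windows, and genuine read-level junction structure. Passing
tests therefore demonstrate correctness of the detection rules under the
stated noise model, not robustness to every artefact of real mapping data.

## Problem sizes and numerics

The seeded recovery and downsampling analyses use 20 replicate simulations
of the 3 × 50 Mbp genome — large enough that every event class appears at
multiple scales while a full run of tests plus the acceptance script stays
in the single-digit minutes on one CPU. Fisher p-values are computed by
`scipy.stats.fisher_exact` and cross-checked in the test suite against
exhaustive enumeration with exact rational arithmetic for margins ≤ 200.
Block calling is cross-checked against a brute-force run/merge/fraction
enumerator on random deviation vectors, and RBH pairing against an
all-pairs mutual-best search. Degenerate inputs (empty tables, zero-margin
contingency tables, blocks without fine-track coverage, genes without
contigs) are handled explicitly and logged rather than imputed.

## Known limitations

Assignment thresholds for donor blocks are calibration defaults (see
above). Nested or overlapping structural events on one chromosome are not
modelled or resolved — complex lines need cytogenetic corroboration.
Junction localization stops at the 100 kbp window scale; single-read
breakpoint inspection is out of scope. The DE engine is consumed as input,
not reimplemented: published analyses use DESeq2, and the simulator's Wald
tables only emulate its output schema and calibration, not its dispersion
shrinkage.
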