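# Methods

This note records the statistical models behind `breakscan`, the defaults
and why they are what they are, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinates and data model

All internal coordinates are 0-based half-open; BED stays 0-based on disk,
GFF3 and SEG are converted to 1-based at the file boundary. Exons are kept
in *transcript* order (reversed genomic order on the minus strand) so that
"proximal" always means 5′ of the transcript and "distal" 3′ — the
direction of an expression step is then interpretable as the gene's fusion
role regardless of strand. Missing expression values are dropped per
profile with the surviving exon indices remembered, not imputed: the
two-sample t-test tolerates unequal group sizes, while imputation would
bias the very step being tested.

## RNA breakpoint analysis

The walking scan performs, at every exon–exon junction, a classical
pooled-variance two-sided Student's t-test of all proximal against all
distal exon values. Pooled rather than Welch: per-side exon counts are
small (often 2–5), where the classical test is the textbook default and
Welch's df estimate is unstable. Each side needs `min_group = 2` exons
(a variance needs two points), so genes with fewer than 4 exons are
untestable and skipped.

The Bonferroni family is the number of junction tests *actually performed
per sample* across the candidate-gene list, recorded on every emitted call
for auditability; with α = 0.05 this reproduces per-platform per-test
cutoffs such as 0.05/3218 = 1.55×10⁻⁵ when the gene set matches. Per gene
and sample the junction of minimum P is reported (most-5′ junction on
ties — deterministic), emitted when P < α/N. Directional filtering keeps
distal-elevated calls for 3′-partner genes and proximal-elevated calls for
5′-partner genes; in practice the 3′ side is the sensitive one, because a
3′ partner's wildtype allele is usually silent while a 5′ partner's
wildtype allele masks the step.

Numerics: the scan uses one-pass cumulative sums on mean-centered values;
junctions whose within-group sum of squares falls below 10⁻⁷ of the total
(catastrophic-cancellation territory) are recomputed with exact two-pass
sums, keeping agreement with junction-by-junction t-tests to 10⁻¹²
relative. Degenerate variance resolves as: both sides constant and equal →
t = 0, P = 1; zero pooled variance with unequal means → P set to the
smallest positive float and flagged.

## DNA breakpoint analysis

### Segmentation

The fused-lasso signal approximator decomposes into an exact 1-D
total-variation fit (Condat's direct non-iterative algorithm, O(n)
typical) plus a sparsity soft-threshold that sets neutral probes to
exactly 0. The two penalties are deliberately decoupled:

* **Fusion penalty** λ = σ̂·√(2 ln n), with σ̂ the robust noise scale from
  the median absolute first difference. This universal-threshold analogue
  suppresses spurious change-points while biasing a length-L segment's
  level by only ~2λ/L (≈ 0.01 log2 units for a 120-probe CNA at σ = 0.15).
* **Sparsity threshold** calibrated per chromosome as the (1 − FDR)
  quantile of |TV fit| over 20 within-chromosome permutations of the probe
  ratios — the smallest threshold whose expected fraction of probes called
  non-neutral under the spatially-scrambled null is ≤ FDR (default 1%).

Tying the two to a single grid-searched penalty was tried first and
rejected: on signal-rich tracks the permutation null retains the elevated
marginal distribution, forcing the common penalty high enough that the
double shrinkage clipped CNA boundaries by >10 probes. Known limitation of
the permutation calibration: a whole-chromosome constant offset is
indistinguishable from neutral under within-chromosome permutation and is
shrunk away; copy-number inputs are assumed centered on diploid.

The fit is verified in the test suite against an independent exact route —
the dual box-constrained quadratic program solved by BVLS — to 10⁻⁸.

### Copy-number smoothing

Segmentation overcalls transitions; smoothing walks each chromosome to
keep only well-defined CNAs and refine their boundaries. A candidate CNA
is a maximal same-sign non-zero run of the fitted values; it is accepted
when its raw-ratio mean and length pass either gate (|log2| ≥ θ = 0.3 over
≥ 50 probes, or |log2| ≥ 1.0 over ≥ 10 probes — high-level events are
short and bright). The lower boundary is the first probe p that

1. itself reads as non-CNA — fitted value 0, opposite sign, or level
   shifted from the running CNA mean by ≥ θ (fitted values are local
   averages, so a per-probe level shift *is* an "average log2 ratio
   change"), **and**
2. is confirmed by a look-ahead vote: ≥ 95% of the fitted values in the
   window starting at p (100 probes; 50 for high-level CNAs) are neutral,
   sign-flipped, or — evaluated window-wise — have a window mean differing
   from the CNA mean by ≥ θ.

Requiring the boundary probe itself to fail membership (condition 1) is
what keeps clean boundaries exact: the 95% vote alone fires up to 5 probes
early whenever the window merely straddles the true boundary. The segment
mean is then recomputed from the raw ratios over [upper, lower), the
gates re-checked, and the scan resumes at the lower boundary (the walk can
legitimately stop inside a run at a ≥ θ level shift, splitting it).
`level_change_mode="probe"` switches criterion 3 in the vote to per-probe
evaluation for users who prefer the stricter reading.

### Intragenic breakpoints and orientation

Each segment boundary strictly inside a gene's genomic span becomes a
breakpoint call, annotated with which transcript end of the gene the
alteration covers. The orientation filter encodes how known fusions
present in copy number: a 3′-partner gene must show amplification of its
3′ end or deletion of its 5′ end (the mirror image for 5′ partners;
`either` passes both). Focality (default: segment < 1,000 probes) is
reported for prioritization only, never used for exclusion — "focal" has
no canonical size, so the cap is configurable and carried on every call.

## Fusion nomination

Inputs are any SAM/BAM with mate information; reads with an NM tag above 2
are treated as unmapped (re-alignment is out of scope; when NM is absent
the mismatch rule is skipped). Readthrough filtering removes same-strand
pairs with no intervening annotated gene — same-strand genes ~1 Mb apart
with genes between them are genuine fusion candidates and survive.

Chimeric rescue builds, for every ordered exon pair of the nominated
genes, the junction string of read-length−1 nt on each side, and slides
each unmapped read ungapped across every offset covering ≥ 1 nt of both
sides, in both orientations; a hit needs ≤ 2 mismatches, and the best
(fewest mismatches, lowest exon pair on ties) junction per read is kept.
Reads longer than the available context are evaluated truncated and
flagged. The junction estimate is the modal chimeric junction when rescue
succeeded, else the nearest exon boundaries compatible with all
supporting pairs. The predicted fragment length of a pair is computed in
fusion-transcript coordinates (distance of each read's inner end to the
junction plus both read lengths); candidates need a median in [100, 400]
nt — the paired-end library's size-selection window — and ≥ 2 supporting
reads, with discordant pairs and rescued chimeric reads pooled.

Which gene is the 5′ partner is resolved by trying both orientations and
keeping the one with more rescued chimeric reads, then higher support,
then median insert closest to 300 nt (deterministic). Frame prediction:
the fusion preserves the 3′ gene's reading frame iff the coding length
contributed by the 5′ gene is congruent mod 3 to the junction's offset
within the 3′ gene's codon structure; junctions in either UTR return
"unknown" (a junction upstream of the 3′ start codon is annotated
"internal ATG possible"). Only exon-boundary junctions in the annotated
orientation are attempted; intra-gene events (EGFRvIII-style exon1–exon8
junctions) are exposed via `allow_intragenic`.

## Supervised signature

A gene passes when its expression (log2) correlates with the binary class
at |R| ≥ 0.5, differs by a two-tailed pooled t-test at P < 0.001, and
shows ≥ 2-fold class-mean difference (2^|Δmean|). The FDR is the *global*
estimator: mean pass count over label permutations (class sizes preserved,
seeded) divided by the observed pass count, capped at 1; with zero
discoveries it is reported as 0 by convention. A per-gene estimator would
need far more permutations for the same stability at these stringent
thresholds.

## Synthetic data: what a green test establishes

The generator plants ground truth in all three modalities: i.i.d. normal
exon baselines with an additive step distal to a chosen junction;
piecewise-constant copy-number means with Gaussian probe noise on an even
probe grid; and paired-end fragments from chimeric transcripts with
Gaussian insert lengths, uniform-random genomes (exons 100–300 nt, 8–20
per gene), per-base substitution errors and constant quality strings.
Junction-overlapping reads are written unmapped to exercise rescue.
Everything is a pure function of the seed (byte-identical re-runs).

Deliberate simplifications: synthetic genes are intronless (exons abut, so
genomic and transcript coordinates coincide and SAM records stay `<len>M`);
there is no alternative splicing, no probe-affinity or GC structure, no
platform-specific probe spacing, and background reads are concordant only.
A green recovery test therefore establishes the statistical machinery —
test calibration, boundary placement, filter logic, junction arithmetic —
not robustness to alignment artifacts, splice isoforms or array batch
effects, which real data will add.

Default planted-event parameters mirror the regimes the pipeline is meant
for: expression steps of ~2 log2 units over 0.3-sd exon noise, CNAs of 0.8
(standard) or ≥ 1.0 (high-level) log2 over 0.15-sd probe noise, fusion
libraries of 10–100 pairs with 200–350 nt inserts and 1% base error —
values typical of exon arrays, SNP-array log2 ratios and early paired-end
RNA-seq respectively.
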